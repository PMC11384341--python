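wavelength_nm,value
500.0,9.0
520.0,8.0
540.0,7.2
560.0,6.5
580.0,5.9
600.0,5.3
650.0,4.0
700.0,3.0
750.0,2.3
800.0,1.8
850.0,1.4
900.0,1.1
910.0,1.05
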