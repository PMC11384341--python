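wavelength_nm,value
500.0,10.0
510.0,10.6
520.0,11.0
530.0,11.2
540.0,10.8
550.0,10.0
560.0,9.0
570.0,8.0
580.0,7.1
600.0,5.6
650.0,3.8
700.0,2.7
750.0,2.0
800.0,1.5
850.0,1.15
900.0,0.9
910.0,0.87
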