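wavelength_nm,value
500.0,11.0
520.0,9.0
540.0,7.6
560.0,6.5
580.0,5.6
600.0,4.8
620.0,4.1
640.0,3.6
660.0,3.2
680.0,2.9
700.0,2.7
720.0,2.6
740.0,2.6
760.0,2.7
780.0,2.9
800.0,3.1
820.0,3.25
830.0,3.3
840.0,3.28
860.0,3.1
880.0,2.8
900.0,2.4
910.0,2.2
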