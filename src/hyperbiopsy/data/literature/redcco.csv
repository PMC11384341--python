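wavelength_nm,value
500.0,13.0
520.0,11.0
540.0,10.0
560.0,9.5
580.0,9.0
590.0,10.5
595.0,13.0
600.0,18.0
605.0,21.5
610.0,18.0
615.0,12.0
620.0,8.0
640.0,4.5
660.0,3.3
680.0,2.6
700.0,2.2
720.0,1.9
740.0,1.7
760.0,1.55
780.0,1.45
800.0,1.4
820.0,1.35
840.0,1.3
860.0,1.25
880.0,1.2
900.0,1.15
910.0,1.13
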