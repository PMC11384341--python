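wavelength_nm,value
500.0,0.0065
550.0,0.0045
600.0,0.0035
650.0,0.003
700.0,0.0055
720.0,0.008
740.0,0.0085
750.0,0.0075
760.0,0.0068
780.0,0.0058
800.0,0.0055
820.0,0.006
840.0,0.0075
860.0,0.009
880.0,0.011
900.0,0.014
910.0,0.018
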