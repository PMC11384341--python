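wavelength_nm,value
500.0,0.00025
520.0,0.00041
540.0,0.00047
550.0,0.00045
560.0,0.00062
580.0,0.0009
600.0,0.0022
620.0,0.0028
640.0,0.0031
650.0,0.0034
660.0,0.0039
680.0,0.0047
700.0,0.006
710.0,0.0085
720.0,0.0115
730.0,0.017
740.0,0.0236
750.0,0.026
760.0,0.0255
770.0,0.0247
780.0,0.0236
790.0,0.0227
800.0,0.0223
810.0,0.025
820.0,0.0279
830.0,0.0312
840.0,0.0364
850.0,0.0415
860.0,0.0457
870.0,0.0507
880.0,0.0561
890.0,0.0617
900.0,0.0679
910.0,0.0745
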