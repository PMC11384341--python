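wavelength_nm,value
500.0,20.93
505.0,20.2
510.0,20.04
515.0,21.7
520.0,24.2
525.0,30.0
530.0,39.3
535.0,48.0
540.0,53.24
545.0,51.0
550.0,43.02
555.0,36.0
560.0,32.61
565.0,35.2
570.0,44.5
575.0,54.43
580.0,50.1
585.0,37.0
590.0,17.0
595.0,7.0
600.0,3.2
610.0,1.506
620.0,0.942
630.0,0.61
640.0,0.442
650.0,0.368
660.0,0.32
670.0,0.294
680.0,0.278
690.0,0.276
700.0,0.29
710.0,0.314
720.0,0.348
730.0,0.39
740.0,0.446
750.0,0.518
760.0,0.586
770.0,0.65
780.0,0.71
790.0,0.766
800.0,0.816
810.0,0.864
820.0,0.908
830.0,0.95
840.0,0.994
850.0,1.058
860.0,1.094
870.0,1.128
880.0,1.154
890.0,1.178
900.0,1.198
910.0,1.216
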