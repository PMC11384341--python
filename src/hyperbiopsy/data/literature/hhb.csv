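wavelength_nm,value
500.0,20.86
505.0,22.5
510.0,25.77
515.0,28.6
520.0,31.59
525.0,35.2
530.0,39.04
535.0,43.0
540.0,46.59
545.0,50.0
550.0,53.41
555.0,53.79
560.0,53.29
565.0,51.0
570.0,45.07
575.0,40.0
580.0,37.02
585.0,29.0
590.0,24.0
595.0,19.0
600.0,14.68
610.0,9.44
620.0,6.51
630.0,5.15
640.0,4.35
650.0,3.75
660.0,3.23
670.0,2.8
680.0,2.41
690.0,2.05
700.0,1.794
710.0,1.54
720.0,1.3
730.0,1.102
740.0,1.2
750.0,1.405
755.0,1.5
760.0,1.549
765.0,1.45
770.0,1.312
780.0,1.075
790.0,0.89
800.0,0.762
810.0,0.718
820.0,0.693
830.0,0.685
840.0,0.68
850.0,0.691
860.0,0.7
870.0,0.72
880.0,0.736
890.0,0.75
900.0,0.762
910.0,0.776
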