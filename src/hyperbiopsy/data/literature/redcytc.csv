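wavelength_nm,value
500.0,9.0
510.0,10.5
515.0,12.0
520.0,14.7
525.0,13.0
530.0,10.5
535.0,9.5
540.0,11.0
545.0,17.0
550.0,29.0
555.0,15.0
560.0,7.5
565.0,5.0
570.0,4.0
580.0,3.2
600.0,2.4
650.0,1.4
700.0,0.95
750.0,0.7
800.0,0.55
850.0,0.45
900.0,0.38
910.0,0.37
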