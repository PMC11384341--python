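wavelength_nm,value
500.0,8.0
510.0,8.5
520.0,9.5
525.0,10.5
530.0,11.8
535.0,11.5
540.0,10.0
545.0,9.0
550.0,10.0
555.0,14.0
560.0,23.0
562.0,25.0
565.0,20.0
570.0,10.0
575.0,5.5
580.0,4.0
600.0,2.5
650.0,1.2
700.0,0.8
750.0,0.6
800.0,0.5
850.0,0.4
900.0,0.35
910.0,0.34
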