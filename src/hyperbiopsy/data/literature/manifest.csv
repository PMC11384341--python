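name,unit_kind,path
HbO2,molar_extinction,hbo2.csv
HHb,molar_extinction,hhb.csv
oxCCO,molar_extinction,oxcco.csv
redCCO,molar_extinction,redcco.csv
redCytB,molar_extinction,redcytb.csv
oxCytB,molar_extinction,oxcytb.csv
redCytC,molar_extinction,redcytc.csv
oxCytC,molar_extinction,oxcytc.csv
water,absorption_coefficient,water.csv
lipid,absorption_coefficient,lipid.csv
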