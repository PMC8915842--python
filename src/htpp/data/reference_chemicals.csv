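chemical,group,min_uM,max_uM
"5,8,11-Eicosatriynoic acid",test,0.0833,250
Actinomycin D,test,3.33E-04,1
Amiodarone hydrochloride,test,0.0333,100
Amperozide,test,0.0333,100
Aphidicolin,test,0.00333,10
Bafilomycin A1,test,1.67E-04,0.5
Berberine chloride,test,0.0333,100
Ca-074-Me,test,0.001,3
Cladribine,test,0.0333,100
Cucurbitacin I,test,3.33E-04,1
Cycloheximide,test,0.0333,100
Cytarabine,test,0.00333,10
Docetaxel,test,3.33E-05,0.1
Ethoxyquin,test,0.0333,100
Etoposide,test,0.00333,10
Exo-1,test,0.1,300
FCCP,test,0.0333,100
Fluazinam,test,0.0333,100
Lys05,test,0.0333,100
Rapamycin,test,0.00333,10
Saccharin,negative,0.0333,100
Sorbitol,negative,0.0333,100
Staurosporine,viability_control,1.00E-04,10
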