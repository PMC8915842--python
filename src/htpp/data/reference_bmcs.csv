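chemical,cv_bmc,pp_bmc,ratio
"5,8,11-Eicosatriynoic acid",1.42E+02,9.74E+00,14.6
Actinomycin D,4.96E-05,—,—
Amiodarone hydrochloride,3.92E+00,6.12E-01,6.4
Amperozide,>100,2.97E+00,—
Aphidicolin,>10,5.35E-02,—
Bafilomycin A1,1.60E-02,2.46E-03,6.5
Berberine chloride,3.05E+01,1.68E+00,18.2
Ca-074-Me,>3,5.42E-02,—
Cladribine,4.65E-01,1.05E-02,44.3
Cucurbitacin I,5.76E-02,3.24E-04,177.8
Cycloheximide,9.10E-01,3.24E-02,28.1
Cytarabine,5.14E-01,1.48E-03,347.3
Docetaxel,8.94E-04,6.76E-04,1.3
Ethoxyquin,>100,1.00E+01,—
Etoposide,5.52E-01,2.51E-01,2.2
Exo-1,>300,>300,—
FCCP,2.72E+00,4.76E-01,5.7
Fluazinam,8.56E-01,2.95E-01,2.9
Lys05,1.60E+00,7.89E-01,2.0
Rapamycin,5.43E+00,1.05E-03,5171.4
Saccharin (negative),>100,>100,—
Sorbitol (negative),>100,>100,—
Staurosporine (positive),7.13E-02,3.89E-03,18.3
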