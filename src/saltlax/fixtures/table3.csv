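indicator,CK,S,S+La0.25,S+La0.5,S+La0.75,S+La1.0
root biomass,0.1,0.1,0.1,0.1,0.1,0.1
stem-leaf biomass,0.1,0.1,0.1,0.1,0.1,0.1
R-S,0.1,0.2,0.2,0.2,0.2,0.2
TL,1.0,0.9,1.0,0.9,0.9,0.9
MTD,0.6,0.5,0.5,0.5,0.5,0.6
TRL,24.1,23.0,28.1,29.4,30.0,25.8
AD,0.0,0.0,0.1,0.0,0.0,0.0
RV,0.1,0.1,0.0,0.1,0.1,0.1
Tips,73.8,75.2,70.0,68.7,68.1,72.3
SLA,4.1,5.0,4.9,4.9,5.6,5.1
Chl,8.3,9.5,9.5,9.9,8.9,7.7
Pn,3.4,2.9,3.4,3.1,2.9,2.8
Gs,24.7,22.7,22.4,23.1,22.5,16.9
Ci,58.5,59.5,59.4,58.6,59.5,66.9
Tr,1.0,0.5,0.5,0.5,0.6,0.6
L-SOD,2.5,4.3,5.8,8.0,10.8,5.5
R-SOD,2.1,2.5,4.6,5.0,6.8,1.6
L-POD,44.5,37.1,34.6,36.5,31.3,47.9
R-POD,17.3,22.3,17.3,19.4,20.3,26.9
L-CAT,22.9,21.8,24.7,21.4,21.3,10.9
R-CAT,10.5,11.6,12.9,9.6,9.3,6.9
L-MDA,0.1,0.2,0.0,0.1,0.1,0.2
R-MDA,0.1,0.1,0.0,0.1,0.1,0.1
glycyrrhizic acid,57.7,57.9,57.7,50.7,53.7,69.2
glycyrrhetinic acid,1.8,2.2,2.0,2.1,2.7,2.0
liquiritin,31.2,32.3,32.6,37.9,34.1,21.8
liquiritigenin,6.9,6.1,6.0,7.4,7.6,5.7
isoliquiritigenin,2.4,1.5,1.7,1.8,2.0,1.3
total flavonoids,0.0,0.0,0.0,0.0,0.0,0.0
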