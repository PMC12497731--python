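treatment,indicator,mean,sd
CK,glycyrrhizic acid,3.1,0.8
CK,glycyrrhetinic acid,87.3,4.1
CK,liquiritin,1.6,0.4
CK,liquiritigenin,325.7,4.7
CK,isoliquiritigenin,114.9,13.7
CK,total flavonoids,1.5,0.2
S,glycyrrhizic acid,2.6,0.5
S,glycyrrhetinic acid,85.6,4.0
S,liquiritin,1.2,0.2
S,liquiritigenin,228.9,12.5
S,isoliquiritigenin,58.6,9.3
S,total flavonoids,1.2,0.1
S+La0.25,glycyrrhizic acid,2.9,0.5
S+La0.25,glycyrrhetinic acid,101.3,6.0
S+La0.25,liquiritin,1.5,0.3
S+La0.25,liquiritigenin,321.4,11.4
S+La0.25,isoliquiritigenin,79.3,7.7
S+La0.25,total flavonoids,1.4,0.1
S+La0.5,glycyrrhizic acid,4.0,0.2
S+La0.5,glycyrrhetinic acid,161.1,6.4
S+La0.5,liquiritin,2.4,0.3
S+La0.5,liquiritigenin,518.8,37.6
S+La0.5,isoliquiritigenin,127.3,5.8
S+La0.5,total flavonoids,2.0,0.2
S+La0.75,glycyrrhizic acid,5.1,0.4
S+La0.75,glycyrrhetinic acid,199.4,3.1
S+La0.75,liquiritin,3.0,0.6
S+La0.75,liquiritigenin,644.5,51.9
S+La0.75,isoliquiritigenin,156.1,18.3
S+La0.75,total flavonoids,2.4,0.4
S+La1.0,glycyrrhizic acid,2.2,0.5
S+La1.0,glycyrrhetinic acid,69.8,3.2
S+La1.0,liquiritin,0.8,0.1
S+La1.0,liquiritigenin,202.0,7.6
S+La1.0,isoliquiritigenin,40.6,3.0
S+La1.0,total flavonoids,1.1,0.1
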