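treatment,indicator,mean,sd
CK,SLA,13.8,0.5
CK,Chl,26.6,1.4
CK,Pn,10.9,0.7
CK,Gs,71.9,5.0
CK,Ci,194.1,16.6
CK,Tr,3.3,0.2
S,SLA,11.0,0.6
S,Chl,24.2,0.1
S,Pn,6.3,0.2
S,Gs,52.2,1.7
S,Ci,148.3,6.3
S,Tr,1.4,0.1
S+La0.25,SLA,16.5,0.1
S+La0.25,Chl,28.4,0.3
S+La0.25,Pn,8.0,0.9
S+La0.25,Gs,63.3,2.4
S+La0.25,Ci,191.3,13.7
S+La0.25,Tr,1.5,0.1
S+La0.5,SLA,17.2,0.3
S+La0.5,Chl,30.8,0.7
S+La0.5,Pn,9.2,1.0
S+La0.5,Gs,67.9,3.7
S+La0.5,Ci,186.5,1.2
S+La0.5,Tr,1.6,0.1
S+La0.75,SLA,18.6,0.1
S+La0.75,Chl,35.7,0.6
S+La0.75,Pn,10.1,0.9
S+La0.75,Gs,70.5,3.4
S+La0.75,Ci,208.9,18.5
S+La0.75,Tr,2.1,0.1
S+La1.0,SLA,13.7,0.3
S+La1.0,Chl,25.6,0.3
S+La1.0,Pn,8.4,1.0
S+La1.0,Gs,56.4,4.2
S+La1.0,Ci,178.3,11.5
S+La1.0,Tr,1.5,0.1
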