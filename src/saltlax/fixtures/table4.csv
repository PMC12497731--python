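treatment,replicate,antioxidant,photosynthesis,growth,pharmacological
CK,1,470.7,134.5,740.4,1421.1
CK,2,441.8,146.1,729.2,1442.1
CK,3,472.6,138.6,690.8,1389.1
CK,4,480.6,131.1,685.1,1295.8
CK,5,456.0,125.9,750.6,1471.9
S,1,208.7,103.0,675.9,1327.5
S,2,204.9,103.5,659.4,1208.4
S,3,215.4,100.7,685.4,1358.9
S,4,209.0,102.5,640.7,1256.5
S,5,203.2,96.3,697.6,1335.6
S+La0.25,1,428.9,131.5,739.0,1424.1
S+La0.25,2,466.7,122.2,707.3,1493.2
S+La0.25,3,423.2,132.9,718.0,1451.9
S+La0.25,4,406.8,141.5,745.3,1422.9
S+La0.25,5,433.2,136.2,728.3,1460.3
S+La0.5,1,384.6,129.1,805.2,1491.0
S+La0.5,2,402.2,131.4,851.8,1549.4
S+La0.5,3,383.8,139.6,791.7,1467.0
S+La0.5,4,361.1,131.9,767.6,1585.1
S+La0.5,5,390.5,134.1,797.5,1450.3
S+La0.75,1,435.9,144.8,881.5,1645.4
S+La0.75,2,432.6,135.0,880.5,1714.8
S+La0.75,3,425.6,144.3,960.2,1522.2
S+La0.75,4,420.7,138.9,908.7,1684.3
S+La0.75,5,436.1,150.3,870.2,1606.6
S+La1.0,1,262.8,131.8,670.7,1284.1
S+La1.0,2,249.6,105.9,741.2,1219.6
S+La1.0,3,236.8,130.8,672.3,1231.9
S+La1.0,4,262.9,126.7,655.4,1385.2
S+La1.0,5,263.2,119.0,807.0,1319.2
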