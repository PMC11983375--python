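name,lipid_class,formula,prior
PI 38:4,PI,C47H83O13P,1
PI 36:4,PI,C45H79O13P,1
PS 38:3,PS,C44H80NO10P,1
PS 38:4,PS,C44H78NO10P,1
PS 36:1,PS,C42H80NO10P,1
PE 38:4,PE,C43H78NO8P,1
PE O-38:5,PE-O,C43H78NO7P,1
PA 40:5,PA,C43H75O8P,1
PE 36:4,PE,C41H74NO8P,1
PE O-36:5,PE-O,C41H74NO7P,1
LPI 20:4,LPI,C29H49O12P,1
LPI 18:0,LPI,C27H53O12P,1
NeuAcHex2Cer 34:1;O2,NeuAcHex2Cer,C57H104N2O21,1
SHex2Cer 42:2,SHex2Cer,C54H101NO16S,1
PI 40:3,PI,C49H89O13P,1
PI 40:4,PI,C49H87O13P,1
PI 40:6,PI,C49H83O13P,1
PI 38:2,PI,C47H87O13P,1
PI 38:3,PI,C47H85O13P,1
PI 36:1,PI,C45H85O13P,1
PI 36:2,PI,C45H83O13P,1
PI 36:3,PI,C45H81O13P,1
PI 34:1,PI,C43H81O13P,1
PS 36:2,PS,C42H78NO10P,1
PG 36:1,PG,C42H81O10P,1
PG 36:2,PG,C42H79O10P,1
PG 34:1,PG,C40H77O10P,1
PE 36:1,PE,C41H80NO8P,1
PE 36:2,PE,C41H78NO8P,1
PE 36:3,PE,C41H76NO8P,1
PE 34:1,PE,C39H76NO8P,1
PE 34:2,PE,C39H74NO8P,1
SHex2Cer 44:2,SHex2Cer,C56H105NO16S,1
SHex2Cer 42:1,SHex2Cer,C54H103NO16S,1
SHex2Cer 42:3,SHex2Cer,C54H99NO16S,1
SHex2Cer 40:1,SHex2Cer,C52H99NO16S,1
SHex2Cer 38:1,SHex2Cer,C50H95NO16S,1
SHex2Cer 36:1,SHex2Cer,C48H91NO16S,1
SHex2Cer 34:1,SHex2Cer,C46H87NO16S,1
SHexCer 42:1;OH,SHexCer,C48H93NO12S,1
SHexCer 42:2;OH,SHexCer,C48H91NO12S,1
SHexCer 41:1;OH,SHexCer,C47H91NO12S,1
SHexCer 42:1,SHexCer,C48H93NO11S,1
SHexCer 40:1;OH,SHexCer,C46H89NO12S,1
PE O-40:5,PE-O,C45H82NO7P,1
PE O-40:7,PE-O,C45H78NO7P,1
PI 40:5,PI,C49H85O13P,1
PS 40:5,PS,C46H80NO10P,1
PS 40:6,PS,C46H78NO10P,1
SM 42:2,SM,C47H93N2O6P,1
SM 34:1,SM,C39H79N2O6P,1
PE O-36:2,PE-O,C41H80NO7P,1
PA 38:4,PA,C41H73O8P,1
PA O-38:1,PA-O,C41H81O7P,1
PE O-34:1,PE-O,C39H78NO7P,1
PE O-34:2,PE-O,C39H76NO7P,1
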