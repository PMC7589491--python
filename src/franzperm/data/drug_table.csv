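name,bcs_class,fa_percent,papp_franz,papp_nonsink,papp_caco2,papp_corti,papp_pampa74,papp_permeapad,log_p,log_d,pka,intrinsic_solubility,actively_transported,hp_literature
metoprolol,I,95,15.8,59.0,23.7,48.1,3.5,1.0,1.9,-0.2,9.6,1000.0,False,True
caffeine,I,100,36.2,53.3,30.8,41.1,10.8,20.4,-0.1,0.02,0.6,21.17,False,True
propranolol,I,93,33.1,88.4,41.9,39.7,23.5,,2.65,1.3,9.5,33.0,False,True
theophylline,I,97,22.1,,25.0,40.5,,7.2,-0.25,-0.05,0.6;8.55,8.33,False,True
carbamazepine,II,100,5.97,,,,11.3,,2.5,1.8,1.0;13.9,0.12,False,False
diclofenac,II,100,68.1,104.9,,,12.5,,4.4,1.2,3.99,0.001,False,True
ibuprofen,II,93,57.5,36.0,52.5,,6.8,16.6,3.1,0.7,4.9,0.01,False,True
ketoprofen,II,100,12.1,,20.1,42.7,16.7,,3.3,-1.51,4.5,0.051,True,False
naproxen,II,98,2.89,1.7,39.5,48.8,10.6,,3.2,0.2,4.2,33.0,False,True
piroxicam,II,100,11.0,9.6,35.6,,8.2,,2.0,-0.07,2.33;5.1,0.11,False,False
verapamil,II,98,5.39,5.0,15.8,41.6,7.4,9.3,3.8,2.7,8.9,0.44,True,False
atenolol,III,52,25.8,22.0,0.2,20.9,0.0,4.3,0.2,,9.6,26.5,False,True
cimetidine,III,93,35.6,31.0,0.7,,0.0,,0.4,0.4,6.8,6.0,False,True
methyldopa,III,41,,,0.2,3.2,,,0.4,,1.7;9.9,10.0,False,False
ranitidine,III,55,6.81,5.3,0.5,21.5,0.5,,0.3,-0.3,2.1;8.1,100.0,True,False
trimethoprim,III,97,6.61,7.7,83.0,45.5,5.0,,0.9,0.7,7.1,0.4,True,False
acyclovir,IV,21,0.40,0.4,0.3,9.1,0.0,7.9,-1.7,-1.7,2.3;9.3,10.0,False,False
amoxicillin,IV,93,0.85,0.07,0.8,,1.5,,0.9,,3.2;11.7,4.0,False,False
furosemide,IV,60,4.57,4.5,0.1,27.5,0.6,,2.3,-0.7,3.5;10.6,0.01,False,False
hydrochlorothiazide,IV,70,2.74,2.7,0.5,31.0,0.1,,-0.1,-0.1,7.9,1.0,False,False
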