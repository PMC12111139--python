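drug_code,drug_name,drug_class,default_units_per_day,min_antidepressant_dose_mg,ddd_mg
MPH-IR,methylphenidate,MPH,1,,30
MPH-LA,methylphenidate extended-release,MPH,1,,30
ATX-40,atomoxetine,ATX,1,,80
FLZ-05,flumazenil,FLUMAZENIL,1,,
AMI-25,amitriptyline,AD_TCA,1,75,75
IMI-25,imipramine,AD_TCA,1,75,100
CLO-25,clomipramine,AD_TCA,1,75,100
FLX-20,fluoxetine,AD_SSRI,1,20,20
SER-50,sertraline,AD_SSRI,1,50,50
CIT-20,citalopram,AD_SSRI,1,20,20
ESC-10,escitalopram,AD_SSRI,1,10,10
VEN-75,venlafaxine,AD_OTHER,1,75,100
BUP-150,bupropion,AD_OTHER,1,150,300
MIR-15,mirtazapine,AD_OTHER,1,15,30
AGO-25,agomelatine,AD_OTHER,1,25,25
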