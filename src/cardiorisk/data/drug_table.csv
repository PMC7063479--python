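name,ic50_cal_nM,ic50_kr_nM,cmax_nM
ajmaline,71000,1040,900
amiodarone,270,30,0.3
bepridil,211,33,21.5
chlorpromazine,NA,1470,20.5
cibenzoline,30000,22600,739
cisapride,NA,6.5,3.8
diltiazem,450,17300,87.5
dofetilide,60000,5,1.2
fluvoxamine,4900,3100,196
haloperidol,1700,27,2.4
mexiletine,100000,50000,2787
nifedipine,60,275000,5.4
nitrendipine,0.31,10000,1.6
phenytoin,103000,100000,4250
pimozide,162,20,0.6
prenylamine,1240,65,13
propranolol,18000,2828,19
quinidine,15600,300,2080.5
sertindole,8900,14,0.8
tedisamil,NA,2500,80
terfenadine,375,8.9,4.5
thioridazine,1300,33,593.5
verapamil,100,143,53
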