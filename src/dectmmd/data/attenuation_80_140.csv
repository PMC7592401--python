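name,density_g_cm3,mu_low_cm1,mu_high_cm1,group
air,0.0012,0.000237,0.000209,default
water,1.0000,0.222165,0.194703,default
blood,1.0600,0.231822,0.203907,default
fat,0.9200,0.191536,0.173297,default
bone,1.9200,0.608135,0.449335,default
lexan,1.2000,0.236673,0.214290,default
acrylic,1.1900,0.242815,0.218666,default
teflon,2.1600,0.444607,0.380436,default
koh_solid,2.0440,0.841774,0.567395,solute
iodine,4.9330,29.515775,14.157369,solute
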