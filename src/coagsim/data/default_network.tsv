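# coagsim parameter table
version	coagsim-default-1.0
species	TF	cofactor	0.0	0.0	0
species	CA	cofactor	0.0	0.0	0
species	VII	zymogen	10.0	0.139	1
species	TF_VIIa	complex	0.0	1.0	0
species	X	zymogen	170.0	0.017	1
species	Xa	active	0.0	15.0	0
species	V	zymogen	20.0	0.046	0
species	Va	active	0.0	10.0	0
species	Xa_Va	complex	0.0	10.0	0
species	II	zymogen	1400.0	0.0107	1
species	IIa	active	0.0	40.0	0
species	Fg	fibrin-related	3600.0	0.007	0
species	Fbn	fibrin-related	0.0	0.0	0
species	XFbn	fibrin-related	0.0	0.0	0
species	VIII	zymogen	0.7	0.058	0
species	VIIIa	active	0.0	20.0	0
species	IX	zymogen	90.0	0.029	1
species	IXa	active	0.0	2.0	0
species	VIIIa_IXa	complex	0.0	20.0	0
species	XI	zymogen	30.0	0.014	0
species	XIa	active	0.0	3.0	0
species	XII	zymogen	375.0	0.0116	0
species	XIIa	active	0.0	3.0	0
species	XIII	zymogen	70.0	0.0046	0
species	XIIIa	active	0.0	2.0	0
species	PC	zymogen	60.0	0.087	1
species	APC	active	0.0	1.8	0
species	PS	cofactor	300.0	0.0165	1
species	APC_PS	complex	0.0	2.0	0
species	Va_i	active	0.0	1.0	0
species	VIIIa_i	active	0.0	1.0	0
species	VK	vitamin	100.0	0.002	0
species	VKO	vitamin	10.0	0.02	0
reaction	complex_formation	.	TF	VII	TF_VIIa	0.0	.	0.05
reaction	mm_activation	TF_VIIa	X	.	Xa	0.045	240.0	.
reaction	mm_activation	TF_VIIa	IX	.	IXa	0.34	240.0	.
reaction	mm_activation	Xa	V	.	Va	0.2	70.0	.
reaction	mm_activation	IIa	V	.	Va	2.0	140.0	.
reaction	mm_activation	IIa	VIII	.	VIIIa	0.9	110.0	.
reaction	complex_formation	.	VIIIa	IXa	VIIIa_IXa	0.0	.	0.01
reaction	mm_activation	VIIIa_IXa	X	.	Xa	6.0	160.0	.
reaction	complex_formation	.	Xa	Va	Xa_Va	0.0	.	0.04
reaction	mm_activation	Xa_Va	II	.	IIa	30.0	300.0	.
reaction	mm_activation	Xa	II	.	IIa	0.005	300.0	.
reaction	mm_activation	IXa	X	.	Xa	0.01	160.0	.
reaction	mm_activation	IIa	Fg	.	Fbn	84.0	7200.0	.
reaction	mm_activation	IIa	XIII	.	XIIIa	0.1	70.0	.
reaction	mm_activation	XIIIa	Fbn	.	XFbn	0.02	2000.0	.
reaction	mm_activation	CA	XII	.	XIIa	0.05	500.0	.
reaction	mm_activation	XIIa	XI	.	XIa	0.05	200.0	.
reaction	mm_activation	XIa	IX	.	IXa	0.15	200.0	.
reaction	mm_activation	IIa	PC	.	APC	0.05	60.0	.
reaction	complex_formation	.	APC	PS	APC_PS	0.0	.	0.005
reaction	mm_activation	APC_PS	Va	.	Va_i	0.2	140.0	.
reaction	mm_activation	APC_PS	VIIIa	.	VIIIa_i	0.2	110.0	.
reaction	first_order	.	VKO	.	VK	0.0	.	0.00025
reaction	first_order	.	VK	.	VKO	0.0	.	2.5e-05
param	warfarin_imax	1.0
param	warfarin_ic50	140.0
param	rivaroxaban_ki	7.4
param	vk_normal	100.0
param	vk_km	80.0
param	vk_species	VK
param	vko_species	VKO
param	fibrin_species	Fbn
param	fibrinogen_species	Fg
param	xa_catalysts	Xa,Xa_Va
pk	warfarin	0.2	10.0	0.9	1.0	308.33
pk	rivaroxaban	6.0	50.0	0.8	1.0	435.88
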