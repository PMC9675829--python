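synonym	molecule	atc_codes
metformin	metformin	A10BA02
metformin hcl	metformin	A10BA02
glucophage	metformin	A10BA02
insulin human	insulin human	A10AB01
insulin	insulin human	A10AB01
humulin	insulin human	A10AB01
insulin glargine	insulin glargine	A10AE04
lantus	insulin glargine	A10AE04
glibenclamide	glibenclamide	A10BB01
glyburide	glibenclamide	A10BB01
gliclazide	gliclazide	A10BB09
glimepiride	glimepiride	A10BB12
sitagliptin	sitagliptin	A10BH01
januvia	sitagliptin	A10BH01
vildagliptin	vildagliptin	A10BH02
pioglitazone	pioglitazone	A10BG03
empagliflozin	empagliflozin	A10BK03
dapagliflozin	dapagliflozin	A10BK01
liraglutide	liraglutide	A10BJ02
atorvastatin	atorvastatin	C10AA05
lipitor	atorvastatin	C10AA05
simvastatin	simvastatin	C10AA01
rosuvastatin	rosuvastatin	C10AA07
crestor	rosuvastatin	C10AA07
fenofibrate	fenofibrate	C10AB05
atenolol	atenolol	C07AB03
bisoprolol	bisoprolol	C07AB07
metoprolol	metoprolol	C07AB02
carvedilol	carvedilol	C07AG02
lisinopril	lisinopril	C09AA03
perindopril	perindopril	C09AA04
ramipril	ramipril	C09AA05
losartan	losartan	C09CA01
valsartan	valsartan	C09CA03
telmisartan	telmisartan	C09CA07
amlodipine	amlodipine	C08CA01
acetylsalicylic acid	acetylsalicylic acid	B01AC06;N02BA01
aspirin	acetylsalicylic acid	B01AC06;N02BA01
clopidogrel	clopidogrel	B01AC04
plavix	clopidogrel	B01AC04
warfarin	warfarin	B01AA03
paracetamol	paracetamol	N02BE01
acetaminophen	paracetamol	N02BE01
panadol	paracetamol	N02BE01
tramadol	tramadol	N02AX02
ibuprofen	ibuprofen	M01AE01
brufen	ibuprofen	M01AE01
diclofenac	diclofenac	M01AB05
voltaren	diclofenac	M01AB05
naproxen	naproxen	M01AE02
celecoxib	celecoxib	M01AH01
omeprazole	omeprazole	A02BC01
esomeprazole	esomeprazole	A02BC05
nexium	esomeprazole	A02BC05
sodium fluoride	sodium fluoride	A01AA01
chlorhexidine	chlorhexidine	A01AB03
sertraline	sertraline	N06AB06
escitalopram	escitalopram	N06AB10
fluoxetine	fluoxetine	N06AB03
amitriptyline	amitriptyline	N06AA09
levothyroxine	levothyroxine	H03AA01
cholecalciferol	cholecalciferol	A11CC05
vitamin d3	cholecalciferol	A11CC05
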