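the	23135851162
of	13151942776
and	12997637966
to	12136980858
a	9081174698
in	8469404971
is	4705743816
was	2595235130
for	5933321709
with	4303955953
on	3750423199
that	3400031103
blood	27529634
heart	45614117
pain	31313375
fever	8256324
cold	25166456
cough	3794221
flu	7366325
cancer	48651765
sugar	15894057
pressure	28661523
bone	12247949
skin	28204262
brain	22595699
lung	6907063
liver	7904336
kidney	6085527
muscle	12715448
nerve	6099643
wound	4437866
doctor	24506595
nurse	10083113
hospital	33330569
medicine	19832699
sick	11709234
healthy	20306522
tired	8645431
dizzy	1431465
rash	2471870
swelling	2336776
bruise	574972
infection	10559816
diabetes	12679244
asthma	5375073
stroke	9425280
anemia	1327655
pneumonia	2461036
arthritis	4421734
hypertension	2583475
tumor	4368550
biopsy	1558574
lesion	966166
carcinoma	1238302
edema	831543
ischemia	394060
stenosis	499127
embolism	323085
thrombosis	471195
sepsis	638121
nephritis	99294
hepatitis	3222163
dermatitis	940724
bronchitis	1159693
gastritis	347421
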