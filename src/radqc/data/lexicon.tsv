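# Default entity lexicon: surface<TAB>category[;category...]<TAB>key=value[;key=value...]
# Orientations
左	orientation	laterality=left
右	orientation	laterality=right
上	orientation	laterality=none
下	orientation	laterality=none
# Anatomical locations
肺	anatomical_location
上叶	anatomical_location
下叶	anatomical_location
中叶	anatomical_location
心脏	anatomical_location
肝脏	anatomical_location
肾	anatomical_location
乳腺	anatomical_location
腹部	anatomical_location
颞叶	anatomical_location
膝关节	anatomical_location
腰椎	anatomical_location
肺纹理	anatomical_location
纵隔	anatomical_location
鼻咽	anatomical_location
# Qualitative terms
可见	qualitative
弥漫	qualitative
恶性	qualitative
均匀	qualitative
# Size-related terms
大	size
小	size
中等	size
增大	size
# Measurement units
cm	measurement_unit
mm	measurement_unit
HU	measurement_unit
# Positive signs
阴影	positive_sign
结节	positive_sign
肿物	positive_sign
积液	positive_sign
斑片	positive_sign
# Negative signs
通畅	negative_sign
清晰	negative_sign
阴性	negative_sign
未见异常	negative_sign
未见	negative_sign
# Diagnoses
肺炎	diagnosis
感染	diagnosis
炎症	diagnosis
增生	diagnosis
# Gender-related terms (also anatomical locations: multi-category entries)
前列腺	anatomical_location;gender_related	sex_specific=male
子宫	anatomical_location;gender_related	sex_specific=female
卵巢	anatomical_location;gender_related	sex_specific=female
睾丸	anatomical_location;gender_related	sex_specific=male
# Device-related terms
X线	device_related	modality_set=DR
磁共振	device_related	modality_set=MRI
密度	device_related	modality_set=CT|DR
信号	device_related	modality_set=MRI
CT值	device_related	modality_set=CT
# Age-related terms
腺样体	age_related	age_band=0-14
前囟	age_related	age_band=0-1
松果体钙化	age_related	age_band=10-120
骨骺	age_related	age_band=0-17
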