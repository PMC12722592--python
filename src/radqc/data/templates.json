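{
  "slot_types": {
    "side": {"kind": "entity", "category": "orientation", "require": {"laterality": ["left", "right"]}},
    "lobe": {"kind": "entity", "category": "anatomical_location", "surfaces": ["上叶", "下叶", "中叶"]},
    "sign": {"kind": "entity", "category": "positive_sign", "surfaces": ["结节", "阴影", "肿物"]},
    "neg": {"kind": "entity", "category": "negative_sign", "surfaces": ["清晰"]},
    "dx": {"kind": "entity", "category": "diagnosis", "surfaces": ["肺炎", "感染", "炎症"]},
    "organ_sex": {"kind": "entity", "category": "gender_related", "require": {"sex_specific": "$patient_sex"}},
    "age_ent": {"kind": "entity", "category": "age_related", "require": {"age_band_contains": "$age_years"}},
    "len": {"kind": "number", "low": 0.4, "high": 3.9, "decimals": 1},
    "mmlen": {"kind": "number", "low": 2, "high": 9, "decimals": 0},
    "hu": {"kind": "number", "low": -20, "high": 80, "decimals": 0}
  },
  "templates": [
    {
      "id": "ct-chest-nodule",
      "modalities": ["CT"],
      "findings": "胸部CT平扫示：{side:a}肺{lobe:b}可见{sign:c}影，大小约{len:d}cm×{len:e}cm，CT值约{hu:f}HU，边界{neg:g}。纵隔未见异常密度影。",
      "impression": "{side:a}肺{lobe:b}{sign:c}，建议随访复查。"
    },
    {
      "id": "ct-abdomen-kidney",
      "modalities": ["CT"],
      "findings": "上腹部CT扫描：肝脏形态大小正常，实质密度均匀，未见异常强化。{side:a}肾可见小结节，直径约{mmlen:d}mm。",
      "impression": "{side:a}肾小结节，直径约{mmlen:d}mm，建议随访。"
    },
    {
      "id": "ct-pelvis-gender",
      "modalities": ["CT"],
      "findings": "盆腔CT平扫：{organ_sex:a}形态正常，密度均匀，盆腔内未见异常密度影。",
      "impression": "{organ_sex:a}未见明显异常。"
    },
    {
      "id": "ct-head-age",
      "modalities": ["CT"],
      "findings": "颅脑CT平扫：脑实质密度均匀，{age_ent:a}显示清晰，中线结构居中。",
      "impression": "颅脑CT平扫未见明显异常。"
    },
    {
      "id": "mri-brain",
      "modalities": ["MRI"],
      "findings": "颅脑MRI平扫：{side:a}颞叶可见异常信号影，T2WI呈高信号，大小约{len:d}cm×{len:e}cm，边界{neg:g}。",
      "impression": "{side:a}颞叶异常信号，建议增强检查。"
    },
    {
      "id": "mri-knee",
      "modalities": ["MRI"],
      "findings": "{side:a}膝关节MRI示：关节腔内可见少量积液信号，周围软组织未见异常信号。",
      "impression": "{side:a}膝关节少量积液。"
    },
    {
      "id": "mri-pelvis-gender",
      "modalities": ["MRI"],
      "findings": "盆腔磁共振扫描：{organ_sex:a}形态信号未见异常，盆腔内未见积液信号。",
      "impression": "{organ_sex:a}未见明显异常。"
    },
    {
      "id": "dr-chest-normal",
      "modalities": ["DR"],
      "findings": "胸部正位X线片示：两肺纹理清晰，心脏形态大小正常，未见异常密度影。",
      "impression": "胸部X线检查未见明显异常。"
    },
    {
      "id": "dr-chest-patch",
      "modalities": ["DR"],
      "findings": "胸部正位X线片示：{side:a}肺下野可见斑片状阴影，边界模糊，{side:a}肺其余肺野清晰。",
      "impression": "{side:a}肺{dx:b}可能，建议CT进一步检查。"
    },
    {
      "id": "dr-nasopharynx-age",
      "modalities": ["DR"],
      "findings": "鼻咽侧位X线片示：{age_ent:a}清晰显示，气道通畅，骨质密度未见异常。",
      "impression": "鼻咽侧位X线检查未见明显异常。"
    }
  ]
}
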