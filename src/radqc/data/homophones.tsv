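# Homophone / near-homophone confusion groups: group_key<TAB>member[;member...]
# The non-medical member of each group is the plausible mis-typed form.
g01	上叶;商业
g02	下叶;夏叶
g03	中叶;忠叶
g04	结节;截节
g05	阴影;音影
g06	肿物;中物
g07	积液;积夜
g08	清晰;青析
g09	通畅;通肠
g10	密度;蜜度
g11	信号;心号
g12	可见;克见
g13	肺炎;废炎
g14	感染;敢染
g15	炎症;延症
g16	子宫;紫宫
g17	前列腺;潜列腺
g18	卵巢;乱巢
g19	磁共振;词共振
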