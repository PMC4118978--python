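subject_id,midbrain,pons,medulla,ablat,pattern,pattern_side,sbr_status
p01,True,True,True,True,efferent,left,delayed_unilateral
p02,False,True,True,False,none,none,normal
p03,True,False,False,True,afferent,left,normal
p04,True,False,False,False,none,none,normal
p05,True,True,True,True,commissural,right,normal
p06,True,False,False,False,none,none,absent_bilateral
p07,False,False,False,False,none,none,normal
p08,True,True,True,True,afferent,right,absent_bilateral
p09,False,False,False,False,none,none,normal
p10,True,True,True,True,afferent,left,delayed_bilateral
p11,True,False,False,False,none,none,normal
p12,False,False,False,False,none,none,normal
p13,False,True,True,True,mixed,bilateral,delayed_bilateral
p14,False,False,False,False,none,none,normal
p15,False,False,False,False,none,none,normal
p16,True,True,True,True,afferent,right,normal
p17,False,False,False,False,none,none,normal
p18,False,True,True,False,none,none,normal
p19,True,True,True,True,mixed,bilateral,absent_bilateral
p20,True,True,True,False,none,none,absent_bilateral
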