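ecology_index,membership_mask,strain,rate
1,1111,ADE,0.804
1,1111,TRP,0.869
1,1111,HIS,1.157
1,1111,LYS,0.732
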