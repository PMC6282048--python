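anc_b0	ROOT
anc_b1	ROOT
anc_b2	ROOT
mid_b0	anc_b0
mid_b1	anc_b1
mid_b2	anc_b2
priv_dis1	mid_b0
priv_dis14	mid_b2
priv_dis2	mid_b0
priv_dis8	mid_b1
t_dis1	priv_dis1
t_dis10	mid_b1
t_dis11	mid_b2
t_dis12	mid_b2
t_dis13	mid_b2
t_dis14	priv_dis14
t_dis15	mid_b2
t_dis2	priv_dis2
t_dis3	mid_b0
t_dis4	mid_b0
t_dis5	mid_b0
t_dis6	mid_b1
t_dis7	mid_b1
t_dis8	priv_dis8
t_dis9	mid_b1
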