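dis1	t_dis1
dis2	t_dis2
dis3	t_dis3
dis4	t_dis4
dis5	t_dis5
dis6	t_dis6
dis7	t_dis7
dis8	t_dis8
dis9	t_dis9
dis10	t_dis10
dis11	t_dis11
dis12	t_dis12
dis13	t_dis13
dis14	t_dis14
dis15	t_dis15
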