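	dis1	dis2	dis3	dis4	dis5	dis6	dis7	dis8	dis9	dis10	dis11	dis12	dis13	dis14	dis15
mir1	1	0	0	1	1	0	1	0	0	0	0	0	0	0	0
mir2	1	0	0	1	0	0	0	0	1	1	0	0	0	0	0
mir3	1	1	1	1	1	0	0	1	0	0	0	0	0	0	0
mir4	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0
mir5	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0
mir6	0	0	0	1	1	0	0	0	0	0	0	0	0	0	0
mir7	1	0	1	1	1	0	1	0	1	0	0	0	0	0	0
mir8	0	0	0	0	0	0	0	1	0	1	0	0	0	0	0
mir9	1	0	0	0	1	1	1	1	1	1	0	0	0	0	0
mir10	0	0	0	0	0	0	1	1	0	1	0	0	0	0	0
mir11	0	0	0	0	0	0	1	1	1	1	0	0	0	0	0
mir12	0	0	0	0	0	1	1	1	1	1	0	0	0	0	0
mir13	0	0	0	0	0	1	1	1	1	1	0	0	1	0	0
mir14	0	1	0	0	0	0	1	1	1	1	1	0	0	0	0
mir15	0	0	0	0	0	0	0	0	0	0	0	1	1	1	1
mir16	0	0	0	0	0	0	0	0	0	0	1	1	1	1	0
mir17	0	0	0	0	0	0	0	0	0	0	1	1	1	1	1
mir18	0	0	0	0	0	0	1	0	0	0	1	0	1	1	0
mir19	0	0	0	0	0	0	0	0	0	0	1	1	1	1	0
mir20	0	0	0	0	0	0	0	0	0	0	0	1	0	0	1
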