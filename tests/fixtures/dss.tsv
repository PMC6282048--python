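	dis1	dis2	dis3	dis4	dis5	dis6	dis7	dis8	dis9	dis10	dis11	dis12	dis13	dis14	dis15
dis1	1.0	0.22580645161290322	0.3442622950819672	0.3442622950819672	0.3442622950819672	0.04918032786885246	0.04918032786885246	0.03225806451612903	0.04918032786885246	0.04918032786885246	0.04918032786885246	0.04918032786885246	0.04918032786885246	0.03225806451612903	0.04918032786885246
dis2	0.22580645161290322	1.0	0.3442622950819672	0.3442622950819672	0.3442622950819672	0.04918032786885246	0.04918032786885246	0.03225806451612903	0.04918032786885246	0.04918032786885246	0.04918032786885246	0.04918032786885246	0.04918032786885246	0.03225806451612903	0.04918032786885246
dis3	0.3442622950819672	0.3442622950819672	1.0	0.4666666666666667	0.4666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667
dis4	0.3442622950819672	0.3442622950819672	0.4666666666666667	1.0	0.4666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667
dis5	0.3442622950819672	0.3442622950819672	0.4666666666666667	0.4666666666666667	1.0	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667
dis6	0.04918032786885246	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.06666666666666667	1.0	0.4666666666666667	0.3442622950819672	0.4666666666666667	0.4666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667
dis7	0.04918032786885246	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.4666666666666667	1.0	0.3442622950819672	0.4666666666666667	0.4666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667
dis8	0.03225806451612903	0.03225806451612903	0.04918032786885246	0.04918032786885246	0.04918032786885246	0.3442622950819672	0.3442622950819672	1.0	0.3442622950819672	0.3442622950819672	0.04918032786885246	0.04918032786885246	0.04918032786885246	0.03225806451612903	0.04918032786885246
dis9	0.04918032786885246	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.4666666666666667	0.4666666666666667	0.3442622950819672	1.0	0.4666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667
dis10	0.04918032786885246	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.4666666666666667	0.4666666666666667	0.3442622950819672	0.4666666666666667	1.0	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667
dis11	0.04918032786885246	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667	0.06666666666666667	1.0	0.4666666666666667	0.4666666666666667	0.3442622950819672	0.4666666666666667
dis12	0.04918032786885246	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.4666666666666667	1.0	0.4666666666666667	0.3442622950819672	0.4666666666666667
dis13	0.04918032786885246	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.4666666666666667	0.4666666666666667	1.0	0.3442622950819672	0.4666666666666667
dis14	0.03225806451612903	0.03225806451612903	0.04918032786885246	0.04918032786885246	0.04918032786885246	0.04918032786885246	0.04918032786885246	0.03225806451612903	0.04918032786885246	0.04918032786885246	0.3442622950819672	0.3442622950819672	0.3442622950819672	1.0	0.3442622950819672
dis15	0.04918032786885246	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.06666666666666667	0.04918032786885246	0.06666666666666667	0.06666666666666667	0.4666666666666667	0.4666666666666667	0.4666666666666667	0.3442622950819672	1.0
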