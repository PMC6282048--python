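	mir1	mir2	mir3	mir4	mir5	mir6	mir7	mir8	mir9	mir10	mir11	mir12	mir13	mir14	mir15	mir16	mir17	mir18	mir19	mir20
mir1	1.0	0.745191194503982	0.6944436751310687	0.6445505324062525	0.6206918181303431	0.7133092629432549	0.661641459600691	0.0637871310802064	0.09427572283969199	0.12996931466280287	0.10062743517659152	0.08693329568712604	0.00559226456031735	0.09999959796450761	0.037653933350343005	0.05148652635165423	0.1328706829104694	0.0767681448622832	0.07479766838533465	0.08503448564178032
mir2	0.745191194503982	1.0	0.8545425651877918	0.6809466306595302	0.7836188973814248	0.732269664042706	0.8449383393678898	0.10695546204957009	0.13797324043056855	0.06408987690766545	0.12170509376819286	0.10141285874251318	0.07646158967527023	0.04417272120901102	0.02853025136934683	0.16987800849140366	0.039328536429987605	0.09084051706172644	0.12341734362728168	0.02363451264757528
mir3	0.6944436751310687	0.8545425651877918	1.0	0.7370096660237633	0.7120899544471564	0.7971308811423314	0.8433428716441549	0.14660153155826325	0.1767994279405094	0.09699352964043217	0.04308839690637595	0.09261100883260698	0.11293608447501383	0.050363194085175714	0.13040880086692572	0.06541584310403567	0.05986763325192223	0.05736763283524332	0.12768512079644534	0.11368726656928385
mir4	0.6445505324062525	0.6809466306595302	0.7370096660237633	1.0	0.7838746788106767	0.7525761757927978	0.726009503028946	0.0465538157920712	0.09221268604406536	0.13590805287544017	0.14165090340707676	0.1868934365264474	0.051889693132327025	0.11722978552524789	0.05779409421376115	0.14280288683590198	0.0858727396228426	0.12580698368076457	0.13956263249825124	0.1558978794230334
mir5	0.6206918181303431	0.7836188973814248	0.7120899544471564	0.7838746788106767	1.0	0.7223095863947457	0.7593243371115446	0.06360102365390663	0.031284638676607295	0.12833051204531395	0.11983315430463215	0.11619975404084135	0.13266835776956695	0.19090469457207176	0.11657996025601614	0.12511804068855056	0.06286605289577736	0.038970171670451824	0.1323541188276421	0.1045239863088097
mir6	0.7133092629432549	0.732269664042706	0.7971308811423314	0.7525761757927978	0.7223095863947457	1.0	0.7134611163817061	0.05812998107517567	0.15804120769351768	0.12501081335682043	0.10838499940223656	0.10351740822168712	0.10333078052220994	0.05663313304774358	0.15916080777917413	0.1057963651520129	0.09807772771044217	0.10911412001629978	0.1774385311875913	0.07616445627078822
mir7	0.661641459600691	0.8449383393678898	0.8433428716441549	0.726009503028946	0.7593243371115446	0.7134611163817061	1.0	0.0937462278610691	0.10128231218731162	0.03579898064789475	0.05219388484352099	0.1272662826751694	0.12487238001801297	0.14025405146772885	0.12753192173147893	0.007387780761773589	0.10811932245580969	0.05819704614786214	0.09583478594516802	0.0945117804354779
mir8	0.0637871310802064	0.10695546204957009	0.14660153155826325	0.0465538157920712	0.06360102365390663	0.05812998107517567	0.0937462278610691	1.0	0.7913727881164814	0.6398106726536253	0.7082688660932455	0.7343292789803826	0.6993090458566305	0.7073182404114597	0.09572359380321227	0.11990436081245812	0.06706630644133935	0.12722031555612756	0.12860577023730274	0.04931223233150868
mir9	0.09427572283969199	0.13797324043056855	0.1767994279405094	0.09221268604406536	0.031284638676607295	0.15804120769351768	0.10128231218731162	0.7913727881164814	1.0	0.6749010778116296	0.8010093604481585	0.7793965708245105	0.7525667286577475	0.721777613153993	0.17792654258574947	0.11119148857834805	0.08997065541833657	0.09594452154229324	0.09125638159563257	0.08216007565265634
mir10	0.12996931466280287	0.06408987690766545	0.09699352964043217	0.13590805287544017	0.12833051204531395	0.12501081335682043	0.03579898064789475	0.6398106726536253	0.6749010778116296	1.0	0.8821107650646776	0.650542420894608	0.7497354775285623	0.7221139185396936	0.0620879766929566	0.1221598337466706	0.05814511878133901	0.15839802371463113	0.037298252230683934	0.06502781090075405
mir11	0.10062743517659152	0.12170509376819286	0.04308839690637595	0.14165090340707676	0.11983315430463215	0.10838499940223656	0.05219388484352099	0.7082688660932455	0.8010093604481585	0.8821107650646776	1.0	0.7700347141081944	0.8864901192937609	0.7108744607248849	0.1522435695588397	0.10374202720561213	0.1560193807402329	0.17352237405075832	0.1180048094931623	0.08967757355259742
mir12	0.08693329568712604	0.10141285874251318	0.09261100883260698	0.1868934365264474	0.11619975404084135	0.10351740822168712	0.1272662826751694	0.7343292789803826	0.7793965708245105	0.650542420894608	0.7700347141081944	1.0	0.678832623157972	0.7060159242663215	0.0629368542202069	0.06671516649121402	0.1269558553632373	0.09527123304203139	0.1418270411605544	0.09667961333907063
mir13	0.00559226456031735	0.07646158967527023	0.11293608447501383	0.051889693132327025	0.13266835776956695	0.10333078052220994	0.12487238001801297	0.6993090458566305	0.7525667286577475	0.7497354775285623	0.8864901192937609	0.678832623157972	1.0	0.6346740579447923	0.15894678390110292	0.025544384246621123	0.07321002583285145	0.0651848928162984	0.0852648634858554	0.15970984975581343
mir14	0.09999959796450761	0.04417272120901102	0.050363194085175714	0.11722978552524789	0.19090469457207176	0.05663313304774358	0.14025405146772885	0.7073182404114597	0.721777613153993	0.7221139185396936	0.7108744607248849	0.7060159242663215	0.6346740579447923	1.0	0.16747916665455198	0.11292409160540876	0.09014037181570783	0.09859210108574158	0.078581328434386	0.09542747836866788
mir15	0.037653933350343005	0.02853025136934683	0.13040880086692572	0.05779409421376115	0.11657996025601614	0.15916080777917413	0.12753192173147893	0.09572359380321227	0.17792654258574947	0.0620879766929566	0.1522435695588397	0.0629368542202069	0.15894678390110292	0.16747916665455198	1.0	0.7459479449421196	0.7159339150170889	0.786842558738387	0.7624954451713909	0.7621735193928174
mir16	0.05148652635165423	0.16987800849140366	0.06541584310403567	0.14280288683590198	0.12511804068855056	0.1057963651520129	0.007387780761773589	0.11990436081245812	0.11119148857834805	0.1221598337466706	0.10374202720561213	0.06671516649121402	0.025544384246621123	0.11292409160540876	0.7459479449421196	1.0	0.7345897111840114	0.7758055618257227	0.7655628315928626	0.8632976317565336
mir17	0.1328706829104694	0.039328536429987605	0.05986763325192223	0.0858727396228426	0.06286605289577736	0.09807772771044217	0.10811932245580969	0.06706630644133935	0.08997065541833657	0.05814511878133901	0.1560193807402329	0.1269558553632373	0.07321002583285145	0.09014037181570783	0.7159339150170889	0.7345897111840114	1.0	0.7575382663292278	0.651649615615727	0.7976799453946454
mir18	0.0767681448622832	0.09084051706172644	0.05736763283524332	0.12580698368076457	0.038970171670451824	0.10911412001629978	0.05819704614786214	0.12722031555612756	0.09594452154229324	0.15839802371463113	0.17352237405075832	0.09527123304203139	0.0651848928162984	0.09859210108574158	0.786842558738387	0.7758055618257227	0.7575382663292278	1.0	0.8013212306883142	0.6352353198474567
mir19	0.07479766838533465	0.12341734362728168	0.12768512079644534	0.13956263249825124	0.1323541188276421	0.1774385311875913	0.09583478594516802	0.12860577023730274	0.09125638159563257	0.037298252230683934	0.1180048094931623	0.1418270411605544	0.0852648634858554	0.078581328434386	0.7624954451713909	0.7655628315928626	0.651649615615727	0.8013212306883142	1.0	0.8535181122338354
mir20	0.08503448564178032	0.02363451264757528	0.11368726656928385	0.1558978794230334	0.1045239863088097	0.07616445627078822	0.0945117804354779	0.04931223233150868	0.08216007565265634	0.06502781090075405	0.08967757355259742	0.09667961333907063	0.15970984975581343	0.09542747836866788	0.7621735193928174	0.8632976317565336	0.7976799453946454	0.6352353198474567	0.8535181122338354	1.0
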