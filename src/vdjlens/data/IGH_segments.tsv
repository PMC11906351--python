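name	kind	chrom	start	end	switch_order
IGHV7-81	V	chr14	106845000	106845500	
IGHV3-74	V	chr14	106827855	106828399	
IGHV3-73	V	chr14	106805965	106806524	
IGHV3-72	V	chr14	106785481	106786024	
IGHV3-71	V	chr14	106762929	106763389	
IGHV2-70	V	chr14	106741666	106742197	
IGHV1-69	V	chr14	106718584	106719137	
IGHV3-66	V	chr14	106692822	106693291	
IGHV3-64	V	chr14	106671593	106672047	
IGHV4-61	V	chr14	106651657	106652200	
IGHV4-59	V	chr14	106631493	106632038	
IGHV1-58	V	chr14	106613454	106613969	
IGHV3-53	V	chr14	106588626	106589108	
IGHV5-51	V	chr14	106568298	106568827	
IGHV3-49	V	chr14	106544707	106545222	
IGHV3-48	V	chr14	106527440	106527873	
IGHV1-46	V	chr14	106507746	106508310	
IGHV1-45	V	chr14	106481959	106482459	
IGHV3-43	V	chr14	106455633	106456196	
IGHV4-39	V	chr14	106442512	106442985	
IGHV3-38	V	chr14	106416467	106416919	
IGHV4-34	V	chr14	106390436	106390917	
IGHV3-33	V	chr14	106375806	106376340	
IGHV4-31	V	chr14	106348252	106348699	
IGHV3-30	V	chr14	106329142	106329649	
IGHV4-28	V	chr14	106310098	106310559	
IGHV2-26	V	chr14	106291575	106292060	
IGHV1-24	V	chr14	106266569	106267117	
IGHV3-23	V	chr14	106241443	106241928	
IGHV3-21	V	chr14	106224950	106225397	
IGHV3-20	V	chr14	106199841	106200267	
IGHV1-18	V	chr14	106179486	106180025	
IGHV3-15	V	chr14	106164964	106165477	
IGHV3-13	V	chr14	106139546	106140017	
IGHV3-11	V	chr14	106120131	106120622	
IGHV3-9	V	chr14	106099455	106099956	
IGHV1-8	V	chr14	106073089	106073663	
IGHV3-7	V	chr14	106049383	106049854	
IGHV4-4	V	chr14	106028933	106029392	
IGHV6-1	V	chr14	106010000	106010450	
IGHD2-2	D	chr14	105902000	105902026	
IGHD3-10	D	chr14	105895365	105895391	
IGHD4-17	D	chr14	105887610	105887632	
IGHD6-25	D	chr14	105882000	105882021	
IGHJ1	J	chr14	105867600	105867662	
IGHJ2	J	chr14	105866747	105866795	
IGHJ3	J	chr14	105865162	105865213	
IGHJ4	J	chr14	105864336	105864387	
IGHJ5	J	chr14	105863198	105863253	
IGHJ6	J	chr14	105862100	105862159	
IGHM	CONSTANT	chr14	105851500	105856000	0
IGHD	CONSTANT	chr14	105839000	105847500	0
IGHG3	CONSTANT	chr14	105769000	105773500	1
IGHG1	CONSTANT	chr14	105736000	105743000	2
IGHA1	CONSTANT	chr14	105703500	105708200	3
IGHG2	CONSTANT	chr14	105639500	105645700	4
IGHG4	CONSTANT	chr14	105624500	105628500	5
IGHE	CONSTANT	chr14	105605000	105608500	6
IGHA2	CONSTANT	chr14	105583500	105588400	7
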