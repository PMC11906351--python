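name	kind	chrom	start	end	switch_order
TRAV1-1	V	chr14	21700000	21700475	
TRAV1-2	V	chr14	21722307	21722843	
TRAV2	V	chr14	21738623	21739162	
TRAV3	V	chr14	21758004	21758544	
TRAV4	V	chr14	21775928	21776360	
TRAV5	V	chr14	21791388	21791844	
TRAV6	V	chr14	21814346	21814841	
TRAV7	V	chr14	21831993	21832490	
TRAV8-1	V	chr14	21844688	21845240	
TRAV9-1	V	chr14	21865676	21866107	
TRAV10	V	chr14	21885439	21885988	
TRAV12-1	V	chr14	21906953	21907419	
TRAV8-2	V	chr14	21920849	21921289	
TRAV8-3	V	chr14	21939220	21939683	
TRAV13-1	V	chr14	21956270	21956838	
TRAV12-2	V	chr14	21981513	21982022	
TRAV8-4	V	chr14	21996687	21997171	
TRAV13-2	V	chr14	22016483	22016964	
TRAV14DV4	V	chr14	22030771	22031241	
TRAV9-2	V	chr14	22052132	22052693	
TRAV12-3	V	chr14	22072160	22072605	
TRAV8-6	V	chr14	22092993	22093522	
TRAV16	V	chr14	22105853	22106344	
TRAV17	V	chr14	22126973	22127526	
TRAV18	V	chr14	22149517	22149964	
TRAV19	V	chr14	22162258	22162777	
TRAV20	V	chr14	22182675	22183176	
TRAV21	V	chr14	22205997	22206502	
TRAV22	V	chr14	22224752	22225229	
TRAV23DV6	V	chr14	22242938	22243424	
TRAV24	V	chr14	22255940	22256445	
TRAV25	V	chr14	22279421	22279909	
TRAV26-1	V	chr14	22295293	22295793	
TRAV26-2	V	chr14	22309374	22309942	
TRAV27	V	chr14	22329821	22330386	
TRAV29DV5	V	chr14	22348466	22348926	
TRAV34	V	chr14	22372852	22373291	
TRAV35	V	chr14	22386796	22387354	
TRAV38-1	V	chr14	22406254	22406812	
TRAV39	V	chr14	22424500	22424942	
TRAJ57	J	chr14	22480000	22480060	
TRAJ54	J	chr14	22483523	22483591	
TRAJ52	J	chr14	22486447	22486513	
TRAJ49	J	chr14	22489709	22489770	
TRAJ47	J	chr14	22492875	22492942	
TRAJ45	J	chr14	22496222	22496290	
TRAJ43	J	chr14	22499812	22499879	
TRAJ41	J	chr14	22502288	22502346	
TRAJ39	J	chr14	22506377	22506433	
TRAJ37	J	chr14	22508367	22508426	
TRAJ34	J	chr14	22512018	22512080	
TRAJ32	J	chr14	22515998	22516063	
TRAJ29	J	chr14	22517784	22517843	
TRAJ27	J	chr14	22521455	22521523	
TRAJ24	J	chr14	22525041	22525098	
TRAJ22	J	chr14	22528316	22528368	
TRAJ18	J	chr14	22531246	22531311	
TRAJ15	J	chr14	22533905	22533963	
TRAJ9	J	chr14	22536907	22536971	
TRAJ4	J	chr14	22540900	22540958	
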