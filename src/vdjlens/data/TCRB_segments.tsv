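name	kind	chrom	start	end	switch_order
TRBV2	V	chr7	142370000	142370572	
TRBV3-1	V	chr7	142383905	142384445	
TRBV4-1	V	chr7	142394954	142395500	
TRBV5-1	V	chr7	142400999	142401477	
TRBV6-1	V	chr7	142415565	142416131	
TRBV4-2	V	chr7	142427396	142427867	
TRBV6-2	V	chr7	142438515	142439087	
TRBV7-2	V	chr7	142450237	142450783	
TRBV6-4	V	chr7	142457313	142457799	
TRBV7-3	V	chr7	142467928	142468452	
TRBV5-4	V	chr7	142481859	142482349	
TRBV6-5	V	chr7	142495095	142495534	
TRBV9	V	chr7	142504937	142505445	
TRBV10-1	V	chr7	142513370	142513813	
TRBV11-1	V	chr7	142524972	142525520	
TRBV10-2	V	chr7	142538947	142539381	
TRBV11-2	V	chr7	142550593	142551051	
TRBV12-3	V	chr7	142561199	142561725	
TRBV13	V	chr7	142571057	142571547	
TRBV14	V	chr7	142580177	142580725	
TRBV15	V	chr7	142595207	142595745	
TRBV16	V	chr7	142606043	142606480	
TRBV18	V	chr7	142614253	142614808	
TRBV19	V	chr7	142630110	142630659	
TRBV20-1	V	chr7	142640622	142641064	
TRBV24-1	V	chr7	142647471	142648029	
TRBV25-1	V	chr7	142660998	142661569	
TRBV27	V	chr7	142673418	142673936	
TRBV28	V	chr7	142684609	142685116	
TRBV29-1	V	chr7	142694500	142695070	
TRBD1	D	chr7	142721000	142721012	
TRBJ1-1	J	chr7	142727000	142727045	
TRBJ1-2	J	chr7	142728304	142728355	
TRBJ1-3	J	chr7	142729761	142729810	
TRBJ1-4	J	chr7	142731114	142731160	
TRBJ1-5	J	chr7	142732955	142733008	
TRBJ1-6	J	chr7	142734531	142734587	
TRBJ2-1	J	chr7	142736095	142736142	
TRBJ2-2	J	chr7	142737774	142737825	
TRBJ2-3	J	chr7	142738592	142738645	
TRBJ2-4	J	chr7	142740274	142740319	
TRBJ2-5	J	chr7	142741837	142741892	
TRBJ2-6	J	chr7	142743055	142743110	
TRBJ2-7	J	chr7	142744900	142744954	
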