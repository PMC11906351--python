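locus	chrom	span_start	span_end	orientation	cn_proxy_gene	baseline_regions
TCRA	chr14	21621904	22752132	forward	OR10G3	21621904-21695000;22546000-22752132
TCRB	chr7	142299011	142813287	forward	PRSS58	142299011-142364000;142750000-142813287
TCRG	chr7	38240024	38368055	reverse	STARD3NL	38240024-38257000;38350000-38368055
IGH	chr14	105566277	106879844	reverse	TMEM121	105566277-105580000;106852000-106879844
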