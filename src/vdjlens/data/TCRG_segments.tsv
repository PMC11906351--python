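name	kind	chrom	start	end	switch_order
TRGV11	V	chr7	38345000	38345394	
TRGV10	V	chr7	38336651	38337140	
TRGV9	V	chr7	38329699	38330116	
TRGV8	V	chr7	38322290	38322682	
TRGV5	V	chr7	38313332	38313752	
TRGV4	V	chr7	38304556	38305044	
TRGV3	V	chr7	38296055	38296486	
TRGV2	V	chr7	38290000	38290495	
TRGJP1	J	chr7	38272000	38272053	
TRGJP	J	chr7	38269467	38269522	
TRGJ1	J	chr7	38267216	38267277	
TRGJP2	J	chr7	38264983	38265044	
TRGJ2	J	chr7	38262000	38262053	
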