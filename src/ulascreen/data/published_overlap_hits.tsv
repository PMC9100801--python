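feature_id	cell_lines
hsa-miR-129-5p	SiHa;HeLa;FK18B
hsa-miR-137	SiHa;HeLa;FK18B
hsa-miR-185-3p	SiHa;HeLa;FK18B
hsa-miR-193a-3p	SiHa;HeLa;FK18B
hsa-miR-193b-3p	SiHa;HeLa;FK18B
hsa-miR-224-3p	SiHa;HeLa;FK18B
hsa-miR-491-5p	SiHa;HeLa;FK18B
hsa-miR-522-3p	SiHa;HeLa;FK18B
hsa-miR-532-3p	SiHa;HeLa;FK18B
hsa-miR-646	SiHa;HeLa;FK18B
hsa-miR-1233-1-5p	SiHa;HeLa;FK18B
hsa-miR-1263	SiHa;HeLa;FK18B
hsa-miR-2277-5p	SiHa;HeLa;FK18B
hsa-miR-3916	SiHa;HeLa;FK18B
hsa-miR-4265	SiHa;HeLa;FK18B
hsa-miR-4430	SiHa;HeLa;FK18B
hsa-miR-4440	SiHa;HeLa;FK18B
hsa-miR-4505	SiHa;HeLa;FK18B
hsa-miR-4706	SiHa;HeLa;FK18B
hsa-miR-4746-3p	SiHa;HeLa;FK18B
hsa-miR-4749-5p	SiHa;HeLa;FK18B
hsa-miR-5189	SiHa;HeLa;FK18B
hsa-miR-22-5p	SiHa;HeLa
hsa-miR-103a-2-5p	SiHa;HeLa
hsa-miR-425-3p	SiHa;HeLa
hsa-miR-1911-3p	SiHa;HeLa
hsa-miR-4436b-3p	SiHa;HeLa
hsa-miR-323a-5p	SiHa;FK18B
hsa-miR-342-5p	SiHa;FK18B
hsa-miR-378c	SiHa;FK18B
hsa-miR-608	SiHa;FK18B
hsa-miR-766-5p	SiHa;FK18B
hsa-miR-1250	SiHa;FK18B
hsa-miR-1287	SiHa;FK18B
hsa-miR-3680-3p	SiHa;FK18B
hsa-miR-4270	SiHa;FK18B
hsa-miR-4498	SiHa;FK18B
hsa-miR-5681a	SiHa;FK18B
hsa-miR-1272	HeLa;FK18B
hsa-miR-3147	HeLa;FK18B
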