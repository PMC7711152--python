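sample_id	substrate_bin	incubation	is_control
background_inc1_r1	background	1	False
background_inc1_r2	background	1	False
background_inc1_r3	background	1	False
carbonate_inc1_r1	carbonate	1	False
carbonate_inc1_r2	carbonate	1	False
carbonate_inc1_r3	carbonate	1	False
silica_inc1_r1	silica	1	False
silica_inc1_r2	silica	1	False
silica_inc1_r3	silica	1	False
background_inc2_r1	background	2	False
background_inc2_r2	background	2	False
background_inc2_r3	background	2	False
carbonate_inc2_r1	carbonate	2	False
carbonate_inc2_r2	carbonate	2	False
carbonate_inc2_r3	carbonate	2	False
silica_inc2_r1	silica	2	False
silica_inc2_r2	silica	2	False
silica_inc2_r3	silica	2	False
background_inc3_r1	background	3	False
background_inc3_r2	background	3	False
background_inc3_r3	background	3	False
carbonate_inc3_r1	carbonate	3	False
carbonate_inc3_r2	carbonate	3	False
carbonate_inc3_r3	carbonate	3	False
silica_inc3_r1	silica	3	False
silica_inc3_r2	silica	3	False
silica_inc3_r3	silica	3	False
background_inc4_r1	background	4	False
background_inc4_r2	background	4	False
background_inc4_r3	background	4	False
carbonate_inc4_r1	carbonate	4	False
carbonate_inc4_r2	carbonate	4	False
carbonate_inc4_r3	carbonate	4	False
silica_inc4_r1	silica	4	False
silica_inc4_r2	silica	4	False
silica_inc4_r3	silica	4	False
background_inc5_r1	background	5	False
background_inc5_r2	background	5	False
background_inc5_r3	background	5	False
carbonate_inc5_r1	carbonate	5	False
carbonate_inc5_r2	carbonate	5	False
carbonate_inc5_r3	carbonate	5	False
silica_inc5_r1	silica	5	False
silica_inc5_r2	silica	5	False
silica_inc5_r3	silica	5	False
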