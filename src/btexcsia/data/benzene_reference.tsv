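culture_label	culture_type	condition	initial_benzene_uM	epsilon_C_permil	epsilon_C_ci95	epsilon_C_r2	epsilon_H_permil	epsilon_H_ci95	epsilon_H_r2	source
Ralstonia pickettii VKOl	pure	oxic	885	-1.7	0.2	0.98	-11	4	0.86	Fischer et al. 2008
Cupriavidus necator ATCC 17697	pure	oxic	1180	-4.3	0.4	0.99	-17	11	0.89	Fischer et al. 2008
Burkholderia sp.	pure	oxic	700	-3.5	0.3	0.97	-11	2	0.91	Hunkeler et al. 2001
Acinetobacter sp.	pure	oxic	700	-1.5	0.8	0.99	-13	1	0.99	Hunkeler et al. 2001
Azoarcus denitrificans strain BC	pure	oxic	603	-2.6	0.8	0.97	-16	4	0.97	Fischer et al. 2008
Azoarcus denitrificans strain BC	pure	chlorate-reducing	462	-1.5	0.5	0.86	-28	6	0.98	Fischer et al. 2008
Nitrate-reducing, mixed negative	mixed	nitrate-reducing	250	-2.2	0.4	0.98	-35	6	0.91	Mancini et al. 2003
Sulfate-reducing, mixed negative	mixed	sulfate-reducing	192	-3.6	0.3	0.92	-79	4	0.79	Mancini et al. 2003
Sulfate-reducing, mixed negative	mixed	sulfate-reducing	192	-1.9	0.3	0.97	-59	10	0.99	Fischer et al. 2008
Methanogenic, mixed negative	mixed	methanogenic	750	-1.9	0.1	0.98	-60	3	0.92	Mancini et al. 2003
Methanogenic, mixed negative	mixed	methanogenic	900	-0.8	0.2	0.93	-34	8	0.88	Mancini et al. 2008
Methanogenic, mixed negative	mixed	methanogenic	450	-1.1	0.1	0.88	-38	6	0.80	Mancini et al. 2008
Sulfate-reducing, enriched positive	mixed	sulfate-reducing	450	-2.5	0.2	0.97	-55	4	0.93	Bergmann et al. 2011
Iron-reducing, enriched positive	mixed	iron-reducing	200	-3.0	0.5	0.93	-56	8	0.93	Bergmann et al. 2011
Sulfate-reducing, enriched positive	mixed	sulfate-reducing	400	-2.4	0.3	0.91	-57	0.0	0.98	this study
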