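# qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore
t1	chr1	100.00	30	0	0	1	30	1001	1030	1e-12	60.2
t2	chr1	100.00	30	0	0	1	30	2001	2030	1e-09	58.4
t3	chr1	100.00	30	0	0	1	30	3030	3001	1e-08	57.0
t4	chr2	100.00	30	0	0	1	30	4001	4030	1e-07	55.1
t5	chr2	96.70	30	1	0	1	30	5001	5030	1e-09	52.8
t6	chr2	96.70	30	1	0	1	30	6030	6001	1e-09	52.8
t7	chr3	96.70	30	0	1	1	30	7001	7031	1e-09	50.5
t8	chr3	96.70	30	0	1	1	30	8001	8031	1e-09	50.5
t9	chr3	100.00	30	0	0	1	30	9001	9030	1e-06	48.9
t10	chr3	100.00	29	0	0	1	29	9501	9529	1e-09	56.6
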