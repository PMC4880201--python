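gene	probeset_id	experiment	MASlog2fc	MASlimmap	MASviplow	RMAlog2fc	RMAlimmap	RMAviplow
Ahnak	NA	EXTNOR	0.680	0.0001	1.669	0.514	0.0001	2.862
Camk2n1	NA	EXTNOR	-0.318	0.023	0.740	-0.353	0.004	1.509
Ccl2	NA	REC	-1.019	0.091	0.844	-1.162	0.056	1.915
Cldn5	NA	EXTNOR	0.532	0.025	3.577	0.452	0.010	1.128
Cldn11	NA	REC	0.187	0.094	0.051	0.164	0.090	0.355
Cxcl1	NA	REC	1.100	0.029	1.289	1.078	0.042	1.221
Il1a	1368592_at	REC	-1.215	0.023	1.160	-1.122	0.035	1.874
Icam2	NA	EXTNOR	0.485	0.003	0.872	0.393	0.018	0.769
Nfkbia	NA	REC	-0.683	0.018	1.143	-0.665	0.020	1.913
Ocln	NA	EXTNOR	0.406	0.017	0.314	0.428	0.006	0.978
Rara	NA	REC	-1.210	0.014	1.879	-0.175	0.007	0.978
Sucla2	NA	EXTNOR	-0.288	0.092	0.146	-0.131	0.020	1.118
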