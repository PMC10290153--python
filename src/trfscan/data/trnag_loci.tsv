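chrom	start	end	strand	gene_name
NC_040252.1	105273828	105273898	-	TRNAG-CCC
NC_040252.1	105275606	105275676	+	TRNAG-CCC
NC_040252.1	105276143	105276213	-	TRNAG-CCC
NC_040252.1	105289175	105289245	+	TRNAG-CCC
NC_040252.1	105289720	105289790	-	TRNAG-CCC
NC_040252.1	105291492	105291562	+	TRNAG-CCC
NC_040252.1	105392585	105392655	-	TRNAG-CCC
NC_040252.1	105478889	105478959	-	TRNAG-CCC
NC_040252.1	105505558	105505628	+	TRNAG-CCC
NC_040252.1	105587574	105587644	-	TRNAG-CCC
NC_040252.1	120100333	120100403	-	TRNAG-GCC
NC_040253.1	165210771	165210841	+	TRNAG-GCC
NC_040259.1	7062119	7062189	-	TRNAG-CCC
NC_040262.1	35658466	35658536	-	TRNAG-GCC
NC_040265.1	946283	946353	-	TRNAG-GCC
NC_040265.1	946941	947011	-	TRNAG-GCC
NC_040265.1	953972	954042	+	TRNAG-GCC
NC_040265.1	1344225	1344295	+	TRNAG-GCC
NC_040271.1	33381996	33382066	+	TRNAG-GCC
NC_040271.1	34261573	34261643	+	TRNAG-GCC
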