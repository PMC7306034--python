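# Isolate catalogue: 40 bacterial strains from naphthalene-amended biofilm
# enrichments (aerobic and oxygen-limited), with 16S rRNA gene accession,
# isolation source, nearest cultured neighbor, lineage, 16S fragment length
# and identity, naphthalene degradation call (GC-MS screen, +/-) and
# detection of the NDO-related 2Fe-2S reductase gene (hybrid-primer PCR, +/-).
strain	accession	enrichment	week	nearest_neighbor	lineage	fragment_bp	identity_pct	degrades_naphthalene	ndo_detected
R1.1_4	MN197554	aerobic	1	Pseudomonas silesiensis A3(T)	Gammaproteobacteria	1422	99.7	+	+
R1.1_5	MN197555	aerobic	1	Acidovorax delafieldii DSM 64(T)	Gammaproteobacteria	1413	99.7	+	+
R1.1_7	MN197556	aerobic	1	Pseudomonas arsenicoxydans CECT 7543(T)	Gammaproteobacteria	1440	99.2	+	+
RN1.1_1	MN197557	aerobic	1	Pseudomonas silesiensis A3(T)	Gammaproteobacteria	1442	99.6	-	-
RN1.1_3 uj	MN197558	aerobic	1	Pseudomonas silesiensis A(T)	Gammaproteobacteria	1431	99.9	+	+
RN1.1_4F	MN197559	aerobic	1	Rhodococcus jostii DSM 44719(T)	Actinobacteria	1416	99.9	+	-
RN1.1_5	MN197560	aerobic	1	Pseudomonas silesiensis A(T)	Gammaproteobacteria	1475	99.3	+	+
RN1.1_7	MN197561	aerobic	1	Massilia aurea AP13(T)	Gammaproteobacteria	1358	99.0	-	-
BGN1.1_2	MN197562	aerobic	1	Acidovorax facilis CCUG 2113(T)	Gammaproteobacteria	1355	99.6	-	-
BGN1.1_3	MN197563	aerobic	1	Acidovorax delafieldii DSM 64(T)	Gammaproteobacteria	1364	99.5	+	-
BGN1.1_4	MN197564	aerobic	1	Acidovorax delafieldii DSM 64(T)	Gammaproteobacteria	1432	99.9	+	-
BGN1.1_5	MN197565	aerobic	1	Rhodococcus jostii DSM 44719(T)	Actinobacteria	1407	99.6	+	-
BGN1.1_6	MN197566	aerobic	1	Pseudomonas mandelii NBRC 103147(T)	Gammaproteobacteria	1355	99.7	+	+
BGN1.1_8	MN197567	aerobic	1	Rhodococcus jostii DSM 44719(T)	Actinobacteria	1393	99.8	+	-
R3.6_1	MN197568	aerobic	6	Pseudomonas umsongensis DSM 16611(T)	Gammaproteobacteria	1430	99.7	-	-
R3.6_2	MN197569	aerobic	6	Pseudomonas umsongensis DSM 16611(T)	Gammaproteobacteria	1438	99.5	+	+
R3.6_3	MN197570	aerobic	6	Pseudomonas laurylsulfatiphila AP3_16(T)	Gammaproteobacteria	1376	99.4	+	+
R3.6_4	MN197571	aerobic	6	Pseudomonas laurentiana GSL-010(T)	Gammaproteobacteria	1439	99.6	+	+
RN3.6_1	MN197572	aerobic	6	Pseudomonas umsongensis DSM 16611(T)	Gammaproteobacteria	1446	99.0	-	-
RN3.6_3	MN197573	aerobic	6	Pseudomonas laurentiana GSL-010(T)	Gammaproteobacteria	1436	99.2	+	+
RN3.6_4	MN197574	aerobic	6	Pseudomonas silesiensis A3(T)	Gammaproteobacteria	1425	99.8	-	-
BGN3.6_1	MN197575	aerobic	6	Pseudomonas umsongensis DSM 16611(T)	Gammaproteobacteria	1425	99.9	-	-
BGN3.6_2	MN197576	aerobic	6	Pseudomonas reidholzensis CCOS 865(T)	Gammaproteobacteria	1437	99.5	-	-
BGN3.6_3	MN197577	aerobic	6	Pseudomonas frederiksbergensis JAJ28(T)	Gammaproteobacteria	1434	99.5	+	+
BGN3.6_4	MN197578	aerobic	6	Pseudomonas umsongensis DSM 16611(T)	Gammaproteobacteria	1438	99.9	+	+
BGN3.6_5	MN197579	aerobic	6	Pseudomonas laurentiana GSL-010(T)	Gammaproteobacteria	1352	99.3	+	+
BGN3.6_6	MN197580	aerobic	6	Pseudomonas frederiksbergensis JAJ28(T)	Gammaproteobacteria	1441	99.5	+	+
HR1.1_1	MN197581	oxygen-limited	2	Pseudomonas veronii DSM11331(T)	Gammaproteobacteria	1433	99.8	+	+
HR1.1_2	MN197582	oxygen-limited	2	Pseudomonas laurentiana GSL-010(T)	Gammaproteobacteria	1432	99.6	+	+
HR1.1_5	MN197583	oxygen-limited	2	Pseudomonas veronii DSM11331(T)	Gammaproteobacteria	1384	99.8	+	+
HBGN1.1_3	MN197584	oxygen-limited	2	Pseudomonas laurentiana GSL-010(T)	Gammaproteobacteria	1429	99.6	+	+
HBGN1.1_4	MN197585	oxygen-limited	2	Achromobacter anxifer LMG 26857	Gammaproteobacteria	1420	99.9	-	-
HR3.3_1	MN197586	oxygen-limited	6	Pseudomonas veronii DSM11331(T)	Gammaproteobacteria	1392	99.6	+	+
HR3.3_3	MN197587	oxygen-limited	6	Pseudomonas marginalis ATCC 10844(T)	Gammaproteobacteria	1360	99.3	+	+
HR3.3_4	MN197588	oxygen-limited	6	Pseudomonas marginalis ATCC 10844(T)	Gammaproteobacteria	1447	98.7	+	+
HR3.3_5	MN197589	oxygen-limited	6	Achromobacter spanius LMG 5911(T)	Gammaproteobacteria	1430	99.7	-	-
HRN3.3_1	MN197590	oxygen-limited	6	Pseudomonas veronii DSM11331(T)	Gammaproteobacteria	1441	99.6	+	+
HRN3.3_3	MN197591	oxygen-limited	6	Pseudomonas veronii DSM11331(T)	Gammaproteobacteria	1391	99.4	+	+
HRN3.3_4	MN197592	oxygen-limited	6	Pseudomonas veronii DSM11331(T)	Gammaproteobacteria	1440	99.8	+	+
HBGN3.3_1	MN197593	oxygen-limited	6	Pseudomonas veronii DSM11331(T)	Gammaproteobacteria	1438	99.6	+	+
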