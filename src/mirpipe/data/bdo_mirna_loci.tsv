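id	family	scaffold	start	end	strand	mature_sequence	mature_read_count
bdo-mir-2a-2	mir-2	scaffold00002	2204161	2204222	-	ucacagccagcuuugaugagcua	11192
bdo-mir-2a-1	mir-2	scaffold00002	2204624	2204688	-	uaucacagccagcuuugaugagcu	7541
bdo-mir-2b	mir-2	scaffold00002	2205153	2205237	-	uaucacagccagcuuugaggagcg	10527
bdo-mir-11593	mir-11593	scaffold00003	476312	476370	+	uccaugaaauucuguaauucug	1914
bdo-mir-11594	mir-11594	scaffold00003	477604	477663	+	guccaugaaauucuuuauuucug	224
bdo-mir-11	mir-11	scaffold00005	2323679	2323748	+	caucacagucugaguucuugcu	2123
bdo-mir-998	mir-998	scaffold00005	2326077	2326163	+	uagcaccaugagauucagcuc	243
bdo-mir-100	mir-100	scaffold00010	2862114	2862173	+	aacccguaaauccgaacuugug	82
bdo-let-7	let-7	scaffold00010	2862318	2862376	+	ugagguaguagguuguauagu	516
bdo-mir-125	mir-125	scaffold00010	2862662	2862722	+	ucccugagacccuaacuuguga	196
bdo-mir-2c	mir-2	scaffold00020	1019361	1019426	+	ucacagccagcuuugaugagca	4392
bdo-mir-13b	mir-13	scaffold00020	1021893	1021957	+	uaucacagccauuuugacgaguu	2289
bdo-mir-9b	mir-9	scaffold00027	1320119	1320184	-	ucuuuggugauuuuagcuguaug	1582
bdo-mir-79	mir-79	scaffold00027	1321251	1321313	-	uaaagcuagauuaccaaagcau	4037
bdo-mir-306	mir-306	scaffold00027	1321793	1321859	-	ccagguacuuagugacucuca	1412
bdo-mir-9c	mir-9	scaffold00027	1324096	1324160	-	ucuuugguauucuagcuguaga	1336
bdo-mir-5	mir-5	scaffold00054	203234	203297	-	aaaggaacguucguugugauau	676
bdo-mir-4	mir-4	scaffold00054	203558	203615	-	auaaagcuagacaaccauugca	668
bdo-mir-309b	mir-309	scaffold00054	203736	203796	-	ucacuggguaaaguuuguccca	542
bdo-mir-6	mir-6	scaffold00054	203902	203964	-	uaucacaguggcuguuccuuau	1764
bdo-mir-5b	mir-5	scaffold00054	204040	204101	-	uaucacagugauuuuccuugu	953
bdo-mir-286	mir-286	scaffold00054	204943	205010	-	ugacuagaccgaacacucgugcu	5017
bdo-mir-309	mir-309	scaffold00054	205266	205336	-	ucacuggguaaaguuuguccu	1086
bdo-mir-5c	mir-5	scaffold00054	206688	206749	-	uaucacagugauuuuccuugu	953
bdo-mir-12	mir-12	scaffold00073	1266978	1267046	+	ugaguauuacaucagguacugg	1833
bdo-mir-304	mir-304	scaffold00073	1266554	1266619	+	uaaucucaauuuguaacugugag	487
bdo-mir-283	mir-283	scaffold00073	1264481	1264548	+	aaauaucagcugguaauucugg	339
bdo-mir-994	mir-994	scaffold00147	463832	463903	-	uaaggaaauaguagccgugau	1180
bdo-mir-318	mir-318	scaffold00147	463659	463730	-	ucacugggcuuuguuuaucuca	343
bdo-mir-305	mir-305	scaffold03687	2585	2645	-	auuguacuucaucaggugcucugg	18881
bdo-mir-275	mir-275	scaffold03687	2783	2848	-	ucagguaccugaaguagcgcgcg	1720
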