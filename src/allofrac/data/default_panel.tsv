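target_id	chrom	pos	ref	alt	maf	is_control	maf_afr	maf_eur	maf_eas
SNP001	17	58544578	T	C	0.328	0	0.337	0.394	0.33
SNP002	18	103669602	T	A	0.282	0	0.292	0.265	0.34
SNP003	19	34041391	G	C	0.424	0	0.434	0.482	0.412
SNP004	3	199147280	A	C	0.499	0	0.446	0.457	0.416
SNP005	11	67291512	T	G	0.431	0	0.423	0.358	0.377
SNP006	18	77131078	T	C	0.424	0	0.397	0.418	0.384
SNP007	7	14661361	C	T	0.295	0	0.305	0.257	0.259
SNP008	12	137232386	T	G	0.336	0	0.37	0.286	0.339
SNP009	9	133930799	A	T	0.443	0	0.377	0.375	0.379
SNP010	5	47480649	G	A	0.415	0	0.42	0.425	0.5
SNP011	19	16230128	A	T	0.367	0	0.336	0.325	0.397
SNP012	2	38963030	C	T	0.443	0	0.5	0.441	0.452
SNP013	12	126870712	C	A	0.294	0	0.3	0.279	0.271
SNP014	2	161157313	C	T	0.368	0	0.333	0.38	0.365
SNP015	5	28958713	A	T	0.449	0	0.383	0.463	0.5
SNP016	6	88141787	T	A	0.413	0	0.42	0.454	0.425
SNP017	5	112386667	G	T	0.301	0	0.288	0.317	0.27
SNP018	8	73956783	G	A	0.376	0	0.357	0.409	0.423
SNP019	21	155591858	T	C	0.478	0	0.447	0.5	0.5
SNP020	12	93258971	G	T	0.385	0	0.324	0.376	0.362
SNP021	11	173901864	G	C	0.352	0	0.288	0.313	0.28
SNP022	16	42156469	G	T	0.44	0	0.468	0.426	0.429
SNP023	14	57441931	G	C	0.454	0	0.5	0.5	0.43
SNP024	6	16456560	C	A	0.397	0	0.369	0.365	0.274
SNP025	18	18861620	C	T	0.39	0	0.433	0.405	0.395
SNP026	3	8715551	C	A	0.42	0	0.433	0.443	0.426
SNP027	11	21493867	T	A	0.325	0	0.316	0.294	0.328
SNP028	11	163792481	G	A	0.384	0	0.381	0.423	0.361
SNP029	13	150554347	C	G	0.341	0	0.393	0.369	0.344
SNP030	22	4168591	G	A	0.296	0	0.263	0.292	0.286
SNP031	21	85189049	G	C	0.484	0	0.5	0.496	0.458
SNP032	2	15060838	C	T	0.333	0	0.411	0.301	0.311
SNP033	2	13130179	A	C	0.499	0	0.483	0.5	0.426
SNP034	11	120856222	A	C	0.356	0	0.348	0.295	0.367
SNP035	8	108742251	C	A	0.311	0	0.358	0.268	0.336
SNP036	6	53484554	G	C	0.494	0	0.498	0.5	0.418
SNP037	22	87253735	T	C	0.467	0	0.496	0.441	0.495
SNP038	21	132679976	A	G	0.337	0	0.316	0.293	0.315
SNP039	19	172265423	C	T	0.342	0	0.333	0.341	0.335
SNP040	22	58795807	C	A	0.323	0	0.366	0.253	0.334
SNP041	9	60281988	A	C	0.315	0	0.319	0.296	0.331
SNP042	3	191295750	C	A	0.379	0	0.364	0.429	0.407
SNP043	13	71374731	A	T	0.43	0	0.475	0.428	0.458
SNP044	12	106965601	T	G	0.414	0	0.437	0.426	0.371
SNP045	19	177024553	T	C	0.348	0	0.343	0.353	0.329
SNP046	20	158386277	T	G	0.409	0	0.403	0.369	0.374
SNP047	20	102119550	T	G	0.376	0	0.389	0.335	0.405
SNP048	10	25138003	T	A	0.426	0	0.367	0.394	0.44
SNP049	13	92458184	C	G	0.344	0	0.345	0.374	0.406
SNP050	4	69351101	C	T	0.346	0	0.303	0.366	0.341
SNP051	9	16432015	T	A	0.288	0	0.256	0.239	0.275
SNP052	15	141469705	C	T	0.47	0	0.462	0.496	0.459
SNP053	2	33490560	T	G	0.376	0	0.339	0.387	0.323
SNP054	9	114996969	C	G	0.396	0	0.34	0.439	0.428
SNP055	4	99943181	T	C	0.281	0	0.241	0.354	0.293
SNP056	16	164805714	G	C	0.445	0	0.497	0.373	0.425
SNP057	4	10885628	T	G	0.366	0	0.332	0.361	0.391
SNP058	7	134856970	C	A	0.295	0	0.277	0.284	0.367
SNP059	15	59389369	G	C	0.485	0	0.455	0.5	0.405
SNP060	20	67955676	G	C	0.476	0	0.459	0.431	0.444
SNP061	16	71594532	A	C	0.421	0	0.406	0.449	0.457
SNP062	15	170103586	G	T	0.488	0	0.5	0.5	0.5
SNP063	1	153144190	T	G	0.467	0	0.5	0.483	0.366
SNP064	10	9734032	C	A	0.333	0	0.347	0.34	0.292
SNP065	4	157456246	A	G	0.435	0	0.422	0.466	0.397
SNP066	9	103742937	C	T	0.305	0	0.343	0.344	0.281
SNP067	20	21321363	A	T	0.347	0	0.293	0.396	0.338
SNP068	7	29085832	C	G	0.409	0	0.373	0.414	0.35
SNP069	20	84374707	C	A	0.331	0	0.402	0.35	0.374
SNP070	12	120649694	T	G	0.474	0	0.491	0.457	0.5
SNP071	18	88826950	G	C	0.463	0	0.498	0.483	0.423
SNP072	3	29894000	G	C	0.464	0	0.461	0.5	0.463
SNP073	8	179529911	C	T	0.492	0	0.488	0.442	0.463
SNP074	15	166558341	T	C	0.392	0	0.425	0.452	0.39
SNP075	15	108225530	G	C	0.445	0	0.459	0.425	0.453
SNP076	20	123150535	T	G	0.404	0	0.37	0.436	0.398
SNP077	4	46955405	G	A	0.351	0	0.325	0.344	0.309
SNP078	3	103150192	T	C	0.349	0	0.423	0.354	0.354
SNP079	1	12516577	A	T	0.348	0	0.322	0.421	0.36
SNP080	6	185088243	C	A	0.321	0	0.291	0.301	0.381
SNP081	10	64735863	A	G	0.348	0	0.337	0.354	0.237
SNP082	4	26226476	A	G	0.492	0	0.458	0.5	0.461
SNP083	13	111937589	G	C	0.406	0	0.428	0.449	0.408
SNP084	14	20870654	C	G	0.376	0	0.433	0.447	0.374
SNP085	19	43692802	C	G	0.479	0	0.453	0.5	0.48
SNP086	7	87173216	G	A	0.399	0	0.38	0.346	0.402
SNP087	3	56741952	A	C	0.469	0	0.5	0.482	0.43
SNP088	8	35940207	G	A	0.497	0	0.475	0.5	0.5
SNP089	9	27060697	A	G	0.367	0	0.263	0.339	0.329
SNP090	3	66405607	T	G	0.285	0	0.253	0.285	0.257
SNP091	8	50110764	G	C	0.332	0	0.388	0.344	0.369
SNP092	11	112945127	C	A	0.329	0	0.393	0.328	0.298
SNP093	18	89133890	A	C	0.493	0	0.5	0.482	0.462
SNP094	20	49107479	A	G	0.401	0	0.364	0.344	0.437
CTRL01	4	126024333	T	A	0.354	1	0.409	0.326	0.409
CTRL02	12	119468968	C	G	0.446	1	0.417	0.459	0.383
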