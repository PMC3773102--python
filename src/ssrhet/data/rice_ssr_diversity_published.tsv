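marker	chromosome	n_alleles_2x	he_2x	shannon_2x	pic_2x	n_alleles_4x	he_4x	shannon_4x	pic_4x
PSM41	1	5	0.735	1.471	0.699	5	0.729	1.451	0.691
RM23	1	3	0.599	0.978	0.513	3	0.647	1.067	0.571
RM443	1	2	0.555	0.882	0.456	3	0.561	0.942	0.493
RM104	1	2	0.469	0.662	0.349	2	0.375	0.562	0.305
RM237	1	2	0.302	0.479	0.256	2	0.332	0.515	0.277
RM262	2	4	0.705	1.303	0.656	4	0.669	1.215	0.613
RM341	2	3	0.599	0.980	0.505	3	0.515	0.824	0.424
RM109	2	3	0.477	0.831	0.428	3	0.453	0.801	0.409
PSM122	2	3	0.619	1.018	0.539	3	0.611	1.011	0.536
RM498	2	3	0.542	0.884	0.457	3	0.492	0.800	0.411
RM29	2	2	0.499	0.693	0.375	2	0.485	0.678	0.368
RM526	2	2	0.498	0.691	0.374	2	0.497	0.690	0.373
RM211	2	2	0.485	0.678	0.368	2	0.455	0.647	0.352
RM106	2	2	0.368	0.555	0.300	2	0.432	0.624	0.339
PSM379	3	5	0.788	1.578	0.753	5	0.681	1.256	0.622
RM168	3	4	0.572	1.062	0.525	4	0.469	0.887	0.431
RM22	3	3	0.559	0.899	0.466	4	0.639	1.162	0.579
RM232	3	3	0.401	0.679	0.345	3	0.384	0.703	0.351
RM156	3	3	0.444	0.780	0.398	3	0.494	0.849	0.438
PSM381	3	3	0.656	1.081	0.581	3	0.662	1.091	0.588
RM565	3	3	0.226	0.461	0.214	3	0.536	0.916	0.478
RM282	3	3	0.609	0.998	0.526	2	0.435	0.627	0.341
PSM429	3	2	0.455	0.647	0.352	2	0.420	0.611	0.332
RM175	3	2	0.049	0.117	0.048	2	0.051	0.122	0.050
RM468	3	2	0.245	0.410	0.215	2	0.307	0.485	0.260
RM416	3	2	0.400	0.589	0.320	2	0.353	0.538	0.291
RM60	3	2	0.051	0.122	0.050	2	0.512	0.613	0.043
RM307	4	5	0.668	1.268	0.608	5	0.498	0.845	0.436
RM241	4	4	0.479	0.879	0.427	4	0.704	1.477	0.647
RM559	4	2	0.129	0.624	0.422	3	0.451	0.722	0.514
PSM194	4	3	0.547	0.932	0.488	3	0.508	0.781	0.404
RM255	4	2	0.293	0.469	0.250	2	0.208	0.362	0.186
RM471	4	2	0.394	0.584	0.317	2	0.495	0.688	0.372
RM261	4	2	0.478	0.671	0.364	2	0.278	0.451	0.239
PSM196	4	2	0.368	0.555	0.300	2	0.496	0.690	0.373
PSM133	4	2	0.260	0.429	0.226	2	0.488	0.681	0.369
RM273	4	2	0.191	0.341	0.173	2	0.412	0.602	0.327
RM164	5	4	0.724	1.327	0.672	4	0.681	1.261	0.632
RM480	5	4	0.698	1.268	0.641	4	0.543	1.010	0.495
RM31	5	4	0.650	1.166	0.585	4	0.719	1.314	0.665
RM122	5	3	0.513	0.785	0.406	3	0.495	0.688	0.372
RM249	5	3	0.579	0.963	0.506	3	0.605	1.008	0.534
PSM383	5	2	0.428	0.619	0.336	3	0.447	0.714	0.368
RM13	5	2	0.497	0.690	0.373	3	0.516	0.785	0.406
RM574	5	2	0.469	0.662	0.359	2	0.478	0.671	0.364
RM527	6	5	0.704	1.346	0.654	5	0.792	1.664	0.787
RM276	6	5	0.747	1.461	0.704	5	0.726	1.433	0.684
RM528	6	3	0.604	1.010	0.536	3	0.639	1.055	0.563
PSM138	6	3	0.566	0.919	0.477	3	0.573	0.922	0.479
RM510	6	3	0.529	0.808	0.418	3	0.570	0.947	0.496
RM340	6	3	0.474	0.807	0.414	4	0.575	1.063	0.526
RM275	6	2	0.149	0.281	0.138	2	0.284	0.458	0.244
RM103	6	2	0.334	0.517	0.278	2	0.368	0.555	0.300
PSM142	7	4	0.725	1.335	0.675	4	0.726	1.339	0.676
RM248	7	4	0.688	1.219	0.624	4	0.645	1.158	0.577
PSM147	7	3	0.528	0.805	0.416	3	0.355	0.540	0.244
RM234	7	2	0.467	0.660	0.358	2	0.415	0.606	0.329
RM560	7	2	0.157	0.293	0.144	2	0.165	0.305	0.496
RM455	7	2	0.450	0.642	0.349	2	0.478	0.671	0.526
RM44	8	4	0.397	0.761	0.363	4	0.260	0.429	0.226
RM210	8	3	0.526	0.836	0.431	3	0.542	0.884	0.684
RM152	8	3	0.539	0.851	0.439	3	0.571	0.918	0.676
RM458	8	2	0.255	0.423	0.223	2	0.420	0.611	0.300
RM408	8	2	0.432	0.624	0.339	2	0.367	0.554	0.329
PSM151	8	2	0.452	0.644	0.350	2	0.426	0.617	0.577
RM126	8	2	0.480	0.673	0.365	2	0.301	0.478	0.255
RM256	8	2	0.049	0.117	0.048	2	0.049	0.117	0.048
RM242	9	4	0.637	1.153	0.573	4	0.477	0.825	0.407
RM257	9	4	0.547	0.997	0.490	3	0.528	0.868	0.449
PSM399	9	3	0.535	0.878	0.454	3	0.374	0.688	0.343
PSM340	9	3	0.595	0.995	0.526	3	0.562	0.917	0.476
RM553	9	3	0.611	1.011	0.536	3	0.447	0.714	0.368
RM434	9	3	0.418	0.719	0.365	3	0.500	0.693	0.375
PSM160	9	2	0.486	0.679	0.368	2	0.482	0.675	0.366
RM591	10	5	0.785	1.572	0.751	5	0.744	1.472	0.704
PSM166	10	3	0.607	0.996	0.525	3	0.586	0.958	0.501
RM258	10	3	0.516	0.860	0.444	2	0.272	0.443	0.235
PSM163	10	2	0.266	0.436	0.231	2	0.420	0.611	0.332
PSM169	10	2	0.500	0.693	0.375	2	0.334	0.517	0.278
RM484	10	2	0.180	0.325	0.164	2	0.139	0.266	0.129
RM202	11	5	0.764	1.518	0.725	5	0.683	1.370	0.647
PSM365	11	5	0.749	1.477	0.708	5	0.727	1.405	0.682
RM224	11	5	0.740	1.467	0.700	5	0.718	1.362	0.666
PSM410	11	4	0.529	0.948	0.465	5	0.704	1.342	0.651
RM229	11	4	0.685	1.228	0.624	4	0.671	1.273	0.604
PSM173	11	3	0.517	0.788	0.408	3	0.532	0.847	0.437
RM167	11	3	0.528	0.805	0.416	3	0.610	1.018	0.541
RM254	11	3	0.538	0.919	0.480	3	0.595	0.995	0.526
PSM411	11	3	0.580	0.943	0.491	3	0.637	1.057	0.565
PSM416	11	2	0.498	0.691	0.374	2	0.500	0.693	0.375
PSM188	12	3	0.586	0.984	0.520	3	0.635	1.046	0.557
RM19	12	3	0.541	0.856	0.432	3	0.553	0.896	0.464
RM101	12	3	0.610	1.001	0.528	3	0.614	1.013	0.536
PSM419	12	3	0.618	1.030	0.549	3	0.514	0.826	0.425
PSM420	12	3	0.141	0.314	0.133	3	0.441	0.706	0.364
PSM187	12	2	0.349	0.533	0.288	2	0.289	0.464	0.247
RM463	12	2	0.293	0.469	0.250	2	0.307	0.485	0.260
PSM191	12	2	0.202	0.355	0.182	3	0.245	0.472	0.226
PSM190	12	2	0.497	0.690	0.374	2	0.498	0.691	0.374
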