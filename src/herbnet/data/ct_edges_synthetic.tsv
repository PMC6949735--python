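source	target
mol01	P03372
mol01	P35354
mol01	P35228
mol01	P23219
mol01	P29474
mol01	P37231
mol01	Q92731
mol01	P16389
mol01	P42574
mol01	P01375
mol01	P08709
mol01	Q04206
mol01	P01584
mol01	P10415
mol01	P11388
mol01	P27338
mol01	P00749
mol01	P01579
mol01	P04637
mol01	P05362
mol01	P05412
mol01	P28223
mol01	P38936
mol01	P55211
mol01	P01100
mol01	P01137
mol01	P03956
mol01	P05231
mol01	P08588
mol01	P09211
mol01	P09601
mol01	P09917
mol01	P24385
mol01	Q14790
mol01	O15392
mol01	P00441
mol01	P05177
mol01	P05771
mol01	P06400
mol01	P08253
mol01	P09488
mol01	P10145
mol01	P14780
mol01	P15559
mol01	P15692
mol01	P17252
mol01	P19320
mol01	P29466
mol01	P31749
mol01	P35869
mol01	P42224
mol01	P60568
mol01	Q16678
mol01	O95456
mol01	O96017
mol01	P00325
mol01	P00533
mol01	P00750
mol01	P01106
mol01	P01133
mol01	P01308
mol01	P01344
mol01	P02741
mol01	P02778
mol01	P04040
mol01	P04141
mol01	P04626
mol01	P04792
mol01	P05112
mol01	P05164
mol01	P07858
mol01	P09038
mol01	P09874
mol41	P03372
mol41	P35354
mol41	P35228
mol41	P23219
mol41	P29474
mol41	P37231
mol41	Q92731
mol41	P16389
mol41	P42574
mol41	P01375
mol41	P08709
mol41	Q04206
mol41	P01584
mol41	P10415
mol41	P11388
mol41	P27338
mol41	P00749
mol41	P01579
mol41	P04637
mol41	P05362
mol41	P05412
mol41	P28223
mol41	P38936
mol41	P55211
mol41	P01100
mol41	P01137
mol41	P03956
mol41	P05231
mol41	P08588
mol41	P09211
mol41	P09601
mol41	P09917
mol41	P24385
mol41	Q14790
mol41	O15392
mol17	P03372
mol17	P35354
mol17	P35228
mol17	P23219
mol17	P29474
mol17	P37231
mol17	Q92731
mol17	P16389
mol17	P42574
mol17	P01375
mol17	P08709
mol17	Q04206
mol17	P01584
mol17	P10415
mol17	P11388
mol17	P27338
mol17	P00749
mol17	P01579
mol17	P04637
mol17	P05362
mol17	P05412
mol17	P28223
mol17	P38936
mol17	P55211
mol17	P00441
mol17	P01100
mol16	P03372
mol16	P35354
mol16	P35228
mol16	P23219
mol16	P29474
mol16	P37231
mol16	Q92731
mol16	P16389
mol16	P42574
mol16	P01375
mol16	P08709
mol16	Q04206
mol16	P01584
mol16	P10415
mol16	P11388
mol33	P03372
mol33	P35354
mol33	P35228
mol33	P23219
mol33	P29474
mol33	P37231
mol33	Q92731
mol33	P16389
mol33	P42574
mol33	P01375
mol33	P08709
mol33	P27338
mol33	Q04206
mol33	P00749
mol33	P01137
mol32	P03372
mol32	P35354
mol32	P35228
mol32	P23219
mol32	P29474
mol32	P37231
mol32	Q92731
mol32	P16389
mol32	P42574
mol32	P01375
mol32	P01579
mol18	P03372
mol18	P35354
mol18	P35228
mol18	P23219
mol18	P29474
mol18	P37231
mol18	Q92731
mol18	P16389
mol18	P01584
mol18	P03956
mol31	P03372
mol31	P35354
mol31	P35228
mol31	P23219
mol31	P29474
mol31	P37231
mol31	Q92731
mol31	P16389
mol31	P04637
mol31	P05177
mol03	P03372
mol03	P35354
mol03	P35228
mol03	P23219
mol03	P29474
mol03	P37231
mol03	Q92731
mol03	P16389
mol03	P05231
mol04	P03372
mol04	P35354
mol04	P35228
mol04	P23219
mol04	P29474
mol04	P37231
mol04	Q92731
mol04	P16389
mol04	P05362
mol06	P03372
mol06	P35354
mol06	P35228
mol06	P23219
mol06	P29474
mol06	P37231
mol06	Q92731
mol06	P16389
mol06	P05412
mol12	P03372
mol12	P35354
mol12	P35228
mol12	P23219
mol12	P29474
mol12	P37231
mol12	Q92731
mol12	P16389
mol12	P05771
mol13	P03372
mol13	P35354
mol13	P35228
mol13	P23219
mol13	P29474
mol13	P37231
mol13	Q92731
mol13	P06400
mol13	P08253
mol15	P03372
mol15	P35354
mol15	P35228
mol15	P23219
mol15	P29474
mol15	P37231
mol15	Q92731
mol15	P08588
mol15	P08709
mol24	P03372
mol24	P35354
mol24	P35228
mol24	P23219
mol24	P29474
mol24	P37231
mol24	Q92731
mol24	P09211
mol24	P09488
mol05	P03372
mol05	P35354
mol05	P35228
mol05	P23219
mol05	P29474
mol05	P37231
mol05	Q92731
mol05	P09601
mol07	P03372
mol07	P35354
mol07	P35228
mol07	P23219
mol07	P29474
mol07	P37231
mol07	P09917
mol07	P10145
mol09	P03372
mol09	P35354
mol09	P35228
mol09	P23219
mol09	P29474
mol09	P37231
mol09	P10415
mol09	P11388
mol10	P03372
mol10	P35354
mol10	P35228
mol10	P23219
mol10	P29474
mol10	P37231
mol10	P11926
mol10	P13500
mol19	P03372
mol19	P35354
mol19	P35228
mol19	P23219
mol19	P29474
mol19	P37231
mol19	P14780
mol19	P15336
mol02	P03372
mol02	P35354
mol02	P35228
mol02	P23219
mol02	P15559
mol02	P15692
mol02	P16389
mol11	P03372
mol11	P35354
mol11	P35228
mol11	P23219
mol11	P17252
mol11	P17677
mol11	P17936
mol35	P03372
mol35	P35354
mol35	P35228
mol35	P18031
mol35	P18509
mol35	P19320
mol35	P19875
mol08	P03372
mol08	P35354
mol08	P35228
mol08	P21731
mol08	P21860
mol08	P22301
mol30	P03372
mol30	P35354
mol30	P23219
mol30	P24385
mol30	P27338
mol30	P28223
mol37	P03372
mol37	P35354
mol37	P28702
mol37	P29466
mol37	P29474
mol37	P30279
mol22	P03372
mol22	P31749
mol22	P35228
mol22	P35354
mol22	P35869
mol29	P03372
mol29	P37231
mol29	P38936
mol29	P40763
mol29	P42224
mol34	P03372
mol34	P42574
mol34	P55211
mol34	P60484
mol34	P60568
mol21	P03372
mol21	P84022
mol21	Q00534
mol14	P03372
mol14	Q04206
mol20	P03372
mol23	P03372
mol25	P03372
mol26	Q07869
mol27	Q14790
mol28	Q16236
mol36	Q16678
mol38	Q92731
mol39	Q9NS23
mol40	Q9UNQ0
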