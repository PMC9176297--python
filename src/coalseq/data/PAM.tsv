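# synthetic PAM250-derived mutation matrix (inverse log-odds, fixed-point target frequencies)
A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
1.53097630765e-24	8.4776535101e-17	1.30989658031e-22	2.15898035163e-25	1.24797311193e-25	1.71780288558e-23	2.08832657135e-25	1.48328529322e-25	1.72147886101e-21	1.87784924356e-23	1.05945390959e-20	1.12877750767e-21	1.67014238409e-22	1.8812686897e-18	1.70787142349e-24	9.40675057414e-21	1.3499357045e-23	1	2.45150373706e-18	1.98479456063e-24
0	6.73403954728e-15	6.56503443425e-20	2.15898035163e-22	9.9130027898e-23	1.08386034703e-20	2.08832657135e-22	1.86734554858e-22	5.44379414463e-19	9.4115406755e-21	2.11388846026e-18	3.56950789581e-19	6.64895658952e-20	1.8812686897e-16	1.70787142349e-21	3.74489485517e-18	1.07229204515e-20	1	2.45150373706e-16	1.57657835964e-21
1.21609770786e-22	0	1.04048783831e-20	2.71799522823e-23	9.9130027898e-24	2.16258570511e-21	2.6290473888e-23	1.17821538856e-23	1.72147886101e-19	1.18484277205e-21	2.66122790031e-19	1.42104668867e-19	1.32664125169e-20	2.36837695987e-17	2.1500827351e-22	4.71454329767e-19	1.07229204515e-21	1	3.08626035169e-17	1.57657835964e-22
7.6730578038e-22	6.73403954728e-15	0	2.15898035163e-22	3.94643749234e-23	8.6094087614e-21	1.65881675895e-22	9.35889749718e-23	6.85333078525e-19	4.71694403533e-21	1.05945390959e-18	3.56950789581e-19	3.33237215961e-20	1.1870002967e-16	8.55963354128e-22	2.36286891318e-18	5.37419083748e-21	1	1.94729863588e-16	6.27647149911e-22
1.53097630765e-21	1.06727334363e-14	1.30989658031e-19	0	6.25468191608e-23	2.16258570511e-20	5.24563917913e-22	2.35084876371e-22	1.08617973072e-18	9.4115406755e-21	1.67912128904e-18	5.65728876451e-19	5.28145395051e-20	1.1870002967e-16	1.35661049295e-21	3.74489485517e-18	1.07229204515e-20	1	2.45150373706e-16	1.25232070532e-21
1.21609770786e-21	6.73403954728e-15	4.14225669306e-20	1.08205338989e-22	0	5.43216968964e-21	1.0466426172e-22	1.17821538856e-22	5.44379414463e-19	1.18484277205e-20	1.33377344941e-18	2.25220722304e-19	4.19520799329e-20	2.36837695987e-16	1.07759401808e-21	4.71454329767e-18	8.51751847331e-21	1	7.75233550152e-16	1.57657835964e-21
9.65980745538e-22	1.06727334363e-14	6.56503443425e-20	2.71799522823e-22	3.94643749234e-23	0	2.6290473888e-22	9.35889749718e-23	1.08617973072e-18	5.93828071208e-21	1.67912128904e-18	4.49374419764e-19	5.28145395051e-20	9.42867850298e-17	1.07759401808e-21	1.87689349269e-18	5.37419083748e-21	1	1.54679428792e-16	7.90160946663e-22
1.53097630765e-21	1.06727334363e-14	1.04048783831e-19	5.42311345116e-22	6.25468191608e-23	2.16258570511e-20	0	1.86734554858e-22	1.08617973072e-18	9.4115406755e-21	2.11388846026e-18	5.65728876451e-19	6.64895658952e-20	1.49434483733e-16	1.35661049295e-21	3.74489485517e-18	1.07229204515e-20	1	2.45150373706e-16	1.25232070532e-21
1.92738497856e-21	6.73403954728e-15	8.26488867858e-20	3.42175326196e-22	9.9130027898e-23	1.08386034703e-20	2.6290473888e-22	0	5.44379414463e-19	7.47585249081e-21	1.67912128904e-18	3.56950789581e-19	5.28145395051e-20	1.49434483733e-16	1.70787142349e-21	4.71454329767e-18	1.07229204515e-20	1	1.94729863588e-16	1.57657835964e-21
4.84137217593e-22	8.4776535101e-15	5.21479221306e-20	1.36222450945e-22	3.94643749234e-23	1.08386034703e-20	1.31764498787e-22	4.69055994641e-23	0	3.74680182887e-21	1.05945390959e-18	2.25220722304e-19	2.64699729499e-20	1.1870002967e-16	6.79915860074e-22	1.18423973402e-18	3.39088517955e-21	1	2.45150373706e-16	4.98557852619e-22
7.6730578038e-22	5.34903774616e-15	3.29031144677e-20	1.08205338989e-22	7.87417800684e-23	5.43216968964e-21	1.0466426172e-22	5.90506511208e-23	3.43480189739e-19	0	4.2177619828e-18	2.25220722304e-19	1.05378860357e-19	3.75362452088e-16	6.79915860074e-22	1.87689349269e-18	6.76570541314e-21	1	3.08626035169e-16	3.14568738758e-21
3.05469933177e-22	2.12949028231e-15	1.30989658031e-20	3.42175326196e-23	1.57110506384e-23	2.72253409934e-21	4.16675930916e-23	2.35084876371e-23	1.72147886101e-19	7.47585249081e-21	0	8.96619845065e-20	8.37054041247e-20	2.36837695987e-16	2.70679379268e-22	5.93525836245e-19	2.13950390832e-21	1	1.54679428792e-16	9.94753695162e-22
4.84137217593e-22	1.06727334363e-14	4.14225669306e-20	1.08205338989e-22	2.49003372032e-23	6.83869646346e-21	1.0466426172e-22	4.69055994641e-23	3.43480189739e-19	3.74680182887e-21	8.41554153778e-19	0	4.19520799329e-20	5.9490939502e-17	5.40076364893e-22	1.49086949481e-18	4.26887152101e-21	1	9.75961216361e-17	4.98557852619e-22
6.09492646023e-22	6.73403954728e-15	2.61358728321e-20	6.82729533471e-23	3.13476672674e-23	5.43216968964e-21	8.31377782511e-23	4.69055994641e-23	2.72836012778e-19	1.18484277205e-20	5.30984774104e-18	2.83536090571e-19	0	2.36837695987e-16	5.40076364893e-22	1.18423973402e-18	4.26887152101e-21	1	1.94729863588e-16	1.57657835964e-21
1.53097630765e-22	1.06727334363e-15	8.26488867858e-21	1.36222450945e-23	1.57110506384e-23	8.6094087614e-22	1.65881675895e-23	1.17821538856e-23	1.08617973072e-19	3.74680182887e-21	1.33377344941e-18	3.56950789581e-20	2.10258468865e-20	0	1.07759401808e-22	3.74489485517e-19	1.07229204515e-21	1	6.15789897391e-16	3.14568738758e-22
1.53097630765e-21	1.06727334363e-14	6.56503443425e-20	1.71493905152e-22	7.87417800684e-23	1.08386034703e-20	1.65881675895e-22	1.48328529322e-22	6.85333078525e-19	7.47585249081e-21	1.67912128904e-18	3.56950789581e-19	5.28145395051e-20	1.1870002967e-16	0	3.74489485517e-18	8.51751847331e-21	1	1.54679428792e-16	1.25232070532e-21
6.09492646023e-22	4.24889171038e-15	3.29031144677e-20	8.59505559069e-23	6.25468191608e-23	3.42746736214e-21	8.31377782511e-23	7.4340365279e-23	2.16721348399e-19	3.74680182887e-21	6.68470225396e-19	1.78899178771e-19	2.10258468865e-20	7.48946555106e-17	6.79915860074e-22	0	4.26887152101e-21	1	9.75961216361e-17	4.98557852619e-22
1.21609770786e-21	6.73403954728e-15	5.21479221306e-20	1.71493905152e-22	7.87417800684e-23	6.83869646346e-21	1.65881675895e-22	1.17821538856e-22	4.3241593931e-19	9.4115406755e-21	1.67912128904e-18	3.56950789581e-19	5.28145395051e-20	1.49434483733e-16	1.07759401808e-21	2.97467571954e-18	0	1	1.94729863588e-16	1.25232070532e-21
1.7176406964e-08	0.951129198156	1.46960580851e-06	2.42221417546e-09	1.4001323171e-09	1.92724611734e-07	2.34294592829e-09	1.66413495184e-09	1.93137028632e-05	2.10680613823e-07	0.000118862789841	1.26640378082e-05	1.87377460602e-06	0.0211064250056	1.91610376107e-08	0.000105536692673	1.5145267056e-07	0	0.0275040349423	2.22679077024e-08
1.53097630765e-22	1.06727334363e-15	1.04048783831e-20	2.15898035163e-23	3.94643749234e-23	1.08386034703e-21	2.08832657135e-23	1.17821538856e-23	1.72147886101e-19	2.36407213224e-21	6.68470225396e-19	4.49374419764e-20	1.32664125169e-20	4.72553329567e-16	1.07759401808e-22	3.74489485517e-19	1.07229204515e-21	1	0	2.49870830957e-22
1.21609770786e-21	6.73403954728e-15	4.14225669306e-20	1.36222450945e-22	9.9130027898e-23	6.83869646346e-21	1.31764498787e-22	1.17821538856e-22	4.3241593931e-19	2.97619048259e-20	5.30984774104e-18	2.83536090571e-19	1.32664125169e-19	2.98160993949e-16	1.07759401808e-21	2.36286891318e-18	8.51751847331e-21	1	3.08626035169e-16	0
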