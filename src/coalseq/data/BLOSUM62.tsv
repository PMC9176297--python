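# synthetic BLOSUM62-derived mutation matrix (inverse log-odds, fixed-point target frequencies)
A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
1.48093638221e-24	1.77098773052e-24	9.94341384278e-26	6.78794246384e-26	1.49701656514e-21	8.61688112177e-23	2.33050895563e-24	4.30619219256e-23	5.38402446632e-22	1.3858266276e-24	4.55298975178e-23	2.01274395376e-24	2.64886013488e-21	4.45864289004e-18	7.37216178916e-26	1.95899321069e-24	6.33459595694e-23	1	3.76367970934e-16	1.4772260839e-24
0	4.53372859013e-22	2.54551394375e-23	1.73771327074e-23	3.83236240677e-19	1.55982209891e-20	5.96610292642e-22	1.10238520129e-20	6.89155131689e-20	3.54771616665e-22	8.24179181608e-21	5.15262452163e-22	3.39054097264e-19	2.01775143836e-16	2.66900766368e-23	1.00300452387e-21	1.62165656498e-20	1	1.20437750699e-14	5.34812969611e-22
3.79119713846e-22	0	5.0910278875e-23	1.73771327074e-23	1.35494472289e-19	3.11964419783e-20	8.43734367306e-22	5.51192600647e-21	1.37831026338e-19	1.77385808333e-22	5.82782688228e-21	1.45738229606e-21	3.39054097264e-19	1.42676572481e-16	1.88727341802e-23	5.01502261937e-22	1.14668435385e-20	1	1.20437750699e-14	1.89084938739e-22
3.79119713846e-22	9.06745718027e-22	0	6.95085308297e-23	1.91618120338e-19	3.11964419783e-20	1.19322058528e-21	1.55900810263e-20	2.75662052675e-19	2.50861415916e-22	5.82782688228e-21	1.03052490433e-21	3.39054097264e-19	2.01775143836e-16	2.66900766368e-23	1.41846260078e-21	2.2933687077e-20	1	1.7032470046e-14	2.67406484806e-22
3.79119713846e-22	4.53372859013e-22	1.0182055775e-22	0	1.91618120338e-19	3.11964419783e-20	2.38644117057e-21	1.10238520129e-20	1.37831026338e-19	2.50861415916e-22	4.12089590804e-21	7.2869114803e-22	2.39747451365e-19	2.01775143836e-16	3.77454683605e-23	1.00300452387e-21	1.62165656498e-20	1	1.20437750699e-14	2.67406484806e-22
3.79119713846e-22	1.60291511507e-22	1.27275697188e-23	8.68856635371e-24	0	5.51480391793e-21	1.49152573161e-22	2.75596300324e-21	3.44577565844e-20	2.50861415916e-22	5.82782688228e-21	1.82172787008e-22	2.39747451365e-19	1.42676572481e-16	9.43636709012e-24	3.54615650196e-22	8.10828282489e-21	1	8.516235023e-15	2.67406484806e-22
2.68078120542e-22	6.41166046029e-22	3.59990034246e-23	2.457497675e-23	9.58090601692e-20	0	1.19322058528e-21	3.89752025657e-21	9.74612533813e-20	1.25430707958e-22	4.12089590804e-21	7.2869114803e-22	3.39054097264e-19	1.00887571918e-16	1.88727341802e-23	5.01502261937e-22	8.10828282489e-21	1	1.20437750699e-14	1.89084938739e-22
3.79119713846e-22	6.41166046029e-22	5.0910278875e-23	6.95085308297e-23	9.58090601692e-20	4.41184313435e-20	0	5.51192600647e-21	1.37831026338e-19	1.77385808333e-22	4.12089590804e-21	1.03052490433e-21	2.39747451365e-19	1.42676572481e-16	2.66900766368e-23	7.09231300392e-22	1.14668435385e-20	1	1.20437750699e-14	2.67406484806e-22
3.79119713846e-22	2.26686429507e-22	3.59990034246e-23	1.73771327074e-23	9.58090601692e-20	7.79911049457e-21	2.98305146321e-22	0	4.87306266907e-20	8.86929041663e-23	2.06044795402e-21	2.57631226081e-22	1.19873725682e-19	1.00887571918e-16	1.33450383184e-23	5.01502261937e-22	5.73342176926e-21	1	6.02188753494e-15	1.33703242403e-22
1.89559856923e-22	4.53372859013e-22	5.0910278875e-23	1.73771327074e-23	9.58090601692e-20	1.55982209891e-20	5.96610292642e-22	3.89752025657e-21	0	1.25430707958e-22	2.91391344114e-21	3.64345574015e-22	1.69527048632e-19	2.01775143836e-16	1.33450383184e-23	3.54615650196e-22	5.73342176926e-21	1	3.4064940092e-14	1.33703242403e-22
3.79119713846e-22	2.26686429507e-22	1.79995017123e-23	1.2287488375e-23	2.70988944579e-19	7.79911049457e-21	2.98305146321e-22	2.75596300324e-21	4.87306266907e-20	0	2.33113075291e-20	2.57631226081e-22	6.78108194529e-19	4.03550287672e-16	1.33450383184e-23	3.54615650196e-22	1.14668435385e-20	1	1.7032470046e-14	1.51267950992e-21
2.68078120542e-22	2.26686429507e-22	1.27275697188e-23	6.1437441875e-24	1.91618120338e-19	7.79911049457e-21	2.10933591826e-22	1.94876012829e-21	3.44577565844e-20	7.0954323333e-22	0	2.57631226081e-22	6.78108194529e-19	2.85353144962e-16	9.43636709012e-24	2.50751130969e-22	8.10828282489e-21	1	1.20437750699e-14	5.34812969611e-22
3.79119713846e-22	1.28233209206e-21	5.0910278875e-23	2.457497675e-23	1.35494472289e-19	3.11964419783e-20	1.19322058528e-21	5.51192600647e-21	9.74612533813e-20	1.77385808333e-22	5.82782688228e-21	0	3.39054097264e-19	1.42676572481e-16	2.66900766368e-23	7.09231300392e-22	1.14668435385e-20	1	1.20437750699e-14	2.67406484806e-22
1.89559856923e-22	2.26686429507e-22	1.27275697188e-23	6.1437441875e-24	1.35494472289e-19	1.10296078359e-20	2.10933591826e-22	1.94876012829e-21	3.44577565844e-20	3.54771616665e-22	1.16556537646e-20	2.57631226081e-22	0	2.01775143836e-16	9.43636709012e-24	2.50751130969e-22	5.73342176926e-21	1	8.516235023e-15	3.78169877479e-22
6.70195301356e-23	5.66716073767e-23	4.49987542808e-24	3.07187209375e-24	4.79045300846e-20	1.94977762364e-21	7.45762865803e-23	9.74380064144e-22	2.43653133453e-20	1.25430707958e-22	2.91391344114e-21	6.44078065204e-23	1.19873725682e-19	0	2.35909177253e-24	8.8653912549e-23	2.02707070622e-21	1	1.7032470046e-14	9.45424693697e-23
5.36156241085e-22	4.53372859013e-22	3.59990034246e-23	3.47542654149e-23	1.91618120338e-19	2.20592156717e-20	8.43734367306e-22	7.79504051315e-21	9.74612533813e-20	2.50861415916e-22	5.82782688228e-21	7.2869114803e-22	3.39054097264e-19	1.42676572481e-16	0	7.09231300392e-22	1.62165656498e-20	1	1.20437750699e-14	3.78169877479e-22
7.58239427693e-22	4.53372859013e-22	7.19980068492e-23	3.47542654149e-23	2.70988944579e-19	2.20592156717e-20	8.43734367306e-22	1.10238520129e-20	9.74612533813e-20	2.50861415916e-22	5.82782688228e-21	7.2869114803e-22	3.39054097264e-19	2.01775143836e-16	2.66900766368e-23	0	2.2933687077e-20	1	1.20437750699e-14	2.67406484806e-22
3.79119713846e-22	3.20583023014e-22	3.59990034246e-23	1.73771327074e-23	1.91618120338e-19	1.10296078359e-20	4.21867183653e-22	3.89752025657e-21	4.87306266907e-20	2.50861415916e-22	5.82782688228e-21	3.64345574015e-22	2.39747451365e-19	1.42676572481e-16	1.88727341802e-23	7.09231300392e-22	0	1	8.516235023e-15	3.78169877479e-22
3.88869143487e-09	4.65031780005e-09	2.61097429358e-10	1.78240024599e-10	3.93091530782e-06	2.26264897102e-07	6.11952702596e-09	1.13073410156e-07	1.41375484314e-06	3.63894911469e-09	1.19553901596e-07	5.28512923823e-09	6.9554640175e-06	0.0117076510685	1.93580647692e-10	5.14398877014e-09	1.66335902994e-07	0	0.988279390331	3.8789488116e-09
4.73899642308e-23	5.66716073767e-23	4.49987542808e-24	2.17214158843e-24	3.38736180724e-20	2.75740195897e-21	7.45762865803e-23	6.88990750809e-22	4.87306266907e-20	6.27153539791e-23	1.45695672057e-21	6.44078065204e-23	5.99368628412e-20	2.01775143836e-16	2.35909177253e-24	6.26877827421e-23	1.43335544231e-21	1	0	6.68516212014e-23
5.36156241084e-22	2.26686429507e-22	1.79995017123e-23	1.2287488375e-23	2.70988944579e-19	1.10296078359e-20	4.21867183653e-22	3.89752025657e-21	4.87306266907e-20	1.41908646666e-21	1.64835836322e-20	3.64345574015e-22	6.78108194529e-19	2.85353144962e-16	1.88727341802e-23	3.54615650196e-22	1.62165656498e-20	1	1.7032470046e-14	0
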