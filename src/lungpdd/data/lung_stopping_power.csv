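energy_MeV,value
1.00000000e-03,1.18434090e+02
1.07384763e-03,1.13179321e+02
1.15314873e-03,1.08089772e+02
1.23830602e-03,1.03167615e+02
1.32975199e-03,9.84139374e+01
1.42795101e-03,9.38288894e+01
1.53340181e-03,8.94118018e+01
1.64663989e-03,8.51613007e+01
1.76824034e-03,8.10754067e+01
1.89882070e-03,7.71516248e+01
2.03904410e-03,7.33870249e+01
2.18962267e-03,6.97783134e+01
2.35132111e-03,6.63218968e+01
2.52496059e-03,6.30139386e+01
2.71142294e-03,5.98504102e+01
2.91165509e-03,5.68271346e+01
3.12667391e-03,5.39398268e+01
3.35757136e-03,5.11841278e+01
3.60552003e-03,4.85556351e+01
3.87177913e-03,4.60499296e+01
4.15770084e-03,4.36625986e+01
4.46473718e-03,4.13892556e+01
4.79444742e-03,3.92255579e+01
5.14850599e-03,3.71672211e+01
5.52871094e-03,3.52100318e+01
5.93699312e-03,3.33498580e+01
6.37542598e-03,3.15826579e+01
6.84623606e-03,2.99044869e+01
7.35181435e-03,2.83115036e+01
7.89472839e-03,2.67999744e+01
8.47773535e-03,2.53662762e+01
9.10379599e-03,2.40068996e+01
9.77608972e-03,2.27184501e+01
1.04980308e-02,2.14976489e+01
1.12732854e-02,2.03413333e+01
1.21057908e-02,1.92464558e+01
1.29997747e-02,1.82100839e+01
1.39597772e-02,1.72293980e+01
1.49906737e-02,1.63016904e+01
1.60976993e-02,1.54243630e+01
1.72864762e-02,1.45949250e+01
1.85630415e-02,1.38109906e+01
1.99338781e-02,1.30702765e+01
2.14059477e-02,1.23705988e+01
2.29867261e-02,1.17098705e+01
2.46842413e-02,1.10860984e+01
2.65071139e-02,1.04973801e+01
2.84646014e-02,9.94190113e+00
3.05666447e-02,9.41793185e+00
3.28239188e-02,8.92382438e+00
3.52478874e-02,8.45800966e+00
3.78508602e-02,8.01899449e+00
4.06460564e-02,7.60535855e+00
4.36476712e-02,7.21575155e+00
4.68709482e-02,6.84889039e+00
5.03322565e-02,6.50355639e+00
5.40491742e-02,6.17859258e+00
5.80405775e-02,5.87290106e+00
6.23267364e-02,5.58544046e+00
6.69294180e-02,5.31522342e+00
7.18719967e-02,5.06131419e+00
7.71795731e-02,4.82282630e+00
8.28791015e-02,4.59892027e+00
8.89995265e-02,4.38880145e+00
9.55719303e-02,4.19171788e+00
1.02629691e-01,4.00695828e+00
1.10208650e-01,3.83385005e+00
1.18347297e-01,3.67175740e+00
1.27086964e-01,3.52007950e+00
1.36472035e-01,3.37824872e+00
1.46550171e-01,3.24572896e+00
1.57372553e-01,3.12201395e+00
1.68994143e-01,3.00662574e+00
1.81473959e-01,2.89911312e+00
1.94875380e-01,2.79905021e+00
2.09266465e-01,2.70603500e+00
2.24720297e-01,2.61968802e+00
2.41315357e-01,2.53965102e+00
2.59135924e-01,2.46558569e+00
2.78272497e-01,2.39717251e+00
2.98822261e-01,2.33410950e+00
3.20889576e-01,2.27611117e+00
3.44586509e-01,2.22290742e+00
3.70033406e-01,2.17424253e+00
3.97359495e-01,2.12987421e+00
4.26703550e-01,2.08957262e+00
4.58214595e-01,2.05280158e+00
4.92052656e-01,2.01897852e+00
5.28389577e-01,1.98841606e+00
5.67409893e-01,1.96093036e+00
6.09311767e-01,1.93634466e+00
6.54307996e-01,1.91448889e+00
7.02627089e-01,1.89519935e+00
7.54514432e-01,1.87831836e+00
8.10233532e-01,1.86369404e+00
8.70067356e-01,1.85118007e+00
9.34319766e-01,1.84063555e+00
1.00331706e+00,1.83192484e+00
1.07740965e+00,1.82491746e+00
1.15697379e+00,1.81948808e+00
1.24241356e+00,1.81551640e+00
1.33416286e+00,1.81288718e+00
1.43268762e+00,1.81149024e+00
1.53848820e+00,1.81122044e+00
1.65210190e+00,1.81197768e+00
1.77410571e+00,1.81366693e+00
1.90511920e+00,1.81619824e+00
2.04580774e+00,1.81948665e+00
2.19688578e+00,1.82345225e+00
2.35912059e+00,1.82802008e+00
2.53333604e+00,1.83312010e+00
2.72041690e+00,1.83868705e+00
2.92131323e+00,1.84466042e+00
3.13704528e+00,1.85098426e+00
3.36870863e+00,1.85760710e+00
3.61747977e+00,1.86448173e+00
3.88462207e+00,1.87156508e+00
4.17149219e+00,1.87881801e+00
4.47954699e+00,1.88620514e+00
4.81035091e+00,1.89369464e+00
5.16558391e+00,1.90125800e+00
5.54705003e+00,1.90886987e+00
5.95668651e+00,1.91650786e+00
6.39657367e+00,1.92415227e+00
6.86894546e+00,1.93178598e+00
7.37620078e+00,1.93939420e+00
7.92091571e+00,1.94696429e+00
8.50585654e+00,1.95448561e+00
9.13399386e+00,1.96194933e+00
9.80851764e+00,1.96934829e+00
1.05328534e+01,1.97667681e+00
1.13106796e+01,1.98393059e+00
1.21459465e+01,1.99110658e+00
1.30428958e+01,1.99820281e+00
1.40060827e+01,2.00521835e+00
1.50403987e+01,2.01215313e+00
1.61510964e+01,2.01900792e+00
1.73438166e+01,2.02578420e+00
1.86246163e+01,2.03248408e+00
2.00000000e+01,2.03911024e+00
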