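energy_MeV,value
1.00000000e-03,5.32752108e+03
1.07384763e-03,4.22635615e+03
1.15314873e-03,3.35280421e+03
1.23830602e-03,2.65981720e+03
1.32975199e-03,2.11007199e+03
1.42795101e-03,1.67396020e+03
1.53340181e-03,1.32799358e+03
1.64663989e-03,1.05353893e+03
1.76824034e-03,8.35814582e+02
1.89882070e-03,6.63094270e+02
2.03904410e-03,5.26075565e+02
2.18962267e-03,4.17378870e+02
2.35132111e-03,3.31149967e+02
2.52496059e-03,2.62744715e+02
2.71142294e-03,2.08478927e+02
2.91165509e-03,1.65429944e+02
3.12667391e-03,1.31279227e+02
3.35757136e-03,1.04187483e+02
3.60552003e-03,8.26956048e+01
3.87177913e-03,6.56460849e+01
4.15770084e-03,5.21206749e+01
4.46473718e-03,4.13909301e+01
4.79444742e-03,3.28789763e+01
5.14850599e-03,2.61263869e+01
5.52871094e-03,2.07694925e+01
5.93699312e-03,1.65197947e+01
6.37542598e-03,1.31484281e+01
6.84623606e-03,1.04738337e+01
7.35181435e-03,8.35198066e+00
7.89472839e-03,6.66860942e+00
8.47773535e-03,5.33307755e+00
9.10379599e-03,4.27347821e+00
9.77608972e-03,3.43276740e+00
1.04980308e-02,2.76569174e+00
1.12732854e-02,2.23635137e+00
1.21057908e-02,1.81626647e+00
1.29997747e-02,1.48284359e+00
1.39597772e-02,1.21815884e+00
1.49906737e-02,1.00799272e+00
1.60976993e-02,8.41064404e-01
1.72864762e-02,7.08424277e-01
1.85630415e-02,6.02972103e-01
1.99338781e-02,5.19074742e-01
2.14059477e-02,4.52262908e-01
2.29867261e-02,3.98990611e-01
2.46842413e-02,3.56444334e-01
2.65071139e-02,3.22391645e-01
2.84646014e-02,2.95061124e-01
3.05666447e-02,2.73047107e-01
3.28239188e-02,2.55234126e-01
3.52478874e-02,2.40736983e-01
3.78508602e-02,2.28853208e-01
4.06460564e-02,2.19025362e-01
4.36476712e-02,2.10811132e-01
4.68709482e-02,2.03859621e-01
5.03322565e-02,1.97892541e-01
5.40491742e-02,1.92689302e-01
5.80405775e-02,1.88075188e-01
6.23267364e-02,1.83911985e-01
6.69294180e-02,1.80090541e-01
7.18719967e-02,1.76524873e-01
7.71795731e-02,1.73147484e-01
8.28791015e-02,1.69905654e-01
8.89995265e-02,1.66758486e-01
9.55719303e-02,1.63674556e-01
1.02629691e-01,1.60630041e-01
1.10208650e-01,1.57607225e-01
1.18347297e-01,1.54593296e-01
1.27086964e-01,1.51579377e-01
1.36472035e-01,1.48559746e-01
1.46550171e-01,1.45531193e-01
1.57372553e-01,1.42492498e-01
1.68994143e-01,1.39443999e-01
1.81473959e-01,1.36387228e-01
1.94875380e-01,1.33324613e-01
2.09266465e-01,1.30259223e-01
2.24720297e-01,1.27194558e-01
2.41315357e-01,1.24134371e-01
2.59135924e-01,1.21082523e-01
2.78272497e-01,1.18042861e-01
2.98822261e-01,1.15019125e-01
3.20889576e-01,1.12014874e-01
3.44586509e-01,1.09033431e-01
3.70033406e-01,1.06077847e-01
3.97359495e-01,1.03150884e-01
4.26703550e-01,1.00255005e-01
4.58214595e-01,9.73923807e-02
4.92052656e-01,9.45649034e-02
5.28389577e-01,9.17742086e-02
5.67409893e-01,8.90217016e-02
6.09311767e-01,8.63085876e-02
6.54307996e-01,8.36359026e-02
7.02627089e-01,8.10045445e-02
7.54514432e-01,7.84153023e-02
8.10233532e-01,7.58688829e-02
8.70067356e-01,7.33659340e-02
9.34319766e-01,7.09070641e-02
1.00331706e+00,6.84928568e-02
1.07740965e+00,6.61238998e-02
1.15697379e+00,6.38011846e-02
1.24241356e+00,6.15265429e-02
1.33416286e+00,5.93023038e-02
1.43268762e+00,5.71309403e-02
1.53848820e+00,5.50148397e-02
1.65210190e+00,5.29561599e-02
1.77410571e+00,5.09567489e-02
1.90511920e+00,4.90181065e-02
2.04580774e+00,4.71413749e-02
2.19688578e+00,4.53273473e-02
2.35912059e+00,4.35764886e-02
2.53333604e+00,4.18889625e-02
2.72041690e+00,4.02646608e-02
2.92131323e+00,3.87032346e-02
3.13704528e+00,3.72041230e-02
3.36870863e+00,3.57665822e-02
3.61747977e+00,3.43897107e-02
3.88462207e+00,3.30724726e-02
4.17149219e+00,3.18137195e-02
4.47954699e+00,3.06122086e-02
4.81035091e+00,2.94666197e-02
5.16558391e+00,2.83755701e-02
5.54705003e+00,2.73376275e-02
5.95668651e+00,2.63513212e-02
6.39657367e+00,2.54151528e-02
6.86894546e+00,2.45276046e-02
7.37620078e+00,2.36871478e-02
7.92091571e+00,2.28922492e-02
8.50585654e+00,2.21413772e-02
9.13399386e+00,2.14330078e-02
9.80851764e+00,2.07656284e-02
1.05328534e+01,2.01377430e-02
1.13106796e+01,1.95478750e-02
1.21459465e+01,1.89945709e-02
1.30428958e+01,1.84764030e-02
1.40060827e+01,1.79919717e-02
1.50403987e+01,1.75399076e-02
1.61510964e+01,1.71188732e-02
1.73438166e+01,1.67275647e-02
1.86246163e+01,1.63647126e-02
2.00000000e+01,1.60290831e-02
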