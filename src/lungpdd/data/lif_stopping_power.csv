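energy_MeV,value
1.00000000e-03,9.16051664e+01
1.07384763e-03,8.77361623e+01
1.15314873e-03,8.39681408e+01
1.23830602e-03,8.03055466e+01
1.32975199e-03,7.67517354e+01
1.42795101e-03,7.33091030e+01
1.53340181e-03,6.99792010e+01
1.64663989e-03,6.67628421e+01
1.76824034e-03,6.36601939e+01
1.89882070e-03,6.06708642e+01
2.03904410e-03,5.77939770e+01
2.18962267e-03,5.50282410e+01
2.35132111e-03,5.23720106e+01
2.52496059e-03,4.98233411e+01
2.71142294e-03,4.73800375e+01
2.91165509e-03,4.50396980e+01
3.12667391e-03,4.27997529e+01
3.35757136e-03,4.06574992e+01
3.60552003e-03,3.86101309e+01
3.87177913e-03,3.66547662e+01
4.15770084e-03,3.47884707e+01
4.46473718e-03,3.30082789e+01
4.79444742e-03,3.13112120e+01
5.14850599e-03,2.96942938e+01
5.52871094e-03,2.81545645e+01
5.93699312e-03,2.66890926e+01
6.37542598e-03,2.52949848e+01
6.84623606e-03,2.39693948e+01
7.35181435e-03,2.27095306e+01
7.89472839e-03,2.15126602e+01
8.47773535e-03,2.03761169e+01
9.10379599e-03,1.92973031e+01
9.77608972e-03,1.82736934e+01
1.04980308e-02,1.73028372e+01
1.12732854e-02,1.63823600e+01
1.21057908e-02,1.55099648e+01
1.29997747e-02,1.46834328e+01
1.39597772e-02,1.39006232e+01
1.49906737e-02,1.31594733e+01
1.60976993e-02,1.24579978e+01
1.72864762e-02,1.17942877e+01
1.85630415e-02,1.11665099e+01
1.99338781e-02,1.05729050e+01
2.14059477e-02,1.00117866e+01
2.29867261e-02,9.48153899e+00
2.46842413e-02,8.98061597e+00
2.65071139e-02,8.50753868e+00
2.84646014e-02,8.06089380e+00
3.05666447e-02,7.63933159e+00
3.28239188e-02,7.24156382e+00
3.52478874e-02,6.86636183e+00
3.78508602e-02,6.51255445e+00
4.06460564e-02,6.17902597e+00
4.36476712e-02,5.86471413e+00
4.68709482e-02,5.56860811e+00
5.03322565e-02,5.28974652e+00
5.40491742e-02,5.02721551e+00
5.80405775e-02,4.78014681e+00
6.23267364e-02,4.54771585e+00
6.69294180e-02,4.32913999e+00
7.18719967e-02,4.12367666e+00
7.71795731e-02,3.93062165e+00
8.28791015e-02,3.74930743e+00
8.89995265e-02,3.57910151e+00
9.55719303e-02,3.41940481e+00
1.02629691e-01,3.26965015e+00
1.10208650e-01,3.12930075e+00
1.18347297e-01,2.99784876e+00
1.27086964e-01,2.87481391e+00
1.36472035e-01,2.75974209e+00
1.46550171e-01,2.65220408e+00
1.57372553e-01,2.55179431e+00
1.68994143e-01,2.45812957e+00
1.81473959e-01,2.37084788e+00
1.94875380e-01,2.28960735e+00
2.09266465e-01,2.21408504e+00
2.24720297e-01,2.14397593e+00
2.41315357e-01,2.07899188e+00
2.59135924e-01,2.01886063e+00
2.78272497e-01,1.96332488e+00
2.98822261e-01,1.91214131e+00
3.20889576e-01,1.86507977e+00
3.44586509e-01,1.82192236e+00
3.70033406e-01,1.78246269e+00
3.97359495e-01,1.74650507e+00
4.26703550e-01,1.71386377e+00
4.58214595e-01,1.68373341e+00
4.92052656e-01,1.65539043e+00
5.28389577e-01,1.62976123e+00
5.67409893e-01,1.60669112e+00
6.09311767e-01,1.58603160e+00
6.54307996e-01,1.56764007e+00
7.02627089e-01,1.55137947e+00
7.54514432e-01,1.53711801e+00
8.10233532e-01,1.52472895e+00
8.70067356e-01,1.51409040e+00
9.34319766e-01,1.50508511e+00
1.00331706e+00,1.49760042e+00
1.07740965e+00,1.49152808e+00
1.15697379e+00,1.48676424e+00
1.24241356e+00,1.48320937e+00
1.33416286e+00,1.48076822e+00
1.43268762e+00,1.47934982e+00
1.53848820e+00,1.47886746e+00
1.65210190e+00,1.47923867e+00
1.77410571e+00,1.48038524e+00
1.90511920e+00,1.48223316e+00
2.04580774e+00,1.48471263e+00
2.19688578e+00,1.48775803e+00
2.35912059e+00,1.49130783e+00
2.53333604e+00,1.49530457e+00
2.72041690e+00,1.49969476e+00
2.92131323e+00,1.50442879e+00
3.13704528e+00,1.50946084e+00
3.36870863e+00,1.51474872e+00
3.61747977e+00,1.52025376e+00
3.88462207e+00,1.52594070e+00
4.17149219e+00,1.53177745e+00
4.47954699e+00,1.53773500e+00
4.81035091e+00,1.54378725e+00
5.16558391e+00,1.54991081e+00
5.54705003e+00,1.55608483e+00
5.95668651e+00,1.56229087e+00
6.39657367e+00,1.56851272e+00
6.86894546e+00,1.57473619e+00
7.37620078e+00,1.58094902e+00
7.92091571e+00,1.58714071e+00
8.50585654e+00,1.59330232e+00
9.13399386e+00,1.59942642e+00
9.80851764e+00,1.60550690e+00
1.05328534e+01,1.61153886e+00
1.13106796e+01,1.61751851e+00
1.21459465e+01,1.62344303e+00
1.30428958e+01,1.62931054e+00
1.40060827e+01,1.63511991e+00
1.50403987e+01,1.64087078e+00
1.61510964e+01,1.64656340e+00
1.73438166e+01,1.65219862e+00
1.86246163e+01,1.65777780e+00
2.00000000e+01,1.66330274e+00
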