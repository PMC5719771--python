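energy_MeV,value
1.00000000e-03,1.16954093e+02
1.07384763e-03,1.11747103e+02
1.15314873e-03,1.06705724e+02
1.23830602e-03,1.01831844e+02
1.32975199e-03,9.71263108e+01
1.42795101e-03,9.25890612e+01
1.53340181e-03,8.82192461e+01
1.64663989e-03,8.40153367e+01
1.76824034e-03,7.99752230e+01
1.89882070e-03,7.60963005e+01
2.03904410e-03,7.23755484e+01
2.18962267e-03,6.88095993e+01
2.35132111e-03,6.53948006e+01
2.52496059e-03,6.21272705e+01
2.71142294e-03,5.90029461e+01
2.91165509e-03,5.60176271e+01
3.12667391e-03,5.31670135e+01
3.35757136e-03,5.04467396e+01
3.60552003e-03,4.78524034e+01
3.87177913e-03,4.53795917e+01
4.15770084e-03,4.30239031e+01
4.46473718e-03,4.07809669e+01
4.79444742e-03,3.86464598e+01
5.14850599e-03,3.66161201e+01
5.52871094e-03,3.46857596e+01
5.93699312e-03,3.28512738e+01
6.37542598e-03,3.11086499e+01
6.84623606e-03,2.94539741e+01
7.35181435e-03,2.78834366e+01
7.89472839e-03,2.63933359e+01
8.47773535e-03,2.49800821e+01
9.10379599e-03,2.36401988e+01
9.77608972e-03,2.23703248e+01
1.04980308e-02,2.11672144e+01
1.12732854e-02,2.00277378e+01
1.21057908e-02,1.89488802e+01
1.29997747e-02,1.79277411e+01
1.39597772e-02,1.69615326e+01
1.49906737e-02,1.60475779e+01
1.60976993e-02,1.51833091e+01
1.72864762e-02,1.43662649e+01
1.85630415e-02,1.35940883e+01
1.99338781e-02,1.28645239e+01
2.14059477e-02,1.21754147e+01
2.29867261e-02,1.15247001e+01
2.46842413e-02,1.09104121e+01
2.65071139e-02,1.03306728e+01
2.84646014e-02,9.78369134e+00
3.05666447e-02,9.26776070e+00
3.28239188e-02,8.78125488e+00
3.52478874e-02,8.32262581e+00
3.78508602e-02,7.89040043e+00
4.06460564e-02,7.48317774e+00
4.36476712e-02,7.09962596e+00
4.68709482e-02,6.73847971e+00
5.03322565e-02,6.39853724e+00
5.40491742e-02,6.07865780e+00
5.80405775e-02,5.77775893e+00
6.23267364e-02,5.49481404e+00
6.69294180e-02,5.22884984e+00
7.18719967e-02,4.97894399e+00
7.71795731e-02,4.74422279e+00
8.28791015e-02,4.52385893e+00
8.89995265e-02,4.31706932e+00
9.55719303e-02,4.12311300e+00
1.02629691e-01,3.94128912e+00
1.10208650e-01,3.77093502e+00
1.18347297e-01,3.61142432e+00
1.27086964e-01,3.46216511e+00
1.36472035e-01,3.32259826e+00
1.46550171e-01,3.19219567e+00
1.57372553e-01,3.07045869e+00
1.68994143e-01,2.95691658e+00
1.81473959e-01,2.85112497e+00
1.94875380e-01,2.75266443e+00
2.09266465e-01,2.66113908e+00
2.24720297e-01,2.57617523e+00
2.41315357e-01,2.49742013e+00
2.59135924e-01,2.42454068e+00
2.78272497e-01,2.35722226e+00
2.98822261e-01,2.29516757e+00
3.20889576e-01,2.23809553e+00
3.44586509e-01,2.18574025e+00
3.70033406e-01,2.13784999e+00
3.97359495e-01,2.09418623e+00
4.26703550e-01,2.05452275e+00
4.58214595e-01,2.01813732e+00
4.92052656e-01,1.98432783e+00
5.28389577e-01,1.95375585e+00
5.67409893e-01,1.92623724e+00
6.09311767e-01,1.90159520e+00
6.54307996e-01,1.87965984e+00
7.02627089e-01,1.86026781e+00
7.54514432e-01,1.84326199e+00
8.10233532e-01,1.82849119e+00
8.70067356e-01,1.81580995e+00
9.34319766e-01,1.80507834e+00
1.00331706e+00,1.79616177e+00
1.07740965e+00,1.78893097e+00
1.15697379e+00,1.78326182e+00
1.24241356e+00,1.77903533e+00
1.33416286e+00,1.77613761e+00
1.43268762e+00,1.77445986e+00
1.53848820e+00,1.77389832e+00
1.65210190e+00,1.77435430e+00
1.77410571e+00,1.77573418e+00
1.90511920e+00,1.77794934e+00
2.04580774e+00,1.78091621e+00
2.19688578e+00,1.78455616e+00
2.35912059e+00,1.78879550e+00
2.53333604e+00,1.79356537e+00
2.72041690e+00,1.79880169e+00
2.92131323e+00,1.80444500e+00
3.13704528e+00,1.81044038e+00
3.36870863e+00,1.81673727e+00
3.61747977e+00,1.82328934e+00
3.88462207e+00,1.83005429e+00
4.17149219e+00,1.83699372e+00
4.47954699e+00,1.84407285e+00
4.81035091e+00,1.85126042e+00
5.16558391e+00,1.85852841e+00
5.54705003e+00,1.86585190e+00
5.95668651e+00,1.87320881e+00
6.39657367e+00,1.88057976e+00
6.86894546e+00,1.88794782e+00
7.37620078e+00,1.89529837e+00
7.92091571e+00,1.90261889e+00
8.50585654e+00,1.90989878e+00
9.13399386e+00,1.91712922e+00
9.80851764e+00,1.92430300e+00
1.05328534e+01,1.93141436e+00
1.13106796e+01,1.93845890e+00
1.21459465e+01,1.94543338e+00
1.30428958e+01,1.95233567e+00
1.40060827e+01,1.95916459e+00
1.50403987e+01,1.96591985e+00
1.61510964e+01,1.97260193e+00
1.73438166e+01,1.97921202e+00
1.86246163e+01,1.98575192e+00
2.00000000e+01,1.99222398e+00
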