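energy_MeV,value
1.00000000e-03,1.19776810e+02
1.07384763e-03,1.14458247e+02
1.15314873e-03,1.09307356e+02
1.23830602e-03,1.04326273e+02
1.32975199e-03,9.95160458e+01
1.42795101e-03,9.48767751e+01
1.53340181e-03,9.04077402e+01
1.64663989e-03,8.61075109e+01
1.76824034e-03,8.19740486e+01
1.89882070e-03,7.80047972e+01
2.03904410e-03,7.41967630e+01
2.18962267e-03,7.05465880e+01
2.35132111e-03,6.70506136e+01
2.52496059e-03,6.37049376e+01
2.71142294e-03,6.05054658e+01
2.91165509e-03,5.74479562e+01
3.12667391e-03,5.45280589e+01
3.35757136e-03,5.17413510e+01
3.60552003e-03,4.90833674e+01
3.87177913e-03,4.65496272e+01
4.15770084e-03,4.41356572e+01
4.46473718e-03,4.18370121e+01
4.79444742e-03,3.96492917e+01
5.14850599e-03,3.75681557e+01
5.52871094e-03,3.55893366e+01
5.93699312e-03,3.37086497e+01
6.37542598e-03,3.19220023e+01
6.84623606e-03,3.02254009e+01
7.35181435e-03,2.86149566e+01
7.89472839e-03,2.70868899e+01
8.47773535e-03,2.56375339e+01
9.10379599e-03,2.42633369e+01
9.77608972e-03,2.29608637e+01
1.04980308e-02,2.17267964e+01
1.12732854e-02,2.05579350e+01
1.21057908e-02,1.94511961e+01
1.29997747e-02,1.84036129e+01
1.39597772e-02,1.74123330e+01
1.49906737e-02,1.64746172e+01
1.60976993e-02,1.55878376e+01
1.72864762e-02,1.47494746e+01
1.85630415e-02,1.39571153e+01
1.99338781e-02,1.32084502e+01
2.14059477e-02,1.25012706e+01
2.29867261e-02,1.18334659e+01
2.46842413e-02,1.12030204e+01
2.65071139e-02,1.06080104e+01
2.84646014e-02,1.00466009e+01
3.05666447e-02,9.51704293e+00
3.28239188e-02,9.01767030e+00
3.52478874e-02,8.54689644e+00
3.78508602e-02,8.10321159e+00
4.06460564e-02,7.68517968e+00
4.36476712e-02,7.29143552e+00
4.68709482e-02,6.92068185e+00
5.03322565e-02,6.57168656e+00
5.40491742e-02,6.24328000e+00
5.80405775e-02,5.93435222e+00
6.23267364e-02,5.64385046e+00
6.69294180e-02,5.37077658e+00
7.18719967e-02,5.11418462e+00
7.71795731e-02,4.87317846e+00
8.28791015e-02,4.64690950e+00
8.89995265e-02,4.43457446e+00
9.55719303e-02,4.23541324e+00
1.02629691e-01,4.04870686e+00
1.10208650e-01,3.87377545e+00
1.18347297e-01,3.70997637e+00
1.27086964e-01,3.55670230e+00
1.36472035e-01,3.41337951e+00
1.46550171e-01,3.27946613e+00
1.57372553e-01,3.15445045e+00
1.68994143e-01,3.03784940e+00
1.81473959e-01,2.92920693e+00
1.94875380e-01,2.82809261e+00
2.09266465e-01,2.73410012e+00
2.24720297e-01,2.64684594e+00
2.41315357e-01,2.56596800e+00
2.59135924e-01,2.49112439e+00
2.78272497e-01,2.42199217e+00
2.98822261e-01,2.35826616e+00
3.20889576e-01,2.29965783e+00
3.44586509e-01,2.24589421e+00
3.70033406e-01,2.19671687e+00
3.97359495e-01,2.15188094e+00
4.26703550e-01,2.11115417e+00
4.58214595e-01,2.07403911e+00
4.92052656e-01,2.03997663e+00
5.28389577e-01,2.00920197e+00
5.67409893e-01,1.98153006e+00
6.09311767e-01,1.95678293e+00
6.54307996e-01,1.93478931e+00
7.02627089e-01,1.91538426e+00
7.54514432e-01,1.89840891e+00
8.10233532e-01,1.88371017e+00
8.70067356e-01,1.87114055e+00
9.34319766e-01,1.86055797e+00
1.00331706e+00,1.85182562e+00
1.07740965e+00,1.84481191e+00
1.15697379e+00,1.83939036e+00
1.24241356e+00,1.83543958e+00
1.33416286e+00,1.83284328e+00
1.43268762e+00,1.83149021e+00
1.53848820e+00,1.83127422e+00
1.65210190e+00,1.83209426e+00
1.77410571e+00,1.83385435e+00
1.90511920e+00,1.83646362e+00
2.04580774e+00,1.83983628e+00
2.19688578e+00,1.84389158e+00
2.35912059e+00,1.84855381e+00
2.53333604e+00,1.85375217e+00
2.72041690e+00,1.85942076e+00
2.92131323e+00,1.86549839e+00
3.13704528e+00,1.87192855e+00
3.36870863e+00,1.87865921e+00
3.61747977e+00,1.88564266e+00
3.88462207e+00,1.89283539e+00
4.17149219e+00,1.90019783e+00
4.47954699e+00,1.90769423e+00
4.81035091e+00,1.91529242e+00
5.16558391e+00,1.92296361e+00
5.54705003e+00,1.93068220e+00
5.95668651e+00,1.93842554e+00
6.39657367e+00,1.94617377e+00
6.86894546e+00,1.95390959e+00
7.37620078e+00,1.96161808e+00
7.92091571e+00,1.96928650e+00
8.50585654e+00,1.97690412e+00
9.13399386e+00,1.98446205e+00
9.80851764e+00,1.99195309e+00
1.05328534e+01,1.99937154e+00
1.13106796e+01,2.00671309e+00
1.21459465e+01,2.01397471e+00
1.30428958e+01,2.02115446e+00
1.40060827e+01,2.02825142e+00
1.50403987e+01,2.03526562e+00
1.61510964e+01,2.04219785e+00
1.73438166e+01,2.04904968e+00
1.86246163e+01,2.05582330e+00
2.00000000e+01,2.06252148e+00
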