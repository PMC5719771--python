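energy_MeV,value
1.00000000e-03,8.78492180e+03
1.07384763e-03,6.96910645e+03
1.15314873e-03,5.52862378e+03
1.23830602e-03,4.38589177e+03
1.32975199e-03,3.47936475e+03
1.42795101e-03,2.76021868e+03
1.53340181e-03,2.18972153e+03
1.64663989e-03,1.73714726e+03
1.76824034e-03,1.37812098e+03
1.89882070e-03,1.09330613e+03
2.03904410e-03,8.67363057e+02
2.18962267e-03,6.88122837e+02
2.35132111e-03,5.45931896e+02
2.52496059e-03,4.33132072e+02
2.71142294e-03,3.43648158e+02
2.91165509e-03,2.72660705e+02
3.12667391e-03,2.16346456e+02
3.35757136e-03,1.71672424e+02
3.60552003e-03,1.36232552e+02
3.87177913e-03,1.08118114e+02
4.15770084e-03,8.58149259e+01
4.46473718e-03,6.81217852e+01
4.79444742e-03,5.40857816e+01
5.14850599e-03,4.29509724e+01
5.52871094e-03,3.41176697e+01
5.93699312e-03,2.71101418e+01
6.37542598e-03,2.15509914e+01
6.84623606e-03,1.71408297e+01
7.35181435e-03,1.36421517e+01
7.89472839e-03,1.08665448e+01
8.47773535e-03,8.66454121e+00
9.10379599e-03,6.91756795e+00
9.77608972e-03,5.53156091e+00
1.04980308e-02,4.43189875e+00
1.12732854e-02,3.55938397e+00
1.21057908e-02,2.86705486e+00
1.29997747e-02,2.31765621e+00
1.39597772e-02,1.88163305e+00
1.49906737e-02,1.53553891e+00
1.60976993e-02,1.26077322e+00
1.72864762e-02,1.04257963e+00
1.85630415e-02,8.69251381e-01
1.99338781e-02,7.31501006e-01
2.14059477e-02,6.21960215e-01
2.29867261e-02,5.34783236e-01
2.46842413e-02,4.65332121e-01
2.65071139e-02,4.09927111e-01
2.84646014e-02,3.65648610e-01
3.05666447e-02,3.30180093e-01
3.28239188e-02,3.01683504e-01
3.52478874e-02,2.78700403e-01
3.78508602e-02,2.60073565e-01
4.06460564e-02,2.44884787e-01
4.36476712e-02,2.32405563e-01
4.68709482e-02,2.22057955e-01
5.03322565e-02,2.13383570e-01
5.40491742e-02,2.06018944e-01
5.80405775e-02,1.99676029e-01
6.23267364e-02,1.94126715e-01
6.69294180e-02,1.89190550e-01
7.18719967e-02,1.84725006e-01
7.71795731e-02,1.80617753e-01
8.28791015e-02,1.76780527e-01
8.89995265e-02,1.73144258e-01
9.55719303e-02,1.69655207e-01
1.02629691e-01,1.66271879e-01
1.10208650e-01,1.62962573e-01
1.18347297e-01,1.59703418e-01
1.27086964e-01,1.56476803e-01
1.36472035e-01,1.53270115e-01
1.46550171e-01,1.50074717e-01
1.57372553e-01,1.46885122e-01
1.68994143e-01,1.43698320e-01
1.81473959e-01,1.40513225e-01
1.94875380e-01,1.37330223e-01
2.09266465e-01,1.34150797e-01
2.24720297e-01,1.30977220e-01
2.41315357e-01,1.27812299e-01
2.59135924e-01,1.24659171e-01
2.78272497e-01,1.21521132e-01
2.98822261e-01,1.18401504e-01
3.20889576e-01,1.15303532e-01
3.44586509e-01,1.12230304e-01
3.70033406e-01,1.09184698e-01
3.97359495e-01,1.06169347e-01
4.26703550e-01,1.03186621e-01
4.58214595e-01,1.00238624e-01
4.92052656e-01,9.73271967e-02
5.28389577e-01,9.44539413e-02
5.67409893e-01,9.16202384e-02
6.09311767e-01,8.88272761e-02
6.54307996e-01,8.60760795e-02
7.02627089e-01,8.33675400e-02
7.54514432e-01,8.07024436e-02
8.10233532e-01,7.80814971e-02
8.70067356e-01,7.55053510e-02
9.34319766e-01,7.29746183e-02
1.00331706e+00,7.04898896e-02
1.07740965e+00,6.80517633e-02
1.15697379e+00,6.56613017e-02
1.24241356e+00,6.33205276e-02
1.33416286e+00,6.10320332e-02
1.43268762e+00,5.87985769e-02
1.53848820e+00,5.66228209e-02
1.65210190e+00,5.45071685e-02
1.77410571e+00,5.24536730e-02
1.90511920e+00,5.04639943e-02
2.04580774e+00,4.85393897e-02
2.19688578e+00,4.66807243e-02
2.35912059e+00,4.48884961e-02
2.53333604e+00,4.31628666e-02
2.72041690e+00,4.15036963e-02
2.92131323e+00,3.99105797e-02
3.13704528e+00,3.83828795e-02
3.36870863e+00,3.69197591e-02
3.61747977e+00,3.55202121e-02
3.88462207e+00,3.41830892e-02
4.17149219e+00,3.29071222e-02
4.47954699e+00,3.16909453e-02
4.81035091e+00,3.05331136e-02
5.16558391e+00,2.94321198e-02
5.54705003e+00,2.83864084e-02
5.95668651e+00,2.73943885e-02
6.39657367e+00,2.64544443e-02
6.86894546e+00,2.55649450e-02
7.37620078e+00,2.47242528e-02
7.92091571e+00,2.39307304e-02
8.50585654e+00,2.31827470e-02
9.13399386e+00,2.24786841e-02
9.80851764e+00,2.18169398e-02
1.05328534e+01,2.11959335e-02
1.13106796e+01,2.06141087e-02
1.21459465e+01,2.00699370e-02
1.30428958e+01,1.95619199e-02
1.40060827e+01,1.90885915e-02
1.50403987e+01,1.86485201e-02
1.61510964e+01,1.82403099e-02
1.73438166e+01,1.78626024e-02
1.86246163e+01,1.75140769e-02
2.00000000e+01,1.71934519e-02
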