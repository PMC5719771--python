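energy_MeV,value
1.00000000e-03,1.04377746e+04
1.07384763e-03,8.28030359e+03
1.15314873e-03,6.56878622e+03
1.23830602e-03,5.21104292e+03
1.32975199e-03,4.13394789e+03
1.42795101e-03,3.27949055e+03
1.53340181e-03,2.60165126e+03
1.64663989e-03,2.06392269e+03
1.76824034e-03,1.63734368e+03
1.89882070e-03,1.29893939e+03
2.03904410e-03,1.03048392e+03
2.18962267e-03,8.17518716e+02
2.35132111e-03,6.48573817e+02
2.52496059e-03,5.14550138e+02
2.71142294e-03,4.08229390e+02
2.91165509e-03,3.23885318e+02
3.12667391e-03,2.56975297e+02
3.35757136e-03,2.03895670e+02
3.60552003e-03,1.61787664e+02
3.87177913e-03,1.28383420e+02
4.15770084e-03,1.01883849e+02
4.46473718e-03,8.08617373e+01
4.79444742e-03,6.41848795e+01
5.14850599e-03,5.09550987e+01
5.52871094e-03,4.04598728e+01
5.93699312e-03,3.21339590e+01
6.37542598e-03,2.55289512e+01
6.84623606e-03,2.02891293e+01
7.35181435e-03,1.61323013e+01
7.89472839e-03,1.28346040e+01
8.47773535e-03,1.02184472e+01
9.10379599e-03,8.14294835e+00
9.77608972e-03,6.49634543e+00
1.04980308e-02,5.18997733e+00
1.12732854e-02,4.15350897e+00
1.21057908e-02,3.33114328e+00
1.29997747e-02,2.67861609e+00
1.39597772e-02,2.16081229e+00
1.49906737e-02,1.74987470e+00
1.60976993e-02,1.42370380e+00
1.72864762e-02,1.16476762e+00
1.85630415e-02,9.59157624e-01
1.99338781e-02,7.95839750e-01
2.14059477e-02,6.66060239e-01
2.29867261e-02,5.62874314e-01
2.46842413e-02,4.80772273e-01
2.65071139e-02,4.15382876e-01
2.84646014e-02,3.63238053e-01
3.05666447e-02,3.21586246e-01
3.28239188e-02,2.88244347e-01
3.52478874e-02,2.61480238e-01
3.78508602e-02,2.39919628e-01
4.06460564e-02,2.22472149e-01
4.36476712e-02,2.08272726e-01
4.68709482e-02,1.96635092e-01
5.03322565e-02,1.87014895e-01
5.40491742e-02,1.78980456e-01
5.80405775e-02,1.72189562e-01
6.23267364e-02,1.66371067e-01
6.69294180e-02,1.61310296e-01
7.18719967e-02,1.56837467e-01
7.71795731e-02,1.52818507e-01
8.28791015e-02,1.49147760e-01
8.89995265e-02,1.45742206e-01
9.55719303e-02,1.42536857e-01
1.02629691e-01,1.39481111e-01
1.10208650e-01,1.36535837e-01
1.18347297e-01,1.33671056e-01
1.27086964e-01,1.30864093e-01
1.36472035e-01,1.28098091e-01
1.46550171e-01,1.25360817e-01
1.57372553e-01,1.22643706e-01
1.68994143e-01,1.19941080e-01
1.81473959e-01,1.17249521e-01
1.94875380e-01,1.14567358e-01
2.09266465e-01,1.11894246e-01
2.24720297e-01,1.09230822e-01
2.41315357e-01,1.06578433e-01
2.59135924e-01,1.03938903e-01
2.78272497e-01,1.01314352e-01
2.98822261e-01,9.87070523e-02
3.20889576e-01,9.61193136e-02
3.44586509e-01,9.35533974e-02
3.70033406e-01,9.10114545e-02
3.97359495e-01,8.84954826e-02
4.26703550e-01,8.60073003e-02
4.58214595e-01,8.35485363e-02
4.92052656e-01,8.11206286e-02
5.28389577e-01,7.87248332e-02
5.67409893e-01,7.63622391e-02
6.09311767e-01,7.40337876e-02
6.54307996e-01,7.17402940e-02
7.02627089e-01,6.94824705e-02
7.54514432e-01,6.72609476e-02
8.10233532e-01,6.50762949e-02
8.70067356e-01,6.29290392e-02
9.34319766e-01,6.08196793e-02
1.00331706e+00,5.87486974e-02
1.07740965e+00,5.67165868e-02
1.15697379e+00,5.47242747e-02
1.24241356e+00,5.27735858e-02
1.33416286e+00,5.08668761e-02
1.43268762e+00,4.90066587e-02
1.53848820e+00,4.71953581e-02
1.65210190e+00,4.54351607e-02
1.77410571e+00,4.37279291e-02
1.90511920e+00,4.20751640e-02
2.04580774e+00,4.04779949e-02
2.19688578e+00,3.89371922e-02
2.35912059e+00,3.74531900e-02
2.53333604e+00,3.60261165e-02
2.72041690e+00,3.46558269e-02
2.92131323e+00,3.33419369e-02
3.13704528e+00,3.20838549e-02
3.36870863e+00,3.08808126e-02
3.61747977e+00,2.97318926e-02
3.88462207e+00,2.86360534e-02
4.17149219e+00,2.75921517e-02
4.47954699e+00,2.65989620e-02
4.81035091e+00,2.56551937e-02
5.16558391e+00,2.47595062e-02
5.54705003e+00,2.39105216e-02
5.95668651e+00,2.31068362e-02
6.39657367e+00,2.23470295e-02
6.86894546e+00,2.16296734e-02
7.37620078e+00,2.09533383e-02
7.92091571e+00,2.03166002e-02
8.50585654e+00,1.97180451e-02
9.13399386e+00,1.91562739e-02
9.80851764e+00,1.86299063e-02
1.05328534e+01,1.81375838e-02
1.13106796e+01,1.76779725e-02
1.21459465e+01,1.72497656e-02
1.30428958e+01,1.68516852e-02
1.40060827e+01,1.64824839e-02
1.50403987e+01,1.61409461e-02
1.61510964e+01,1.58258892e-02
1.73438166e+01,1.55361641e-02
1.86246163e+01,1.52706561e-02
2.00000000e+01,1.50282850e-02
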