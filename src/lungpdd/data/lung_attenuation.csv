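energy_MeV,value
1.00000000e-03,9.20219135e+03
1.07384763e-03,7.30012509e+03
1.15314873e-03,5.79121976e+03
1.23830602e-03,4.59420818e+03
1.32975199e-03,3.64462130e+03
1.42795101e-03,2.89131591e+03
1.53340181e-03,2.29372025e+03
1.64663989e-03,1.81964880e+03
1.76824034e-03,1.44356884e+03
1.89882070e-03,1.14522534e+03
2.03904410e-03,9.08550014e+02
2.18962267e-03,7.20795922e+02
2.35132111e-03,5.71850945e+02
2.52496059e-03,4.53693158e+02
2.71142294e-03,3.59958782e+02
2.91165509e-03,2.85599448e+02
3.12667391e-03,2.26610292e+02
3.35757136e-03,1.79814263e+02
3.60552003e-03,1.42691015e+02
3.87177913e-03,1.13241160e+02
4.15770084e-03,8.98785873e+01
4.46473718e-03,7.13450403e+01
4.79444742e-03,5.66423447e+01
5.14850599e-03,4.49786508e+01
5.52871094e-03,3.57257857e+01
5.93699312e-03,2.83854206e+01
6.37542598e-03,2.25622322e+01
6.84623606e-03,1.79426105e+01
7.35181435e-03,1.42777694e+01
7.89472839e-03,1.13703468e+01
8.47773535e-03,9.06377516e+00
9.10379599e-03,7.23384957e+00
9.77608972e-03,5.78203795e+00
1.04980308e-02,4.63017456e+00
1.12732854e-02,3.71625018e+00
1.21057908e-02,2.99107252e+00
1.29997747e-02,2.41561690e+00
1.39597772e-02,1.95892461e+00
1.49906737e-02,1.59643563e+00
1.60976993e-02,1.30866600e+00
1.72864762e-02,1.08015857e+00
1.85630415e-02,8.98650690e-01
1.99338781e-02,7.54413861e-01
2.14059477e-02,6.39729955e-01
2.29867261e-02,5.48475675e-01
2.46842413e-02,4.75792915e-01
2.65071139e-02,4.17827272e-01
2.84646014e-02,3.71520607e-01
3.05666447e-02,3.34446499e-01
3.28239188e-02,3.04679709e-01
3.52478874e-02,2.80692641e-01
3.78508602e-02,2.61273210e-01
4.06460564e-02,2.45459697e-01
4.36476712e-02,2.32489071e-01
4.68709482e-02,2.21756011e-01
5.03322565e-02,2.12780396e-01
5.40491742e-02,2.05181526e-01
5.80405775e-02,1.98657675e-01
6.23267364e-02,1.92969880e-01
6.69294180e-02,1.87929074e-01
7.18719967e-02,1.83385889e-01
7.71795731e-02,1.79222560e-01
8.28791015e-02,1.75346504e-01
8.89995265e-02,1.71685217e-01
9.55719303e-02,1.68182224e-01
1.02629691e-01,1.64793847e-01
1.10208650e-01,1.61486644e-01
1.18347297e-01,1.58235350e-01
1.27086964e-01,1.55021234e-01
1.36472035e-01,1.51830782e-01
1.46550171e-01,1.48654629e-01
1.57372553e-01,1.45486696e-01
1.68994143e-01,1.42323492e-01
1.81473959e-01,1.39163535e-01
1.94875380e-01,1.36006886e-01
2.09266465e-01,1.32854759e-01
2.24720297e-01,1.29709199e-01
2.41315357e-01,1.26572829e-01
2.59135924e-01,1.23448625e-01
2.78272497e-01,1.20339751e-01
2.98822261e-01,1.17249416e-01
3.20889576e-01,1.14180770e-01
3.44586509e-01,1.11136819e-01
3.70033406e-01,1.08120374e-01
3.97359495e-01,1.05134012e-01
4.26703550e-01,1.02180052e-01
4.58214595e-01,9.92605579e-02
4.92052656e-01,9.63773380e-02
5.28389577e-01,9.35319652e-02
5.67409893e-01,9.07257966e-02
6.09311767e-01,8.79600012e-02
6.54307996e-01,8.52355876e-02
7.02627089e-01,8.25534334e-02
7.54514432e-01,7.99143131e-02
8.10233532e-01,7.73189236e-02
8.70067356e-01,7.47679063e-02
9.34319766e-01,7.22618664e-02
1.00331706e+00,6.98013871e-02
1.07740965e+00,6.73870597e-02
1.15697379e+00,6.50199335e-02
1.24241356e+00,6.27020069e-02
1.33416286e+00,6.04358401e-02
1.43268762e+00,5.82241577e-02
1.53848820e+00,5.60695894e-02
1.65210190e+00,5.39745092e-02
1.77410571e+00,5.19409457e-02
1.90511920e+00,4.99705389e-02
2.04580774e+00,4.80645311e-02
2.19688578e+00,4.62237775e-02
2.35912059e+00,4.44487705e-02
2.53333604e+00,4.27396702e-02
2.72041690e+00,4.10963391e-02
2.92131323e+00,3.95183770e-02
3.13704528e+00,3.80051546e-02
3.36870863e+00,3.65558456e-02
3.61747977e+00,3.51694555e-02
3.88462207e+00,3.38448489e-02
4.17149219e+00,3.25807724e-02
4.47954699e+00,3.13758760e-02
4.81035091e+00,3.02287315e-02
5.16558391e+00,2.91378489e-02
5.54705003e+00,2.81016902e-02
5.95668651e+00,2.71186823e-02
6.39657367e+00,2.61872274e-02
6.86894546e+00,2.53057126e-02
7.37620078e+00,2.44725180e-02
7.92091571e+00,2.36860241e-02
8.50585654e+00,2.29446176e-02
9.13399386e+00,2.22466973e-02
9.80851764e+00,2.15906783e-02
1.05328534e+01,2.09749965e-02
1.13106796e+01,2.03981119e-02
1.21459465e+01,1.98585119e-02
1.30428958e+01,1.93547135e-02
1.40060827e+01,1.88852657e-02
1.50403987e+01,1.84487517e-02
1.61510964e+01,1.80437899e-02
1.73438166e+01,1.76690354e-02
1.86246163e+01,1.73231809e-02
2.00000000e+01,1.70049577e-02
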