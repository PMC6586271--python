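"""Bundled quantile table of the Tracy-Widom (beta=1) distribution.

CDF knots on a regular grid of the standardized statistic, generated
from the Chiani (2014) shifted-gamma approximation (accuracy ~1e-3);
consumers interpolate between knots.
"""

import numpy as np

TW1_X = np.array([
    -6.00, -5.90, -5.80, -5.70, -5.60, -5.50,
    -5.40, -5.30, -5.20, -5.10, -5.00, -4.90,
    -4.80, -4.70, -4.60, -4.50, -4.40, -4.30,
    -4.20, -4.10, -4.00, -3.90, -3.80, -3.70,
    -3.60, -3.50, -3.40, -3.30, -3.20, -3.10,
    -3.00, -2.90, -2.80, -2.70, -2.60, -2.50,
    -2.40, -2.30, -2.20, -2.10, -2.00, -1.90,
    -1.80, -1.70, -1.60, -1.50, -1.40, -1.30,
    -1.20, -1.10, -1.00, -0.90, -0.80, -0.70,
    -0.60, -0.50, -0.40, -0.30, -0.20, -0.10,
    -0.00, 0.10, 0.20, 0.30, 0.40, 0.50,
    0.60, 0.70, 0.80, 0.90, 1.00, 1.10,
    1.20, 1.30, 1.40, 1.50, 1.60, 1.70,
    1.80, 1.90, 2.00, 2.10, 2.20, 2.30,
    2.40, 2.50, 2.60, 2.70, 2.80, 2.90,
    3.00, 3.10, 3.20, 3.30, 3.40, 3.50,
    3.60, 3.70, 3.80, 3.90, 4.00, 4.10,
    4.20, 4.30, 4.40, 4.50, 4.60, 4.70,
    4.80, 4.90, 5.00, 5.10, 5.20, 5.30,
    5.40, 5.50, 5.60, 5.70, 5.80, 5.90,
    6.00,
])

TW1_CDF = np.array([
    7.5957728744e-07, 1.4894123236e-06, 2.8356866976e-06, 5.2497469425e-06,
    9.4633920811e-06, 1.6631614313e-05, 2.8530857842e-05, 4.7826451398e-05,
    7.8423046357e-05, 1.2591072178e-04, 1.9811652339e-04, 3.0576629652e-04,
    4.6325461720e-04, 6.8951149665e-04, 1.0089436639e-03, 1.4524162256e-03,
    2.0582282267e-03, 2.8730241712e-03, 3.9525741076e-03, 5.3623486645e-03,
    7.1778135364e-03, 9.4843712321e-03, 1.2376886897e-02, 1.5958749760e-02,
    2.0340441758e-02, 2.5637609252e-02, 3.1968660974e-02, 3.9451943830e-02,
    4.8202575848e-02, 5.8329040499e-02, 6.9929666953e-02, 8.3089134951e-02,
    9.7875149784e-02, 1.1433543168e-01, 1.3249515464e-01, 1.5235495305e-01,
    1.7388959097e-01, 1.9704736054e-01, 2.2175024430e-01, 2.4789484288e-01,
    2.7535403653e-01, 3.0397931906e-01, 3.3360371569e-01, 3.6404517517e-01,
    3.9511031141e-01, 4.2659836054e-01, 4.5830521772e-01, 4.9002742127e-01,
    5.2156596184e-01, 5.5272980801e-01, 5.8333905766e-01, 6.1322764448e-01,
    6.4224555041e-01, 6.7026049592e-01, 6.9715910090e-01, 7.2284752742e-01,
    7.4725163219e-01, 7.7031666977e-01, 7.9200659840e-01, 8.1230304735e-01,
    8.3120400882e-01, 8.4872231902e-01, 8.6488399162e-01, 8.7972646371e-01,
    8.9329680916e-01, 9.0564996835e-01, 9.1684703588e-01, 9.2695364067e-01,
    9.3603844514e-01, 9.4417178305e-01, 9.5142444872e-01, 9.5786664398e-01,
    9.6356708427e-01, 9.6859226023e-01, 9.7300584795e-01, 9.7686825770e-01,
    9.8023630937e-01, 9.8316302125e-01, 9.8569749799e-01, 9.8788490397e-01,
    9.8976650780e-01, 9.9137978512e-01, 9.9275856724e-01, 9.9393322450e-01,
    9.9493087440e-01, 9.9577560581e-01, 9.9648871181e-01, 9.9708892490e-01,
    9.9759264956e-01, 9.9801418814e-01, 9.9836595692e-01, 9.9865869026e-01,
    9.9890163114e-01, 9.9910270736e-01, 9.9926869292e-01, 9.9940535458e-01,
    9.9951758406e-01, 9.9960951623e-01, 9.9968463437e-01, 9.9974586300e-01,
    9.9979564959e-01, 9.9983603582e-01, 9.9986871961e-01, 9.9989510869e-01,
    9.9991636670e-01, 9.9993345277e-01, 9.9994715515e-01, 9.9995811987e-01,
    9.9996687495e-01, 9.9997385078e-01, 9.9997939728e-01, 9.9998379816e-01,
    9.9998728291e-01, 9.9999003667e-01, 9.9999220844e-01, 9.9999391786e-01,
    9.9999526074e-01, 9.9999631366e-01, 9.9999713767e-01, 9.9999778133e-01,
    9.9999828319e-01,
])
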