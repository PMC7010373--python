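"""Published reference values used as frozen expectations.

UPPER_QUANTILE_TABLE: upper alpha=0.05 quantiles of the central beta
distribution, 6 significant digits, rows indexed by b, columns by a.
NONCENTRALITY_TABLE: the noncentrality parameter solving the power
equation at alpha=0.05, beta=0.10 on the same grid.
NONCENTRAL_CDF_CASES: noncentral beta cdf spot values with the
published 7-digit correct value and two earlier algorithms' outputs
with their correct-digit counts.
"""

A_VALUES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 5.0, 10.0, 25.0)

B_VALUES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 20, 30, 40, 50, 100, 250, 500)

UPPER_QUANTILE_TABLE = {
    1: (9.02500e-01, 9.50000e-01, 9.66383e-01, 9.74679e-01, 9.79692e-01, 9.83048e-01, 9.89794e-01, 9.94884e-01, 9.97950e-01),
    2: (6.58372e-01, 7.76393e-01, 8.31750e-01, 8.64650e-01, 8.86622e-01, 9.02389e-01, 9.37150e-01, 9.66681e-01, 9.86158e-01),
    3: (4.99474e-01, 6.31597e-01, 7.04013e-01, 7.51395e-01, 7.85230e-01, 8.10745e-01, 8.71244e-01, 9.28130e-01, 9.69022e-01),
    4: (3.99294e-01, 5.27129e-01, 6.03932e-01, 6.57408e-01, 6.97399e-01, 7.28662e-01, 8.07097e-01, 8.87334e-01, 9.49692e-01),
    5: (3.31756e-01, 4.50720e-01, 5.26623e-01, 5.81803e-01, 6.24472e-01, 6.58739e-01, 7.48632e-01, 8.47282e-01, 9.29506e-01),
    6: (2.83463e-01, 3.93038e-01, 4.65976e-01, 5.20703e-01, 5.64102e-01, 5.99689e-01, 6.96463e-01, 8.09135e-01, 9.09126e-01),
    7: (2.47316e-01, 3.48164e-01, 4.17435e-01, 4.70679e-01, 5.13741e-01, 5.49642e-01, 6.50188e-01, 7.73308e-01, 8.88911e-01),
    8: (2.19284e-01, 3.12344e-01, 3.77834e-01, 4.29136e-01, 4.71285e-01, 5.06901e-01, 6.09138e-01, 7.39886e-01, 8.69067e-01),
    9: (1.96926e-01, 2.83129e-01, 3.44972e-01, 3.94163e-01, 4.35104e-01, 4.70087e-01, 5.72619e-01, 7.08799e-01, 8.49712e-01),
    10: (1.78687e-01, 2.58866e-01, 3.17294e-01, 3.64359e-01, 4.03954e-01, 4.38105e-01, 5.40005e-01, 6.79913e-01, 8.30912e-01),
    11: (1.63528e-01, 2.38404e-01, 2.93680e-01, 3.38681e-01, 3.76883e-01, 4.10099e-01, 5.10752e-01, 6.53069e-01, 8.12701e-01),
    12: (1.50733e-01, 2.20922e-01, 2.73308e-01, 3.16340e-01, 3.53157e-01, 3.85390e-01, 4.84396e-01, 6.28099e-01, 7.95094e-01),
    13: (1.39791e-01, 2.05817e-01, 2.55557e-01, 2.96734e-01, 3.32202e-01, 3.63442e-01, 4.60549e-01, 6.04844e-01, 7.78091e-01),
    14: (1.30326e-01, 1.92636e-01, 2.39958e-01, 2.79396e-01, 3.13568e-01, 3.43825e-01, 4.38883e-01, 5.83155e-01, 7.61683e-01),
    15: (1.22059e-01, 1.81036e-01, 2.26143e-01, 2.63957e-01, 2.96893e-01, 3.26193e-01, 4.19120e-01, 5.62893e-01, 7.45857e-01),
    20: (9.26567e-02, 1.39108e-01, 1.75534e-01, 2.06725e-01, 2.34411e-01, 2.59467e-01, 3.41807e-01, 4.79012e-01, 6.74797e-01),
    30: (6.25175e-02, 9.50339e-02, 1.21191e-01, 1.44090e-01, 1.64826e-01, 1.83943e-01, 2.49305e-01, 3.68153e-01, 5.65062e-01),
    40: (4.71693e-02, 7.21575e-02, 9.25215e-02, 1.10553e-01, 1.27053e-01, 1.42414e-01, 1.96078e-01, 2.98634e-01, 4.85211e-01),
    50: (3.78708e-02, 5.81551e-02, 7.48160e-02, 8.96715e-02, 1.03353e-01, 1.16167e-01, 1.61545e-01, 2.51097e-01, 4.24830e-01),
    100: (1.90711e-02, 2.95130e-02, 3.82269e-02, 4.61073e-02, 5.34614e-02, 6.04365e-02, 8.58514e-02, 1.39660e-01, 2.61259e-01),
    250: (7.66110e-03, 1.19114e-02, 1.54926e-02, 1.87595e-02, 2.18331e-02, 2.47712e-02, 3.56731e-02, 5.98536e-02, 1.20972e-01),
    500: (3.83600e-03, 5.97355e-03, 7.78040e-03, 9.43349e-03, 1.09931e-02, 1.24879e-02, 1.80690e-02, 3.06519e-02, 6.38108e-02),
}

NONCENTRALITY_TABLE = {
    1: (4.61803e+01, 9.00517e+01, 1.33936e+02, 1.77823e+02, 2.21712e+02, 2.65601e+02, 4.41161e+02, 8.80065e+02, 2.19678e+03),
    2: (1.93236e+01, 3.04220e+01, 4.08997e+01, 5.11554e+01, 6.13048e+01, 7.13948e+01, 1.11490e+02, 2.11206e+02, 5.09746e+02),
    3: (1.53086e+01, 2.20966e+01, 2.82383e+01, 3.41350e+01, 3.99085e+01, 4.56104e+01, 6.80824e+01, 1.23556e+02, 2.89087e+02),
    4: (1.37822e+01, 1.90179e+01, 2.36054e+01, 2.79378e+01, 3.21380e+01, 3.62590e+01, 5.23587e+01, 9.17573e+01, 2.08805e+02),
    5: (1.29870e+01, 1.74388e+01, 2.12434e+01, 2.47874e+01, 2.81929e+01, 3.15140e+01, 4.43773e+01, 7.55652e+01, 1.67745e+02),
    6: (1.25009e+01, 1.64830e+01, 1.98196e+01, 2.28917e+01, 2.58210e+01, 2.86621e+01, 3.95760e+01, 6.57902e+01, 1.42832e+02),
    7: (1.21736e+01, 1.58437e+01, 1.88700e+01, 2.16290e+01, 2.42420e+01, 2.67637e+01, 3.63771e+01, 5.92546e+01, 1.26087e+02),
    8: (1.19383e+01, 1.53865e+01, 1.81924e+01, 2.07289e+01, 2.31168e+01, 2.54110e+01, 3.40954e+01, 5.45774e+01, 1.14042e+02),
    9: (1.17611e+01, 1.50436e+01, 1.76849e+01, 2.00552e+01, 2.22750e+01, 2.43990e+01, 3.23869e+01, 5.10640e+01, 1.04947e+02),
    10: (1.16228e+01, 1.47769e+01, 1.72907e+01, 1.95324e+01, 2.16217e+01, 2.36137e+01, 3.10600e+01, 4.83276e+01, 9.78285e+01),
    11: (1.15120e+01, 1.45636e+01, 1.69759e+01, 1.91149e+01, 2.11002e+01, 2.29868e+01, 3.00000e+01, 4.61356e+01, 9.20991e+01),
    12: (1.14212e+01, 1.43892e+01, 1.67186e+01, 1.87739e+01, 2.06743e+01, 2.24748e+01, 2.91336e+01, 4.43398e+01, 8.73842e+01),
    13: (1.13454e+01, 1.42440e+01, 1.65045e+01, 1.84902e+01, 2.03200e+01, 2.20489e+01, 2.84125e+01, 4.28416e+01, 8.34334e+01),
    14: (1.12812e+01, 1.41211e+01, 1.63236e+01, 1.82505e+01, 2.00207e+01, 2.16891e+01, 2.78028e+01, 4.15723e+01, 8.00727e+01),
    15: (1.12262e+01, 1.40158e+01, 1.61686e+01, 1.80453e+01, 1.97645e+01, 2.13810e+01, 2.72807e+01, 4.04832e+01, 7.71776e+01),
    20: (1.10375e+01, 1.36562e+01, 1.56397e+01, 1.73453e+01, 1.88905e+01, 2.03304e+01, 2.54976e+01, 3.67467e+01, 6.71490e+01),
    30: (1.08550e+01, 1.33096e+01, 1.51311e+01, 1.66726e+01, 1.80510e+01, 1.93210e+01, 2.37807e+01, 3.31188e+01, 5.72176e+01),
    40: (1.07660e+01, 1.31411e+01, 1.48842e+01, 1.63462e+01, 1.76437e+01, 1.88312e+01, 2.29461e+01, 3.13414e+01, 5.22527e+01),
    50: (1.07132e+01, 1.30415e+01, 1.47383e+01, 1.61535e+01, 1.74032e+01, 1.85419e+01, 2.24526e+01, 3.02856e+01, 4.92627e+01),
    100: (1.06093e+01, 1.28456e+01, 1.44516e+01, 1.57748e+01, 1.69308e+01, 1.79737e+01, 2.14819e+01, 2.81960e+01, 4.32297e+01),
    250: (1.05479e+01, 1.27301e+01, 1.42828e+01, 1.55519e+01, 1.66527e+01, 1.76392e+01, 2.09095e+01, 2.69549e+01, 3.95540e+01),
    500: (1.05276e+01, 1.26919e+01, 1.42270e+01, 1.54783e+01, 1.65608e+01, 1.75288e+01, 2.07203e+01, 2.65432e+01, 3.83154e+01),
}

# (a, b, lam, x, correct_7digit, algo1_value, algo1_digits, algo2_value, algo2_digits)
NONCENTRAL_CDF_CASES = (
    (5, 5, 54.0, 0.8640, 0.4563026, 0.4563026, 7, 0.4563021, 5),
    (5, 5, 170.0, 0.9560, 0.6022422, 0.6022421, 6, 0.6022353, 5),
    (10, 10, 54.0, 0.8686, 0.9187791, 0.9187790, 6, 0.9187770, 5),
    (20, 20, 54.0, 0.8787, 0.9998677, 0.9998677, 7, 0.9998655, 5),
    (20, 20, 250.0, 0.9220, 0.9641191, 0.9641169, 5, 0.9641113, 4),
)
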