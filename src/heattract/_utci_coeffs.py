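"""Coefficient table of the sixth-order UTCI regression polynomial.

The operational UTCI approximation expresses the index as

    UTCI = Ta + offset(Ta, va, dTmrt, pa)

where Ta is 2 m air temperature [degC], va the 10 m wind speed [m/s],
dTmrt = Tmrt - Ta [degC], and pa the water vapour pressure [kPa].  The
offset is a complete polynomial of total degree six in the four inputs.
Each entry below is (i, j, k, l, coeff) for the monomial
Ta**i * va**j * dTmrt**k * pa**l, in the canonical published ordering
(grouped by ascending pa power).
"""

UTCI_POLYNOMIAL: list[tuple[int, int, int, int, float]] = [
    # --- pa^0 -------------------------------------------------------------
    (0, 0, 0, 0, 6.07562052e-01),
    (1, 0, 0, 0, -2.27712343e-02),
    (2, 0, 0, 0, 8.06470249e-04),
    (3, 0, 0, 0, -1.54271372e-04),
    (4, 0, 0, 0, -3.24651735e-06),
    (5, 0, 0, 0, 7.32602852e-08),
    (6, 0, 0, 0, 1.35959073e-09),
    (0, 1, 0, 0, -2.25836520e00),
    (1, 1, 0, 0, 8.80326035e-02),
    (2, 1, 0, 0, 2.16844454e-03),
    (3, 1, 0, 0, -1.53347087e-05),
    (4, 1, 0, 0, -5.72983704e-07),
    (5, 1, 0, 0, -2.55090145e-09),
    (0, 2, 0, 0, -7.51269505e-01),
    (1, 2, 0, 0, -4.08350271e-03),
    (2, 2, 0, 0, -5.21670675e-05),
    (3, 2, 0, 0, 1.94544667e-06),
    (4, 2, 0, 0, 1.14099531e-08),
    (0, 3, 0, 0, 1.58137256e-01),
    (1, 3, 0, 0, -6.57263143e-05),
    (2, 3, 0, 0, 2.22697524e-07),
    (3, 3, 0, 0, -4.16117031e-08),
    (0, 4, 0, 0, -1.27762753e-02),
    (1, 4, 0, 0, 9.66891875e-06),
    (2, 4, 0, 0, 2.52785852e-09),
    (0, 5, 0, 0, 4.56306672e-04),
    (1, 5, 0, 0, -1.74202546e-07),
    (0, 6, 0, 0, -5.91491269e-06),
    (0, 0, 1, 0, 3.98374029e-01),
    (1, 0, 1, 0, 1.83945314e-04),
    (2, 0, 1, 0, -1.73754510e-04),
    (3, 0, 1, 0, -7.60781159e-07),
    (4, 0, 1, 0, 3.77830287e-08),
    (5, 0, 1, 0, 5.43079673e-10),
    (0, 1, 1, 0, -2.00518269e-02),
    (1, 1, 1, 0, 8.92859837e-04),
    (2, 1, 1, 0, 3.45433048e-06),
    (3, 1, 1, 0, -3.77925774e-07),
    (4, 1, 1, 0, -1.69699377e-09),
    (0, 2, 1, 0, 1.69992415e-04),
    (1, 2, 1, 0, -4.99204314e-05),
    (2, 2, 1, 0, 2.47417178e-07),
    (3, 2, 1, 0, 1.07596466e-08),
    (0, 3, 1, 0, 8.49242932e-05),
    (1, 3, 1, 0, 1.35191328e-06),
    (2, 3, 1, 0, -6.21531254e-09),
    (0, 4, 1, 0, -4.99410301e-06),
    (1, 4, 1, 0, -1.89489258e-08),
    (0, 5, 1, 0, 8.15300114e-08),
    (0, 0, 2, 0, 7.55043090e-04),
    (1, 0, 2, 0, -5.65095215e-05),
    (2, 0, 2, 0, -4.52166564e-07),
    (3, 0, 2, 0, 2.46688878e-08),
    (4, 0, 2, 0, 2.42674348e-10),
    (0, 1, 2, 0, 1.54547250e-04),
    (1, 1, 2, 0, 5.24110970e-06),
    (2, 1, 2, 0, -8.75874982e-08),
    (3, 1, 2, 0, -1.50743064e-09),
    (0, 2, 2, 0, -1.56236307e-05),
    (1, 2, 2, 0, -1.33895614e-07),
    (2, 2, 2, 0, 2.49709824e-09),
    (0, 3, 2, 0, 6.51711721e-07),
    (1, 3, 2, 0, 1.94960053e-09),
    (0, 4, 2, 0, -1.00361113e-08),
    (0, 0, 3, 0, -1.21206673e-05),
    (1, 0, 3, 0, -2.18203660e-07),
    (2, 0, 3, 0, 7.51269482e-09),
    (3, 0, 3, 0, 9.79063848e-11),
    (0, 1, 3, 0, 1.25006734e-06),
    (1, 1, 3, 0, -1.81584736e-09),
    (2, 1, 3, 0, -3.52197671e-10),
    (0, 2, 3, 0, -3.36514630e-08),
    (1, 2, 3, 0, 1.35908359e-10),
    (0, 3, 3, 0, 4.17032620e-10),
    (0, 0, 4, 0, -1.30369025e-09),
    (1, 0, 4, 0, 4.13908461e-10),
    (2, 0, 4, 0, 9.22652254e-12),
    (0, 1, 4, 0, -5.08220384e-09),
    (1, 1, 4, 0, -2.24730961e-11),
    (0, 2, 4, 0, 1.17139133e-10),
    (0, 0, 5, 0, 6.62154879e-10),
    (1, 0, 5, 0, 4.03863260e-13),
    (0, 1, 5, 0, 1.95087203e-12),
    (0, 0, 6, 0, -4.73602469e-12),
    # --- pa^1 -------------------------------------------------------------
    (0, 0, 0, 1, 5.12733497e00),
    (1, 0, 0, 1, -3.12788561e-01),
    (2, 0, 0, 1, -1.96701861e-02),
    (3, 0, 0, 1, 9.99690870e-04),
    (4, 0, 0, 1, 9.51738512e-06),
    (5, 0, 0, 1, -4.66426341e-07),
    (0, 1, 0, 1, 5.48050612e-01),
    (1, 1, 0, 1, -3.30552823e-03),
    (2, 1, 0, 1, -1.64119440e-03),
    (3, 1, 0, 1, -5.16670694e-06),
    (4, 1, 0, 1, 9.52692432e-07),
    (0, 2, 0, 1, -4.29223622e-02),
    (1, 2, 0, 1, 5.00845667e-03),
    (2, 2, 0, 1, 1.00601257e-06),
    (3, 2, 0, 1, -1.81748644e-06),
    (0, 3, 0, 1, -1.25813502e-03),
    (1, 3, 0, 1, -1.79330391e-04),
    (2, 3, 0, 1, 2.34994441e-06),
    (0, 4, 0, 1, 1.29735808e-04),
    (1, 4, 0, 1, 1.29064870e-06),
    (0, 5, 0, 1, -2.28558686e-06),
    (0, 0, 1, 1, -3.69476348e-02),
    (1, 0, 1, 1, 1.62325322e-03),
    (2, 0, 1, 1, -3.14279680e-05),
    (3, 0, 1, 1, 2.59835559e-06),
    (4, 0, 1, 1, -4.77136523e-08),
    (0, 1, 1, 1, 8.64203390e-03),
    (1, 1, 1, 1, -6.87405181e-04),
    (2, 1, 1, 1, -9.13863872e-06),
    (3, 1, 1, 1, 5.15916806e-07),
    (0, 2, 1, 1, -3.59217476e-05),
    (1, 2, 1, 1, 3.28696511e-05),
    (2, 2, 1, 1, -7.10542454e-07),
    (0, 3, 1, 1, -1.24382300e-05),
    (1, 3, 1, 1, -7.38584400e-09),
    (0, 4, 1, 1, 2.20609296e-07),
    (0, 0, 2, 1, -7.32469180e-04),
    (1, 0, 2, 1, -1.87381964e-05),
    (2, 0, 2, 1, 4.80925239e-06),
    (3, 0, 2, 1, -8.75492040e-08),
    (0, 1, 2, 1, 2.77862930e-05),
    (1, 1, 2, 1, -5.06004592e-06),
    (2, 1, 2, 1, 1.14325367e-07),
    (0, 2, 2, 1, 2.53016723e-06),
    (1, 2, 2, 1, -1.72857035e-08),
    (0, 3, 2, 1, -3.95079398e-08),
    (0, 0, 3, 1, -3.59413173e-07),
    (1, 0, 3, 1, 7.04388046e-07),
    (2, 0, 3, 1, -1.89309167e-08),
    (0, 1, 3, 1, -4.79768731e-07),
    (1, 1, 3, 1, 7.96079978e-09),
    (0, 2, 3, 1, 1.62897058e-09),
    (0, 0, 4, 1, 3.94367674e-08),
    (1, 0, 4, 1, -1.18566247e-09),
    (0, 1, 4, 1, 3.34678041e-10),
    (0, 0, 5, 1, -1.15606447e-10),
    # --- pa^2 -------------------------------------------------------------
    (0, 0, 0, 2, -2.80626406e00),
    (1, 0, 0, 2, 5.48712484e-01),
    (2, 0, 0, 2, -3.99428410e-03),
    (3, 0, 0, 2, -9.54009191e-04),
    (4, 0, 0, 2, 1.93090978e-05),
    (0, 1, 0, 2, -3.08806365e-01),
    (1, 1, 0, 2, 1.16952364e-02),
    (2, 1, 0, 2, 4.95271903e-04),
    (3, 1, 0, 2, -1.90710882e-05),
    (0, 2, 0, 2, 2.10787756e-03),
    (1, 2, 0, 2, -6.98445738e-04),
    (2, 2, 0, 2, 2.30109073e-05),
    (0, 3, 0, 2, 4.17856590e-04),
    (1, 3, 0, 2, -1.27043871e-05),
    (0, 4, 0, 2, -3.04620472e-06),
    (0, 0, 1, 2, 5.14507424e-02),
    (1, 0, 1, 2, -4.32510997e-03),
    (2, 0, 1, 2, 8.99281156e-05),
    (3, 0, 1, 2, -7.14663943e-07),
    (0, 1, 1, 2, -2.66016305e-04),
    (1, 1, 1, 2, 2.63789586e-04),
    (2, 1, 1, 2, -7.01199003e-06),
    (0, 2, 1, 2, -1.06823306e-04),
    (1, 2, 1, 2, 3.61341136e-06),
    (0, 3, 1, 2, 2.29748967e-07),
    (0, 0, 2, 2, 3.04788893e-04),
    (1, 0, 2, 2, -6.42070836e-05),
    (2, 0, 2, 2, 1.16257971e-06),
    (0, 1, 2, 2, 7.68023384e-06),
    (1, 1, 2, 2, -5.47446896e-07),
    (0, 2, 2, 2, -3.59937910e-08),
    (0, 0, 3, 2, -4.36497725e-06),
    (1, 0, 3, 2, 1.68737969e-07),
    (0, 1, 3, 2, 2.67489271e-08),
    (0, 0, 4, 2, 3.23926897e-09),
    # --- pa^3 -------------------------------------------------------------
    (0, 0, 0, 3, -3.53874123e-02),
    (1, 0, 0, 3, -2.21201190e-01),
    (2, 0, 0, 3, 1.55126038e-02),
    (3, 0, 0, 3, -2.63917279e-04),
    (0, 1, 0, 3, 4.53433455e-02),
    (1, 1, 0, 3, -4.32943862e-03),
    (2, 1, 0, 3, 1.45389826e-04),
    (0, 2, 0, 3, 2.17508610e-04),
    (1, 2, 0, 3, -6.66724702e-05),
    (0, 3, 0, 3, 3.33217140e-05),
    (0, 0, 1, 3, -2.26921615e-03),
    (1, 0, 1, 3, 3.80261982e-04),
    (2, 0, 1, 3, -5.45314314e-09),
    (0, 1, 1, 3, -7.96355448e-04),
    (1, 1, 1, 3, 2.53458034e-05),
    (0, 2, 1, 3, -6.31223658e-06),
    (0, 0, 2, 3, 3.02122035e-04),
    (1, 0, 2, 3, -4.77403547e-06),
    (0, 1, 2, 3, 1.73825715e-06),
    (0, 0, 3, 3, -4.09087898e-07),
    # --- pa^4 -------------------------------------------------------------
    (0, 0, 0, 4, 6.14155345e-01),
    (1, 0, 0, 4, -6.16755931e-02),
    (2, 0, 0, 4, 1.33374846e-03),
    (0, 1, 0, 4, 3.55375387e-03),
    (1, 1, 0, 4, -5.13027851e-04),
    (0, 2, 0, 4, 1.02449757e-04),
    (0, 0, 1, 4, -1.48526421e-03),
    (1, 0, 1, 4, -4.11469183e-05),
    (0, 1, 1, 4, -6.80434415e-06),
    (0, 0, 2, 4, -9.77675906e-06),
    # --- pa^5 -------------------------------------------------------------
    (0, 0, 0, 5, 8.82773108e-02),
    (1, 0, 0, 5, -3.01859306e-03),
    (0, 1, 0, 5, 1.04452989e-03),
    (0, 0, 1, 5, 2.47090539e-04),
    # --- pa^6 -------------------------------------------------------------
    (0, 0, 0, 6, 1.48348065e-03),
]

assert len(UTCI_POLYNOMIAL) == 210
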