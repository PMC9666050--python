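"""Embedded orthonormal scaling-filter coefficient tables.

Each entry is the low-pass (scaling) decomposition filter h(k) in causal
order, normalised so that sum h = sqrt(2) and sum h^2 = 1.  The matching
high-pass filter is derived by the quadrature-mirror rule
g(k) = (-1)^k h(L-1-k) and is not stored.

Provenance:

* ``db4``  -- Daubechies extremal-phase filter with 4 vanishing moments
  (Daubechies, "Ten Lectures on Wavelets", 1992, Table 6.1).
* ``sym3`` -- Daubechies least-asymmetric ("symlet") filter, 3 vanishing
  moments (ibid., Table 6.3).
* ``coif2`` -- Coiflet filter of order 2 (12 taps; Daubechies 1992, Sec. 8.2).
* ``fk8``  -- Fejer-Korovkin length-8 filter (Nielsen, J. Approx. Theory
  108, 2001).  The published table is reproduced here to ~1e-6 and was
  refined onto the exact orthonormal quadrature-mirror manifold
  (minimal-norm correction) so the filter-bank identities hold to
  machine precision.
* ``dmey`` -- 62-tap FIR approximation of the discrete Meyer wavelet
  (Abry, 1997; the table distributed with common wavelet toolboxes).
  The truncation makes the published table only approximately orthogonal
  (sum h^2 deviates from 1 by ~2e-3), which would leak an ~1e-2 error
  into reconstruction.  The table below is the published filter projected
  onto the exact orthonormal quadrature-mirror manifold (largest single
  coefficient change 7.7e-4), restoring perfect reconstruction and
  Parseval energy conservation to machine precision.
"""

SCALING_FILTERS: dict[str, tuple[float, ...]] = {
    "db4": (
        0.2303778133088965, 0.7148465705529157, 0.6308807679298589,
        -0.027983769416859854, -0.18703481171909309, 0.030841381835560764,
        0.0328830116668852, -0.010597401785069032,
    ),
    "sym3": (
        0.3326705529509569, 0.8068915093133388, 0.4598775021193313,
        -0.13501102001039084, -0.08544127388224149, 0.035226291882100656,
    ),
    "coif2": (
        0.01638733646320364, -0.04146493678687178, -0.0673725547237256,
        0.3861100668227629, 0.8127236354494135, 0.4170051844232391,
        -0.07648859907828076, -0.05943441864643109, 0.02368017194684777,
        0.005611434819368834, -0.0018232088709110323, -0.000720549445520347,
    ),
    "fk8": (
        0.3492357826113885, 0.7826819748630616, 0.4752694536186619,
        -0.09968281783324758, -0.15997894562516618, 0.04310720691174189,
        0.04258049058166333, -0.0189995827550083,
    ),
    "dmey": (
        4.895243827019077e-07, -1.0168008088695125e-06, 5.417015736338286e-07,
        -1.6407260475715816e-06, -3.926302241444383e-06, 8.242764825983625e-06,
        9.810802183953775e-06, -2.830329073799865e-05, -3.1578387875802245e-05,
        9.188912302900705e-05, 0.00010288139324250443, -0.00024038950295272879,
        -0.00029610504911026746, 0.0006148759421496286, 0.00046989208892458066,
        -0.00044045087232298246, -0.0026276808174067424, 0.0020787269184381093,
        0.006105390996033696, -0.006408128073394963, -0.01099953785387307,
        0.015167078681254796, 0.01748328269951481, -0.03214412903104335,
        -0.02427203574441639, 0.06359667966332892, 0.030693622834829487,
        -0.13275552581354244, -0.0349913713443066, 0.444030241792037,
        0.7438178411892494, 0.44403025776637517, -0.03499137072877154,
        -0.1327555010567437, 0.030693624091177155, 0.06359658531353565,
        -0.02427203333893344, -0.03214427846155973, 0.01748327744005195,
        0.01516690818833447, -0.010999531971473553, -0.006408568304035864,
        0.006105387283074865, 0.0020804645785018477, -0.0026277345021260786,
        -0.0004517213033247564, 0.0004702437978578819, 0.000592960253056877,
        -0.00029594721013043266, -0.00022976024492594692, 0.00010371904216979729,
        8.210930234018346e-05, -3.217983946743096e-05, -2.6632878964333184e-05,
        1.040284815893132e-05, 5.406609356829681e-06, -4.136366236650237e-06,
        -8.337386087319985e-07, 3.4721484041141453e-06, 1.8796028659597045e-06,
        -1.92923792398584e-06, -6.452138804616009e-07,
    ),
}
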