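"""Reference regression rows from a published SCA1 volumetric screen.

Each row carries the reported fixed-effect estimate (mm^3/yr), its standard
error, denominator df, t statistic, uncorrected p and family-wise corrected
p (family size 34).  They are used purely as arithmetic fixtures: the
relations t = beta/SE, p = 2*P(T_df > |t|) and p_corr = min(1, 34*p) must
reproduce the printed values at their printed precision.
"""

# (screen, region, beta, se, df, t, p, p_bonferroni)
GROUP_BY_TIME_ROWS = [
    ("group-by-time", "cerebellum",           -1111.813, 337.350, 60.0, -3.30, 1.65e-3, 5.62e-2),
    ("group-by-time", "cereb_lobule_6",        -191.258,  41.204, 60.3, -4.64, 1.91e-5, 6.51e-4),
    ("group-by-time", "cereb_wm_deep_nuclei",  -258.660,  56.339, 60.5, -4.59, 2.28e-5, 7.76e-4),
    ("group-by-time", "caudate",               -106.223,  25.915, 59.8, -4.10, 1.27e-4, 4.32e-3),
    ("group-by-time", "putamen",               -136.797,  28.651, 59.2, -4.77, 1.22e-5, 4.16e-4),
    ("group-by-time", "pallidum",               -75.485,  14.032, 60.0, -5.38, 1.30e-6, 4.41e-5),
    ("group-by-time", "pons",                  -348.144,  40.743, 59.9, -8.54, 5.91e-12, 2.01e-10),
]

AFFECTED_ONLY_ROWS = [
    ("affected-only", "cereb_lobule_6",        -210.984,  34.977, 24.8, -6.03, 2.75e-6, 9.33e-5),
    ("affected-only", "cereb_wm_deep_nuclei",  -308.859,  46.010, 24.7, -6.71, 5.18e-7, 1.76e-5),
    ("affected-only", "corpus_callosum",        -46.005,  11.630, 24.6, -3.96, 5.69e-4, 1.93e-2),
    ("affected-only", "caudate",               -106.709,  25.568, 24.8, -4.17, 3.21e-4, 1.09e-2),
    ("affected-only", "putamen",               -141.078,  24.830, 24.7, -5.68, 6.75e-6, 2.29e-4),
    ("affected-only", "pallidum",               -58.671,  13.059, 24.6, -4.49, 1.44e-4, 4.90e-3),
    ("affected-only", "thalamus",              -210.560,  33.103, 24.9, -6.36, 1.20e-6, 4.07e-5),
    ("affected-only", "pons",                  -304.985,  31.126, 25.1, -9.80, 4.70e-10, 1.60e-8),
    ("affected-only", "scp",                     -8.247,   2.218, 24.9, -3.72, 1.02e-3, 3.48e-2),
]

ALL_ROWS = GROUP_BY_TIME_ROWS + AFFECTED_ONLY_ROWS

FAMILY_SIZE = 34
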