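"""Registry of the 34 volumes of interest (VOIs) screened by the pipeline.

Each region carries the defaults the synthetic-cohort generator needs to
emulate an early-stage SCA1 longitudinal study:

* ``typical_mm3`` — a realistic adult regional volume at the reference
  intracranial volume (ICV) of 1.5e6 mm^3; the power-law scale constant
  alpha is derived from it as ``typical_mm3 / ICV_REF**beta``.
* ``beta`` — allometric scaling exponent of the region against ICV
  (near 1 for cortical/global measures, below 1 for subcortical,
  brainstem and cerebellar structures).
* ``slope_affected_mm3_yr`` — the default linear atrophy rate in affected
  individuals (mm^3/year; unaffected individuals default to zero change).
* ``screen_se_mm3_yr`` — the reported precision (standard error) of the
  group-by-time atrophy contrast at cohort scale; the generator's
  measurement noise is calibrated against it (see
  :data:`NOISE_CALIBRATION`).
"""

from __future__ import annotations

import pandas as pd

#: Reference ICV (mm^3) at which ``typical_mm3`` is quoted.
ICV_REF = 1.5e6

#: Ratio of per-visit measurement SD (mm^3) to the cohort-scale screen SE
#: (mm^3/yr).  Calibrated by Monte Carlo on the default cohort design
#: (13 affected / 20 unaffected, visits at 0/1.5/3.0 years, baseline rows
#: included in the fit) so that the simulated group-by-time SE reproduces
#: the region's ``screen_se_mm3_yr``.
NOISE_CALIBRATION = 5.55

# name, typical_mm3, beta, slope_affected_mm3_yr, screen_se_mm3_yr
_REGION_ROWS = [
    ("whole_brain",          1_200_000.0, 1.00,  -8417.702, 6623.368),
    ("cerebrum",             1_000_000.0, 1.00,  -6864.891, 6402.336),
    ("cerebral_gm",            600_000.0, 0.95,  -5325.858, 3680.643),
    ("cerebral_wm",            450_000.0, 1.05,     82.611, 2117.327),
    ("cerebellum",             130_000.0, 0.80,  -1111.813,  337.350),
    ("cereb_lobules_1_2",          300.0, 0.60,      6.182,    2.126),
    ("cereb_lobule_3",             700.0, 0.60,     -3.674,   10.721),
    ("cereb_lobule_4",           2_500.0, 0.65,    -14.073,   19.859),
    ("cereb_lobule_5",           5_000.0, 0.65,   -104.775,   40.724),
    ("cereb_lobule_6",           9_000.0, 0.70,   -191.258,   41.204),
    ("cereb_crus_1",            12_000.0, 0.70,   -212.965,  121.987),
    ("cereb_crus_2",             9_500.0, 0.70,   -397.944,  197.379),
    ("cereb_lobule_7b",          5_000.0, 0.65,     -5.103,  106.154),
    ("cereb_lobule_8a",          5_500.0, 0.65,    154.298,   91.619),
    ("cereb_lobule_8b",          4_000.0, 0.65,     57.530,   61.447),
    ("cereb_lobule_9",           5_000.0, 0.65,    -45.321,   41.750),
    ("cereb_lobule_10",            700.0, 0.60,     28.049,   17.780),
    ("cereb_wm_deep_nuclei",    25_000.0, 0.75,   -258.660,   56.339),
    ("corpus_callosum",         10_000.0, 0.85,    -26.852,   15.458),
    ("frontal_lobe",           150_000.0, 0.95,  -5563.115, 2729.405),
    ("occipital_lobe",          70_000.0, 0.95,    521.456,  740.068),
    ("parietal_lobe",          100_000.0, 0.95,   -480.415, 1743.822),
    ("temporal_lobe",          110_000.0, 0.95,   1107.655, 1093.294),
    ("caudate",                  7_000.0, 0.70,   -106.223,   25.915),
    ("putamen",                  9_500.0, 0.70,   -136.797,   28.651),
    ("pallidum",                 3_000.0, 0.65,    -75.485,   14.032),
    ("accumbens",                1_000.0, 0.60,     12.328,   31.652),
    ("hippocampus",              7_500.0, 0.70,     -4.378,   11.367),
    ("amygdala",                 3_000.0, 0.65,     -8.450,    7.248),
    ("thalamus",                14_000.0, 0.75,    -59.833,   49.289),
    ("hypothalamus",             1_500.0, 0.60,    -78.270,   41.578),
    ("medulla",                  4_500.0, 0.65,    -29.044,   58.287),
    ("pons",                    14_000.0, 0.65,   -348.144,   40.743),
    ("scp",                        600.0, 0.60,     -4.505,    2.773),
]


def region_table() -> pd.DataFrame:
    """Default region registry as a DataFrame indexed by region name."""
    df = pd.DataFrame(
        _REGION_ROWS,
        columns=["region", "typical_mm3", "beta", "slope_affected_mm3_yr",
                 "screen_se_mm3_yr"],
    ).set_index("region")
    df["alpha"] = df["typical_mm3"] / ICV_REF ** df["beta"]
    df["residual_sd_mm3"] = NOISE_CALIBRATION * df["screen_se_mm3_yr"]
    return df


REGION_NAMES: list[str] = [r[0] for r in _REGION_ROWS]

#: Prefix used for VOI columns in cohort tables.
VOI_PREFIX = "voi_"


def voi_columns(names: list[str] | None = None) -> list[str]:
    """Cohort-table column names for the given (default: all) regions."""
    return [VOI_PREFIX + n for n in (names if names is not None else REGION_NAMES)]
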