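"""Small shared constructors for tests."""

import numpy as np

from sca1vol.screen import LMEResult


def make_lme_result(b0, bt, v00, vtt, v0t, df, voi="pons"):
    """An LMEResult carrying just the intercept/time block the
    detectability module consumes."""
    return LMEResult(voi=voi, term="time_years", beta=bt, se=float(np.sqrt(vtt)),
                     df=df, t=bt / float(np.sqrt(vtt)), p=0.5,
                     fixed_names=["const", "time_years"],
                     fixed_beta=np.array([b0, bt]),
                     fixed_cov=np.array([[v00, v0t], [v0t, vtt]]))
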