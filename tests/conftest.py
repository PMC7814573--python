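import numpy as np
import pytest

from felhoma.refinterval import tukey_outliers


@pytest.fixture(scope="session")
def lean_homa_base_60():
    """60 lean-cat-like HOMA-IR values guaranteed inside their own Tukey fences.

    Drawn lognormal (median 0.8) and iteratively screened until stable, so
    a planted extreme is the only value the fences can flag.
    """
    v = np.random.default_rng(0).lognormal(np.log(0.8), 0.55, 180)
    for _ in range(10):
        kept, flagged = tukey_outliers(v)
        if flagged.size == 0:
            break
        v = kept
    return v[:60]
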