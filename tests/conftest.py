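import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from methbench.io_calls import CALL_COLUMNS, MethylationCallSet, RunMeta


def make_call_set(
    positions, betas=None, depths=None, counts=None, chrom="chr1", meta=None
):
    """Build a small call set from parallel lists; counts override betas."""
    n = len(positions)
    if counts is not None:
        m = np.asarray([c[0] for c in counts], dtype=float)
        u = np.asarray([c[1] for c in counts], dtype=float)
        depth = m + u
        with np.errstate(invalid="ignore"):
            beta = np.where(depth > 0, m / np.maximum(depth, 1), np.nan)
    else:
        beta = np.asarray(betas, dtype=float)
        depth = np.asarray(depths if depths is not None else [1] * n, dtype=float)
        m = np.round(beta * depth)
        m = np.where(np.isnan(m), np.nan, m)
        u = depth - m
    df = pd.DataFrame(
        dict(chrom=chrom, pos=np.asarray(positions, dtype=np.int64),
             beta=beta, depth=depth, count_m=m, count_u=u)
    )[CALL_COLUMNS]
    return MethylationCallSet(df, meta=meta)


@pytest.fixture
def small_meta():
    return RunMeta("wfA", "WGBS", "S1", "normal")
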