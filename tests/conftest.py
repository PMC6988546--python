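import numpy as np
import pandas as pd
import pytest

from streamsdm import swd_io
from streamsdm.swd_io import PresenceSet, SegmentTable
from streamsdm.synthetic import RiverscapeParams, generate_riverscape


def make_segments(n=6, covs=None, orders=None, hucs=None, x=None, y=None):
    """Hand-built chain network S0 <- S1 <- ... (S0 is the outlet)."""
    df = pd.DataFrame({
        "segment_id": [f"S{i}" for i in range(n)],
        "downstream_id": [None] + [f"S{i}" for i in range(n - 1)],
        "huc8": hucs if hucs is not None else ["H0"] * n,
        "stream_order": orders if orders is not None else [1] * n,
        "x": x if x is not None else np.arange(n, dtype=float),
        "y": y if y is not None else np.zeros(n),
    })
    covs = covs or {}
    for name, vals in covs.items():
        df[name] = vals
    return SegmentTable(df, covariates=list(covs))


def make_presences(rows):
    """rows: list of dicts with at least record_id and segment_id."""
    return PresenceSet(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def riverscape():
    """A mid-sized seeded riverscape shared across tests (read-only)."""
    params = RiverscapeParams(n_segments=800, n_presences=30, seed=7)
    seg, pres, suit = generate_riverscape(params)
    pres = swd_io.dedupe_presences(pres, seg)
    return params, seg, pres, suit


@pytest.fixture(scope="session")
def small_fit(riverscape):
    """One fitted default-beta model on the shared riverscape."""
    import streamsdm as sdm
    _, seg, pres, _ = riverscape
    fs = sdm.build_features(seg, pres.segment_ids, n_knots=20)
    model = sdm.fit(fs, pres.segment_ids, seg, beta=1.0)
    return seg, pres, model
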