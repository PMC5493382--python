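import numpy as np
import pytest

import skintemp as st
from skintemp.sites import ALL_SITES


@pytest.fixture(scope="session")
def default_cohort():
    """A preprocessed cohort at the study-design defaults (13 subjects, 24 h,
    3-min sampling, quantized, with non-wear gaps)."""
    return st.preprocess(st.generate_cohort(st.SyntheticConfig(seed=42)))


@pytest.fixture(scope="session")
def nogap_cohort():
    """Default-noise cohort without non-wear events: every subject keeps all
    480 samples, so design sizes are exact."""
    cfg = st.SyntheticConfig(seed=7, nonwear_rate_per_day=0.0)
    return st.preprocess(st.generate_cohort(cfg))


@pytest.fixture()
def tiny_config():
    """A fast 3-subject, 6-hour configuration for unit tests."""
    return st.SyntheticConfig(n_subjects=3, duration_h=6.0, seed=11,
                              nonwear_rate_per_day=0.0)


def constant_recording(values_by_site: dict, n: int = 8, subject_id: str = "S01"):
    """A recording where each site is constant at the given value."""
    series = {}
    for site in ALL_SITES:
        v = values_by_site.get(site, 33.0)
        series[site] = st.TemperatureSeries(
            site=site,
            start_time="2000-01-01T12:00",
            sampling_interval_min=3.0,
            values=np.full(n, float(v)),
            valid_mask=np.ones(n, dtype=bool),
        )
    return st.SubjectRecording(subject_id=subject_id, series=series)


def grid_search_weights(X, y, half_width=3.0, points=21, iters=28):
    """Independent brute-force least-squares minimizer: dense grid over the
    weight box, repeatedly re-centred and refined around the best cell.
    Used as an oracle for the closed-form/SVD fit; never calls the package.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    P = X.shape[1]
    center = np.zeros(P)
    hw = half_width
    for _ in range(iters):
        axes = [np.linspace(c - hw, c + hw, points) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        W = np.stack([g.ravel() for g in mesh])              # (P, M)
        sse = ((y[:, None] - X @ W) ** 2).sum(axis=0)
        idx = np.unravel_index(int(np.argmin(sse)), mesh[0].shape)
        center = np.array([axes[d][idx[d]] for d in range(P)])
        if any(i == 0 or i == points - 1 for i in idx):
            hw *= 2.0                                        # best on edge: widen
        else:
            hw = 2.0 * (2.0 * hw / (points - 1))             # refine around best
    return center
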