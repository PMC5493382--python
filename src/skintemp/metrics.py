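"""Reconstruction-accuracy metrics.

MSE = (1/N)·‖T − T̂‖², MAE = (1/N)·Σ|Tᵢ − T̂ᵢ|, signed-error quartiles
(Q1/Q3, linear-interpolation percentiles), leave-one-subject-out
cross-validation error (CVE), a day/night MAE split on wall-clock hours,
and signed-error histograms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CohortDataset
from .errors import InsufficientSamplesError, SingularDesignError
from .sites import SiteGroup

#: Day stratum is wall-clock [07:00, 19:00); night is the complement.
#: Half-open intervals assign each boundary instant to exactly one stratum.
DAY_HOURS = (7, 19)

#: Default histogram bin width: one logger quantization step, °C.
DEFAULT_BIN_WIDTH = 0.0625


def _check_pair(T, That) -> tuple[np.ndarray, np.ndarray]:
    T = np.asarray(T, dtype=float).ravel()
    That = np.asarray(That, dtype=float).ravel()
    if T.size != That.size:
        raise ValueError(f"length mismatch: {T.size} vs {That.size}")
    if T.size == 0:
        raise ValueError("empty vectors")
    return T, That


def mse(T, That) -> float:
    """Mean squared reconstruction error, °C²."""
    T, That = _check_pair(T, That)
    return float(np.mean((T - That) ** 2))


def mae(T, That) -> float:
    """Mean absolute reconstruction error, °C."""
    T, That = _check_pair(T, That)
    return float(np.mean(np.abs(T - That)))


def error_quartiles(T, That) -> tuple[float, float]:
    """25th/75th percentiles of the SIGNED error T − T̂ (linear interpolation)."""
    T, That = _check_pair(T, That)
    if T.size < 4:
        raise InsufficientSamplesError(f"quartiles need at least 4 samples, got {T.size}")
    q1, q3 = np.percentile(T - That, [25, 75], method="linear")
    return float(q1), float(q3)


def day_night_mae(T, That, timestamps) -> tuple[float | None, float | None]:
    """MAE split by wall-clock stratum: day [07:00, 19:00) vs night.

    An empty stratum is reported as ``None`` (undefined), never 0.
    """
    T, That = _check_pair(T, That)
    ts = pd.DatetimeIndex(timestamps)
    if ts.size != T.size:
        raise ValueError("timestamps length mismatch")
    day = (ts.hour >= DAY_HOURS[0]) & (ts.hour < DAY_HOURS[1])
    err = np.abs(T - That)
    mae_day = float(err[day].mean()) if day.any() else None
    mae_night = float(err[~day].mean()) if (~day).any() else None
    return mae_day, mae_night


def error_histogram(T, That, bin_width: float = DEFAULT_BIN_WIDTH):
    """Histogram of the signed error with bins on multiples of ``bin_width``.

    Returns ``(edges, counts)`` with ``len(edges) == len(counts) + 1`` and
    ``counts.sum() == N``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    T, That = _check_pair(T, That)
    err = T - That
    lo = np.floor(err.min() / bin_width) * bin_width
    hi = np.ceil(err.max() / bin_width) * bin_width
    if hi <= lo:  # all errors on one bin edge (e.g. all zero)
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(err, bins=edges)
    return edges, counts


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def loso_cve(design, rank_tol: float | None = None, aggregate: str = "pooled") -> float:
    """Leave-one-subject-out cross-validation error on a built design.

    For each subject, weights are re-fitted on all other subjects' pooled
    rows and the held-out subject's rows are reconstructed; CVE is the mean
    absolute held-out error.  ``aggregate='pooled'`` (default) averages over
    all held-out samples at once; ``'per_subject'`` averages the per-subject
    means.  Folds with a singular training design are skipped with a warning.
    """
    from .subsetfit import DEFAULT_RANK_TOL, LinearCompositeModel

    if aggregate not in ("pooled", "per_subject"):
        raise ValueError("aggregate must be 'pooled' or 'per_subject'")
    rank_tol = DEFAULT_RANK_TOL if rank_tol is None else rank_tol
    subjects = pd.unique(design.subject_ids)
    if subjects.size < 2:
        raise ValueError("cross-validation needs at least 2 subjects with usable rows")
    abs_errors: list[np.ndarray] = []
    for subject in subjects:
        held = design.subject_ids == subject
        model = LinearCompositeModel(rank_tol=rank_tol)
        try:
            model.fit(design.X[~held], design.T[~held])
        except SingularDesignError:
            warnings.warn(
                f"subset {design.subset.canonical_id}: training design singular when "
                f"holding out {subject}; fold skipped",
                stacklevel=2,
            )
            continue
        abs_errors.append(np.abs(design.T[held] - model.predict(design.X[held])))
    if not abs_errors:
        raise SingularDesignError(
            f"subset {design.subset.canonical_id}: every cross-validation fold failed"
        )
    if aggregate == "pooled":
        return float(np.concatenate(abs_errors).mean())
    return float(np.mean([e.mean() for e in abs_errors]))


def cross_validation_error(
    cohort: CohortDataset,
    subset,
    rank_tol: float | None = None,
    aggregate: str = "pooled",
) -> float:
    """LOSO CVE for a subset, built from a preprocessed cohort."""
    from .subsetfit import build_design

    return loso_cve(build_design(cohort, subset), rank_tol=rank_tol, aggregate=aggregate)
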