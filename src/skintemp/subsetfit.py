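"""Reduced-sensor-set weight estimation.

For every nonempty subset of a group's sensors, the composite temperature is
re-modelled as a weighted sum of the available sensors only, and the weight
vector w is re-tuned by unconstrained, no-intercept linear least squares
against the full-set reference composite:

    w_hat = argmin_w || T - X w ||^2  =  (X'X)^{-1} X' T

where X (N x P) stacks the P available sensors' pooled "macro-signals" —
all subjects' group-complete samples appended in ascending subject order —
and T is the reference composite at the same rows.  Excluded sensors carry
weight exactly 0.  The solve uses an SVD-based least-squares routine, whose
solution coincides with the normal-equations formula on full-rank designs.

The solver is exposed as a scikit-learn style estimator,
:class:`LinearCompositeModel` (``fit`` / ``predict`` / ``coef_``), so it
composes with sklearn pipelines and model selection; the module-level
functions are thin wrappers over it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import CohortDataset
from .errors import EmptyDesignError, SingularDesignError
from .reference import compute_reference
from .sites import GROUP_SITES, SiteCode, SiteGroup, parse_site

#: Relative singular-value cutoff below which a design is declared singular.
DEFAULT_RANK_TOL = 1e-10


# ---------------------------------------------------------------------------
# Subsets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorSubset:
    """A nonempty subset of one group's sensor sites."""

    group: SiteGroup
    included: frozenset[SiteCode]

    def __post_init__(self) -> None:
        if not self.included:
            raise ValueError("subset must be nonempty")
        extra = self.included - set(GROUP_SITES[self.group])
        if extra:
            names = ", ".join(sorted(s.value for s in extra))
            raise ValueError(f"sites {names} do not belong to group {self.group.value}")

    @property
    def sites(self) -> tuple[SiteCode, ...]:
        """Included sites in the group's canonical (anatomical) order."""
        return tuple(s for s in GROUP_SITES[self.group] if s in self.included)

    @property
    def canonical_id(self) -> str:
        return "+".join(s.value for s in self.sites)

    def __len__(self) -> int:
        return len(self.included)

    def __contains__(self, site: SiteCode) -> bool:
        return site in self.included

    @classmethod
    def from_codes(cls, group: SiteGroup, codes: Iterable[SiteCode | str]) -> "SensorSubset":
        parsed = frozenset(parse_site(c) if isinstance(c, str) else c for c in codes)
        return cls(group, parsed)


def enumerate_subsets(group: SiteGroup) -> list[SensorSubset]:
    """All nonempty subsets (31 proximal, 15 distal), ordered by size
    ascending then canonical id lexicographic."""
    sites = GROUP_SITES[group]
    subsets = [
        SensorSubset(group, frozenset(combo))
        for size in range(1, len(sites) + 1)
        for combo in itertools.combinations(sites, size)
    ]
    subsets.sort(key=lambda s: (len(s), s.canonical_id))
    return subsets


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """The pooled macro-signal design: X (N x P), reference vector T (N),
    and per-row provenance (subject id, timestamp)."""

    subset: SensorSubset
    X: np.ndarray
    T: np.ndarray
    subject_ids: np.ndarray   # (N,) str, blockwise in ascending subject order
    timestamps: pd.DatetimeIndex

    @property
    def n(self) -> int:
        return self.T.size

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(cohort: CohortDataset, subset: SensorSubset) -> DesignMatrix:
    """Stack the subset's site signals over all subjects' group-complete rows.

    A row exists only where *every* sensor of the group (not just the
    subset) is valid, so the reference T is always defined at that row.
    """
    cols = subset.sites
    X_blocks, T_blocks, id_blocks, ts_blocks = [], [], [], []
    for rec in cohort.sorted_recordings():
        ref = compute_reference(rec, subset.group)
        mask = ref.valid_mask
        if not mask.any():
            continue
        X_blocks.append(np.column_stack([rec[s].values[mask] for s in cols]))
        T_blocks.append(ref.values[mask])
        id_blocks.append(np.repeat(rec.subject_id, mask.sum()))
        ts_blocks.append(rec.timestamps()[mask])
    if not X_blocks:
        raise EmptyDesignError(
            f"no usable {subset.group.value}-complete rows for subset {subset.canonical_id}"
        )
    return DesignMatrix(
        subset=subset,
        X=np.vstack(X_blocks),
        T=np.concatenate(T_blocks),
        subject_ids=np.concatenate(id_blocks),
        timestamps=ts_blocks[0].append(ts_blocks[1:]),
    )


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class LinearCompositeModel(RegressorMixin, BaseEstimator):
    """No-intercept linear least squares for composite-temperature weights.

    Minimizes ``||y - X w||^2`` over unconstrained w (no intercept: the
    composite model is a pure weighted sum of sensor temperatures).  Solved
    by SVD; on full-rank designs the solution equals the normal-equations
    closed form ``(X'X)^{-1} X' y``.

    Parameters
    ----------
    rank_tol : float
        Relative singular-value cutoff; a design whose smallest singular
        value falls below ``rank_tol * s_max`` raises
        :class:`SingularDesignError` at fit time.

    Attributes
    ----------
    coef_ : ndarray of shape (P,)
        Fitted weights.
    rank_ : int
    singular_values_ : ndarray of shape (P,)
    n_features_in_ : int
    """

    def __init__(self, rank_tol: float = DEFAULT_RANK_TOL):
        self.rank_tol = rank_tol

    def fit(self, X, y) -> "LinearCompositeModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.size:
            raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} elements")
        if X.shape[0] == 0:
            raise EmptyDesignError("cannot fit on an empty design")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        coef, _, rank, sv = np.linalg.lstsq(X, y, rcond=self.rank_tol)
        self.n_features_in_ = X.shape[1]
        self.singular_values_ = sv
        self.rank_ = int(rank)
        if rank < X.shape[1]:
            bad = _dependent_columns(X, self.rank_tol)
            raise SingularDesignError(
                f"design is rank deficient (rank {rank} < {X.shape[1]}); "
                f"near-collinear columns: {bad}"
            )
        self.coef_ = coef
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {X.shape[1]} columns, expected {self.n_features_in_}")
        return X @ self.coef_


def _dependent_columns(X: np.ndarray, rank_tol: float) -> list[int]:
    """Indices of columns implicated in the near-null space (for error messages)."""
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    cutoff = rank_tol * (s[0] if s.size else 0.0)
    null_rows = vt[s <= cutoff] if s.size else vt
    if null_rows.size == 0:
        return []
    involvement = np.abs(null_rows).max(axis=0)
    return [int(i) for i in np.flatnonzero(involvement > 1e-6)]


# ---------------------------------------------------------------------------
# Weight vectors and wrappers
# ---------------------------------------------------------------------------

@dataclass
class WeightVector:
    """Fitted weights for one subset; excluded sites carry weight exactly 0."""

    subset: SensorSubset
    coefficients: Mapping[SiteCode, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.subset.sites) - set(self.coefficients)
        if missing:
            names = ", ".join(sorted(s.value for s in missing))
            raise ValueError(f"weights missing for included sites: {names}")

    def weight(self, site: SiteCode) -> float:
        return float(self.coefficients.get(site, 0.0))

    def as_array(self) -> np.ndarray:
        """Weights for the included sites in canonical column order."""
        return np.array([self.coefficients[s] for s in self.subset.sites])

    def full_group_array(self) -> np.ndarray:
        """Weights over the whole group's canonical order (zeros excluded)."""
        return np.array([self.weight(s) for s in GROUP_SITES[self.subset.group]])


def fit_weights(design: DesignMatrix, rank_tol: float = DEFAULT_RANK_TOL) -> WeightVector:
    """Least-squares weights for one design (wrapper over the estimator)."""
    model = LinearCompositeModel(rank_tol=rank_tol)
    try:
        model.fit(design.X, design.T)
    except SingularDesignError as exc:
        cols = design.subset.sites
        raise SingularDesignError(
            f"subset {design.subset.canonical_id}: {exc} "
            f"(columns {[c.value for c in cols]})"
        ) from None
    coeffs = dict(zip(design.subset.sites, model.coef_))
    return WeightVector(subset=design.subset, coefficients=coeffs)


def reconstruct(design: DesignMatrix, weights: WeightVector) -> np.ndarray:
    """The reconstruction T_hat = X w_hat, row-aligned with ``design.T``."""
    if weights.subset != design.subset:
        raise ValueError(
            f"weights are for subset {weights.subset.canonical_id}, "
            f"design is for {design.subset.canonical_id}"
        )
    return design.X @ weights.as_array()


def fit_all(
    cohort: CohortDataset,
    group: SiteGroup,
    rank_tol: float = DEFAULT_RANK_TOL,
    cv_aggregate: str = "pooled",
):
    """Fit every subset of ``group`` and fill in all performance factors.

    Returns a :class:`~skintemp.report.WeightTable`.  Per-subset failures
    (empty or singular designs) are recorded in ``table.failures`` with a
    reason instead of aborting the whole table.
    """
    from . import metrics
    from .report import SubsetResult, WeightTable

    rows: list[SubsetResult] = []
    failures: dict[str, str] = {}
    for subset in enumerate_subsets(group):
        try:
            design = build_design(cohort, subset)
            weights = fit_weights(design, rank_tol=rank_tol)
            that = reconstruct(design, weights)
            q1, q3 = metrics.error_quartiles(design.T, that)
            mae_day, mae_night = metrics.day_night_mae(design.T, that, design.timestamps)
            cve = metrics.loso_cve(design, rank_tol=rank_tol, aggregate=cv_aggregate)
            rows.append(SubsetResult(
                subset=subset,
                weights=weights,
                n_samples=design.n,
                mse=metrics.mse(design.T, that),
                mae=metrics.mae(design.T, that),
                cve=cve,
                q1=q1,
                q3=q3,
                mae_day=mae_day,
                mae_night=mae_night,
            ))
        except (EmptyDesignError, SingularDesignError) as exc:
            failures[subset.canonical_id] = str(exc)
    return WeightTable(group=group, rows=rows, provenance="fitted",
                       metadata=dict(cohort.provenance), failures=failures)
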