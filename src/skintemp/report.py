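"""Weight/accuracy tables, lookup for surviving sensor sets, and application
of looked-up weights to new recordings.

A :class:`WeightTable` is the machine-readable twin of the operative tables
of the nine-sensor protocol: one row per sensor subset (31 proximal, 15
distal) holding the re-tuned weights and the performance factors (MSE, MAE,
CVE, Q1, Q3, day/night MAE).  Weights are stored at full precision; rounding
to 4 decimals happens only on export.

The package also ships the published protocol tables (``provenance ==
"published"``) so that weights can be looked up without refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import SubjectRecording, TemperatureSeries
from .errors import MissingSiteError
from .sites import GROUP_SITES, SiteCode, SiteGroup, parse_site
from .subsetfit import SensorSubset, WeightVector, enumerate_subsets

_FACTOR_COLUMNS = ["mse", "mae", "cve", "q1", "q3", "mae_day", "mae_night"]
_EXPORT_DECIMALS = 4


@dataclass
class SubsetResult:
    """One subset's fitted weights plus its performance factors."""

    subset: SensorSubset
    weights: WeightVector
    n_samples: int
    mse: float
    mae: float
    cve: float
    q1: float
    q3: float
    mae_day: float | None = None
    mae_night: float | None = None

    def __post_init__(self) -> None:
        if self.mse < 0 or self.mae < 0:
            raise ValueError("mse and mae must be nonnegative")
        if self.q1 > self.q3:
            raise ValueError("q1 must not exceed q3")


@dataclass
class WeightTable:
    """All SubsetResults for one group, ordered as ``enumerate_subsets``."""

    group: SiteGroup
    rows: list[SubsetResult]
    provenance: str = "fitted"        # "fitted" | "published"
    metadata: dict = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = 2 ** len(GROUP_SITES[self.group]) - 1
        if len(self.rows) + len(self.failures) != expected:
            raise ValueError(
                f"{self.group.value} table needs {expected} rows "
                f"(got {len(self.rows)} + {len(self.failures)} failed)"
            )

    def __len__(self) -> int:
        return len(self.rows)

    def lookup(self, available: Iterable[SiteCode | str]) -> SubsetResult:
        """The row for the surviving sensors: ``available ∩ group sites``.

        The caller receives both the weights to apply and the accuracy to
        expect.  Sites outside the group are ignored; an empty intersection
        is an error.
        """
        sites = {parse_site(s) if isinstance(s, str) else s for s in available}
        included = frozenset(sites & set(GROUP_SITES[self.group]))
        if not included:
            raise ValueError(
                f"no {self.group.value} sensors among the available sites"
            )
        target = SensorSubset(self.group, included)
        for row in self.rows:
            if row.subset == target:
                return row
        raise KeyError(
            f"subset {target.canonical_id} not present in table "
            f"(failed: {self.failures.get(target.canonical_id, 'absent')})"
        )

    # ---- tabular export ------------------------------------------------

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        return results_frame(self.rows, self.group, rounded=rounded)


def results_frame(rows: list[SubsetResult], group: SiteGroup, rounded: bool = True) -> pd.DataFrame:
    """Tabulate SubsetResults (factors + one weight column per group site)."""
    site_cols = [s.value for s in GROUP_SITES[group]]
    records = []
    for row in rows:
        rec = {
            "n_sensors": len(row.subset),
            "subset_id": row.subset.canonical_id,
            "n_samples": row.n_samples,
            "mse": row.mse, "mae": row.mae, "cve": row.cve,
            "q1": row.q1, "q3": row.q3,
            "mae_day": row.mae_day, "mae_night": row.mae_night,
        }
        for site in GROUP_SITES[group]:
            rec[site.value] = row.weights.weight(site)
        records.append(rec)
    df = pd.DataFrame.from_records(
        records,
        columns=["n_sensors", "subset_id", "n_samples", *_FACTOR_COLUMNS, *site_cols],
    )
    if rounded:
        num = _FACTOR_COLUMNS + site_cols
        df[num] = df[num].round(_EXPORT_DECIMALS)
    return df


def write_table(table: WeightTable, destination) -> Path:
    """Export a table to CSV, rounded to 4 decimals."""
    destination = Path(destination)
    table.to_frame(rounded=True).to_csv(destination, index=False)
    return destination


def read_table(path, group: SiteGroup | None = None, provenance: str = "fitted") -> WeightTable:
    """Read a table CSV back into a :class:`WeightTable`.

    The group is inferred from the site columns when not given.  Values are
    the rounded export values; day/night MAE cells may be empty.
    """
    df = pd.read_csv(path)
    if group is None:
        for candidate in SiteGroup:
            if all(s.value in df.columns for s in GROUP_SITES[candidate]):
                group = candidate
                break
        else:
            raise ValueError(f"{path}: cannot infer group from columns {list(df.columns)}")
    rows = []
    for _, r in df.iterrows():
        included = frozenset(
            s for s in GROUP_SITES[group] if float(r[s.value]) != 0.0
        )
        # guard: a fitted weight could round to exactly 0; trust subset_id first
        if "subset_id" in df.columns and isinstance(r["subset_id"], str):
            included = frozenset(parse_site(tok) for tok in r["subset_id"].split("+"))
        subset = SensorSubset(group, included)
        weights = WeightVector(subset, {s: float(r[s.value]) for s in subset.sites})
        rows.append(SubsetResult(
            subset=subset,
            weights=weights,
            n_samples=int(r["n_samples"]) if "n_samples" in df.columns and not _isna(r.get("n_samples")) else 0,
            mse=float(r["mse"]), mae=float(r["mae"]), cve=float(r["cve"]),
            q1=float(r["q1"]), q3=float(r["q3"]),
            mae_day=None if _isna(r.get("mae_day")) else float(r["mae_day"]),
            mae_night=None if _isna(r.get("mae_night")) else float(r["mae_night"]),
        ))
    rows.sort(key=lambda r: (len(r.subset), r.subset.canonical_id))
    return WeightTable(group=group, rows=rows, provenance=provenance)


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x)


def load_published_table(group: SiteGroup) -> WeightTable:
    """The published nine-sensor protocol table for ``group``.

    Transcribed from the published tables of re-tuned weights and accuracy
    factors; usable for lookup without refitting.  Day/night MAE cells are
    empty (no numeric values were published) and n_samples is 0.
    """
    name = "published_prox.csv" if group is SiteGroup.PROX else "published_dist.csv"
    with resources.as_file(resources.files("skintemp.data") / name) as path:
        return read_table(path, group=group, provenance="published")


# ---------------------------------------------------------------------------
# Applying weights to recordings
# ---------------------------------------------------------------------------

def apply_weights(weights: WeightVector, recording: SubjectRecording) -> TemperatureSeries:
    """Per-instant weighted sum over the sites with nonzero weight.

    Valid exactly where all nonzero-weight sensors are valid.  Missing
    needed sites raise :class:`MissingSiteError` naming the site.
    """
    recording.assert_common_grid()
    needed = [s for s in weights.subset.sites if weights.weight(s) != 0.0]
    if not needed:  # all-zero weights: a constant-zero series on the full grid
        needed = list(weights.subset.sites)
    for site in needed:
        if site not in recording:
            raise MissingSiteError(site, "apply_weights")
    template = recording[needed[0]]
    values = np.zeros(len(template))
    mask = np.ones(len(template), dtype=bool)
    for site in needed:
        w = weights.weight(site)
        values += w * recording[site].values
        if w != 0.0:
            mask &= recording[site].valid_mask
    return TemperatureSeries(
        site=f"T_{weights.subset.group.value}_hat",
        start_time=template.start_time,
        sampling_interval_min=template.sampling_interval_min,
        values=values,
        valid_mask=mask,
    )


# ---------------------------------------------------------------------------
# Optional figures (reconstruction overlays, error histograms)
# ---------------------------------------------------------------------------

def plot_reconstruction(reference: TemperatureSeries, estimate: TemperatureSeries, path) -> None:
    """Overlay of reference composite and subset reconstruction, gaps shown
    as breaks in the line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for series, color, label in ((reference, "0.6", str(reference.site)),
                                 (estimate, "k", str(estimate.site))):
        vals = np.where(series.valid_mask, series.values, np.nan)
        ax.plot(series.timestamps, vals, color=color, lw=1.0, label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("temperature (°C)")
    ax.legend(loc="best")
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_error_histogram(edges: np.ndarray, counts: np.ndarray, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color="0.3")
    ax.set_xlabel("signed error (°C)")
    ax.set_ylabel("absolute frequency")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
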