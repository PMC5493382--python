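"""In-memory containers for sensor recordings.

A :class:`TemperatureSeries` is one sensor's uniformly sampled trace with a
per-sample validity mask (non-wear gaps and excised artifacts are invalid
samples, never interpolated).  A :class:`SubjectRecording` bundles the nine
site traces of one subject; a :class:`CohortDataset` bundles subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import MissingSiteError
from .sites import GROUP_SITES, SiteCode, SiteGroup


@dataclass
class NonWearEvent:
    """A contiguous interval during which sensors were removed (e.g. showering).

    ``start_index`` / ``n_samples`` refer to positions on the recording grid;
    ``sites`` lists the affected sensors (all nine for a shower).
    """

    start_index: int
    n_samples: int
    sites: tuple[SiteCode, ...]


@dataclass
class TemperatureSeries:
    """One sensor's time-stamped temperature trace on a uniform grid.

    Parameters
    ----------
    site : SiteCode or str
        Placement site, or a composite label such as ``"T_PROX"``.
    start_time : pd.Timestamp
        Wall-clock timestamp of the first sample.
    sampling_interval_min : float
        Constant sampling interval, minutes.
    values : ndarray of float, °C
    valid_mask : ndarray of bool
        False marks gaps (non-wear, artifacts); such samples are never used.
    """

    site: SiteCode | str
    start_time: pd.Timestamp
    sampling_interval_min: float
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape or self.values.ndim != 1:
            raise ValueError("values and valid_mask must be 1-D arrays of equal length")
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling_interval_min must be positive")
        self.start_time = pd.Timestamp(self.start_time)

    def __len__(self) -> int:
        return self.values.size

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=len(self), freq=pd.Timedelta(minutes=self.sampling_interval_min)
        )

    def copy(self) -> "TemperatureSeries":
        return replace(self, values=self.values.copy(), valid_mask=self.valid_mask.copy())


@dataclass
class SubjectRecording:
    """One subject's collection of site traces.

    After preprocessing all series share start time, sampling interval and
    length (``assert_common_grid``).
    """

    subject_id: str
    series: dict[SiteCode, TemperatureSeries]
    nonwear_events: list[NonWearEvent] = field(default_factory=list)

    def __getitem__(self, site: SiteCode) -> TemperatureSeries:
        try:
            return self.series[site]
        except KeyError:
            raise MissingSiteError(site, f"subject {self.subject_id}") from None

    def __contains__(self, site: SiteCode) -> bool:
        return site in self.series

    @property
    def sites(self) -> tuple[SiteCode, ...]:
        return tuple(self.series)

    def on_common_grid(self) -> bool:
        it = iter(self.series.values())
        first = next(it)
        return all(
            s.start_time == first.start_time
            and s.sampling_interval_min == first.sampling_interval_min
            and len(s) == len(first)
            for s in it
        )

    def assert_common_grid(self) -> None:
        if not self.on_common_grid():
            raise ValueError(f"subject {self.subject_id}: series are not on a common grid")

    def n_samples(self) -> int:
        self.assert_common_grid()
        return len(next(iter(self.series.values())))

    def timestamps(self) -> pd.DatetimeIndex:
        self.assert_common_grid()
        return next(iter(self.series.values())).timestamps

    def group_valid_mask(self, group: SiteGroup) -> np.ndarray:
        """Complete-case mask for a group: True where EVERY sensor of the
        group is valid.  The reference composite is defined exactly there."""
        self.assert_common_grid()
        mask = np.ones(self.n_samples(), dtype=bool)
        for site in GROUP_SITES[group]:
            mask &= self[site].valid_mask
        return mask

    def complete_count(self, group: SiteGroup) -> int:
        """Number of group-complete grid instants (the N that metrics use)."""
        return int(self.group_valid_mask(group).sum())

    def copy(self) -> "SubjectRecording":
        return SubjectRecording(
            subject_id=self.subject_id,
            series={k: v.copy() for k, v in self.series.items()},
            nonwear_events=list(self.nonwear_events),
        )


@dataclass
class CohortDataset:
    """A multi-subject collection of recordings plus provenance metadata."""

    recordings: list[SubjectRecording]
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.recordings]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self) -> Iterator[SubjectRecording]:
        return iter(self.recordings)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.recordings]

    def sorted_recordings(self) -> list[SubjectRecording]:
        """Recordings in ascending subject_id order (macro-signal append order)."""
        return sorted(self.recordings, key=lambda r: r.subject_id)

    def copy(self) -> "CohortDataset":
        return CohortDataset([r.copy() for r in self.recordings], dict(self.provenance))
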