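"""Reading/writing per-sensor CSV recordings and the preprocessing stage.

File format: one CSV per sensor with header ``timestamp,temperature_C``,
ISO-8601 timestamps, strictly increasing, uniform spacing.  A manifest CSV
(``subject_id,site,filepath``) maps files to subjects and sites.

Preprocessing aligns a subject's sensors onto a shared uniform grid
(nearest-sample within a clock-skew tolerance), marks physiologically
implausible samples invalid, and leaves gaps as gaps — no value is ever
interpolated or fabricated, so every retained sample equals a raw sample.
Group-complete masks (all five proximal or all four distal sensors valid)
are derived downstream; a gap in a distal sensor never discards proximal
samples.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CohortDataset, SubjectRecording, TemperatureSeries
from .errors import AlignmentError, ParseError
from .sites import ALL_SITES, SiteCode, parse_site

#: Default physiological plausibility bounds for skin temperature, °C.
DEFAULT_BOUNDS = (20.0, 42.0)
#: Default tolerance for nearest-sample grid alignment, minutes
#: (half the 3-min sampling interval of the study design).
DEFAULT_MAX_CLOCK_SKEW_MIN = 1.5

_HEADER = ["timestamp", "temperature_C"]
_TIME_TOL = pd.Timedelta(seconds=1)  # spacing jitter tolerated within one file


def read_series(path, site: SiteCode | str) -> TemperatureSeries:
    """Read one sensor CSV into a :class:`TemperatureSeries`.

    Raises :class:`ParseError` (with the 1-based line number) on a malformed
    row, a non-increasing timestamp, or non-uniform spacing.
    """
    if isinstance(site, str):
        site = parse_site(site)
    times: list[pd.Timestamp] = []
    temps: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != _HEADER:
            raise ParseError(f"{path}: expected header {','.join(_HEADER)!r}, got {header!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ParseError(f"{path}: expected 2 fields, got {len(row)}", line=lineno)
            try:
                ts = pd.Timestamp(row[0].strip())
                if ts is pd.NaT:
                    raise ValueError
            except ValueError:
                raise ParseError(f"{path}: invalid timestamp {row[0]!r}", line=lineno) from None
            try:
                temp = float(row[1])
            except ValueError:
                raise ParseError(f"{path}: invalid temperature {row[1]!r}", line=lineno) from None
            if times and ts <= times[-1]:
                raise ParseError(f"{path}: timestamps not strictly increasing", line=lineno)
            times.append(ts)
            temps.append(temp)
    if len(times) < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    diffs = pd.Series(times).diff().dropna()
    interval = diffs.iloc[0]
    if (diffs - interval).abs().max() > _TIME_TOL:
        raise ParseError(f"{path}: non-uniform sampling interval")
    return TemperatureSeries(
        site=site,
        start_time=times[0],
        sampling_interval_min=interval.total_seconds() / 60.0,
        values=np.array(temps, dtype=float),
        valid_mask=np.ones(len(temps), dtype=bool),
    )


def write_series(series: TemperatureSeries, path) -> None:
    """Write a series to CSV; invalid samples are dropped (gaps stay gaps)."""
    ts = series.timestamps
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for t, v, ok in zip(ts, series.values, series.valid_mask):
            if ok:
                writer.writerow([t.isoformat(), f"{v:.4f}"])


def read_recording(paths: dict[SiteCode | str, os.PathLike | str], subject_id: str) -> SubjectRecording:
    """Read one subject's per-site files; no resampling is performed."""
    series: dict[SiteCode, TemperatureSeries] = {}
    for site, path in paths.items():
        code = parse_site(site) if isinstance(site, str) else site
        if code in series:
            raise ParseError(f"duplicate site {code.value} for subject {subject_id}")
        series[code] = read_series(path, code)
    return SubjectRecording(subject_id=subject_id, series=series)


def write_recording(recording: SubjectRecording, out_dir) -> dict[SiteCode, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for site, series in recording.series.items():
        path = out_dir / f"{recording.subject_id}_{site.value}.csv"
        write_series(series, path)
        paths[site] = path
    return paths


def read_manifest(manifest_path) -> CohortDataset:
    """Read a ``subject_id,site,filepath`` manifest into a cohort.

    Relative file paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, dtype=str)
    required = {"subject_id", "site", "filepath"}
    if not required.issubset(df.columns):
        raise ParseError(f"{manifest_path}: manifest needs columns {sorted(required)}")
    recordings = []
    for subject_id, grp in df.groupby("subject_id", sort=True):
        paths: dict[SiteCode, str] = {}
        for _, row in grp.iterrows():
            code = parse_site(row["site"])
            if code in paths:
                raise ParseError(f"duplicate site {code.value} for subject {subject_id}")
            p = Path(row["filepath"])
            paths[code] = p if p.is_absolute() else base / p
        recordings.append(read_recording(paths, str(subject_id)))
    return CohortDataset(recordings, provenance={"kind": "files", "manifest": str(manifest_path)})


def write_cohort(cohort: CohortDataset, out_dir) -> Path:
    """Write one CSV per sensor per subject plus a manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.sorted_recordings():
        paths = write_recording(rec, out_dir)
        for site, path in paths.items():
            rows.append({"subject_id": rec.subject_id, "site": site.value,
                         "filepath": path.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _align_recording(recording: SubjectRecording, max_clock_skew_min: float) -> SubjectRecording:
    """Bring all series of a subject onto one uniform grid by nearest-sample
    alignment; samples with no sensor reading within the skew tolerance are
    invalid on the common grid."""
    if recording.on_common_grid():
        return recording

    intervals = {s.sampling_interval_min for s in recording.series.values()}
    interval = min(intervals)
    if max(intervals) - interval > 1e-9:
        raise AlignmentError(
            f"subject {recording.subject_id}: mixed sampling intervals {sorted(intervals)}"
        )
    step = pd.Timedelta(minutes=interval)
    tol = pd.Timedelta(minutes=max_clock_skew_min)

    starts = [s.start_time for s in recording.series.values()]
    ends = [s.start_time + (len(s) - 1) * step for s in recording.series.values()]
    grid_start, grid_end = max(starts), min(ends)
    if grid_end < grid_start:
        raise AlignmentError(
            f"subject {recording.subject_id}: sensor time ranges do not overlap"
        )
    n_grid = int((grid_end - grid_start) / step) + 1

    aligned: dict[SiteCode, TemperatureSeries] = {}
    for site, series in recording.series.items():
        offset = series.start_time - grid_start
        k = round(offset / step)
        skew = abs(offset - k * step)
        if skew > tol:
            raise AlignmentError(
                f"subject {recording.subject_id}, site {site.value}: clock skew "
                f"{skew.total_seconds() / 60:.2f} min exceeds tolerance {max_clock_skew_min} min"
            )
        # sample j of the grid maps to source index j - k
        values = np.full(n_grid, np.nan)
        mask = np.zeros(n_grid, dtype=bool)
        j = np.arange(n_grid)
        src = j - k
        ok = (src >= 0) & (src < len(series))
        values[ok] = series.values[src[ok]]
        mask[ok] = series.valid_mask[src[ok]]
        aligned[site] = TemperatureSeries(
            site=site, start_time=grid_start, sampling_interval_min=interval,
            values=np.where(mask, values, 0.0), valid_mask=mask,
        )
    return SubjectRecording(recording.subject_id, aligned, list(recording.nonwear_events))


def preprocess(
    cohort: CohortDataset,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    max_clock_skew_min: float = DEFAULT_MAX_CLOCK_SKEW_MIN,
) -> CohortDataset:
    """Grid alignment + plausibility filtering.

    Returns a new cohort; the input is unmodified.  Idempotent.  Samples
    outside ``bounds`` are marked invalid; whether a grid instant survives
    for a group is decided downstream by the complete-case rule
    (:meth:`SubjectRecording.group_valid_mask`).
    """
    low, high = bounds
    if not low < high:
        raise ValueError(f"plausibility bounds must satisfy low < high, got {bounds}")
    out = []
    for rec in cohort.recordings:
        rec = _align_recording(rec.copy(), max_clock_skew_min)
        for series in rec.series.values():
            implausible = (series.values < low) | (series.values > high)
            series.valid_mask &= ~implausible
        out.append(rec)
    provenance = dict(cohort.provenance)
    provenance["preprocessing"] = {
        "bounds": [low, high], "max_clock_skew_min": max_clock_skew_min,
    }
    return CohortDataset(out, provenance)
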