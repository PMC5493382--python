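"""Synthetic multi-subject, multi-site skin-temperature cohorts.

Each site follows a single-harmonic cosinor (mesor + amplitude · cos of the
24-h phase) plus three additive Gaussian noise components: a subject-level
offset shared by all nine sites, a pair-level component shared by left/right
homologous sites (inducing the homologous correlation), and an independent
site-level component.  Values are quantized to the logger resolution and
non-wear events carve contiguous gaps across all sensors simultaneously.

Every subject draws from an independent substream of the master seed
(``SeedSequence(seed, spawn_key=(subject_index,))``), so a cohort is
reproducible regardless of generation order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SyntheticConfig
from .containers import CohortDataset, NonWearEvent, SubjectRecording, TemperatureSeries
from .sites import ALL_SITES, HOMOLOGOUS_PAIRS, SiteCode

DAY_START_HOUR = 7.0
DAY_END_HOUR = 19.0


def _wallclock_hours(config: SyntheticConfig) -> np.ndarray:
    """Wall-clock hour-of-day of each grid sample."""
    t = config.start_hour + np.arange(config.n_samples) * config.sampling_interval_min / 60.0
    return t % 24.0


def quantize(values: np.ndarray, step: float) -> np.ndarray:
    """Round to the nearest multiple of ``step`` (identity for step = 0)."""
    if step <= 0:
        return values
    return np.round(values / step) * step


def _draw_nonwear_events(rng: np.random.Generator, config: SyntheticConfig) -> list[NonWearEvent]:
    n_samples = config.n_samples
    event_len = int(round(config.nonwear_duration_min / config.sampling_interval_min))
    if config.nonwear_rate_per_day <= 0 or event_len <= 0:
        return []
    expected = config.nonwear_rate_per_day * config.duration_h / 24.0
    n_events = int(rng.poisson(expected))
    events = []
    for _ in range(n_events):
        start = int(rng.integers(0, max(1, n_samples - event_len + 1)))
        events.append(NonWearEvent(start_index=start, n_samples=event_len, sites=ALL_SITES))
    return events


def apply_nonwear(recording: SubjectRecording, events: list[NonWearEvent]) -> SubjectRecording:
    """Mark the samples covered by each event invalid (in place); returns the
    recording for chaining."""
    for ev in events:
        stop = ev.start_index + ev.n_samples
        for site in ev.sites:
            recording.series[site].valid_mask[ev.start_index:stop] = False
    recording.nonwear_events.extend(events)
    return recording


def generate_subject(config: SyntheticConfig, subject_index: int) -> SubjectRecording:
    """Generate one subject's nine-site recording.

    Parameters
    ----------
    config : SyntheticConfig
    subject_index : int
        0-based index into the cohort; selects the RNG substream.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range [0, {config.n_subjects})")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(subject_index,)))
    n = config.n_samples
    hours = _wallclock_hours(config)
    day_mask = (hours >= DAY_START_HOUR) & (hours < DAY_END_HOUR)
    noise_scale = np.where(day_mask, config.daytime_noise_multiplier, 1.0)

    # Fixed draw order: subject offset, pair streams, per-site streams, events.
    subject_offset = rng.normal(0.0, config.subject_offset_sd)
    pair_noise = {label: rng.standard_normal(n) for label in HOMOLOGOUS_PAIRS}
    pair_of_site = {
        site: label for label, pair in HOMOLOGOUS_PAIRS.items() for site in pair
    }
    rho = config.homologous_correlation

    start_time = pd.Timestamp("2000-01-01") + pd.Timedelta(hours=config.start_hour)
    series: dict[SiteCode, TemperatureSeries] = {}
    for site in ALL_SITES:
        own = rng.standard_normal(n)
        if site in pair_of_site:
            e = np.sqrt(rho) * pair_noise[pair_of_site[site]] + np.sqrt(1.0 - rho) * own
        else:
            e = own
        values = (
            config.mesor[site]
            + subject_offset
            + config.amplitude[site] * np.cos(2.0 * np.pi * (hours - config.acrophase_h[site]) / 24.0)
            + config.site_noise_sd * noise_scale * e
        )
        series[site] = TemperatureSeries(
            site=site,
            start_time=start_time,
            sampling_interval_min=config.sampling_interval_min,
            values=quantize(values, config.quantization_step),
            valid_mask=np.ones(n, dtype=bool),
        )

    recording = SubjectRecording(subject_id=f"S{subject_index + 1:02d}", series=series)
    apply_nonwear(recording, _draw_nonwear_events(rng, config))
    return recording


def generate_cohort(config: SyntheticConfig) -> CohortDataset:
    """Generate the full cohort; subject ``i`` is identical to
    ``generate_subject(config, i)``."""
    recordings = [generate_subject(config, i) for i in range(config.n_subjects)]
    return CohortDataset(recordings, provenance={"kind": "synthetic", "config": config.to_dict()})
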