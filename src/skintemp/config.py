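"""Configuration of the synthetic cohort generator.

Defaults mirror the nine-sensor study design (13 subjects, 24 h starting at
midday, 3-min sampling, 0.0625 °C logger resolution).  The per-site cosinor
parameters are physiologically plausible choices — distal sites carry the
larger circadian amplitude and lower mesor, proximal sites are warmer and
flatter — since no public dataset pins them down; all are exposed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigError
from .sites import ALL_SITES, SiteCode, parse_site

# Per-site single-harmonic cosinor defaults: mesor (°C), amplitude (°C),
# acrophase (wall-clock hour of the daily peak).  Skin temperature peaks at
# night; distal sites swing hardest (vasodilation of hands/feet).
_DEFAULT_MESOR = {
    SiteCode.A: 35.3, SiteCode.LIA: 35.0, SiteCode.RIA: 35.0,
    SiteCode.LMT: 34.3, SiteCode.RMT: 34.3,
    SiteCode.LH: 31.8, SiteCode.RH: 31.8,
    SiteCode.LF: 30.5, SiteCode.RF: 30.5,
}
_DEFAULT_AMPLITUDE = {
    SiteCode.A: 0.5, SiteCode.LIA: 0.4, SiteCode.RIA: 0.4,
    SiteCode.LMT: 0.7, SiteCode.RMT: 0.7,
    SiteCode.LH: 1.8, SiteCode.RH: 1.8,
    SiteCode.LF: 2.3, SiteCode.RF: 2.3,
}
_DEFAULT_ACROPHASE_H = {
    SiteCode.A: 3.0, SiteCode.LIA: 4.0, SiteCode.RIA: 4.0,
    SiteCode.LMT: 5.0, SiteCode.RMT: 5.0,
    SiteCode.LH: 3.0, SiteCode.RH: 3.0,
    SiteCode.LF: 4.5, SiteCode.RF: 4.5,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic multi-site skin-temperature cohort.

    Attributes
    ----------
    n_subjects : int
        Cohort size (default 13).
    duration_h : float
        Recording duration in hours (default 24).
    sampling_interval_min : float
        Sampling interval in minutes (default 3).
    start_hour : float
        Wall-clock hour of the first sample (default 12, midday-to-midday).
    mesor, amplitude, acrophase_h : dict[SiteCode, float]
        Per-site cosinor parameters (°C, °C, hour of daily peak).
    subject_offset_sd : float
        SD of the subject-level temperature offset shared by all sites, °C.
    site_noise_sd : float
        SD of per-sample sensor/physiological noise at each site, °C.
    homologous_correlation : float in [0, 1]
        Correlation of the noise between left/right homologous sites,
        induced by a shared pair-level noise component.
    daytime_noise_multiplier : float
        Factor applied to site noise during day hours [07:00, 19:00);
        1.0 disables it.  Models activity-driven daytime variability.
    nonwear_rate_per_day : float
        Expected number of non-wear events (e.g. showers) per day; each
        event removes all sensors simultaneously.
    nonwear_duration_min : float
        Duration of each non-wear event, minutes.
    quantization_step : float
        Logger resolution, °C (default 0.0625); 0 disables quantization.
    seed : int
        Master seed; each subject uses an independent substream.
    """

    n_subjects: int = 13
    duration_h: float = 24.0
    sampling_interval_min: float = 3.0
    start_hour: float = 12.0
    mesor: dict[SiteCode, float] = field(default_factory=lambda: dict(_DEFAULT_MESOR))
    amplitude: dict[SiteCode, float] = field(default_factory=lambda: dict(_DEFAULT_AMPLITUDE))
    acrophase_h: dict[SiteCode, float] = field(default_factory=lambda: dict(_DEFAULT_ACROPHASE_H))
    subject_offset_sd: float = 0.5
    site_noise_sd: float = 0.25
    homologous_correlation: float = 0.85
    daytime_noise_multiplier: float = 1.0
    nonwear_rate_per_day: float = 1.0
    nonwear_duration_min: float = 30.0
    quantization_step: float = 0.0625
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (isinstance(self.n_subjects, int) and self.n_subjects >= 1):
            raise ConfigError("n_subjects must be a positive integer")
        if self.duration_h <= 0:
            raise ConfigError("duration_h must be > 0")
        if self.sampling_interval_min <= 0:
            raise ConfigError("sampling_interval_min must be > 0")
        if not 0 <= self.start_hour < 24:
            raise ConfigError("start_hour must lie in [0, 24)")
        if not 0.0 <= self.homologous_correlation <= 1.0:
            raise ConfigError("homologous_correlation must lie in [0, 1]")
        if self.quantization_step < 0:
            raise ConfigError("quantization_step must be >= 0")
        if self.subject_offset_sd < 0:
            raise ConfigError("subject_offset_sd must be >= 0")
        if self.site_noise_sd < 0:
            raise ConfigError("site_noise_sd must be >= 0")
        if self.daytime_noise_multiplier < 0:
            raise ConfigError("daytime_noise_multiplier must be >= 0")
        if self.nonwear_rate_per_day < 0:
            raise ConfigError("nonwear_rate_per_day must be >= 0")
        if self.nonwear_duration_min < 0:
            raise ConfigError("nonwear_duration_min must be >= 0")
        for name, table in (("mesor", self.mesor), ("amplitude", self.amplitude),
                            ("acrophase_h", self.acrophase_h)):
            missing = [s.value for s in ALL_SITES if s not in table]
            if missing:
                raise ConfigError(f"{name} lacks entries for sites: {', '.join(missing)}")
        if any(a < 0 for a in self.amplitude.values()):
            raise ConfigError("amplitude values must be >= 0")

    @property
    def n_samples(self) -> int:
        """Samples per series (duration / sampling interval, floored)."""
        return int(round(self.duration_h * 60.0 / self.sampling_interval_min))

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("mesor", "amplitude", "acrophase_h"):
            d[key] = {site.value: float(v) for site, v in d[key].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("mesor", "amplitude", "acrophase_h"):
            if key in d:
                d[key] = {parse_site(k): float(v) for k, v in d[key].items()}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {', '.join(sorted(unknown))}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def clean_config(**overrides) -> SyntheticConfig:
    """A noise-free, gap-free configuration (useful for exact tests)."""
    defaults = dict(
        subject_offset_sd=0.0,
        site_noise_sd=0.0,
        nonwear_rate_per_day=0.0,
        quantization_step=0.0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)
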