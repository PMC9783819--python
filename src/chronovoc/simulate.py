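"""Synthetic chronogram generator for the three-condition monitoring study.

The generator emulates hourly direct-MS monitoring of one target ion over
eight days with 3 biological x 3 technical replicates, under four growth
conditions:

``medium`` / ``plant``
    no emission: the chronogram is an instrument baseline plus mildly
    autocorrelated Gaussian noise (the plant does not biosynthesise the
    monitored volatile, so its trace is background only).
``fungus``
    constitutive low-level emission by the fungal colony: a smooth
    seasonal envelope (emission days 2-6) modulated by a night-elevated
    circadian factor peaking at 20:00, on top of which heavy-tailed
    Poisson-gamma release bursts ride.  The default parameters are
    calibrated so the biological-mean chronogram reproduces the descriptor
    values observed for the fungus grown alone (seed-averaged skewness
    ~3.5, excess kurtosis ~11.7, Poincare SD1/SD2 ~0.59).
``interaction``
    plant-fungus co-culture: same generative form, higher amplitude
    (total AUC ~5x the fungus alone), longer emission window (days 3-8,
    maximum on day 5), proportionally smaller and more frequent bursts --
    yielding the lower skewness/kurtosis (~2.4 / ~6.0), higher lag-1
    autocorrelation and SD1/SD2 ~0.52 observed during the interaction.

Generative model, per biological replicate b:

    s_b(t)   = amplitude_scale * w(t) * c(t) * (1 + B_b(t))
    x_br(t)  = max(0, s_b(t) + baseline + n_br(t))

where w is a smooth raised-sine emission window rising from
``emission_onset_day`` to ``emission_peak_day`` and falling to
``emission_offset_day``; c is the circadian factor (cosine peaking at
``circadian_peak_hour`` plus an additive lift during the dark phase of the
16:8 photoperiod); B_b is a shot-noise process (Poisson arrivals,
gamma-distributed amplitudes, exponential decay); and n_br is stationary
AR(1) Gaussian noise, drawn independently per technical replicate r.
Technical replicates share the biological replicate's noiseless signal and
differ only in noise draws.  Intensities are clipped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .io import Chronogram, ReplicateSet, aggregate_replicates


class Condition(str, Enum):
    MEDIUM = "medium"
    PLANT = "plant"
    FUNGUS = "fungus"
    INTERACTION = "interaction"


#: conditions whose chronograms contain an emission term
EMITTING = frozenset({Condition.FUNGUS, Condition.INTERACTION})


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the three-condition chronogram generator.

    Time-like emission parameters are in days since inoculation, where day d
    covers hours [(d-1)*24, d*24): ``emission_onset_day``/``offset_day`` are
    the first and last emitting days and ``emission_peak_day`` the day on
    which the noiseless envelope culminates.  Clock-hour parameters refer to
    wall-clock time; the simulation clock starts at
    ``inoculation_clock_hour``.  Intensities are dimensionless relative
    units.  Identical (config, seed) pairs yield bit-identical output.
    """

    condition: Condition
    duration_days: int = 8
    sampling_interval_h: float = 1.0
    n_biological: int = 3
    n_technical: int = 3
    n_microscans: int = 10
    baseline: float = 0.05
    noise_sd: float = 0.01
    ar1_coeff: float = 0.25
    burst_rate: float = 0.0          # expected bursts per hour
    burst_scale: float = 0.0         # mean burst amplitude (relative to constitutive level 1)
    burst_shape: float = 1.0         # gamma shape of burst amplitudes
    burst_decay_h: float = 1.0       # exponential decay constant of each burst
    circadian_amplitude: float = 0.0
    circadian_peak_hour: float = 20.0
    lights_on_hour: float = 4.0      # 16:8 photoperiod: light 04:00-20:00
    lights_off_hour: float = 20.0
    inoculation_clock_hour: float = 8.0
    emission_onset_day: float = 0.0
    emission_offset_day: float = 0.0
    emission_peak_day: float = 0.0
    amplitude_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not math.isfinite(v):
                raise ConfigurationError(f"parameter {f.name} must be finite, got {v}")
        if self.duration_days < 1 or self.sampling_interval_h <= 0:
            raise ConfigurationError("duration_days >= 1 and sampling_interval_h > 0 required")
        if min(self.n_biological, self.n_technical, self.n_microscans) < 1:
            raise ConfigurationError("replicate and micro-scan counts must be >= 1")
        for name in ("baseline", "noise_sd", "burst_rate", "burst_scale",
                     "circadian_amplitude", "amplitude_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not -1.0 < self.ar1_coeff < 1.0:
            raise ConfigurationError("ar1_coeff must lie in (-1, 1)")
        if self.burst_shape <= 0 or self.burst_decay_h <= 0:
            raise ConfigurationError("burst_shape and burst_decay_h must be > 0")
        for name in ("circadian_peak_hour", "lights_on_hour", "lights_off_hour",
                     "inoculation_clock_hour"):
            if not 0.0 <= getattr(self, name) < 24.0:
                raise ConfigurationError(f"{name} must be a clock hour in [0, 24)")
        if self.condition in EMITTING:
            if not (0 < self.emission_onset_day
                    <= self.emission_peak_day
                    <= self.emission_offset_day
                    <= self.duration_days):
                raise ConfigurationError(
                    "emitting conditions require 0 < onset <= peak <= offset <= duration (days)"
                )
            if self.emission_onset_day >= self.emission_offset_day:
                raise ConfigurationError("emission_onset_day must be < emission_offset_day")

    @property
    def n_points(self) -> int:
        return int(round(self.duration_days * 24.0 / self.sampling_interval_h))

    def times_h(self) -> np.ndarray:
        return np.arange(self.n_points) * self.sampling_interval_h

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["condition"] = self.condition.value
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation, for parameter-recovery tests.

    ``per_replicate_noiseless_signal`` maps each biological replicate id to
    its noiseless emission series s_b(t) (zero everywhere for non-emitting
    conditions and outside the emission window); ``burst_times`` maps each
    biological replicate id to its burst arrival times in hours.
    """

    config: SimulationConfig
    times_h: np.ndarray
    per_replicate_noiseless_signal: dict[int, np.ndarray]
    burst_times: dict[int, np.ndarray]


def _is_dark(clock_h: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    on, off = cfg.lights_on_hour, cfg.lights_off_hour
    h = np.asarray(clock_h) % 24.0
    if on < off:  # light phase does not wrap midnight
        return (h < on) | (h >= off)
    return (h >= off) & (h < on)


DARK_LIFT_DECAY_H = 2.0  # e-folding of the night-onset production surge
DARK_LIFT_AMPLITUDE = 0.75  # surge height at lights-off, relative to the amplitude


def circadian_factor(times_h: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Circadian modulation: cosine peaking at ``circadian_peak_hour`` plus an
    additive dark-phase lift (largest at lights-off, decaying through the
    night), so production surges when the night begins and the factor
    culminates exactly at the peak hour."""
    clock = (cfg.inoculation_clock_hour + np.asarray(times_h, dtype=float)) % 24.0
    cos_part = 0.5 * (1.0 + np.cos(2.0 * np.pi * (clock - cfg.circadian_peak_hour) / 24.0))
    dark = _is_dark(clock, cfg)
    since_off = (clock - cfg.lights_off_hour) % 24.0
    lift = np.where(dark, DARK_LIFT_AMPLITUDE * np.exp(-since_off / DARK_LIFT_DECAY_H), 0.0)
    return 1.0 + cfg.circadian_amplitude * (cos_part + lift)


FALL_EXPONENT = 2  # cosine-squared decline mirrors the raised-sine onset


def emission_window(times_h: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Smooth raised-sine emission window: 0 outside the emitting days,
    rising to 1 in the middle of ``emission_peak_day`` and declining more
    sharply afterwards, so the peak day dominates the daily totals."""
    t = np.asarray(times_h, dtype=float)
    if cfg.condition not in EMITTING:
        return np.zeros_like(t)
    t_on = (cfg.emission_onset_day - 1.0) * 24.0
    t_peak = (cfg.emission_peak_day - 0.5) * 24.0
    t_off = cfg.emission_offset_day * 24.0
    w = np.zeros_like(t)
    rise = (t >= t_on) & (t <= t_peak)
    if t_peak > t_on:
        w[rise] = np.sin(0.5 * np.pi * (t[rise] - t_on) / (t_peak - t_on)) ** 2
    fall = (t > t_peak) & (t <= t_off)
    if t_off > t_peak:
        w[fall] = np.cos(0.5 * np.pi * (t[fall] - t_peak) / (t_off - t_peak)) ** FALL_EXPONENT
    return w


def emission_envelope(times_h: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Deterministic noiseless factor: window x circadian (no bursts, unscaled)."""
    return emission_window(times_h, cfg) * circadian_factor(times_h, cfg)


def _burst_process(
    times_h: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Shot noise: Poisson arrivals, gamma amplitudes, exponential decay."""
    T = float(times_h[-1]) if times_h.size else 0.0
    if cfg.burst_rate <= 0 or cfg.burst_scale <= 0 or cfg.condition not in EMITTING:
        # consume the same number of stream draws regardless, for clarity of
        # the determinism contract this branch simply returns zeros
        return np.zeros_like(times_h), np.empty(0)
    n_bursts = rng.poisson(cfg.burst_rate * T)
    t_bursts = np.sort(rng.uniform(0.0, T, size=n_bursts))
    amps = rng.gamma(cfg.burst_shape, cfg.burst_scale / cfg.burst_shape, size=n_bursts)
    b = np.zeros_like(times_h)
    for tb, a in zip(t_bursts, amps):
        m = times_h >= tb
        b[m] += a * np.exp(-(times_h[m] - tb) / cfg.burst_decay_h)
    return b, t_bursts


def _ar1_noise(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal SD ``noise_sd``."""
    e = rng.standard_normal(n)
    phi, sd = cfg.ar1_coeff, cfg.noise_sd
    x = np.empty(n)
    x[0] = sd * e[0]
    innov = sd * math.sqrt(1.0 - phi * phi)
    for t in range(1, n):  # n ~ 200: a loop is fine and unambiguous
        x[t] = phi * x[t - 1] + innov * e[t]
    return x


def simulate_replicate_set(cfg: SimulationConfig) -> tuple[ReplicateSet, SyntheticTruth]:
    """Generate the replicate hierarchy for one condition.

    Returns the aggregated :class:`ReplicateSet` (mean/SD filled) and the
    :class:`SyntheticTruth` ground truth.  Random streams are split per
    biological replicate (one child stream for the emission bursts, one per
    technical replicate for the noise) so that changing ``n_technical`` does
    not perturb the biological draws.
    """
    times = cfg.times_h()
    env = emission_envelope(times, cfg)
    root = np.random.SeedSequence(cfg.seed)
    chrons: dict[tuple[int, int], Chronogram] = {}
    signals: dict[int, np.ndarray] = {}
    burst_times: dict[int, np.ndarray] = {}
    for b, bio_seq in enumerate(root.spawn(cfg.n_biological), start=1):
        children = bio_seq.spawn(cfg.n_technical + 1)
        burst, t_bursts = _burst_process(times, cfg, np.random.default_rng(children[0]))
        noiseless = cfg.amplitude_scale * env * (1.0 + burst)
        signals[b] = noiseless
        burst_times[b] = t_bursts
        for r in range(1, cfg.n_technical + 1):
            noise = _ar1_noise(times.size, cfg, np.random.default_rng(children[r]))
            y = np.maximum(noiseless + cfg.baseline + noise, 0.0)
            chrons[(b, r)] = Chronogram(
                times, y, condition=cfg.condition.value, provenance="raw"
            )
    rset = aggregate_replicates(
        ReplicateSet(chronograms=chrons, condition=cfg.condition.value),
        sampling_interval_h=cfg.sampling_interval_h,
    )
    truth = SyntheticTruth(
        config=cfg,
        times_h=times,
        per_replicate_noiseless_signal=signals,
        burst_times=burst_times,
    )
    return rset, truth


# ---------------------------------------------------------------------------
# calibrated per-condition defaults
#
# The background (medium/plant) AR(1) coefficient 0.25 reproduces the
# Poincare ratio ~0.78 reported for the plant-alone trace via the identity
# (SD1/SD2)^2 = (1 - rho1)/(1 + rho1).  The fungus and interaction entries
# were calibrated by seed-averaged simulation (50 seeds) against the
# descriptor values observed in the monitoring study: fungus skewness ~3.51,
# excess kurtosis ~11.66, SD1/SD2 ~0.588; interaction skewness ~2.44, excess
# kurtosis ~6.02, SD1/SD2 ~0.522, total AUC ~5x the fungus alone, emission
# days 3-8 with the maximum on day 5.
# ---------------------------------------------------------------------------

_CONDITION_DEFAULTS: dict[Condition, dict] = {
    Condition.MEDIUM: dict(),
    Condition.PLANT: dict(),
    Condition.FUNGUS: dict(
        noise_sd=1.4,
        burst_rate=0.5,
        burst_scale=9.0,
        burst_shape=3.0,
        burst_decay_h=0.3,
        circadian_amplitude=0.6,
        emission_onset_day=2.0,
        emission_peak_day=4.0,
        emission_offset_day=6.0,
        amplitude_scale=1.0,
    ),
    Condition.INTERACTION: dict(
        burst_rate=0.75,
        burst_scale=4.6,
        burst_shape=2.0,
        burst_decay_h=0.25,
        circadian_amplitude=0.6,
        emission_onset_day=3.0,
        emission_peak_day=4.75,
        emission_offset_day=8.0,
        amplitude_scale=7.4,
    ),
}


def default_config(condition: Condition | str, seed: int = 0, **overrides) -> SimulationConfig:
    """The calibrated default configuration for one condition.

    ``overrides`` replace individual fields (validated as usual).  Unknown
    conditions raise :class:`ConfigurationError`.
    """
    try:
        condition = Condition(condition)
    except ValueError as exc:
        raise ConfigurationError(
            f"unknown condition {condition!r}; expected one of "
            f"{[c.value for c in Condition]}"
        ) from exc
    params = dict(_CONDITION_DEFAULTS[condition])
    params.update(overrides)
    return SimulationConfig(condition=condition, seed=seed, **params)


def write_config_sidecar(cfg: SimulationConfig, path: str | Path) -> None:
    """Record all parameters and the seed next to a written chronogram table."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def read_config_sidecar(path: str | Path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "condition" not in data:
        raise ConfigurationError(f"sidecar {path} is not a simulation config")
    return SimulationConfig(**data)
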