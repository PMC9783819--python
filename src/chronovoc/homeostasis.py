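"""Interpretive layer: detection, circadian analysis and variable classification.

In the homeostasis framework borrowed from the heart-rate-variability
literature, a monitored quantity can behave as

* **background** -- not detected above the white-noise level of the
  instrument (the plant grown alone emits none of the target volatile);
* **physiological** -- emitted with high variability: strongly non-Gaussian
  (high skewness and excess kurtosis), bursty, only weakly autocorrelated
  beyond the background (the fungal colony alone);
* **stabilized** -- emission persists but its statistics are pulled towards
  Gaussian while the autocorrelation rises, indicating regulation by the
  partner organism (the plant-fungus co-culture).

The classification rule table is deliberately explicit and fully
configurable; the label is a pure function of (descriptors, thresholds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .descriptors import DescriptorSet, auc
from .errors import (
    DegenerateBackgroundError,
    IncompleteEvidenceError,
    InsufficientSpanError,
    UndefinedRatioError,
)
from .io import Chronogram


class VariableClass(str, Enum):
    BACKGROUND = "background"
    PHYSIOLOGICAL = "physiological"
    STABILIZED = "stabilized"


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds (all mandatory, no hidden defaults at call
    sites: the pipeline always records the full record it used).

    ``detection_k``: a signal is detected when its mean exceeds the
    background mean by ``k`` background SDs.  ``skewness_min`` /
    ``kurtosis_min``: lower bounds for "high" non-Gaussianity.
    ``reduction_fraction``: relative drop in skewness or kurtosis versus a
    physiological reference that counts as stabilization.  ``acf_margin``:
    how far above the background's lag-1 autocorrelation a physiological
    signal may sit.
    """

    detection_k: float = 3.0
    skewness_min: float = 1.0
    kurtosis_min: float = 3.0
    reduction_fraction: float = 0.25
    acf_margin: float = 0.35


@dataclass
class CircadianSummary:
    """Hour-of-day emission profile and day/night contrast."""

    hour_of_day_profile: np.ndarray  # 24 mean intensities, index = clock hour
    peak_hour: int
    night_day_ratio: float


@dataclass
class ClassificationResult:
    label: VariableClass
    #: criterion name -> (value, threshold, passed)
    evidence: dict[str, tuple[float, float, bool]]
    thresholds_used: Thresholds


def detect_above_noise(
    signal: Chronogram, background: Chronogram, k: float = 3.0
) -> bool:
    """True iff the signal's mean intensity exceeds mean + k*SD of the
    background values (sample SD, denominator n-1)."""
    bg = background.intensities
    sd = float(np.std(bg, ddof=1)) if bg.size > 1 else 0.0
    if sd == 0.0:
        raise DegenerateBackgroundError("background chronogram has zero variance")
    return float(np.mean(signal.intensities)) > float(np.mean(bg)) + k * sd


def circadian_summary(
    c: Chronogram,
    lights_on_hour: float = 4.0,
    lights_off_hour: float = 20.0,
    inoculation_clock_hour: float = 8.0,
) -> CircadianSummary:
    """Average the chronogram by clock hour and quantify the day/night contrast.

    Each sample is mapped to the clock hour (floor of inoculation clock time
    plus elapsed hours, mod 24).  ``night_day_ratio`` is the mean over the
    dark-phase hours divided by the mean over the light-phase hours of the
    configured photoperiod.  Requires at least 48 h of span so every clock
    hour is sampled at least twice under hourly monitoring.
    """
    if c.span_h < 48.0:
        raise InsufficientSpanError(
            f"circadian analysis needs >= 48 h of data, got {c.span_h:.1f} h"
        )
    clock = np.floor((inoculation_clock_hour + c.times) % 24.0).astype(int) % 24
    profile = np.full(24, np.nan)
    for h in range(24):
        sel = clock == h
        if sel.any():
            profile[h] = float(np.mean(c.intensities[sel]))
    peak_hour = int(np.nanargmax(profile))  # ties break to the earliest hour
    hours = np.arange(24)
    if lights_on_hour < lights_off_hour:
        dark = (hours < lights_on_hour) | (hours >= lights_off_hour)
    else:
        dark = (hours >= lights_off_hour) & (hours < lights_on_hour)
    night = float(np.nanmean(profile[dark]))
    day = float(np.nanmean(profile[~dark]))
    return CircadianSummary(
        hour_of_day_profile=profile,
        peak_hour=peak_hour,
        night_day_ratio=night / day,
    )


def production_fold_change(a: Chronogram, b: Chronogram) -> float:
    """AUC(a) / AUC(b) on (biological-mean) chronograms: total-production
    fold change of a over b."""
    denom = auc(b)
    if denom <= 0:
        raise UndefinedRatioError(f"reference AUC must be > 0, got {denom}")
    return auc(a) / denom


def _background_sd(background: DescriptorSet) -> float:
    # Recover the pointwise SD of the background values from the Poincare
    # descriptors: SD1^2 + SD2^2 = Var(x[1:]) + Var(x[:-1]) ~ 2 Var(x).
    return math.sqrt((background.sd1**2 + background.sd2**2) / 2.0)


def classify_variable(
    d: DescriptorSet,
    background: DescriptorSet,
    thresholds: Thresholds,
    reference: DescriptorSet | None = None,
) -> ClassificationResult:
    """Label one condition's descriptors as background / physiological / stabilized.

    Rule table (evaluated top-down; every comparison is recorded as evidence):

    1. not detected above the background noise level -> ``background``;
    2. (requires ``reference``, a physiological series such as the organism
       grown alone) skewness or excess kurtosis reduced by at least
       ``reduction_fraction`` relative to the reference -- or both absolute
       moments below the "high" bounds -- while the lag-1 autocorrelation
       exceeds the reference's -> ``stabilized``;
    3. skewness and excess kurtosis above their bounds and lag-1
       autocorrelation within ``acf_margin`` of the background's ->
       ``physiological``;
    4. otherwise the moments alone decide: high -> ``physiological``,
       reduced/normal-like -> ``stabilized``.
    """
    required = {
        "mean_intensity": d.mean_intensity,
        "skewness": d.skewness,
        "excess_kurtosis": d.excess_kurtosis,
        "acf1": d.acf1,
        "background.sd1": background.sd1,
        "background.sd2": background.sd2,
        "background.acf1": background.acf1,
    }
    missing = [k for k, v in required.items() if v is None or not math.isfinite(v)]
    if missing:
        raise IncompleteEvidenceError(f"missing required descriptors: {missing}")
    bg_sd = _background_sd(background)
    if bg_sd == 0.0:
        raise DegenerateBackgroundError("background descriptors imply zero variance")

    t = thresholds
    evidence: dict[str, tuple[float, float, bool]] = {}

    det_thr = background.mean_intensity + t.detection_k * bg_sd
    detected = d.mean_intensity > det_thr
    evidence["detected_above_noise"] = (d.mean_intensity, det_thr, detected)

    skew_high = d.skewness > t.skewness_min
    kurt_high = d.excess_kurtosis > t.kurtosis_min
    evidence["skewness_high"] = (d.skewness, t.skewness_min, skew_high)
    evidence["kurtosis_high"] = (d.excess_kurtosis, t.kurtosis_min, kurt_high)
    acf_cap = background.acf1 + t.acf_margin
    acf_near_bg = d.acf1 <= acf_cap
    evidence["acf1_near_background"] = (d.acf1, acf_cap, acf_near_bg)

    stabilized = False
    if reference is not None:
        if not (math.isfinite(reference.skewness) and math.isfinite(reference.acf1)):
            raise IncompleteEvidenceError("reference descriptors incomplete")
        skew_red = 1.0 - d.skewness / reference.skewness if reference.skewness else 0.0
        kurt_red = (
            1.0 - d.excess_kurtosis / reference.excess_kurtosis
            if reference.excess_kurtosis
            else 0.0
        )
        reduced = (
            skew_red >= t.reduction_fraction
            or kurt_red >= t.reduction_fraction
            or (not skew_high and not kurt_high)
        )
        acf_up = d.acf1 > reference.acf1
        evidence["skewness_reduced_vs_reference"] = (skew_red, t.reduction_fraction,
                                                     skew_red >= t.reduction_fraction)
        evidence["kurtosis_reduced_vs_reference"] = (kurt_red, t.reduction_fraction,
                                                     kurt_red >= t.reduction_fraction)
        evidence["acf1_above_reference"] = (d.acf1, reference.acf1, acf_up)
        stabilized = reduced and acf_up

    if not detected:
        label = VariableClass.BACKGROUND
    elif stabilized:
        label = VariableClass.STABILIZED
    elif skew_high and kurt_high and acf_near_bg:
        label = VariableClass.PHYSIOLOGICAL
    elif skew_high and kurt_high:
        label = VariableClass.PHYSIOLOGICAL  # moments decide the fallback
    else:
        label = VariableClass.STABILIZED
    return ClassificationResult(label=label, evidence=evidence, thresholds_used=t)
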