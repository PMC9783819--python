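"""End-to-end orchestration of the three-condition monitoring study.

``run_study`` drives simulate-or-ingest -> aggregate -> describe -> classify
-> report from one serializable :class:`RunConfig`, writing per-condition
mean +/- SD tables, a descriptor table, a classification report and a run
manifest.  Given the same config (seeds included), deterministic stages
produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .descriptors import DEFAULT_MAX_LAG, DEFAULT_N_BINS, DescriptorSet, describe
from .errors import ConfigurationError, StageError
from .homeostasis import (
    Thresholds,
    circadian_summary,
    classify_variable,
    production_fold_change,
)
from .io import ReplicateSet, read_chronogram_table, write_chronogram_table
from .simulate import default_config, simulate_replicate_set

log = logging.getLogger("chronovoc.pipeline")


@dataclass
class ConditionSource:
    """Input source for one condition: a synthetic config or a CSV path."""

    kind: str = "synthetic"  # "synthetic" | "csv"
    path: str | None = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("synthetic", "csv"):
            raise ConfigurationError(f"unknown source kind {self.kind!r}")
        if self.kind == "csv" and not self.path:
            raise ConfigurationError("csv source requires a path")


@dataclass
class RunConfig:
    """Fully serializable configuration of one study run."""

    conditions: dict[str, ConditionSource] = field(
        default_factory=lambda: {
            "plant": ConditionSource(),
            "fungus": ConditionSource(),
            "interaction": ConditionSource(),
        }
    )
    background_condition: str = "plant"
    reference_condition: str = "fungus"
    max_lag: int = DEFAULT_MAX_LAG
    n_bins: int = DEFAULT_N_BINS
    thresholds: Thresholds = field(default_factory=Thresholds)
    lights_on_hour: float = 4.0
    lights_off_hour: float = 20.0
    inoculation_clock_hour: float = 8.0
    seed: int = 0
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = {
                k: ConditionSource(**v) if isinstance(v, dict) else v
                for k, v in d["conditions"].items()
            }
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = Thresholds(**d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _condition_seed(base_seed: int, name: str) -> int:
    """Stable per-condition seed derived from the run seed (below 2**31)."""
    digest = sum((i + 1) * ord(ch) for i, ch in enumerate(name)) % (2**16)
    return int((base_seed * 2**15 + digest) % (2**31 - 1))


def _load_condition(name: str, src: ConditionSource, seed: int) -> ReplicateSet:
    if src.kind == "csv":
        return read_chronogram_table(src.path, condition=None)
    cond = src.overrides.get("condition", name)
    overrides = {k: v for k, v in src.overrides.items() if k != "condition"}
    cfg = default_config(cond, seed=seed, **overrides)
    rset, _truth = simulate_replicate_set(cfg)
    return rset


@dataclass
class StudyReport:
    descriptors: pd.DataFrame
    classifications: dict[str, dict]
    fold_change: float | None
    outdir: Path
    manifest: dict


def descriptor_table(described: dict[str, DescriptorSet]) -> pd.DataFrame:
    """One row per condition: the moment / Poincare / AUC / ACF summary."""
    rows = []
    for name, d in described.items():
        rows.append(
            {
                "condition": name,
                "n_points": d.n_points,
                "mean_intensity": d.mean_intensity,
                "skewness": d.skewness,
                "excess_kurtosis": d.excess_kurtosis,
                "sd1": d.sd1,
                "sd2": d.sd2,
                "sd_ratio": d.sd_ratio,
                "auc": d.auc,
                "acf1": d.acf1,
            }
        )
    return pd.DataFrame(rows)


def run_study(config: RunConfig, outdir: str | Path) -> StudyReport:
    """Execute the full study; any stage failure aborts with the stage name
    and the offending condition."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rsets: dict[str, ReplicateSet] = {}
    for name, src in config.conditions.items():
        log.info("stage=load condition=%s kind=%s", name, src.kind)
        try:
            rsets[name] = _load_condition(name, src, _condition_seed(config.seed, name))
        except Exception as exc:
            raise StageError(f"stage=load condition={name}: {exc}") from exc

    described: dict[str, DescriptorSet] = {}
    circadians: dict[str, dict] = {}
    for name, rset in rsets.items():
        log.info("stage=describe condition=%s", name)
        try:
            write_chronogram_table(rset, outdir / f"chronograms_{name}.csv")
            pd.DataFrame(
                {
                    "time_h": rset.mean.times,
                    "mean": rset.mean.intensities,
                    "sd": rset.sd.intensities,
                }
            ).to_csv(outdir / f"mean_sd_{name}.csv", index=False)
            d = describe(rset.mean, max_lag=config.max_lag, n_bins=config.n_bins)
            d.condition = name
            described[name] = d
            summ = circadian_summary(
                rset.mean,
                lights_on_hour=config.lights_on_hour,
                lights_off_hour=config.lights_off_hour,
                inoculation_clock_hour=config.inoculation_clock_hour,
            )
            circadians[name] = {
                "peak_hour": summ.peak_hour,
                "night_day_ratio": summ.night_day_ratio,
            }
        except Exception as exc:
            raise StageError(f"stage=describe condition={name}: {exc}") from exc

    log.info("stage=classify")
    bg_name = config.background_condition
    ref_name = config.reference_condition
    if bg_name not in described:
        raise StageError(f"stage=classify condition={bg_name}: background condition missing")
    classifications: dict[str, dict] = {}
    for name, d in described.items():
        try:
            reference = described.get(ref_name) if name != ref_name else None
            result = classify_variable(
                d, described[bg_name], config.thresholds, reference=reference
            )
            classifications[name] = {
                "label": result.label.value,
                "evidence": {
                    k: {"value": v, "threshold": thr, "passed": bool(p)}
                    for k, (v, thr, p) in result.evidence.items()
                },
                "thresholds": dataclasses.asdict(result.thresholds_used),
            }
        except Exception as exc:
            raise StageError(f"stage=classify condition={name}: {exc}") from exc

    fold = None
    if ref_name in rsets:
        for name in rsets:
            if name not in (bg_name, ref_name):
                try:
                    fold = production_fold_change(rsets[name].mean, rsets[ref_name].mean)
                except Exception as exc:
                    raise StageError(f"stage=fold_change condition={name}: {exc}") from exc
                break

    table = descriptor_table(described)
    table.to_csv(outdir / "descriptors.csv", index=False)
    report = {
        "classifications": classifications,
        "circadian": circadians,
        "fold_change_vs_reference": fold,
    }
    with open(outdir / "classification.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    manifest = {
        "config": config.to_dict(),
        "condition_seeds": {n: _condition_seed(config.seed, n) for n in config.conditions},
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)

    if config.make_plots:
        log.info("stage=plots")
        from . import plots

        pdir = outdir / "plots"
        pdir.mkdir(exist_ok=True)
        for name, rset in rsets.items():
            plots.plot_chronogram(rset.mean, rset.sd, pdir / f"chronogram_{name}.png")
            plots.plot_histogram(described[name], pdir / f"histogram_{name}.png")
            plots.plot_acf(described[name], pdir / f"acf_{name}.png")
            plots.plot_poincare(rset.mean, described[name], pdir / f"poincare_{name}.png")

    return StudyReport(
        descriptors=table,
        classifications=classifications,
        fold_change=fold,
        outdir=outdir,
        manifest=manifest,
    )
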