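"""Chronogram containers and I/O.

A *chronogram* is the intensity-versus-time trace of one target ion monitored
by direct (chromatography-free) mass spectrometry -- the extracted-ion
chromatogram generalized to continuous ambient monitoring.  The canonical
on-disk representation is a long-format CSV with columns

    condition, bio_rep, tech_rep, time_h, intensity

one row per measurement, time in hours since inoculation, '.' decimal
separator, UTF-8, header row.  This module also builds chronograms from
centroided scan streams (in memory or mzML) and aggregates the micro-scan ->
technical -> biological replicate hierarchy into a mean +/- SD series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    UnsupportedModeError,
)

CANONICAL_COLUMNS = ("condition", "bio_rep", "tech_rep", "time_h", "intensity")

#: default target ion: protonated 6-pentyl-2H-pyran-2-one, [M+H]+
DEFAULT_TARGET_MZ = 167.1
#: unit-resolution ion-trap window half-width
DEFAULT_MZ_TOLERANCE = 0.5


@dataclass
class ScanFrame:
    """One centroided scan: a peak list acquired at one time point.

    Peaks are stored as parallel ``mz`` / ``intensity`` arrays sorted
    ascending by m/z; intensities must be finite and non-negative.
    """

    time_h: float
    mz: np.ndarray
    intensity: np.ndarray
    bio_rep: int = 1
    tech_rep: int = 1
    condition: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise FormatError("peak m/z and intensity arrays must be 1-D and equal length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            raise FormatError("peak list must be sorted ascending by m/z")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise FormatError("peak intensities must be finite and >= 0")
        if self.time_h < 0 or not np.isfinite(self.time_h):
            raise FormatError("scan time must be finite and >= 0 hours")


@dataclass
class Chronogram:
    """A single time-ordered intensity series for one target ion.

    ``provenance`` records how the series was obtained (``raw``,
    ``technical-mean``, ``biological-mean``, ``biological-sd``).  NaNs are
    permitted only when ``allow_nan`` is set (used for SD series at time
    points covered by fewer than two biological replicates).
    """

    times: np.ndarray
    intensities: np.ndarray
    target_mz: float = DEFAULT_TARGET_MZ
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE
    condition: str = ""
    provenance: str = "raw"
    allow_nan: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise FormatError("times and intensities must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise EmptyInputError("chronogram must contain at least one point")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("chronogram times must be strictly increasing")
        if np.any(np.isinf(self.intensities)):
            raise FormatError("chronogram intensities must not be infinite")
        if not self.allow_nan and np.any(np.isnan(self.intensities)):
            raise FormatError("chronogram intensities must be finite (NaN not allowed here)")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def span_h(self) -> float:
        return float(self.times[-1] - self.times[0])

    def equals(self, other: "Chronogram") -> bool:
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.intensities, other.intensities, equal_nan=True)
            and self.condition == other.condition
        )


@dataclass
class ReplicateSet:
    """Biological x technical replicate chronograms plus derived mean/SD.

    ``chronograms`` is keyed by ``(bio_rep, tech_rep)``.  ``mean`` and ``sd``
    are filled by :func:`aggregate_replicates`: technical replicates are
    averaged within each biological replicate first, then the biological-
    replicate mean and sample SD (denominator n-1) are taken pointwise.
    """

    chronograms: dict[tuple[int, int], Chronogram]
    condition: str = ""
    mean: Chronogram | None = None
    sd: Chronogram | None = None

    @property
    def bio_reps(self) -> list[int]:
        return sorted({b for b, _ in self.chronograms})

    @property
    def n_replicates(self) -> int:
        return len(self.chronograms)


def extract_xic(
    scans: Sequence[ScanFrame],
    target_mz: float = DEFAULT_TARGET_MZ,
    tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> Chronogram:
    """Build the extracted-ion chronogram for one m/z window.

    Per scan the intensity is the sum of all peak intensities with
    ``|mz - target_mz| <= tolerance``; scans sharing a time stamp
    (micro-scans) are averaged.  A window containing no peak contributes
    zero -- absence of signal is data, not an error.
    """
    scans = list(scans)
    if not scans:
        raise EmptyInputError("extract_xic requires at least one scan")
    if tolerance <= 0:
        raise FormatError("m/z tolerance must be > 0")
    sums: dict[float, list[float]] = {}
    condition = scans[0].condition
    for scan in scans:
        lo = np.searchsorted(scan.mz, target_mz - tolerance, side="left")
        hi = np.searchsorted(scan.mz, target_mz + tolerance, side="right")
        sums.setdefault(scan.time_h, []).append(float(scan.intensity[lo:hi].sum()))
    times = np.array(sorted(sums), dtype=float)
    intens = np.array([np.mean(sums[t]) for t in times], dtype=float)
    return Chronogram(
        times,
        intens,
        target_mz=target_mz,
        mz_tolerance=tolerance,
        condition=condition,
        provenance="raw",
    )


def write_chronogram_table(rset: ReplicateSet, path: str | Path) -> None:
    """Write the replicate hierarchy as the canonical long-format CSV."""
    rows = []
    for (b, r), chron in sorted(rset.chronograms.items()):
        rows.append(
            pd.DataFrame(
                {
                    "condition": chron.condition or rset.condition,
                    "bio_rep": b,
                    "tech_rep": r,
                    "time_h": chron.times,
                    "intensity": chron.intensities,
                }
            )
        )
    if not rows:
        raise EmptyInputError("replicate set contains no chronograms")
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_chronogram_table(
    path: str | Path,
    condition: str | None = None,
    aggregate: bool = True,
) -> ReplicateSet:
    """Read a canonical long-format chronogram CSV into a ReplicateSet.

    If the file holds several conditions, ``condition`` selects one (an error
    names the available conditions otherwise).  Rows are grouped into
    per-replicate chronograms sorted by time; duplicated (replicate, time)
    rows raise :class:`FormatError` naming the offending row.
    """
    try:
        # round_trip: values reread exactly as written (full printed precision)
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse chronogram table {path}: {exc}") from exc
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"chronogram table {path} is missing columns {missing}")
    for col in ("bio_rep", "tech_rep", "time_h", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(f"non-numeric value in column '{col}' at row {bad[0] + 2} of {path}")
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0]) + 2
            raise FormatError(f"missing value in column '{col}' at row {row} of {path}")
        df[col] = coerced
    conditions = sorted(df["condition"].astype(str).unique())
    if condition is None:
        if len(conditions) > 1:
            raise FormatError(
                f"table holds several conditions {conditions}; pass condition= to select one"
            )
        condition = conditions[0]
    df = df[df["condition"].astype(str) == str(condition)]
    if df.empty:
        raise FormatError(f"condition {condition!r} not found; table holds {conditions}")
    chrons: dict[tuple[int, int], Chronogram] = {}
    for (b, r), grp in df.groupby(["bio_rep", "tech_rep"]):
        grp = grp.sort_values("time_h")
        dup = grp["time_h"].duplicated()
        if dup.any():
            t = grp.loc[dup, "time_h"].iloc[0]
            raise FormatError(
                f"duplicated time {t} within replicate (bio={int(b)}, tech={int(r)})"
            )
        chrons[(int(b), int(r))] = Chronogram(
            grp["time_h"].to_numpy(),
            grp["intensity"].to_numpy(),
            condition=str(condition),
            provenance="raw",
        )
    rset = ReplicateSet(chronograms=chrons, condition=str(condition))
    return aggregate_replicates(rset) if aggregate else rset


def _on_grid(
    chron: Chronogram, grid: np.ndarray, interval: float
) -> tuple[np.ndarray, int]:
    """Resample one chronogram onto ``grid`` (multiples of ``interval``).

    Times are snapped to the nominal grid by rounding; interior points missing
    from this replicate (e.g. inlet-cleaning gaps) are filled by linear
    interpolation, points outside the replicate's own range stay NaN.
    Returns the resampled values and the number of interpolated points.
    """
    idx = np.rint(chron.times / interval).astype(int)
    if len(np.unique(idx)) != len(idx):
        raise FormatError("two samples of one replicate round to the same grid point")
    values = np.full(grid.size, np.nan)
    gidx = np.rint(grid / interval).astype(int)
    pos = {k: i for i, k in enumerate(gidx)}
    for k, v in zip(idx, chron.intensities):
        if k in pos:
            values[pos[k]] = v
    inside = (grid >= chron.times[0] - 0.5 * interval) & (grid <= chron.times[-1] + 0.5 * interval)
    hole = np.isnan(values) & inside
    n_filled = int(hole.sum())
    if n_filled:
        values[hole] = np.interp(grid[hole], chron.times, chron.intensities)
    return values, n_filled


def aggregate_replicates(
    rset: ReplicateSet, sampling_interval_h: float | None = None
) -> ReplicateSet:
    """Compute the biological-mean and SD chronograms of a replicate set.

    Technical replicates are averaged within each biological replicate first;
    the biological mean and sample standard deviation (denominator n-1) are
    then taken pointwise.  Time points covered by fewer than two biological
    replicates get SD = NaN and trigger a warning.
    """
    if not rset.chronograms:
        raise EmptyInputError("replicate set contains no chronograms")
    first = next(iter(rset.chronograms.values()))
    if sampling_interval_h is None:
        diffs = np.diff(first.times)
        sampling_interval_h = float(np.median(diffs)) if diffs.size else 1.0
    if sampling_interval_h <= 0:
        raise FormatError("sampling interval must be > 0")
    lo = min(c.times[0] for c in rset.chronograms.values())
    hi = max(c.times[-1] for c in rset.chronograms.values())
    k0 = int(np.rint(lo / sampling_interval_h))
    k1 = int(np.rint(hi / sampling_interval_h))
    grid = np.arange(k0, k1 + 1) * sampling_interval_h

    n_filled_total = 0
    by_bio: dict[int, list[np.ndarray]] = {}
    for (b, _r), chron in sorted(rset.chronograms.items()):
        vals, n_filled = _on_grid(chron, grid, sampling_interval_h)
        n_filled_total += n_filled
        by_bio.setdefault(b, []).append(vals)
    if n_filled_total:
        warnings.warn(
            f"{n_filled_total} missing points filled by linear interpolation during alignment",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        bio_means = np.vstack([np.nanmean(np.vstack(v), axis=0) for b, v in sorted(by_bio.items())])
        mean = np.nanmean(bio_means, axis=0)
        counts = np.sum(~np.isnan(bio_means), axis=0)
        sd = np.full(grid.size, np.nan)
        ok = counts >= 2
        if ok.any():
            sd[ok] = np.nanstd(bio_means[:, ok], axis=0, ddof=1)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} time points covered by fewer than 2 biological replicates; "
            "SD reported as missing there",
            stacklevel=2,
        )
    condition = rset.condition or first.condition
    proto = dict(target_mz=first.target_mz, mz_tolerance=first.mz_tolerance, condition=condition)
    mean_c = Chronogram(grid, mean, provenance="biological-mean", **proto)
    sd_c = Chronogram(grid, sd, provenance="biological-sd", allow_nan=True, **proto)
    return ReplicateSet(chronograms=dict(rset.chronograms), condition=condition, mean=mean_c, sd=sd_c)


# -- mzML reading -----------------------------------------------------------
# A deliberately small standards-based reader for the subset this package
# needs: centroided spectra with 32/64-bit float m/z and intensity arrays
# (uncompressed or zlib) and a scan start time.  Anything else is rejected
# with a clear error rather than guessed at.

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(elem) -> np.ndarray:
    import base64
    import zlib

    names = {cv.get("name") for cv in elem.iter(f"{_MZML_NS}cvParam")}
    binary = elem.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(binary.text or "")
    if "zlib compression" in names:
        raw = zlib.decompress(raw)
    elif "no compression" not in names:
        raise UnsupportedModeError(f"unsupported binary compression in {sorted(names)}")
    if "64-bit float" in names:
        dtype = "<f8"
    elif "32-bit float" in names:
        dtype = "<f4"
    else:
        raise UnsupportedModeError(f"unsupported binary encoding in {sorted(names)}")
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml_scans(
    path: str | Path,
    condition: str = "",
    bio_rep: int = 1,
    tech_rep: int = 1,
    inoculation_offset_h: float = 0.0,
) -> list[ScanFrame]:
    """Read centroided scans from an mzML file into ScanFrames.

    Retention times are converted to hours since inoculation
    (``inoculation_offset_h`` is subtracted, in hours).  Profile-mode spectra
    raise :class:`UnsupportedModeError`; missing retention times raise
    :class:`FormatError`.
    """
    from lxml import etree

    frames: list[ScanFrame] = []
    for _event, spectrum in etree.iterparse(str(path), tag=f"{_MZML_NS}spectrum"):
        spec_id = spectrum.get("id", f"index={spectrum.get('index')}")
        top_params = {
            cv.get("name")
            for cv in spectrum.findall(f"{_MZML_NS}cvParam")
        }
        if "profile spectrum" in top_params:
            raise UnsupportedModeError(
                f"spectrum {spec_id} is profile mode; centroided data required"
            )
        rt_param = None
        for scan in spectrum.iter(f"{_MZML_NS}scan"):
            for cv in scan.findall(f"{_MZML_NS}cvParam"):
                if cv.get("name") == "scan start time":
                    rt_param = cv
                    break
        if rt_param is None:
            raise FormatError(f"spectrum {spec_id} has no scan start time")
        unit = (rt_param.get("unitName") or "minute").lower()
        value = float(rt_param.get("value"))
        if unit.startswith("min"):
            time_h = value / 60.0
        elif unit.startswith("sec"):
            time_h = value / 3600.0
        elif unit.startswith("hour"):
            time_h = value
        else:
            raise FormatError(f"unknown retention-time unit {unit!r}")
        time_h -= inoculation_offset_h
        arrays: dict[str, np.ndarray] = {}
        for bda in spectrum.iter(f"{_MZML_NS}binaryDataArray"):
            names = {cv.get("name") for cv in bda.findall(f"{_MZML_NS}cvParam")}
            for kind in ("m/z array", "intensity array"):
                if kind in names:
                    arrays[kind] = _decode_binary_array(bda)
        if set(arrays) != {"m/z array", "intensity array"}:
            raise FormatError(f"spectrum {spec_id} lacks m/z or intensity arrays")
        mz = arrays["m/z array"]
        inten = arrays["intensity array"]
        order = np.argsort(mz, kind="stable")
        frames.append(
            ScanFrame(
                time_h=time_h,
                mz=mz[order],
                intensity=inten[order],
                bio_rep=bio_rep,
                tech_rep=tech_rep,
                condition=condition,
            )
        )
        spectrum.clear()
    if not frames:
        raise EmptyInputError(f"mzML file {path} contains no spectra")
    return frames
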