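"""Genome-integrity metrics from 1-D fluorescence intensity data.

Two assays are covered:

* **Sister-chromatid cohesion** — a line scan across a DAPI-stained
  chromatid pair shows two intensity peaks; the inter-peak distance in
  pixels measures how far the chromatids have separated (smaller distance =
  tighter cohesion).  Peaks are located on a moving-average-smoothed trace
  and the two highest local maxima at least ``min_separation_px`` apart are
  used.

* **Comet assay** — alkaline single-cell electrophoresis stretches broken
  DNA into a tail behind the nuclear head.  From a 1-D intensity profile
  along the comet axis (head at lower coordinates), the Olive tail moment
  is (fraction of DNA in the tail) x (tail centroid - head centroid).  The
  head ends where the smoothed profile first falls below a fraction
  (default 10%) of the peak on the tail side; everything at higher
  coordinates is tail.  An extent tail moment variant (tail fraction x
  tail length) is also provided.

Both metrics are invariant under uniform intensity scaling.  Group
comparisons use rank-based tests (rank-sum for 2 groups, Kruskal-Wallis
for >= 3), the standard choice for these skewed, small-n distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal, stats


@dataclass
class IntensityTrace:
    """Line-scan intensities (1 px spacing) across a sister-chromatid pair."""

    values: np.ndarray
    sample: str = ""
    treatment: str = ""  # e.g. "colcemid-4hr"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 8:
            raise ValueError("trace must be 1-D with >= 8 samples")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("trace values must be finite and non-negative")


@dataclass
class IntensityProfile:
    """Comet-axis intensities, head at lower coordinates."""

    values: np.ndarray
    sample: str = ""
    timepoint: str = ""  # e.g. "pre-IR", "30min", "8h", "24h"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("profile must be a 1-D intensity vector")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("profile values must be finite and non-negative")
        if self.values.sum() <= 0:
            raise ValueError("profile has zero total mass")


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    kernel = np.ones(window) / window
    # reflect-pad so peak positions are not dragged toward the edges
    pad = window // 2
    padded = np.pad(values, pad, mode="reflect")
    sm = np.convolve(padded, kernel, mode="same")[pad: pad + values.size]
    return sm


def chromatid_distance(
    trace: IntensityTrace,
    min_separation_px: int = 4,
    smoothing_window: int = 3,
) -> float | None:
    """Distance in pixels between the two dominant intensity peaks.

    Returns None (a no-measurement result, deliberately not zero) when
    fewer than two local maxima separated by >= min_separation_px exist.
    """
    sm = _smooth(trace.values, smoothing_window)
    peaks, props = signal.find_peaks(sm, distance=min_separation_px)
    if peaks.size < 2:
        return None
    top2 = peaks[np.argsort(sm[peaks])[-2:]]
    return float(abs(int(top2[0]) - int(top2[1])))


def distance_comparison(
    groups: Mapping[str, Sequence[float]],
    min_n: int = 3,
    bins: int = 10,
) -> dict:
    """Histograms plus a rank-based test of inter-peak distances by group.

    Groups with fewer than ``min_n`` measurements are excluded with a
    warning entry.  Two usable groups -> Wilcoxon rank-sum; three or more
    -> Kruskal-Wallis.
    """
    usable, excluded = {}, []
    for label, vals in groups.items():
        vals = [v for v in vals if v is not None]
        if len(vals) < min_n:
            excluded.append(label)
        else:
            usable[label] = np.asarray(vals, dtype=float)
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 groups with >= {min_n} measurements, have {len(usable)}"
        )
    all_vals = np.concatenate(list(usable.values()))
    edges = np.histogram_bin_edges(all_vals, bins=bins)
    summary = {
        label: {
            "n": int(v.size),
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "histogram": np.histogram(v, bins=edges)[0].tolist(),
        }
        for label, v in usable.items()
    }
    samples = list(usable.values())
    if len(usable) == 2:
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        test = {"method": "rank-sum", "statistic": float(stat), "pvalue": float(p)}
    else:
        stat, p = stats.kruskal(*samples)
        test = {"method": "kruskal-wallis", "statistic": float(stat), "pvalue": float(p)}
    return {
        "groups": summary,
        "bin_edges": edges.tolist(),
        "excluded": excluded,
        "test": test,
    }


def _head_tail_split(
    values: np.ndarray, boundary_frac: float, smoothing_window: int
) -> tuple[int, np.ndarray]:
    """Head/tail boundary index and background-subtracted intensities.

    Pixels whose smoothed intensity sits below boundary_frac of the peak
    are treated as background (set to 0), the convention of comet-scoring
    software; without it the sub-threshold tail of any smooth peak would
    register as spurious tail mass.
    """
    sm = _smooth(values, smoothing_window)
    peak = int(np.argmax(sm))
    thresh = boundary_frac * sm[peak]
    cleaned = np.where(sm >= thresh, values, 0.0)
    below = np.nonzero(sm[peak:] < thresh)[0]
    if below.size == 0:
        return values.size, cleaned  # profile never drops: all head, no tail
    return peak + int(below[0]), cleaned


def olive_tail_moment(
    profile: IntensityProfile,
    boundary_frac: float = 0.10,
    smoothing_window: int = 3,
    variant: str = "olive",
) -> float:
    """Tail moment of a comet profile (Olive by default).

    Olive: tail_fraction x (tail centroid - head centroid), clipped at 0.
    Extent: tail_fraction x tail length (head boundary to last nonzero tail
    pixel).  A profile wholly contained in the head region scores 0.
    """
    if variant not in ("olive", "extent"):
        raise ValueError(f"unknown tail-moment variant {variant!r}")
    split, v = _head_tail_split(profile.values, boundary_frac, smoothing_window)
    head, tail = v[:split], v[split:]
    total = v.sum()
    tail_mass = tail.sum()
    if tail_mass <= 0 or total <= 0:
        return 0.0
    tail_frac = tail_mass / total
    pos = np.arange(v.size, dtype=float)
    if variant == "extent":
        nz = np.nonzero(tail > 0)[0]
        tail_len = float(nz[-1] + 1) if nz.size else 0.0
        return tail_frac * tail_len
    head_centroid = float(pos[:split] @ head / head.sum()) if head.sum() > 0 else 0.0
    tail_centroid = float(pos[split:] @ tail / tail_mass)
    return max(0.0, tail_frac * (tail_centroid - head_centroid))


def measured_tail_fraction(
    profile: IntensityProfile,
    boundary_frac: float = 0.10,
    smoothing_window: int = 3,
) -> float:
    """Fraction of background-subtracted intensity beyond the boundary."""
    split, v = _head_tail_split(profile.values, boundary_frac, smoothing_window)
    total = v.sum()
    return float(v[split:].sum() / total) if total > 0 else 0.0


def repair_kinetics(
    moments_by_timepoint: Mapping[str, Sequence[float]],
    baseline: str = "pre-IR",
    alpha: float = 0.05,
    min_n: int = 3,
) -> dict:
    """Double-strand-break repair kinetics from tail moments over time.

    Each post-irradiation timepoint is compared to the baseline with a
    one-sided rank test (alternative: timepoint > baseline).  A timepoint
    is flagged ``repaired`` when its tail moments are not significantly
    above baseline at ``alpha`` — i.e. damage has returned to the
    pre-irradiation level.
    """
    if baseline not in moments_by_timepoint:
        raise ValueError(f"baseline timepoint {baseline!r} missing")
    if len(moments_by_timepoint) < 2:
        raise ValueError("need >= 2 timepoints (baseline plus >= 1 post-IR)")
    base = np.asarray(moments_by_timepoint[baseline], dtype=float)
    if base.size < min_n:
        raise ValueError(f"baseline needs >= {min_n} comets")
    out = {
        "baseline": baseline,
        "median_baseline": float(np.median(base)),
        "timepoints": {},
    }
    for label, vals in moments_by_timepoint.items():
        if label == baseline:
            continue
        v = np.asarray(vals, dtype=float)
        entry: dict = {"n": int(v.size), "median": float(np.median(v))}
        if v.size < min_n:
            entry["status"] = "undersized"
        else:
            if np.ptp(np.concatenate([v, base])) == 0:
                p = 1.0  # degenerate: all moments identical
            else:
                _, p = stats.mannwhitneyu(v, base, alternative="greater")
            entry["pvalue_vs_baseline"] = float(p)
            entry["repaired"] = bool(p > alpha)
            entry["status"] = "ok"
        out["timepoints"][label] = entry
    return out
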