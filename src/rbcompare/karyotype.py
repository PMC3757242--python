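"""Per-cell chromosome-count (SKY) summaries.

Spectral karyotyping yields, for each scored metaphase, a total chromosome
count.  Published tables condense a sample's cells into a count string such
as ``"36(1), 39(2), 40(8)"`` — each token is ``count(n_cells)``.  This module
parses those strings and computes the count-based aneuploidy metrics: the
percentage of cells above / below a reference count, total aneuploidy, and
the fraction of cells retaining the reference karyotype.

Two reference-count policies are common: the species diploid number (40 for
mouse, 46 for human) for primary tumors, or the modal/clonal count for cell
lines and xenograft sublines whose founder karyotype is itself aberrant
(e.g. a human xenograft clone carrying 47 chromosomes including a
derivative).

Count-based metrics cannot see balanced events: a cell with one gain plus
one loss has the reference total and is scored as retaining it, and
structural aberrations (translocations, isochromosomes, double minutes) are
invisible.  Event-level gain/deletion percentages published alongside count
strings may therefore exceed what this module computes.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

MOUSE_DIPLOID = 40
HUMAN_DIPLOID = 46

_TOKEN_RE = re.compile(r"^\s*(\d+)\s*\(\s*(\d+)\s*\)\s*$")


class KaryotypeParseError(ValueError):
    """Raised when a count string token does not match ``count(n_cells)``."""


@dataclass
class KaryotypeDistribution:
    """Multiset of per-cell chromosome counts for one sample."""

    counts: Counter = field(default_factory=Counter)
    sample: str = ""
    species: str = ""

    @property
    def n_cells(self) -> int:
        return sum(self.counts.values())

    def cells(self) -> np.ndarray:
        """Expand to one entry per cell, sorted by count."""
        out = []
        for c in sorted(self.counts):
            out.extend([c] * self.counts[c])
        return np.asarray(out, dtype=int)

    def to_string(self) -> str:
        """Serialize back to the ``count(n)`` form, ascending by count."""
        return ", ".join(f"{c}({self.counts[c]})" for c in sorted(self.counts))


@dataclass
class AneuploidySummary:
    """Count-based gain/loss/aneuploidy percentages relative to a reference.

    ``pct_gain + pct_loss == pct_aneuploid`` and
    ``retention == 1 - pct_aneuploid/100`` hold exactly on the unrounded
    values; displayed percentages are rounded half-up to one decimal (or to
    an integer with ``display="integer"``).
    """

    ref_count: int
    n_cells: int
    pct_gain: float
    pct_loss: float
    pct_aneuploid: float
    retention: float


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def parse_count_string(text: str, sample: str = "", species: str = "") -> KaryotypeDistribution:
    """Parse a comma-separated ``count(n_cells)`` string.

    Whitespace-tolerant; an empty string yields an empty distribution.
    """
    counts: Counter = Counter()
    stripped = text.strip()
    if stripped:
        for token in stripped.split(","):
            m = _TOKEN_RE.match(token)
            if not m:
                raise KaryotypeParseError(
                    f"malformed karyotype token {token.strip()!r} "
                    f"(expected 'count(n_cells)')"
                )
            counts[int(m.group(1))] += int(m.group(2))
    return KaryotypeDistribution(counts=counts, sample=sample, species=species)


def modal_count(dist: KaryotypeDistribution, diploid: int | None = None) -> int:
    """Most frequent chromosome count.

    Ties break toward ``diploid`` (when given and tied), then toward the
    smaller count.
    """
    if dist.n_cells < 1:
        raise ValueError("modal_count of an empty distribution")
    top = max(dist.counts.values())
    tied = sorted(c for c, n in dist.counts.items() if n == top)
    if diploid is not None and diploid in tied:
        return diploid
    return tied[0]


def aneuploidy_summary(
    dist: KaryotypeDistribution,
    ref_count: int,
    display: str = "decimal",
) -> AneuploidySummary:
    """Gain/loss/aneuploidy percentages and retention versus ``ref_count``.

    ``display="decimal"`` rounds percentages half-up to one decimal;
    ``"integer"`` rounds to whole percent (some published tables print
    integers). ``retention`` is the exact fraction of cells at the
    reference count.
    """
    n = dist.n_cells
    if n < 1:
        raise ValueError("aneuploidy_summary of an empty distribution")
    if ref_count < 1:
        raise ValueError("ref_count must be >= 1")
    nd = {"decimal": 1, "integer": 0}.get(display)
    if nd is None:
        raise ValueError(f"unknown display mode {display!r}")

    n_gain = sum(m for c, m in dist.counts.items() if c > ref_count)
    n_loss = sum(m for c, m in dist.counts.items() if c < ref_count)
    pct_gain = 100.0 * n_gain / n
    pct_loss = 100.0 * n_loss / n
    return AneuploidySummary(
        ref_count=ref_count,
        n_cells=n,
        pct_gain=_round_half_up(pct_gain, nd),
        pct_loss=_round_half_up(pct_loss, nd),
        pct_aneuploid=_round_half_up(pct_gain + pct_loss, nd),
        retention=(n - n_gain - n_loss) / n,
    )


def resolve_reference(dist: KaryotypeDistribution, policy: str | int) -> int:
    """Resolve a reference-count policy to an integer count.

    ``policy`` is an integer, ``"modal"``, or ``"diploid"`` (species tag
    must then be ``"mouse"`` or ``"human"``).
    """
    if isinstance(policy, int):
        return policy
    if policy == "modal":
        diploid = {"mouse": MOUSE_DIPLOID, "human": HUMAN_DIPLOID}.get(dist.species)
        return modal_count(dist, diploid=diploid)
    if policy == "diploid":
        try:
            return {"mouse": MOUSE_DIPLOID, "human": HUMAN_DIPLOID}[dist.species]
        except KeyError:
            raise ValueError(
                f"diploid reference needs species 'mouse' or 'human', got "
                f"{dist.species!r} for sample {dist.sample!r}"
            ) from None
    try:
        return int(policy)
    except (TypeError, ValueError):
        raise ValueError(f"unknown reference policy {policy!r}") from None


def clone_heterogeneity(
    clones: Mapping[str, Sequence[KaryotypeDistribution]],
) -> dict:
    """Intra-clonal karyotype heterogeneity, compared across groups.

    ``clones`` maps a group label (e.g. cell line of origin) to that group's
    single-cell-derived clone distributions.  Per clone the summary reports
    the number of distinct counts, the variance of counts, and the fraction
    of cells off the clone's modal count.  Clones with fewer than 2 cells
    are skipped (listed under ``"skipped"``).

    With >= 2 groups, group dispersion is compared with a rank-based test on
    the per-cell absolute deviation from the clone modal count, pooled over
    a group's clones (rank-sum for 2 groups, Kruskal-Wallis for >= 3).  The
    cell is the observation unit because per-clone designs are typically too
    small (3 clones/group) for a rank test on clone-level values to attain
    conventional significance.  If every cell in every clone sits at its
    modal count the test is degenerate and reported as no difference
    (p = 1.0).
    """
    per_clone = []
    skipped = []
    group_devs: dict[str, list[np.ndarray]] = {}
    for group, dists in clones.items():
        for d in dists:
            if d.n_cells < 2:
                skipped.append({"group": group, "sample": d.sample, "n_cells": d.n_cells})
                continue
            cells = d.cells()
            mode = modal_count(d)
            dev = np.abs(cells - mode)
            per_clone.append(
                {
                    "group": group,
                    "sample": d.sample,
                    "n_cells": int(d.n_cells),
                    "n_distinct_counts": int(len(d.counts)),
                    "count_variance": float(np.var(cells, ddof=1)),
                    "frac_non_modal": float(np.mean(dev > 0)),
                }
            )
            group_devs.setdefault(group, []).append(dev)

    result: dict = {"per_clone": per_clone, "skipped": skipped, "test": None}
    usable = {g: np.concatenate(v) for g, v in group_devs.items() if v}
    if len(usable) >= 2:
        samples = list(usable.values())
        if np.ptp(np.concatenate(samples)) == 0:
            result["test"] = {"method": "degenerate", "pvalue": 1.0,
                              "note": "no dispersion in any group"}
        elif len(usable) == 2:
            stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
            result["test"] = {"method": "rank-sum", "statistic": float(stat),
                              "pvalue": float(p), "groups": list(usable)}
        else:
            stat, p = stats.kruskal(*samples)
            result["test"] = {"method": "kruskal-wallis", "statistic": float(stat),
                              "pvalue": float(p), "groups": list(usable)}
    return result
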