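"""Copy-number lesion classification, burden summaries and recurrence.

Array-CGH segmentation yields per-sample gain/loss segments.  Lesions are
binned by size into whole-chromosome events (>= 90% of the chromosome, a
configurable fraction since array probes rarely reach telomeres), regional
lesions (>= 3 Mb), focal lesions (20 kb to 3 Mb, half-open at the top so a
3 Mb segment is regional), and sub-threshold segments (< 20 kb).  Recurrent
loci are intervals supported by same-type lesions in at least k samples
under a reciprocal-overlap rule.  A small somatic-mutation burden summary
(mean SNV+indel per tumor, fractions of tumors hit) rounds out the
genetic-lesion accounting.

Coordinates are 0-based half-open base pairs throughout.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LESION_CLASSES = ("whole", "regional", "focal", "sub-threshold")


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    call: str  # "gain" or "loss"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"segment start >= end: {self}")
        if self.call not in ("gain", "loss"):
            raise ValueError(f"segment call must be 'gain' or 'loss': {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentSet:
    """All called segments for one sample."""

    sample: str
    segments: list[Segment] = field(default_factory=list)


@dataclass
class LesionThresholds:
    focal_min_bp: int = 20_000
    focal_max_bp: int = 3_000_000
    whole_chrom_fraction: float = 0.90

    def __post_init__(self):
        if not self.focal_min_bp < self.focal_max_bp:
            raise ValueError("focal_min_bp must be < focal_max_bp")
        if not 0 < self.whole_chrom_fraction <= 1:
            raise ValueError("whole_chrom_fraction must be in (0, 1]")


@dataclass(frozen=True)
class LesionCall:
    segment: Segment
    lesion_class: str


def classify_lesion(
    segment: Segment,
    chrom_lengths: Mapping[str, int],
    thresholds: LesionThresholds | None = None,
) -> LesionCall:
    """Assign a segment to exactly one size class.

    Class depends only on segment length and chromosome length: whole when
    length >= whole_chrom_fraction * chrom length, else regional when
    >= focal_max_bp, else focal when >= focal_min_bp, else sub-threshold.
    """
    t = thresholds or LesionThresholds()
    if segment.chrom not in chrom_lengths:
        raise ValueError(f"unknown chromosome {segment.chrom!r}")
    clen = chrom_lengths[segment.chrom]
    if segment.end > clen:
        raise ValueError(
            f"segment end {segment.end} beyond chromosome {segment.chrom} "
            f"length {clen}"
        )
    L = segment.length
    if L >= t.whole_chrom_fraction * clen:
        cls = "whole"
    elif L >= t.focal_max_bp:
        cls = "regional"
    elif L >= t.focal_min_bp:
        cls = "focal"
    else:
        cls = "sub-threshold"
    return LesionCall(segment=segment, lesion_class=cls)


def classify_all(
    sets: Sequence[SegmentSet],
    chrom_lengths: Mapping[str, int],
    thresholds: LesionThresholds | None = None,
) -> pd.DataFrame:
    """Lesion calls for every segment of every sample, as a tidy table."""
    rows = []
    for s in sets:
        for seg in s.segments:
            call = classify_lesion(seg, chrom_lengths, thresholds)
            rows.append(
                (s.sample, seg.chrom, seg.start, seg.end, seg.call, call.lesion_class)
            )
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "call", "class"]
    )


def burden_summary(
    sets: Sequence[SegmentSet],
    genotype_map: Mapping[str, str],
    chrom_lengths: Mapping[str, int],
    thresholds: LesionThresholds | None = None,
) -> dict:
    """Per-sample and per-genotype lesion burdens.

    Returns per-sample class counts, per-genotype mean counts per class, and
    per-genotype fraction of samples with zero regional lesions.
    """
    for s in sets:
        if s.sample not in genotype_map:
            raise ValueError(f"sample {s.sample!r} missing from genotype map")
    calls = classify_all(sets, chrom_lengths, thresholds)
    per_sample = pd.DataFrame(
        0, index=[s.sample for s in sets], columns=list(LESION_CLASSES)
    )
    if len(calls):
        counts = calls.groupby(["sample", "class"]).size().unstack(fill_value=0)
        for cls in counts.columns:
            per_sample.loc[counts.index, cls] = counts[cls]
    per_sample["genotype"] = [genotype_map[s] for s in per_sample.index]

    grouped = per_sample.groupby("genotype")
    per_genotype = grouped[list(LESION_CLASSES)].mean()
    zero_regional = grouped["regional"].apply(lambda c: float((c == 0).mean()))
    return {
        "per_sample": per_sample,
        "per_genotype_mean": per_genotype,
        "frac_zero_regional": zero_regional.to_dict(),
    }


def _reciprocal_overlap(a: Segment, b: Segment) -> float:
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def recurrence(
    sets: Sequence[SegmentSet],
    k: int = 2,
    min_reciprocal_overlap: float = 0.5,
) -> pd.DataFrame:
    """Loci recurrently hit by same-type lesions in >= k samples.

    Each segment seeds a candidate: supporters are segments of the same call
    type from other samples with reciprocal overlap >= the threshold (best
    supporter per sample).  When >= k samples support the seed, the locus is
    the intersection interval of seed and supporters.  Duplicate loci are
    merged; output is sorted by support (descending) then coordinate.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 < min_reciprocal_overlap <= 1:
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")

    by_type: dict[str, list[tuple[str, Segment]]] = defaultdict(list)
    for s in sets:
        for seg in s.segments:
            by_type[seg.call].append((s.sample, seg))

    loci: dict[tuple, dict] = {}
    for call, tagged in by_type.items():
        for seed_sample, seed in tagged:
            best: dict[str, tuple[float, Segment]] = {}
            for sample, seg in tagged:
                if sample == seed_sample:
                    continue
                ro = _reciprocal_overlap(seed, seg)
                if ro >= min_reciprocal_overlap and (
                    sample not in best or ro > best[sample][0]
                ):
                    best[sample] = (ro, seg)
            support = 1 + len(best)
            if support < k:
                continue
            members = [seed] + [seg for _, seg in best.values()]
            start = max(m.start for m in members)
            end = min(m.end for m in members)
            if start >= end:
                continue
            key = (seed.chrom, start, end, call)
            samples = sorted({seed_sample, *best})
            prev = loci.get(key)
            if prev is None or support > prev["support"]:
                loci[key] = {
                    "chrom": seed.chrom,
                    "start": start,
                    "end": end,
                    "call": call,
                    "support": support,
                    "samples": ",".join(samples),
                }
    df = pd.DataFrame(
        list(loci.values()),
        columns=["chrom", "start", "end", "call", "support", "samples"],
    )
    if len(df):
        df = df.sort_values(
            ["support", "chrom", "start", "end"], ascending=[False, True, True, True]
        ).reset_index(drop=True)
    return df


def annotate_genes(
    loci: pd.DataFrame,
    genes: pd.DataFrame,
    cancer_genes: Iterable[str] = (),
) -> pd.DataFrame:
    """Genes overlapping each recurrent locus by >= 1 bp.

    ``genes`` is a BED-like frame with columns chrom/start/end/name
    (0-based half-open).  Returns one row per (locus, gene) hit with a
    cancer-gene flag from the provided symbol list.
    """
    cancer = set(cancer_genes)
    rows = []
    for _, locus in loci.iterrows():
        hit = genes[
            (genes["chrom"] == locus["chrom"])
            & (genes["start"] < locus["end"])
            & (genes["end"] > locus["start"])
        ]
        for _, g in hit.iterrows():
            rows.append(
                {
                    "chrom": locus["chrom"],
                    "locus_start": int(locus["start"]),
                    "locus_end": int(locus["end"]),
                    "call": locus.get("call", ""),
                    "gene": g["name"],
                    "cancer_gene": g["name"] in cancer,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "locus_start", "locus_end", "call", "gene", "cancer_gene"],
    )


def mutation_burden(variants: Mapping[str, Sequence[tuple[str, str]]]) -> dict:
    """Somatic SNV/indel burden over a tumor cohort.

    ``variants`` maps tumor id -> list of (gene, type) with type in
    {"SNV", "indel"}.  Reports the mean mutations per tumor, the fraction of
    tumors carrying >= 1 SNV and >= 1 indel, and genes hit in >= 2 tumors.
    """
    if not variants:
        raise ValueError("mutation_burden needs at least one tumor")
    n = len(variants)
    totals, has_snv, has_indel = [], 0, 0
    gene_tumors: dict[str, set] = defaultdict(set)
    for tumor, muts in variants.items():
        for gene, mtype in muts:
            if mtype not in ("SNV", "indel"):
                raise ValueError(f"unknown variant type {mtype!r} in tumor {tumor!r}")
            gene_tumors[gene].add(tumor)
        totals.append(len(muts))
        has_snv += any(t == "SNV" for _, t in muts)
        has_indel += any(t == "indel" for _, t in muts)
    return {
        "n_tumors": n,
        "mean_mutations_per_tumor": float(np.mean(totals)),
        "frac_with_snv": has_snv / n,
        "frac_with_indel": has_indel / n,
        "recurrent_genes": sorted(g for g, t in gene_tumors.items() if len(t) >= 2),
    }
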