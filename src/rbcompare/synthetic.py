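"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design of a two-species retinoblastoma
comparison: two-group (tumor vs control) log-scale expression matrices on a
mouse-like and a human-like platform joined by a 1:1 ortholog map with a
designed cross-species sign-concordance rate; promoter mark/methylation
scores with shifts coupled to expression direction for a planted set of
epigenetically deregulated genes; per-sample copy-number segment profiles
with planted whole/regional/focal lesions and designed recurrence;
per-cell chromosome-count distributions with designed gain/loss rates;
two-Gaussian chromatid traces with a known peak separation; and comet
profiles with a known tail fraction.

Default sample sizes mirror the source study's array design (27 tumor vs 6
control on the mouse side, 57 vs 8 on the human side); feature counts are
scaled down to a few thousand pairs so everything runs in seconds.  Noise
is independent Gaussian per feature and sample — the simplest model with
the two-group mean-shift structure the agreement statistics assume.
Promoter mark scores are the mean of triplicate simulated ChIP
measurements per condition, reflecting standard ChIP practice; this sets
the per-score noise at noise_sd/sqrt(3).

Every draw comes from one seeded NumPy generator per call: a fixed
SimConfig (including seed) reproduces outputs exactly, and no global state
is touched.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .agdex import CONTROL, TUMOR, ExpressionStudy, OrthologPairSet
from .cnv import Segment, SegmentSet
from .epigenome import ACTIVE_MARKS, MARKS
from .integrity import IntensityProfile, IntensityTrace
from .karyotype import KaryotypeDistribution

# synthetic genome used for segment simulation (chrom -> length in bp)
DEFAULT_GENOME: dict[str, int] = {
    "chr1": 100_000_000,
    "chr2": 90_000_000,
    "chr3": 80_000_000,
    "chr4": 70_000_000,
    "chr5": 60_000_000,
}


@dataclass(frozen=True)
class LesionPlan:
    """One planted copy-number lesion class to place in the cohort."""

    lesion_class: str  # whole | regional | focal
    length_bp: int
    copies: int  # >2 = gain, <2 = loss
    recurrence: int  # number of samples sharing the locus

    @property
    def call(self) -> str:
        return "gain" if self.copies > 2 else "loss"


@dataclass(frozen=True)
class KaryotypePlan:
    n_cells: int = 50
    ref_count: int = 40
    loss_rate: float = 0.1
    gain_rate: float = 0.1


@dataclass(frozen=True)
class TracePlan:
    peak_separation_px: float = 12.0
    peak_sd_px: float = 2.0
    noise_sd: float = 0.02
    n_traces: int = 30
    length_px: int = 101


@dataclass(frozen=True)
class CometPlan:
    tail_fraction: float = 0.3
    head_tail_gap_px: int = 15
    n_profiles: int = 50
    length_px: int = 120


@dataclass
class SimConfig:
    """Study conditions for the synthetic cross-species experiment."""

    seed: int = 0
    n_features_m: int = 4000
    n_features_h: int = 4000
    n_tumor_m: int = 27
    n_ctrl_m: int = 6
    n_tumor_h: int = 57
    n_ctrl_h: int = 8
    concordance_rate: float = 0.7
    de_fraction: float = 0.05
    effect_size: float = 3.0
    noise_sd: float = 1.0
    n_epi_genes: int = 50
    mark_shift: float = 3.0
    n_chip_reps: int = 3
    n_samples_cnv: int = 6
    lesion_plan: tuple[LesionPlan, ...] = (
        LesionPlan("whole", 0, 3, 3),
        LesionPlan("regional", 5_000_000, 1, 2),
        LesionPlan("focal", 500_000, 3, 4),
        LesionPlan("focal", 100_000, 1, 1),
    )
    karyotype_plan: tuple[KaryotypePlan, ...] = (KaryotypePlan(),)
    trace_plan: TracePlan = TracePlan()
    comet_plan: CometPlan = CometPlan()
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))

    def __post_init__(self):
        def bad(name, msg):
            raise ValueError(f"invalid SimConfig.{name}: {msg}")

        for name in ("n_features_m", "n_features_h"):
            if getattr(self, name) < 1:
                bad(name, "must be >= 1")
        for name in ("n_tumor_m", "n_ctrl_m", "n_tumor_h", "n_ctrl_h"):
            if getattr(self, name) < 2:
                bad(name, "each group needs >= 2 samples")
        for name in ("concordance_rate", "de_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                bad(name, "must be in [0, 1]")
        if self.noise_sd <= 0:
            bad("noise_sd", "must be > 0")
        if self.mark_shift < 0:
            bad("mark_shift", "must be >= 0")
        if self.n_epi_genes < 0:
            bad("n_epi_genes", "must be >= 0")
        for plan in self.lesion_plan:
            if plan.lesion_class not in ("whole", "regional", "focal"):
                bad("lesion_plan", f"unknown class {plan.lesion_class!r}")
            if plan.lesion_class != "whole" and plan.length_bp <= 0:
                bad("lesion_plan", "length_bp must be > 0")
            if plan.lesion_class != "whole" and plan.length_bp > max(
                self.genome.values()
            ):
                bad("lesion_plan",
                    f"length {plan.length_bp} exceeds longest chromosome")
            if not 1 <= plan.recurrence <= self.n_samples_cnv:
                bad("lesion_plan",
                    f"recurrence {plan.recurrence} outside [1, n_samples_cnv]")
        for kp in self.karyotype_plan:
            if kp.loss_rate + kp.gain_rate > 1:
                bad("karyotype_plan", "loss_rate + gain_rate must be <= 1")
        if self.trace_plan.peak_separation_px < 2 * self.trace_plan.peak_sd_px:
            bad("trace_plan", "peak_separation_px must be >= 2 * peak_sd_px")
        if not 0 <= self.comet_plan.tail_fraction < 1:
            bad("comet_plan", "tail_fraction must be in [0, 1)")


@dataclass
class TruthTable:
    """Ground truth for every generated object, one record each."""

    features: pd.DataFrame = field(default_factory=pd.DataFrame)
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)
    traces: pd.DataFrame = field(default_factory=pd.DataFrame)
    profiles: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression_pair(
    cfg: SimConfig,
) -> tuple[ExpressionStudy, ExpressionStudy, OrthologPairSet, TruthTable]:
    """Two-species expression studies with a designed concordance rate.

    Ortholog pairs are 1:1 over min(n_features).  A fraction de_fraction of
    pairs is differentially expressed; of those, a fraction
    concordance_rate receives same-sign tumor-mean shifts (+-effect_size)
    in both species and the rest opposite-sign shifts.  Non-DE features
    carry no shift.  With effect_size 0 every truth direction is 'none'.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pairs = min(cfg.n_features_m, cfg.n_features_h)
    ids_m = [f"m{i:05d}" for i in range(cfg.n_features_m)]
    ids_h = [f"h{i:05d}" for i in range(cfg.n_features_h)]
    pairs = OrthologPairSet(list(zip(ids_m[:n_pairs], ids_h[:n_pairs])))

    de = rng.random(n_pairs) < cfg.de_fraction
    if cfg.effect_size == 0:
        de = np.zeros(n_pairs, dtype=bool)
    dir_m = np.where(de, rng.choice([-1, 1], size=n_pairs), 0)
    concordant = np.zeros(n_pairs, dtype=bool)
    concordant[de] = rng.random(int(de.sum())) < cfg.concordance_rate
    dir_h = np.where(de, np.where(concordant, dir_m, -dir_m), 0)

    # planted epigenetically deregulated genes: a subset of the DE mouse
    # features, direction = their expression direction
    epi = np.zeros(n_pairs, dtype=bool)
    de_idx = np.nonzero(de)[0]
    if cfg.n_epi_genes > 0 and de_idx.size > 0:
        chosen = rng.choice(de_idx, size=min(cfg.n_epi_genes, de_idx.size),
                            replace=False)
        epi[chosen] = True

    def build(ids, n_t, n_c, dirs, species):
        n_f = len(ids)
        shifts = np.zeros(n_f)
        shifts[:n_pairs] = dirs * cfg.effect_size
        mat = rng.normal(0.0, cfg.noise_sd, size=(n_f, n_t + n_c))
        mat[:, :n_t] += shifts[:, None]
        labels = [TUMOR] * n_t + [CONTROL] * n_c
        return ExpressionStudy(mat, list(ids), labels, species=species)

    study_m = build(ids_m, cfg.n_tumor_m, cfg.n_ctrl_m, dir_m, "mouse")
    study_h = build(ids_h, cfg.n_tumor_h, cfg.n_ctrl_h, dir_h, "human")

    lab = {1: "up", -1: "down", 0: "none"}
    truth = TruthTable(
        features=pd.DataFrame(
            {
                "feature_m": ids_m[:n_pairs],
                "feature_h": ids_h[:n_pairs],
                "dir_m": [lab[d] for d in dir_m],
                "dir_h": [lab[d] for d in dir_h],
                "de": de,
                "concordant": concordant,
                "epi": epi,
                "epi_direction": [lab[d] if e else "none"
                                  for d, e in zip(dir_m, epi)],
            }
        )
    )
    return study_m, study_h, pairs, truth


def gen_promoter_marks(cfg: SimConfig, truth: TruthTable) -> pd.DataFrame:
    """Tidy promoter mark table (gene/mark/tumor/normal) for mouse genes.

    Planted epi-up genes get +mark_shift on the active marks and
    -mark_shift on H3K9me3 and methylation in tumor vs normal; epi-down the
    converse; every other gene is noise only.  Each condition score is the
    mean of n_chip_reps simulated replicates with sd noise_sd.
    """
    if "epi" not in truth.features.columns:
        raise ValueError("truth table lacks epi flags; run gen_expression_pair first")
    rng = np.random.default_rng(cfg.seed + 1)
    feats = truth.features
    sd = cfg.noise_sd / np.sqrt(max(cfg.n_chip_reps, 1))
    rows = []
    for _, rec in feats.iterrows():
        gene = rec["feature_m"]
        sign = {"up": 1, "down": -1, "none": 0}[rec["epi_direction"]]
        for mark in MARKS:
            if mark in ACTIVE_MARKS:
                shift = sign * cfg.mark_shift
            else:  # repressive mark or methylation moves against expression
                shift = -sign * cfg.mark_shift
            normal = rng.normal(0.0, sd)
            tumor = rng.normal(shift, sd)
            rows.append((gene, mark, tumor, normal))
    return pd.DataFrame(rows, columns=["gene", "mark", "tumor", "normal"])


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

def gen_segments(cfg: SimConfig) -> tuple[list[SegmentSet], TruthTable]:
    """Per-sample segment sets with planted lesion classes and recurrence.

    Recurrence is achieved by placing a lesion at identical coordinates in
    the first `recurrence` samples (cyclically offset per plan entry so
    samples differ).  Lesion positions are drawn to respect the class
    definitions used downstream (whole = full chromosome; regional/focal =
    stated length).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    chroms = list(cfg.genome)
    samples = [f"S{i+1}" for i in range(cfg.n_samples_cnv)]
    per_sample: dict[str, list[Segment]] = {s: [] for s in samples}
    truth_rows = []

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def place(length: int, chrom: str) -> int:
        clen = cfg.genome[chrom]
        if length > clen:
            raise ValueError(
                f"invalid lesion plan: length {length} exceeds {chrom} ({clen} bp)"
            )
        for _ in range(200):
            start = int(rng.integers(0, clen - length + 1))
            if all(start + length <= a or start >= b for a, b in occupied[chrom]):
                occupied[chrom].append((start, start + length))
                return start
        raise RuntimeError("could not place lesion without overlap")

    for li, plan in enumerate(cfg.lesion_plan):
        chrom = chroms[li % len(chroms)]
        if plan.lesion_class == "whole":
            start, length = 0, cfg.genome[chrom]
            occupied[chrom].append((0, length))
        else:
            length = plan.length_bp
            start = place(length, chrom)
        offset = li % cfg.n_samples_cnv
        carriers = [samples[(offset + j) % cfg.n_samples_cnv]
                    for j in range(plan.recurrence)]
        for s in carriers:
            seg = Segment(chrom, start, start + length, plan.call)
            per_sample[s].append(seg)
            truth_rows.append(
                {
                    "sample": s,
                    "chrom": chrom,
                    "start": start,
                    "end": start + length,
                    "call": plan.call,
                    "class": plan.lesion_class,
                    "locus_id": f"L{li}",
                    "recurrence": plan.recurrence,
                }
            )

    sets = [SegmentSet(s, sorted(per_sample[s], key=lambda g: (g.chrom, g.start)))
            for s in samples]
    return sets, TruthTable(segments=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# karyotypes
# ---------------------------------------------------------------------------

def gen_karyotypes(cfg: SimConfig) -> list[KaryotypeDistribution]:
    """Per-sample chromosome-count distributions.

    Each cell keeps the reference count with probability
    1 - loss_rate - gain_rate, otherwise loses or gains 1 + Poisson(1)
    chromosomes.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    out = []
    for si, plan in enumerate(cfg.karyotype_plan):
        u = rng.random(plan.n_cells)
        magnitude = 1 + rng.poisson(1.0, size=plan.n_cells)
        counts = np.full(plan.n_cells, plan.ref_count, dtype=int)
        counts[u < plan.loss_rate] -= magnitude[u < plan.loss_rate]
        gain_mask = (u >= plan.loss_rate) & (u < plan.loss_rate + plan.gain_rate)
        counts[gain_mask] += magnitude[gain_mask]
        counts = np.maximum(counts, 1)
        out.append(
            KaryotypeDistribution(
                counts=Counter(counts.tolist()),
                sample=f"K{si+1}",
                species="mouse" if plan.ref_count == 40 else "human",
            )
        )
    return out


# ---------------------------------------------------------------------------
# traces and comet profiles
# ---------------------------------------------------------------------------

def _gaussian(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def gen_traces(
    cfg: SimConfig,
) -> tuple[list[IntensityTrace], list[IntensityProfile], TruthTable]:
    """Sister-chromatid traces and comet profiles with known truth.

    Traces are two equal Gaussians centred peak_separation_px apart plus
    truncated Gaussian noise.  Comet profiles put 1 - tail_fraction of the
    mass in a head Gaussian and tail_fraction in a tail Gaussian starting
    head_tail_gap_px beyond the head.
    """
    tp, cp = cfg.trace_plan, cfg.comet_plan
    rng = np.random.default_rng(cfg.seed + 4)

    traces, trace_rows = [], []
    x = np.arange(tp.length_px, dtype=float)
    centre = float(tp.length_px // 2)  # integer pixel so peaks land on-grid
    for i in range(tp.n_traces):
        mu1 = centre - tp.peak_separation_px / 2.0
        mu2 = centre + tp.peak_separation_px / 2.0
        vals = _gaussian(x, mu1, tp.peak_sd_px) + _gaussian(x, mu2, tp.peak_sd_px)
        vals = np.clip(vals + rng.normal(0.0, tp.noise_sd, size=x.size), 0, None)
        traces.append(IntensityTrace(vals, sample=f"T{i+1}"))
        trace_rows.append({"trace": f"T{i+1}",
                           "peak_separation_px": tp.peak_separation_px})

    profiles, profile_rows = [], []
    xp = np.arange(cp.length_px, dtype=float)
    head_pos, head_sd, tail_sd = 30.0, 3.0, 5.0
    for i in range(cp.n_profiles):
        head = _gaussian(xp, head_pos, head_sd)
        head *= (1.0 - cp.tail_fraction) / head.sum()
        vals = head
        if cp.tail_fraction > 0:
            tail_pos = head_pos + cp.head_tail_gap_px + 3 * tail_sd
            tail = _gaussian(xp, tail_pos, tail_sd)
            vals = head + cp.tail_fraction * tail / tail.sum()
        profiles.append(IntensityProfile(vals, sample=f"C{i+1}"))
        profile_rows.append({"profile": f"C{i+1}",
                             "tail_fraction": cp.tail_fraction})

    return traces, profiles, TruthTable(
        traces=pd.DataFrame(trace_rows), profiles=pd.DataFrame(profile_rows)
    )
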