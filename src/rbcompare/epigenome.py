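"""Integrative epigenetic-deregulation calls and cross-species overlap.

A gene is called *epigenetically deregulated* when its tumor-vs-normal
expression change is accompanied by a concordant promoter chromatin change:
for an up-regulated gene, a gain of active marks (H3K4me3, H3K9/14Ac) or a
loss of the repressive mark H3K9me3 or of promoter methylation; for a
down-regulated gene the mirror image.  Evidence channels combine by OR —
one concordant channel past its threshold suffices — and discordant-only
evidence never produces a call.  Genes without a significant expression
change are never called (expression gating).

The integration thresholds (tau per channel) are conventions exposed in
``IntegrationConfig``; defaults are set at roughly two null standard
deviations of the corresponding delta under the synthetic generator's
triplicate-averaged noise model.

Cross-species accounting works at the level of ortholog pairs: deregulated
in both species, same direction in both, epigenetically deregulated in
both, and same-direction epi calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .agdex import ExpressionStudy, OrthologPairSet

MARKS = ("H3K4me3", "H3K9/14Ac", "H3K9me3", "methylation")
ACTIVE_MARKS = ("H3K4me3", "H3K9/14Ac")
REPRESSIVE_MARK = "H3K9me3"
METH = "methylation"


@dataclass
class IntegrationConfig:
    fdr_threshold: float = 0.05
    min_abs_logfc: float = 1.0
    tau_active: float = 2.0
    tau_repressive: float = 2.0
    tau_meth: float = 2.0
    promoter_window: tuple[int, int] = (1500, 500)  # (upstream_bp, downstream_bp)

    def __post_init__(self):
        for name in ("fdr_threshold", "min_abs_logfc", "tau_active",
                     "tau_repressive", "tau_meth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CrossSpeciesOverlap:
    n_dereg_species1: int
    n_dereg_species2: int
    n_both: int
    n_both_same_direction: int
    n_epi_1: int
    n_epi_2: int
    n_epi_both: int
    n_epi_both_same_direction: int
    n_unmapped_pairs: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def promoter_signal(
    probe_signals: pd.Series,
    probe_coords: pd.DataFrame,
    gene_tss: pd.DataFrame,
    cfg: IntegrationConfig | None = None,
) -> pd.Series:
    """Mean probe signal in each gene's strand-aware promoter window.

    ``probe_signals`` is indexed by probe id; ``probe_coords`` has columns
    chrom/start/end (0-based half-open) indexed the same way; ``gene_tss``
    has columns chrom/tss/strand indexed by gene.  For a plus-strand gene
    with TSS t the window is [t - upstream, t + downstream); for a
    minus-strand gene upstream extends toward higher coordinates:
    [t - downstream + 1, t + upstream + 1).  Probes overlapping the window
    by >= 1 bp contribute.  Genes with no probe in the window are returned
    as NaN (missing), never zero.
    """
    cfg = cfg or IntegrationConfig()
    up, down = cfg.promoter_window
    if not probe_signals.index.equals(probe_coords.index):
        probe_coords = probe_coords.loc[probe_signals.index]
    if (probe_coords["start"] >= probe_coords["end"]).any():
        bad = probe_coords[probe_coords["start"] >= probe_coords["end"]].index[:5]
        raise ValueError(f"probe intervals with start >= end: {list(bad)}")

    out = {}
    for gene, row in gene_tss.iterrows():
        t = int(row["tss"])
        strand = row["strand"]
        if strand == "+":
            w_start, w_end = t - up, t + down
        elif strand == "-":
            w_start, w_end = t - down + 1, t + up + 1
        else:
            raise ValueError(f"gene {gene!r} has invalid strand {strand!r}")
        mask = (
            (probe_coords["chrom"] == row["chrom"])
            & (probe_coords["start"] < w_end)
            & (probe_coords["end"] > w_start)
        )
        out[gene] = float(probe_signals[mask].mean()) if mask.any() else np.nan
    return pd.Series(out, name="promoter_signal")


def call_expression(
    study: ExpressionStudy, cfg: IntegrationConfig | None = None
) -> pd.DataFrame:
    """Per-gene up/down/none calls by two-sample t-test with BH adjustment.

    'up' requires BH-adjusted p <= fdr_threshold and logFC >= min_abs_logfc
    (input assumed log-scale, logFC = difference of group means); 'down' is
    symmetric.  The pooled-variance (Student) t is used: with the common
    unbalanced array designs (e.g. 27 tumors vs 6 controls) the Welch
    approximation has very few degrees of freedom and loses substantial
    power, while homoscedastic log-scale noise is the standard working
    assumption.  Genes where the test is degenerate (zero variance in both
    groups with equal means) are reported non-significant and flagged.
    """
    cfg = cfg or IntegrationConfig()
    tmask = study.tumor_mask
    t_mat = study.matrix[:, tmask]
    c_mat = study.matrix[:, ~tmask]
    logfc = t_mat.mean(axis=1) - c_mat.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(t_mat, c_mat, axis=1, equal_var=True)
    degenerate = ~np.isfinite(pvals)
    pvals = np.where(degenerate, 1.0, pvals)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")

    call = np.where(
        (padj <= cfg.fdr_threshold) & (logfc >= cfg.min_abs_logfc), "up",
        np.where((padj <= cfg.fdr_threshold) & (logfc <= -cfg.min_abs_logfc),
                 "down", "none"),
    )
    return pd.DataFrame(
        {
            "logfc": logfc,
            "pvalue": pvals,
            "padj": padj,
            "call": call,
            "degenerate": degenerate,
        },
        index=study.feature_ids,
    )


def mark_deltas(marks: pd.DataFrame) -> pd.DataFrame:
    """Tumor-minus-normal delta per gene and mark.

    ``marks`` is tidy with columns gene/mark/tumor/normal (one row per
    gene x mark).  Returns a gene x mark frame of deltas.
    """
    required = {"gene", "mark", "tumor", "normal"}
    if not required.issubset(marks.columns):
        raise ValueError(f"mark table needs columns {sorted(required)}")
    delta = marks.assign(delta=marks["tumor"] - marks["normal"]).pivot(
        index="gene", columns="mark", values="delta"
    )
    missing_marks = set(MARKS) - set(delta.columns)
    if missing_marks:
        raise ValueError(f"mark table missing marks {sorted(missing_marks)}")
    return delta[list(MARKS)]


def classify_epigenetic(
    expr_calls: pd.DataFrame,
    deltas: pd.DataFrame,
    cfg: IntegrationConfig | None = None,
) -> pd.DataFrame:
    """Per-gene epigenetic-deregulation calls.

    epi-up requires expression call 'up' AND at least one concordant
    channel: mean active-mark delta >= tau_active, OR H3K9me3 delta
    <= -tau_repressive, OR methylation delta <= -tau_meth.  epi-down is the
    mirror.  Genes with any missing mark value are excluded (status
    'missing-marks'); genes absent from the delta table likewise.
    Discordant-only evidence yields 'not-epi'.
    """
    cfg = cfg or IntegrationConfig()
    rows = []
    for gene, erow in expr_calls.iterrows():
        expr = erow["call"]
        rec: dict = {"gene": gene, "expr_call": expr, "epi_call": "not-epi",
                     "status": "ok", "active_evidence": False,
                     "repressive_evidence": False, "meth_evidence": False}
        if gene not in deltas.index or deltas.loc[gene].isna().any():
            rec["status"] = "missing-marks"
            rec["epi_call"] = "not-epi"
            rows.append(rec)
            continue
        d = deltas.loc[gene]
        d_active = float(np.mean([d[m] for m in ACTIVE_MARKS]))
        d_rep = float(d[REPRESSIVE_MARK])
        d_meth = float(d[METH])
        if expr == "up":
            ev = {
                "active_evidence": d_active >= cfg.tau_active,
                "repressive_evidence": d_rep <= -cfg.tau_repressive,
                "meth_evidence": d_meth <= -cfg.tau_meth,
            }
            if any(ev.values()):
                rec["epi_call"] = "epi-up"
            rec.update(ev)
        elif expr == "down":
            ev = {
                "active_evidence": d_active <= -cfg.tau_active,
                "repressive_evidence": d_rep >= cfg.tau_repressive,
                "meth_evidence": d_meth >= cfg.tau_meth,
            }
            if any(ev.values()):
                rec["epi_call"] = "epi-down"
            rec.update(ev)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene")


def cross_species_overlap(
    calls1: pd.DataFrame,
    calls2: pd.DataFrame,
    pairs: OrthologPairSet,
) -> CrossSpeciesOverlap:
    """Fig.-style overlap accounting over ortholog pairs.

    ``calls1``/``calls2`` are classify_epigenetic outputs (or any frames
    with expr_call and epi_call indexed by gene).  Species-level counts
    (n_dereg, n_epi) are over all genes of that species; the *both* counts
    are over ortholog pairs where both sides are resolvable.  Pairs with an
    unresolvable gene are excluded and counted in n_unmapped_pairs.
    """
    def dereg(call):  # expression-deregulated
        return call in ("up", "down")

    def epi(call):
        return call in ("epi-up", "epi-down")

    n1 = int(calls1["expr_call"].isin(["up", "down"]).sum())
    n2 = int(calls2["expr_call"].isin(["up", "down"]).sum())
    e1 = int(calls1["epi_call"].isin(["epi-up", "epi-down"]).sum())
    e2 = int(calls2["epi_call"].isin(["epi-up", "epi-down"]).sum())

    n_both = n_both_same = n_epi_both = n_epi_both_same = unmapped = 0
    for g1, g2 in pairs.pairs:
        if g1 not in calls1.index or g2 not in calls2.index:
            unmapped += 1
            continue
        c1, c2 = calls1.loc[g1], calls2.loc[g2]
        if dereg(c1["expr_call"]) and dereg(c2["expr_call"]):
            n_both += 1
            if c1["expr_call"] == c2["expr_call"]:
                n_both_same += 1
        if epi(c1["epi_call"]) and epi(c2["epi_call"]):
            n_epi_both += 1
            if c1["epi_call"] == c2["epi_call"]:
                n_epi_both_same += 1
    return CrossSpeciesOverlap(
        n_dereg_species1=n1,
        n_dereg_species2=n2,
        n_both=n_both,
        n_both_same_direction=n_both_same,
        n_epi_1=e1,
        n_epi_2=e2,
        n_epi_both=n_epi_both,
        n_epi_both_same_direction=n_epi_both_same,
        n_unmapped_pairs=unmapped,
    )
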