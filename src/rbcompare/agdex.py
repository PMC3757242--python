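"""Agreement of differential expression (AGDEX) across two species.

Given tumor-vs-control expression studies in two species and a map of
ortholog-matched features (probe-set pairs), AGDEX asks whether expression
changes agree across species.  Per species a differential vector d is
computed (difference of group means on log-scale data by default, or a
Welch t-statistic).  Over the ortholog-aligned pair vectors (x, y):

* cosine statistic:  sum(x_k y_k) / (||x|| ||y||)
* dop (difference of proportions):  P(sign concordant) - P(sign discordant)
  among pairs where both entries are nonzero
* agreement proportion:  fraction sign-concordant = (dop + 1) / 2

Inference is by permutation of one study's group labels at a time (the
other study's d held fixed), two-sided on |statistic|, with the add-one
convention p = (1 + #exceedances) / (1 + B).  Gene-set analysis runs both
statistics under both permutation schemes and flags a set as robustly
significant only when all four p-values clear the significance level —
a conservative rule that guards against artifacts specific to one species'
sample structure.  Adaptive (sequential) permutation stops early for
clearly null sets once the exceedance count reaches a threshold r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

TUMOR, CONTROL = "tumor", "control"


@dataclass
class ExpressionStudy:
    """Two-group expression matrix (features x samples) for one species."""

    matrix: np.ndarray
    feature_ids: list[str]
    sample_labels: list[str]  # TUMOR / CONTROL per column
    species: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-D (features x samples)")
        if self.matrix.shape[0] != len(self.feature_ids):
            raise ValueError("feature_ids length does not match matrix rows")
        if self.matrix.shape[1] != len(self.sample_labels):
            raise ValueError("sample_labels length does not match matrix columns")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("expression matrix contains non-finite values")
        bad = set(self.sample_labels) - {TUMOR, CONTROL}
        if bad:
            raise ValueError(f"sample labels must be tumor/control, got {sorted(bad)}")
        for g in (TUMOR, CONTROL):
            if self.sample_labels.count(g) < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")

    @property
    def tumor_mask(self) -> np.ndarray:
        return np.asarray([lab == TUMOR for lab in self.sample_labels])


@dataclass
class OrthologPairSet:
    """Ortholog-matched feature pairs (species1 id, species2 id).

    Duplicates are allowed: many-to-many maps are kept as independent
    pairs, matching the probe-set-pair unit of analysis.
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AgdexConfig:
    B_min: int = 100
    B_max: int = 10_000
    alpha: float = 0.01
    exceedance_threshold: int = 10  # adaptive stopping rule
    block: int = 100

    def __post_init__(self):
        if self.B_min > self.B_max:
            raise ValueError("B_min must be <= B_max")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.exceedance_threshold < 1:
            raise ValueError("exceedance_threshold must be >= 1")


# ---------------------------------------------------------------------------
# differential statistics
# ---------------------------------------------------------------------------

def _group_diff(matrix: np.ndarray, tumor_mask: np.ndarray, method: str) -> np.ndarray:
    t = matrix[:, tumor_mask]
    c = matrix[:, ~tumor_mask]
    if method == "mean_diff":
        return t.mean(axis=1) - c.mean(axis=1)
    if method == "tstat":
        # Welch t; zero-variance features yield d = 0 when means are equal
        nt, nc = t.shape[1], c.shape[1]
        num = t.mean(axis=1) - c.mean(axis=1)
        se = np.sqrt(t.var(axis=1, ddof=1) / nt + c.var(axis=1, ddof=1) / nc)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = num / se
        d[(se == 0) & (num == 0)] = 0.0
        d[(se == 0) & (num != 0)] = np.sign(num[(se == 0) & (num != 0)]) * np.inf
        return d
    raise ValueError(f"unknown differential statistic {method!r}")


def diff_stat(study: ExpressionStudy, method: str = "mean_diff") -> pd.Series:
    """Per-feature tumor-vs-control differential statistic."""
    d = _group_diff(study.matrix, study.tumor_mask, method)
    return pd.Series(d, index=study.feature_ids, name=f"d_{study.species or 'study'}")


def match_pairs(
    d1: pd.Series, d2: pd.Series, pairs: OrthologPairSet
) -> tuple[np.ndarray, np.ndarray]:
    """Align two differential vectors along the ortholog pair list."""
    missing1 = [a for a, _ in pairs.pairs if a not in d1.index]
    missing2 = [b for _, b in pairs.pairs if b not in d2.index]
    if missing1 or missing2:
        raise KeyError(
            f"unresolvable ortholog IDs: species1 {sorted(set(missing1))[:5]}, "
            f"species2 {sorted(set(missing2))[:5]}"
        )
    if not pairs.pairs:
        return np.empty(0), np.empty(0)
    ids1, ids2 = zip(*pairs.pairs)
    return d1.loc[list(ids1)].to_numpy(), d2.loc[list(ids2)].to_numpy()


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def cosine_stat(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("cosine_stat needs two equal-length non-empty vectors")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ZeroDivisionError("cosine undefined for a zero-norm vector")
    return float(x @ y / (nx * ny))


def dop_stat(x: np.ndarray, y: np.ndarray) -> float:
    """Difference of sign-concordance proportions over both-nonzero pairs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    both = (x != 0) & (y != 0)
    n = int(both.sum())
    if n == 0:
        raise ZeroDivisionError("dop undefined: no pair with both entries nonzero")
    s = np.sign(x[both]) * np.sign(y[both])
    return float((s > 0).sum() - (s < 0).sum()) / n


def agreement_proportion(x: np.ndarray, y: np.ndarray) -> float:
    """Fraction of sign-concordant pairs among both-nonzero pairs.

    Equals (dop + 1) / 2.
    """
    return (dop_stat(x, y) + 1.0) / 2.0


_STATS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "cosine": cosine_stat,
    "dop": dop_stat,
}


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def _permuted_diffs(
    study: ExpressionStudy, B: int, rng: np.random.Generator, method: str
) -> np.ndarray:
    """(features x B) matrix of differential vectors under label permutation."""
    n = len(study.sample_labels)
    n_t = int(study.tumor_mask.sum())
    masks = np.zeros((n, B), dtype=bool)
    for b in range(B):
        masks[rng.permutation(n)[:n_t], b] = True
    X = study.matrix
    if method == "mean_diff":
        w = masks / n_t - (~masks) / (n - n_t)
        return X @ w
    out = np.empty((X.shape[0], B))
    for b in range(B):
        out[:, b] = _group_diff(X, masks[:, b], method)
    return out


def _stat_on_columns(stat: str, d_perm: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Vectorized statistic over permutation columns paired with a fixed vector."""
    if stat == "cosine":
        norms = np.linalg.norm(d_perm, axis=0)
        nf = np.linalg.norm(fixed)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = (fixed @ d_perm) / (norms * nf)
        vals[~np.isfinite(vals)] = 0.0
        return vals
    if stat == "dop":
        sp = np.sign(d_perm)
        sf = np.sign(fixed)[:, None]
        both = (sp != 0) & (sf != 0)
        prod = sp * sf
        n = both.sum(axis=0)
        conc = ((prod > 0) & both).sum(axis=0)
        disc = ((prod < 0) & both).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = (conc - disc) / n
        vals = np.where(n == 0, 0.0, vals)
        return vals
    raise ValueError(f"unknown statistic {stat!r}")


def _perm_setup(
    studyA: ExpressionStudy,
    studyB: ExpressionStudy,
    pairs: OrthologPairSet,
    scheme: str,
    method: str,
):
    """Resolve which study is permuted and precompute pair index arrays."""
    if scheme not in ("A", "B"):
        raise ValueError("scheme must be 'A' (permute study A) or 'B'")
    dA = diff_stat(studyA, method)
    dB = diff_stat(studyB, method)
    x, y = match_pairs(dA, dB, pairs)
    permuted_study = studyA if scheme == "A" else studyB
    idx_map = {fid: i for i, fid in enumerate(permuted_study.feature_ids)}
    col = 0 if scheme == "A" else 1
    perm_idx = np.asarray([idx_map[p[col]] for p in pairs.pairs], dtype=int)
    fixed = y if scheme == "A" else x
    obs = {name: f(x, y) for name, f in _STATS.items()}
    return permuted_study, perm_idx, fixed, obs


def permutation_pvalue(
    studyA: ExpressionStudy,
    studyB: ExpressionStudy,
    pairs: OrthologPairSet,
    statistic: str = "cosine",
    scheme: str = "A",
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
    method: str = "mean_diff",
) -> float:
    """Two-sided permutation p-value for an agreement statistic.

    Only the named study's group labels are permuted; the other study's
    differential vector is held fixed.  p = (1 + #{|stat_b| >= |stat_obs|})
    / (1 + B), so p >= 1/(B+1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(rng)
    permuted_study, perm_idx, fixed, obs = _perm_setup(
        studyA, studyB, pairs, scheme, method
    )
    d_perm = _permuted_diffs(permuted_study, B, rng, method)[perm_idx, :]
    vals = _stat_on_columns(statistic, d_perm, fixed)
    exceed = int((np.abs(vals) >= abs(obs[statistic]) - 1e-12).sum())
    return (1 + exceed) / (1 + B)


def adaptive_permutation_pvalue(
    studyA: ExpressionStudy,
    studyB: ExpressionStudy,
    pairs: OrthologPairSet,
    statistic: str = "cosine",
    scheme: str = "A",
    cfg: AgdexConfig | None = None,
    rng: np.random.Generator | int | None = None,
    method: str = "mean_diff",
) -> tuple[float, int]:
    """Sequential permutation p-value with early stopping.

    Runs B_min permutations; once the exceedance count reaches the
    threshold r the statistic is clearly compatible with the null and the
    run stops, otherwise permutation continues in blocks up to B_max.
    Returns (p, B_used) with p = (1 + exceedances) / (1 + B_used).
    """
    cfg = cfg or AgdexConfig()
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(rng)
    permuted_study, perm_idx, fixed, obs = _perm_setup(
        studyA, studyB, pairs, scheme, method
    )
    target = abs(obs[statistic]) - 1e-12
    exceed, used = 0, 0
    while used < cfg.B_max:
        if used == 0:
            b = cfg.B_min
        else:
            b = min(cfg.block, cfg.B_max - used)
        d_perm = _permuted_diffs(permuted_study, b, rng, method)[perm_idx, :]
        vals = _stat_on_columns(statistic, d_perm, fixed)
        exceed += int((np.abs(vals) >= target).sum())
        used += b
        if exceed >= cfg.exceedance_threshold:
            break
    return (1 + exceed) / (1 + used), used


# ---------------------------------------------------------------------------
# genome-wide and gene-set analysis
# ---------------------------------------------------------------------------

def genomewide_agdex(
    studyA: ExpressionStudy,
    studyB: ExpressionStudy,
    pairs: OrthologPairSet,
    B: int = 10_000,
    rng: np.random.Generator | int | None = None,
    method: str = "mean_diff",
) -> dict:
    """Genome-wide cosine/dop/agreement with four permutation p-values."""
    rng = np.random.default_rng(rng)
    dA = diff_stat(studyA, method)
    dB = diff_stat(studyB, method)
    x, y = match_pairs(dA, dB, pairs)
    out = {
        "n_pairs": len(pairs),
        "cosine": cosine_stat(x, y),
        "dop": dop_stat(x, y),
        "agreement_proportion": agreement_proportion(x, y),
    }
    for stat in ("cosine", "dop"):
        for scheme in ("A", "B"):
            out[f"p_{stat}_perm{scheme}"] = permutation_pvalue(
                studyA, studyB, pairs, stat, scheme, B, rng, method
            )
    return out


def geneset_agdex(
    studyA: ExpressionStudy,
    studyB: ExpressionStudy,
    pairs: OrthologPairSet,
    genesets: Mapping[str, Sequence[str]],
    cfg: AgdexConfig | None = None,
    rng: np.random.Generator | int | None = None,
    method: str = "mean_diff",
    member_side: str = "B",
) -> pd.DataFrame:
    """Per-gene-set agreement statistics and the four-test significance rule.

    ``genesets`` maps a set name to member feature IDs on one platform
    (``member_side``: 'A' or 'B'); members are mapped to ortholog pairs via
    the pair list.  Per set: cosine, dop, four adaptive permutation
    p-values (2 statistics x 2 permutation schemes), and a
    ``robust_significant`` flag true only when all four p <= alpha.
    Sets with < 2 mapped pairs are reported with status 'skipped'.
    """
    cfg = cfg or AgdexConfig()
    rng = np.random.default_rng(rng)
    names = list(genesets)
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene-set names")
    if member_side not in ("A", "B"):
        raise ValueError("member_side must be 'A' or 'B'")
    col = 0 if member_side == "A" else 1
    dA = diff_stat(studyA, method)
    dB = diff_stat(studyB, method)

    rows = []
    for name in names:
        members = set(genesets[name])
        sub = OrthologPairSet([p for p in pairs.pairs if p[col] in members])
        row: dict = {"set": name, "n_pairs": len(sub)}
        if len(sub) < 2:
            row.update(status="skipped", robust_significant=False)
            rows.append(row)
            continue
        x, y = match_pairs(dA, dB, sub)
        try:
            row["cosine"] = cosine_stat(x, y)
            row["dop"] = dop_stat(x, y)
        except ZeroDivisionError:
            row.update(status="skipped", robust_significant=False)
            rows.append(row)
            continue
        pvals = {}
        for stat in ("cosine", "dop"):
            for scheme in ("A", "B"):
                p, b_used = adaptive_permutation_pvalue(
                    studyA, studyB, sub, stat, scheme, cfg, rng, method
                )
                pvals[f"p_{stat}_perm{scheme}"] = p
                row[f"B_{stat}_perm{scheme}"] = b_used
        row.update(pvals)
        row["status"] = "ok"
        row["robust_significant"] = all(p <= cfg.alpha for p in pvals.values())
        rows.append(row)
    return pd.DataFrame(rows)
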