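# Methods

This note records the statistical models, conventions and numerical choices
behind each module, what the synthetic generator does and does not emulate,
and the known limitations.

## Cross-species agreement of differential expression

Per species, the differential statistic is the difference of tumor and
control group means on log-scale expression (`d_i = mean_tumor −
mean_control`). A standardized (Welch-t) alternative is available via
`method="tstat"`; the mean difference is the default because the agreement
statistics are sign- and direction-based and the simple difference is the
least model-laden choice. Ortholog pairs are treated as independent units
even when maps are many-to-many — the unit of analysis is the probe-set
pair, not the gene.

Over aligned pair vectors (x, y):

- cosine = Σxₖyₖ / (‖x‖‖y‖), sensitive to magnitude agreement;
- dop = (#concordant − #discordant) / #both-nonzero, pure sign agreement.
  Pairs where either entry is exactly zero are excluded from the
  denominator, which avoids assigning a sign arbitrarily; with continuous
  data this exclusion almost never triggers;
- agreement proportion = (dop + 1) / 2.

**Permutation inference.** Only one study's group labels are permuted per
scheme; the other study's differential vector stays fixed. Tests are
two-sided on |stat| with the add-one estimator p = (1 + #{|stat_b| ≥
|stat_obs|}) / (1 + B), so p ≥ 1/(B+1) and p-values are valid (never
anti-conservative) at any B. Gene-set scans use adaptive permutation:
B_min = 100 permutations first, then blocks of 100 up to B_max = 10 000,
stopping once the exceedance count reaches r = 10 — clearly null sets cost
100 permutations, interesting sets get full resolution. r = 10 is the
standard sequential-permutation choice; it is exposed in `AgdexConfig`.
A gene set is flagged *robustly significant* only when all four p-values
(cosine and dop, each under both permutation schemes) are ≤ α = 0.01; this
conservative AND-rule suppresses artifacts tied to one species' sample
structure.

Two properties of this inference are worth knowing. First, with small
balanced groups the exact permutation distribution is coarse (3v3 labels
admit only ~10 distinct |stat| values), so attainable p-values are floored
around 0.1 — unit tests that probe calibration use ≥5 samples per group.
Second, when planted effects dwarf the noise, permutations that partially
overlap the true grouping retain near-perfect sign concordance and put an
irreducible floor (about 2% at 10v10) under the dop permutation p-value;
this is a property of permutation tests under extreme signal, not a
defect, and the four-test demonstration in the test suite therefore uses
moderate (≈2-fold) planted effects.

## Integrative epigenetic calls

Expression calls use a pooled-variance two-sample t per gene with
Benjamini–Hochberg adjustment; a gene is "up" when adjusted p ≤ 0.05 and
log-FC ≥ 1 (log₂ scale), "down" symmetrically. The pooled t was chosen
over Welch deliberately: array designs here are heavily unbalanced (27
tumors vs 6 controls), where Welch's approximation has ~6 degrees of
freedom and loses substantial power, while homoscedastic log-scale noise
is the standard working assumption. Genes with zero variance in both
groups and equal means are flagged degenerate and reported non-significant.

A gene is epigenetically deregulated when its expression call is
accompanied by at least one concordant promoter-chromatin channel
(OR-rule): for "up", mean(ΔH3K4me3, ΔH3K9/14Ac) ≥ τ_active, or ΔH3K9me3 ≤
−τ_rep, or Δmethylation ≤ −τ_meth, with Δ = tumor − normal; "down"
mirrored. Discordant-only evidence never produces a call, and genes
without an expression call are never called (expression gating) — raising
any τ therefore never converts not-epi into epi (monotonicity, property-
tested). The thresholds default to 2.0, roughly two null standard
deviations of the per-channel delta under the generator's
triplicate-averaged noise model; all are exposed in `IntegrationConfig`
because the integration rule itself is a reconstruction — published
integrative analyses rarely restate their exact criteria, so the printed
gene counts of any particular study are context, not targets, for this
implementation.

Promoter windows are (−1500, +500) around the TSS, strand-aware, 0-based
half-open; for minus-strand genes "upstream" extends toward higher genome
coordinates. Genes with no probe in the window are missing, never zero.

Cross-species overlap counts operate on ortholog pairs: deregulated in
both, same direction in both, epigenetically deregulated in both, same
direction among those. Invariants (n_epi_both ≤ min of the sides, same-
direction ≤ both) are asserted on every synthetic run.

## Karyotype metrics

Count strings `"count(n_cells)"` parse into multisets. Relative to a
reference count r: pct_gain = 100·#{cells > r}/n, pct_loss = 100·#{cells <
r}/n, pct_aneuploid = pct_gain + pct_loss, retention = #{cells = r}/n.
Percentages display rounded half-up to one decimal (an integer mode
matches tables that print whole percent). Two reference policies: species
diploid (40 mouse / 46 human) for primary tumors, and the modal count for
clonal lines and xenograft sublines whose founder karyotype is aberrant;
modal ties break toward the diploid number, then toward the smaller count.

Count-based metrics cannot see balanced events (a gain plus a loss in one
cell) or structural aberrations; published event-based gain/deletion
columns can therefore exceed the count-based values, and a published
model-based "retention probability" need not equal the count-based
retention fraction. This module reports the count-based quantities and
labels them as such.

Clone-heterogeneity comparisons test per-cell absolute deviation from the
clone's modal count, pooled across a group's clones (rank-sum for two
groups, Kruskal–Wallis for more). The cell is the observation unit because
typical designs (3 clones per group) make a clone-level rank test unable
to reach conventional significance (exact two-sided minimum p = 0.1 for
3v3). Per-clone descriptives (distinct counts, variance, fraction
non-modal) are still reported.

## Copy-number lesion classes

Classes partition by length L and chromosome length C: whole if L ≥ 0.9·C
(arrays rarely reach telomeres, so full length is not required; the 0.9 is
configurable), else regional if L ≥ 3 Mb, else focal if L ≥ 20 kb, else
sub-threshold. The focal interval is half-open at the top ([20 kb, 3 Mb)),
so an exactly 3 Mb lesion is regional. Recurrence requires same-call-type
lesions in ≥ k samples with ≥ 50% reciprocal overlap (default, exposed);
a recurrent locus is reported as the intersection interval of its
supporters. Coordinates are 0-based half-open internally; SEG input
(1-based inclusive) converts on read and back on write.

## Genome-integrity metrics

Sister-chromatid distance: traces are smoothed with a 3 px moving average
(reflect-padded so peak positions are not dragged toward edges), local
maxima at least 4 px apart are located, and the two highest give the
distance. Fewer than two qualifying maxima yields a no-measurement result
(None), deliberately distinct from zero.

Olive tail moment: the head ends where the smoothed profile first falls
below 10% of its peak on the tail side; pixels below that threshold
anywhere are treated as background and zeroed, the convention of
comet-scoring software — without it the sub-threshold flank of any smooth
peak would register as spurious tail mass. OTM = tail fraction ×
(tail centroid − head centroid), clipped at zero; an extent-tail-moment
variant (tail fraction × tail length) is provided because published work
often names only its scoring software, leaving the variant ambiguous —
Olive is the default. Both metrics are invariant under uniform intensity
scaling. The 10% boundary clips real mass from a diffuse Gaussian tail,
biasing measured tail fraction low by ≈0.02 at the generator's default
geometry; recovery tests therefore use a stated tolerance of 0.05
absolute. Repair kinetics compare each post-irradiation timepoint to
baseline with a one-sided rank test; "repaired" means not significantly
above baseline at α = 0.05.

## Synthetic data: what it emulates, and what it does not

The generator mirrors a two-species retinoblastoma array study: mouse-like
platform with 27 tumor vs 6 control samples, human-like with 57 vs 8
(feature counts scaled to 4000 pairs so the whole suite runs in seconds).
Noise is independent Gaussian per feature and sample (σ = 1 on the log
scale); 5% of ortholog pairs are differentially expressed by default with
mean shift ±3 (≈8-fold, the size of robust tumor-signature genes — chosen
so planted genes sit comfortably above the expression-call filter rather
than at its boundary) and a designed concordance rate of 0.7. Promoter
mark scores are means of triplicate simulated ChIP measurements per
condition (per-score noise σ/√3), with planted shifts of 3σ coupled to the
expression direction of 50 planted epi-genes. Lesions are placed at
identical coordinates across the requested number of samples on a
five-chromosome toy genome; karyotypes perturb a reference count with
designed loss/gain rates and magnitude 1 + Poisson(1); traces are two
Gaussians (separation 12 px, σ 2 px) centred on integer pixels; comet
profiles put a designed fraction of mass in a resolved tail. All draws
come from one seeded NumPy generator per call — a fixed `SimConfig`
reproduces outputs exactly.

Not emulated: probe-level array artifacts and normalization (inputs are
taken as normalized log scale), correlated noise and batch effects,
many-to-many ortholog maps (accepted downstream, not generated),
2-D comet images (profiles are pre-projected), and structural karyotype
events. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated noise model, not robustness to every artifact
of real array data.

## Problem sizes

Defaults throughout were chosen so the full test suite runs in well under
a minute and the acceptance script in seconds: 4000 ortholog pairs, B =
1000 permutations genome-wide, 500 null replicates (B ≤ 1000, adaptive)
for the four-test type-I check, 30 traces and 50 comet profiles. These are
the package's validation sizes; every routine accepts larger inputs
unchanged.
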