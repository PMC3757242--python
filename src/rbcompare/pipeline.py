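"""End-to-end orchestration: simulate inputs, run every stage, manifest.

``simulate_to_dir`` materializes one synthetic study (expression pair,
ortholog map, promoter marks, segments, karyotypes, traces, comet
profiles, truth) as plain-text files.  ``run_pipeline`` consumes such a
directory (or equivalent real inputs), runs the agreement, integration,
karyotype, copy-number and integrity stages, and writes every output plus
a manifest with content hashes so that identical config + seed yields an
identical, verifiable run.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import agdex, cnv, epigenome, integrity, io, karyotype, synthetic


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    indir: Path
    outdir: Path
    seed: int = 0
    agdex_B: int = 1000
    agdex_cfg: agdex.AgdexConfig | None = None
    integration_cfg: epigenome.IntegrationConfig | None = None
    thresholds: cnv.LesionThresholds | None = None
    karyotype_ref: str | int = "modal"
    recurrence_k: int = 2
    min_reciprocal_overlap: float = 0.5
    genesets: Path | None = None


def simulate_to_dir(cfg: synthetic.SimConfig, outdir: str | Path) -> dict[str, str]:
    """Generate one synthetic study and write it under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study_m, study_h, pairs, truth = synthetic.gen_expression_pair(cfg)
    marks = synthetic.gen_promoter_marks(cfg, truth)
    seg_sets, seg_truth = synthetic.gen_segments(cfg)
    karyos = synthetic.gen_karyotypes(cfg)
    traces, profiles, trace_truth = synthetic.gen_traces(cfg)

    def expr_df(study):
        cols = [f"{lab}{i+1}" for i, lab in enumerate(study.sample_labels)]
        return pd.DataFrame(study.matrix, index=study.feature_ids, columns=cols)

    def labels_df(study):
        cols = [f"{lab}{i+1}" for i, lab in enumerate(study.sample_labels)]
        return pd.DataFrame({"sample": cols, "label": study.sample_labels})

    io.write_matrix(expr_df(study_m), outdir / "expr_mouse.tsv")
    io.write_tsv(labels_df(study_m), outdir / "labels_mouse.tsv")
    io.write_matrix(expr_df(study_h), outdir / "expr_human.tsv")
    io.write_tsv(labels_df(study_h), outdir / "labels_human.tsv")
    io.write_ortholog_map(pairs, outdir / "orthologs.tsv")
    io.write_tsv(marks, outdir / "promoter_marks.tsv")
    io.write_segments(seg_sets, outdir / "segments.seg")
    io.write_tsv(
        pd.DataFrame(
            {
                "sample": [k.sample for k in karyos],
                "species": [k.species for k in karyos],
                "count_string": [k.to_string() for k in karyos],
            }
        ),
        outdir / "karyotypes.tsv",
    )
    io.write_traces(
        [(t.sample, t.treatment or "colcemid-4hr", t.values) for t in traces],
        outdir / "traces.tsv",
    )
    io.write_traces(
        [(p.sample, p.timepoint or "pre-IR", p.values) for p in profiles],
        outdir / "comet_profiles.tsv",
    )
    io.write_tsv(
        pd.DataFrame(
            {"chrom": list(cfg.genome), "length": list(cfg.genome.values())}
        ),
        outdir / "genome.tsv",
    )
    truth_obj = {
        "features": truth.features.to_dict(orient="list"),
        "segments": seg_truth.segments.to_dict(orient="list"),
        "traces": trace_truth.traces.to_dict(orient="list"),
        "profiles": trace_truth.profiles.to_dict(orient="list"),
        "seed": cfg.seed,
    }
    io.write_json(truth_obj, outdir / "truth.json")
    return {p.name: _sha256(p) for p in sorted(outdir.iterdir())}


def load_study(expr_path, labels_path, species="") -> agdex.ExpressionStudy:
    expr = io.read_matrix(expr_path)
    labels = pd.read_csv(labels_path, sep="\t")
    lab_map = dict(zip(labels["sample"], labels["label"]))
    try:
        sample_labels = [lab_map[c] for c in expr.columns]
    except KeyError as exc:
        raise ValueError(f"sample {exc} in matrix but not in labels file") from exc
    return agdex.ExpressionStudy(
        expr.to_numpy(), list(expr.index), sample_labels, species=species
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on the inputs in ``cfg.indir``; return the manifest."""
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    required = [
        "expr_mouse.tsv", "labels_mouse.tsv", "expr_human.tsv",
        "labels_human.tsv", "orthologs.tsv", "promoter_marks.tsv",
        "segments.seg", "karyotypes.tsv", "traces.tsv",
        "comet_profiles.tsv", "genome.tsv",
    ]
    for name in required:
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing pipeline input: {indir / name}")

    rng = np.random.default_rng(cfg.seed)
    stage = "load"
    try:
        study_m = load_study(indir / "expr_mouse.tsv", indir / "labels_mouse.tsv", "mouse")
        study_h = load_study(indir / "expr_human.tsv", indir / "labels_human.tsv", "human")
        pairs = io.read_ortholog_map(indir / "orthologs.tsv")

        stage = "agdex"
        summary = agdex.genomewide_agdex(study_m, study_h, pairs, B=cfg.agdex_B, rng=rng)
        io.write_json(summary, outdir / "agdex_summary.json")
        if cfg.genesets is not None:
            sets = io.read_gmt(cfg.genesets)
            gs = agdex.geneset_agdex(
                study_m, study_h, pairs, sets, cfg.agdex_cfg, rng=rng
            )
            io.write_tsv(gs, outdir / "agdex_genesets.tsv")

        stage = "epigenome"
        icfg = cfg.integration_cfg or epigenome.IntegrationConfig()
        marks = pd.read_csv(indir / "promoter_marks.tsv", sep="\t")
        calls_m = epigenome.call_expression(study_m, icfg)
        calls_h = epigenome.call_expression(study_h, icfg)
        deltas = epigenome.mark_deltas(marks)
        epi_m = epigenome.classify_epigenetic(calls_m, deltas, icfg)
        # no promoter marks for the human side in the synthetic design:
        # the human table carries expression calls with epi status unknown
        epi_h = pd.DataFrame(
            {"expr_call": calls_h["call"], "epi_call": "not-epi"},
            index=calls_h.index,
        )
        overlap = epigenome.cross_species_overlap(epi_m, epi_h, pairs)
        io.write_tsv(epi_m.reset_index(), outdir / "epigenetic_calls_mouse.tsv")
        io.write_json(overlap.as_dict(), outdir / "cross_species_overlap.json")

        stage = "karyotype"
        ktab = pd.read_csv(indir / "karyotypes.tsv", sep="\t")
        krows = []
        for _, row in ktab.iterrows():
            dist = karyotype.parse_count_string(
                row["count_string"], sample=row["sample"], species=row["species"]
            )
            ref = karyotype.resolve_reference(dist, cfg.karyotype_ref)
            s = karyotype.aneuploidy_summary(dist, ref)
            krows.append(
                {
                    "sample": row["sample"], "species": row["species"],
                    "n_cells": s.n_cells, "ref_count": s.ref_count,
                    "pct_gain": s.pct_gain, "pct_loss": s.pct_loss,
                    "pct_aneuploid": s.pct_aneuploid, "retention": s.retention,
                }
            )
        io.write_tsv(pd.DataFrame(krows), outdir / "karyotype_summary.tsv")

        stage = "cnv"
        seg_sets = io.read_segments(indir / "segments.seg")
        genome = pd.read_csv(indir / "genome.tsv", sep="\t")
        chrom_lengths = dict(zip(genome["chrom"], genome["length"]))
        thr = cfg.thresholds or cnv.LesionThresholds()
        lesion_calls = cnv.classify_all(seg_sets, chrom_lengths, thr)
        io.write_tsv(lesion_calls, outdir / "lesion_calls.tsv")
        genotype_map = {s.sample: "synthetic" for s in seg_sets}
        burden = cnv.burden_summary(seg_sets, genotype_map, chrom_lengths, thr)
        io.write_tsv(
            burden["per_genotype_mean"].reset_index(), outdir / "cnv_burden.tsv"
        )
        rec = cnv.recurrence(seg_sets, k=cfg.recurrence_k,
                             min_reciprocal_overlap=cfg.min_reciprocal_overlap)
        io.write_tsv(rec, outdir / "recurrent_loci.tsv")

        stage = "integrity"
        tdf = io.read_traces(indir / "traces.tsv")
        vcols = [c for c in tdf.columns if c.startswith("v")]
        dist_rows = []
        for _, row in tdf.iterrows():
            tr = integrity.IntensityTrace(
                row[vcols].to_numpy(dtype=float), sample=row["sample"],
                treatment=row.get("label", ""),
            )
            d = integrity.chromatid_distance(tr)
            dist_rows.append({"sample": row["sample"], "label": row.get("label", ""),
                              "distance_px": d})
        io.write_tsv(pd.DataFrame(dist_rows), outdir / "chromatid_distances.tsv")

        pdf = io.read_traces(indir / "comet_profiles.tsv")
        vcols = [c for c in pdf.columns if c.startswith("v")]
        otm_rows = []
        for _, row in pdf.iterrows():
            pr = integrity.IntensityProfile(
                row[vcols].to_numpy(dtype=float), sample=row["sample"],
                timepoint=row.get("label", ""),
            )
            otm_rows.append(
                {
                    "sample": row["sample"], "timepoint": row.get("label", ""),
                    "olive_tail_moment": integrity.olive_tail_moment(pr),
                    "tail_fraction": integrity.measured_tail_fraction(pr),
                }
            )
        io.write_tsv(pd.DataFrame(otm_rows), outdir / "tail_moments.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
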