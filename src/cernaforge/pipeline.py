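"""End-to-end orchestration: simulate -> filter -> DE -> targets -> ceRNA ->
enrich -> validate, off one flat config with deterministic seeding.

Every threshold defaults to the workflow's printed screening rules
(length > 200 bp, >= 2 exons, FDR < 0.05, |log2FC| > 1, 100 kb cis window,
|r| > 0.999 trans, SCC < -0.7, PCC > 0.9, sponge P < 0.05). Each stage
writes its outputs under ``outdir`` and contributes record counts to a run
manifest; re-running with the same config reproduces the outputs and the
manifest byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .cerna import build_cerna_network, network_stats, screen_coexpressed_pairs, screen_negative_pairs
from .de import DEFAULT_COMPARISONS, de_summary, differential_expression
from .enrich import overrepresentation
from .filters import classify_position, filter_cascade
from .io import write_edge_list, write_expression_table, write_gtf
from .simulate import SimConfig, simulate_all
from .targets import predict_cis, predict_trans
from .trait_stats import ddct, duncan_groups, fatty_acid_ratios, trait_correlation

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("cernaforge")


@dataclass(frozen=True)
class PipelineConfig:
    """Flat run configuration; all thresholds default to the screening rules."""

    outdir: str = "cernaforge_run"
    seed: int = 0
    min_length: int = 200
    min_exons: int = 2
    fdr: float = 0.05
    lfc: float = 1.0
    cis_window: int = 100_000
    trans_r: float = 0.999
    scc: float = -0.7
    pcc: float = 0.9
    alpha: float = 0.05
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if not (0 < self.fdr <= 1 and 0 <= self.alpha <= 1):
            raise ValueError("fdr must be in (0,1], alpha in [0,1]")
        if not (-1 <= self.scc <= 0 <= self.pcc <= 1):
            raise ValueError("scc must be in [-1,0], pcc in [0,1]")
        if self.min_length < 0 or self.min_exons < 1 or self.cis_window < 0:
            raise ValueError("invalid structural thresholds")


def _stage(name: str, **counts) -> dict:
    logger.info("stage %s: %s", name, counts)
    return {"stage": name, **counts}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_config = replace(config.sim, seed=config.seed, cis_window=config.cis_window)
    stages: list[dict] = []

    # 1. simulate
    bundle = simulate_all(sim_config)
    annotation, truth = bundle["annotation"], bundle["truth"]
    lnc, mir, mrna = bundle["lnc"], bundle["mir"], bundle["mrna"]
    write_gtf(annotation, outdir / "annotation.gtf")
    for name, mat in (("lnc", lnc), ("mir", mir), ("mrna", mrna)):
        write_expression_table(mat, outdir / f"expr_{name}.tsv", outdir / f"design_{name}.tsv")
    stages.append(
        _stage(
            "simulate",
            transcripts=len(annotation),
            lnc_features=len(lnc.feature_ids),
            mir_features=len(mir.feature_ids),
            mrna_features=len(mrna.feature_ids),
            samples=len(lnc.sample_ids),
        )
    )

    # 2. lncRNA identification + positional classification
    mrnas = [t for t in annotation if t.biotype == "mRNA"]
    candidates = [t for t in annotation if t.biotype == "novel_candidate"]
    reports = filter_cascade(candidates, mrnas, config.min_length, config.min_exons)
    passing_ids = {r.transcript_id for r in reports if r.passed}
    passing = [t for t in candidates if t.transcript_id in passing_ids]
    classes = {t.transcript_id: classify_position(t, mrnas).value for t in passing}
    report_df = pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in reports],
            "passed": [r.passed for r in reports],
            "failed_rules": [",".join(r.failed_rules) for r in reports],
        }
    ).sort_values("transcript_id")
    report_df.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    write_gtf(passing, outdir / "novel_lncrna.gtf")
    pd.Series(classes, name="positional_class").rename_axis("transcript_id").sort_index().to_csv(
        outdir / "lncrna_classes.tsv", sep="\t"
    )
    stages.append(_stage("filter", candidates=len(candidates), novel_lncrna=len(passing)))

    # 3. differential expression per comparison
    de_results = {}
    for comp in config.comparisons:
        res = differential_expression(
            lnc, comp[0], comp[1], alpha_fdr=config.fdr, min_abs_log2fc=config.lfc
        )
        de_results[comp] = res
        res.round(10).to_csv(outdir / f"de_{comp[0]}_vs_{comp[1]}.tsv", sep="\t")
    summary = de_summary(de_results)
    stages.append(
        _stage(
            "de",
            **{
                f"{a}_vs_{b}": summary["counts"][(a, b)]["total"]
                for a, b in config.comparisons
            },
        )
    )

    # 4. target prediction
    lnc_records = [t for t in annotation if t.transcript_id in set(lnc.feature_ids)]
    cis_pairs = predict_cis(lnc_records, mrnas, window=config.cis_window)
    trans_pairs = predict_trans(lnc, mrna, threshold=config.trans_r)
    pd.DataFrame([p.__dict__ for p in cis_pairs]).to_csv(
        outdir / "targets_cis.tsv", sep="\t", index=False
    )
    pd.DataFrame([p.__dict__ for p in trans_pairs]).to_csv(
        outdir / "targets_trans.tsv", sep="\t", index=False
    )
    stages.append(_stage("targets", cis=len(cis_pairs), trans=len(trans_pairs)))

    # 5. ceRNA network
    neg_lnc = screen_negative_pairs(lnc, mir, scc_cut=config.scc)
    neg_mrna = screen_negative_pairs(mrna, mir, scc_cut=config.scc)
    coexp = screen_coexpressed_pairs(lnc, mrna, pcc_cut=config.pcc)
    expressed_mirs = [m for m in mir.feature_ids if (mir.values.loc[m] > 0).any()]
    network = build_cerna_network(
        neg_lnc + neg_mrna,
        coexp,
        bundle["sponge_sets"],
        alpha=config.alpha,
        universe=expressed_mirs,
    )
    stats = network_stats(network)
    write_edge_list(network.edges, outdir / "cerna.sif", outdir / "cerna_edges.tsv")
    triad_df = pd.DataFrame(
        [
            {
                "lncrna_id": t.lncrna_id,
                "mrna_id": t.mrna_id,
                "shared_mirnas": ",".join(sorted(t.shared_mirnas)),
                "x": t.x,
                "K": t.K,
                "M": t.M,
                "N": t.N,
                "p_hyper": t.p_hyper,
            }
            for t in sorted(network.triads, key=lambda t: (t.lncrna_id, t.mrna_id))
        ]
    )
    triad_df.to_csv(outdir / "cerna_triads.tsv", sep="\t", index=False)
    stages.append(_stage("cerna", **stats))

    # 6. enrichment of network mRNAs
    study = sorted({t.mrna_id for t in network.triads})
    enr = overrepresentation(
        study, bundle["terms"], mrna.feature_ids, bundle["term_names"]
    ) if study else []
    pd.DataFrame([r.__dict__ for r in enr]).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    stages.append(_stage("enrich", terms_tested=len(enr), significant=sum(r.q_value < 0.05 for r in enr)))

    # 7. validation statistics: qPCR ddCt, trait correlations, ratios, Duncan letters
    rel = ddct(bundle["qpcr"], calibrator_group=sim_config.stage_labels[0])
    rel.to_csv(outdir / "qpcr_relative_expression.tsv", sep="\t", index=False)
    corr = trait_correlation(lnc.log2p(), bundle["traits"])
    corr.to_csv(outdir / "trait_correlations.tsv", sep="\t", index=False)
    ratios = fatty_acid_ratios(bundle["traits"], bundle["trait_classes"])
    ratios.to_csv(outdir / "fatty_acid_ratios.tsv", sep="\t")
    first_target = rel["target_id"].iloc[0]
    sub = rel[rel["target_id"] == first_target]
    letters = duncan_groups(
        {g: grp["rel_expression"].to_numpy() for g, grp in sub.groupby("group")}
    )
    stages.append(
        _stage(
            "validate",
            qpcr_targets=rel["target_id"].nunique(),
            trait_pairs=len(corr),
            duncan_groups=len(letters),
        )
    )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: v
            for k, v in asdict(config).items()
            if k not in {"sim", "outdir", "comparisons"}
        },
        "comparisons": ["%s_vs_%s" % c for c in config.comparisons],
        "stages": stages,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
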