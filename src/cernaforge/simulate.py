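"""Synthetic annotation, tri-layer expression, target sets, traits and qPCR.

The generator emits data shaped like a staged bulk-RNA-seq study of muscle
tissue - four growth stages x four replicates by default - with *planted,
recoverable structure*, so every downstream stage of the pipeline can be
tested against known truth without any external download:

* annotation: mRNAs are longer, more exonic and carry long ORFs; lncRNAs
  are short, few-exoned, low-ORF. Labelled decoys each violate exactly one
  identification rule. Some lncRNA loci are placed within the cis window
  of a gene, others deliberately beyond it.
* expression: log-normal abundances (multiplicative replicate noise on a
  strictly positive FPKM scale) with lncRNA baselines below mRNA baselines;
  planted differential features are mean-shifted between two stages by a
  known log2 fold change; each planted ceRNA triad shares a latent
  per-sample factor on which the lncRNA and mRNA load positively and their
  shared miRNAs load negatively.
* target sets: each planted triad's shared miRNAs target both its lncRNA
  and mRNA; background targeting is sprinkled uniformly at low density.
* traits: planted (lncRNA, trait) pairs with a chosen population
  correlation; traits carry SFA/MUFA/PUFA and n-3/n-6 class labels.
* qPCR: Ct values follow Ct = c0 - log2(abundance) + noise, plus a
  constant-abundance reference gene.

One integer seed drives a single numpy Generator stream, so identical
configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import (
    RULE_CLASS_CODE,
    RULE_CODING_OVERLAP,
    RULE_CODING_POTENTIAL,
    RULE_EXON_COUNT,
    RULE_KNOWN_ANNOTATION,
    RULE_LENGTH,
)
from .io import DEFAULT_STAGES, ExpressionMatrix, GenomicInterval, TranscriptRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_annotation",
    "simulate_expression",
    "simulate_target_sets",
    "simulate_traits",
    "simulate_qpcr",
    "simulate_term_annotation",
    "simulate_all",
]

_DECOY_RULES = (
    RULE_CLASS_CODE,
    RULE_LENGTH,
    RULE_EXON_COUNT,
    RULE_CODING_OVERLAP,
    RULE_KNOWN_ANNOTATION,
    RULE_CODING_POTENTIAL,
)

#: Fatty-acid trait catalogue: name -> (saturation class, omega class).
TRAIT_CATALOG = {
    "C14:0": ("SFA", "none"),
    "C16:0": ("SFA", "none"),
    "C18:0": ("SFA", "none"),
    "C14:1": ("MUFA", "none"),
    "C17:1": ("MUFA", "none"),
    "C18:1n9": ("MUFA", "none"),
    "C18:2n6": ("PUFA", "n-6"),
    "C20:4n6": ("PUFA", "n-6"),
    "C18:3n3": ("PUFA", "n-3"),
    "C20:5n3": ("PUFA", "n-3"),
    "IMF": ("other", "none"),
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulation; the defaults mirror the study design
    (4 stages x 4 replicates) at desk scale."""

    seed: int = 0
    n_mrna: int = 200
    n_known_lnc: int = 10
    n_novel_lnc: int = 20
    n_mirna: int = 50
    n_stages: int = 4
    n_reps: int = 4
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_planted_de: int = 5
    de_log2fc: float = 2.0
    n_planted_triads: int = 10
    triad_effect: float = 0.95
    n_shared_mirnas: int = 3
    noise_sd: float = 0.1
    n_traits: int = 11
    n_planted_traits: int = 5
    trait_effect_r: float = 0.8
    target_density: float = 0.02
    n_decoys_per_rule: int = 3
    n_cis_pairs: int = 5
    n_cis_decoys: int = 5
    cis_window: int = 100_000

    def __post_init__(self) -> None:
        counts = (
            self.n_mrna,
            self.n_known_lnc,
            self.n_novel_lnc,
            self.n_mirna,
            self.n_planted_de,
            self.n_planted_triads,
            self.n_decoys_per_rule,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.de_log2fc <= 0:
            raise ValueError("de_log2fc must be > 0")
        if not (0 < self.triad_effect < 1):
            raise ValueError("triad_effect must lie in (0, 1)")
        if not (-1 <= self.trait_effect_r <= 1):
            raise ValueError("trait_effect_r must lie in [-1, 1]")
        if self.n_planted_triads > 0:
            if self.n_novel_lnc < self.n_planted_triads + self.n_cis_pairs + self.n_cis_decoys:
                raise ValueError(
                    "n_novel_lnc too small to host planted triads plus cis pairs/decoys"
                )
            if self.n_mirna < self.n_planted_triads * self.n_shared_mirnas:
                raise ValueError("n_mirna too small for disjoint shared-miRNA sets")
        if len(self.stages) < self.n_stages:
            raise ValueError("need at least n_stages stage labels")
        if self.n_decoys_per_rule > 0 and self.n_mrna == 0:
            raise ValueError("coding-overlap decoys need at least one mRNA to overlap")

    @property
    def stage_labels(self) -> tuple[str, ...]:
        return self.stages[: self.n_stages]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{s}_{r + 1}" for s in self.stage_labels for r in range(self.n_reps)]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimTruth:
    """Ground-truth ledger of everything the generator planted."""

    planted_de: dict[tuple[str, str], set[tuple[str, str]]] = field(default_factory=dict)
    planted_triads: set[tuple[str, str, frozenset[str]]] = field(default_factory=set)
    planted_cis_pairs: set[tuple[str, str, int]] = field(default_factory=set)
    cis_decoys: set[tuple[str, str, int]] = field(default_factory=set)
    planted_trait_pairs: set[tuple[str, str, float]] = field(default_factory=set)
    decoys: dict[str, frozenset[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_GENE_SPACING = 1_000_000  # gene anchors 1 Mb apart: beyond-window placements stay beyond


def _make_exons(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    strand: str,
    n_exons: int,
    total_length: int,
) -> list[GenomicInterval]:
    cuts = np.sort(rng.choice(np.arange(1, total_length), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate([[0], cuts, [total_length]])).astype(int)
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append(GenomicInterval(chrom, pos, pos + int(size), strand))
        pos += int(size) + int(rng.integers(200, 5000)) if i < len(sizes) - 1 else 0
    return exons


def _mrna(rng: np.random.Generator, idx: int, chrom: str, start: int) -> TranscriptRecord:
    length = int(rng.integers(2000, 10001))
    n_exons = int(rng.integers(4, 21))
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptRecord(
        transcript_id=f"mRNA_{idx:04d}",
        gene_id=f"gene_{idx:04d}",
        exons=_make_exons(rng, chrom, start, strand, n_exons, length),
        class_code="=",
        orf_length=max(90, length // 3),
        coding_call_a=True,
        coding_call_b=True,
        coding_score=float(rng.uniform(0.8, 1.0)),
        biotype="mRNA",
    )


def _lnc(
    rng: np.random.Generator,
    tid: str,
    chrom: str,
    start: int,
    biotype: str,
    class_code: str,
    length: int | None = None,
    n_exons: int | None = None,
    strand: str | None = None,
    coding_a: bool = False,
    coding_b: bool = False,
    db_annotated: bool = False,
) -> TranscriptRecord:
    length = length if length is not None else int(rng.integers(300, 3001))
    n_exons = n_exons if n_exons is not None else int(rng.integers(2, 5))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=tid.rsplit(".", 1)[0] if "." in tid else tid,
        exons=_make_exons(rng, chrom, start, strand, n_exons, length),
        class_code=class_code,
        orf_length=int(rng.integers(30, min(281, length))),
        coding_call_a=coding_a,
        coding_call_b=coding_b,
        coding_score=float(rng.uniform(0.0, 0.2)),
        biotype=biotype,
        db_annotated=db_annotated,
    )


def simulate_annotation(config: SimConfig) -> tuple[list[TranscriptRecord], SimTruth]:
    """Generate mRNA, known-lncRNA and novel-candidate transcript records.

    mRNA anchors sit 1 Mb apart on four chromosomes. The first
    ``n_cis_pairs`` good novel lncRNAs land within the cis window of their
    anchor gene (gap 10-90 kb) and are recorded as planted cis pairs; the
    next ``n_cis_decoys`` land beyond it (gap 150-250 kb); the rest are
    >= 400 kb from any gene. Each decoy transcript violates exactly one
    identification rule, recorded in ``truth.decoys``.
    """
    rng = config.rng()
    truth = SimTruth()
    novel_codes = np.array(list("ujxioce"))

    mrnas: list[TranscriptRecord] = []
    for i in range(config.n_mrna):
        chrom = f"chr{i % 4 + 1}"
        anchor = 100_000 + (i // 4) * _GENE_SPACING
        mrnas.append(_mrna(rng, i, chrom, anchor))

    records = list(mrnas)
    for i in range(config.n_known_lnc):
        chrom = f"chr{i % 4 + 1}"
        start = 550_000 + (i // 4) * _GENE_SPACING  # mid-way between anchors
        records.append(_lnc(rng, f"known_lnc_{i:03d}", chrom, start, "known_lncRNA", "="))

    novel: list[TranscriptRecord] = []
    for i in range(config.n_novel_lnc):
        tid = f"novel_lnc_{i:03d}"
        code = str(rng.choice(novel_codes))
        if i < config.n_cis_pairs and mrnas:
            gene = mrnas[i % len(mrnas)]
            gap = int(rng.integers(10_000, 90_001))
            start = gene.end + gap
            rec = _lnc(rng, tid, gene.chrom, start, "novel_candidate", code)
            truth.planted_cis_pairs.add((tid, gene.gene_id, gap))
        elif i < config.n_cis_pairs + config.n_cis_decoys and mrnas:
            gene = mrnas[i % len(mrnas)]
            gap = int(rng.integers(config.cis_window + 50_000, config.cis_window + 150_001))
            rec = _lnc(rng, tid, gene.chrom, gene.end + gap, "novel_candidate", code)
            # record the intended anchor only; the decoy may sit near the
            # next gene on dense annotations, so tests use sparse configs
            truth.cis_decoys.add((tid, gene.gene_id, gap))
        else:
            chrom = f"chr{i % 4 + 1}"
            start = 400_000 + (i // 4) * _GENE_SPACING + int(rng.integers(0, 50_000))
            rec = _lnc(rng, tid, chrom, start, "novel_candidate", code)
        novel.append(rec)
    records.extend(novel)

    far_start = 600_000  # mid-gap: > 100 kb from both flanking anchors
    decoy_idx = 0
    for rule in _DECOY_RULES:
        for _ in range(config.n_decoys_per_rule):
            tid = f"decoy_{rule}_{decoy_idx:03d}"
            chrom = f"chr{decoy_idx % 4 + 1}"
            start = far_start + (decoy_idx // 4) * _GENE_SPACING + 120_000
            code = str(rng.choice(novel_codes))
            if rule == RULE_CLASS_CODE:
                rec = _lnc(rng, tid, chrom, start, "novel_candidate", "=")
            elif rule == RULE_LENGTH:
                rec = _lnc(rng, tid, chrom, start, "novel_candidate", code, length=150)
            elif rule == RULE_EXON_COUNT:
                rec = _lnc(rng, tid, chrom, start, "novel_candidate", code, n_exons=1)
            elif rule == RULE_CODING_OVERLAP:
                host = mrnas[decoy_idx % len(mrnas)]
                exon = host.exons[0]
                rec = _lnc(
                    rng,
                    tid,
                    host.chrom,
                    exon.start + max(1, len(exon) // 2),
                    "novel_candidate",
                    code,
                    strand=host.strand,
                    length=400,
                    n_exons=2,
                )
            elif rule == RULE_KNOWN_ANNOTATION:
                rec = _lnc(rng, tid, chrom, start, "novel_candidate", code, db_annotated=True)
            else:  # coding potential: the two predictors disagree
                rec = _lnc(rng, tid, chrom, start, "novel_candidate", code, coding_b=True)
            truth.decoys[tid] = frozenset({rule})
            records.append(rec)
            decoy_idx += 1
    return records, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _stage_of(sample: str) -> str:
    return sample.rpartition("_")[0]


def simulate_expression(
    annotation: list[TranscriptRecord],
    config: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Generate lncRNA / miRNA / mRNA FPKM matrices with planted structure.

    Baseline log2-FPKM means put lncRNAs below mRNAs. Planted DE features
    (lncRNA layer) are shifted by +/- ``de_log2fc`` in stage B of their
    designated comparison. Each planted triad adds a standard-normal
    per-sample latent factor z with loading ``triad_effect`` (log2-sd
    units): + on its lncRNA and mRNA, - on its shared miRNAs; the induced
    pairwise log-scale correlation is effect^2 / (effect^2 + noise_sd^2).
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = truth if truth is not None else SimTruth()
    samples = config.sample_ids
    n_samples = len(samples)
    stages = config.stage_labels

    lnc_ids = [
        t.transcript_id
        for t in annotation
        if t.biotype == "known_lncRNA"
        or (t.biotype == "novel_candidate" and not t.transcript_id.startswith("decoy"))
    ]
    mrna_ids = [t.transcript_id for t in annotation if t.biotype == "mRNA"]
    mir_ids = [f"miR_{i:03d}" for i in range(config.n_mirna)]

    def baseline(ids, lo, hi):
        mu = rng.uniform(lo, hi, size=len(ids))
        return np.tile(mu[:, None], (1, n_samples))

    log_lnc = baseline(lnc_ids, 0.5, 4.0)
    log_mrna = baseline(mrna_ids, 3.0, 8.0)
    log_mir = baseline(mir_ids, 2.0, 6.0)

    # planted DE on the lncRNA layer, one comparison per contiguous stage pair
    comparisons = [(stages[i], stages[i + 1]) for i in range(len(stages) - 1)]
    if len(stages) >= 2:
        comparisons.append((stages[0], stages[-1]))
    triad_base = config.n_cis_pairs + config.n_cis_decoys
    triad_numbers = range(triad_base, triad_base + config.n_planted_triads)
    de_pool = [
        i
        for i, fid in enumerate(lnc_ids)
        if not (fid.startswith("novel_lnc") and int(fid.rsplit("_", 1)[1]) in triad_numbers)
    ]
    col_stage = np.array([_stage_of(s) for s in samples])
    for comp in comparisons:
        chosen = []
        for _ in range(min(config.n_planted_de, len(de_pool))):
            pick = de_pool.pop(int(rng.integers(len(de_pool))))
            chosen.append(pick)
        truth.planted_de.setdefault(comp, set())
        for i in chosen:
            direction = "up" if rng.random() < 0.5 else "down"
            shift = config.de_log2fc if direction == "up" else -config.de_log2fc
            log_lnc[i, col_stage == comp[1]] += shift
            truth.planted_de[comp].add((lnc_ids[i], direction))
        if not de_pool:
            break

    # planted triads: shared latent factor per triad
    triad_lnc_idx = [
        lnc_ids.index(f"novel_lnc_{config.n_cis_pairs + config.n_cis_decoys + k:03d}")
        for k in range(config.n_planted_triads)
    ]
    triad_mrna_idx = list(range(config.n_planted_triads))
    lam = config.triad_effect
    for k in range(config.n_planted_triads):
        z = rng.standard_normal(n_samples)
        li, mi = triad_lnc_idx[k], triad_mrna_idx[k]
        log_lnc[li] += lam * z
        log_mrna[mi] += lam * z
        shared = mir_ids[k * config.n_shared_mirnas : (k + 1) * config.n_shared_mirnas]
        for mir in shared:
            log_mir[mir_ids.index(mir)] -= lam * z
        truth.planted_triads.add((lnc_ids[li], mrna_ids[mi], frozenset(shared)))

    for mat in (log_lnc, log_mrna, log_mir):
        mat += rng.normal(0.0, config.noise_sd, size=mat.shape)

    def to_matrix(ids, logs, layer):
        values = pd.DataFrame(np.exp2(logs), index=ids, columns=samples)
        return ExpressionMatrix(values=values, layer=layer)

    return (
        to_matrix(lnc_ids, log_lnc, "lncRNA"),
        to_matrix(mir_ids, log_mir, "miRNA"),
        to_matrix(mrna_ids, log_mrna, "mRNA"),
        truth,
    )


def simulate_target_sets(
    config: SimConfig,
    truth: SimTruth,
    lnc_ids: list[str],
    mrna_ids: list[str],
    mir_ids: list[str],
) -> dict[str, set[str]]:
    """miRNA -> target-feature sets: planted triad sponges plus background.

    Every shared miRNA of a planted triad targets both the triad's lncRNA
    and mRNA; background (miRNA, feature) assignments are drawn uniformly
    at ``target_density`` so spurious overlaps rarely reach significance.
    """
    rng = np.random.default_rng(config.seed + 2)
    targets: dict[str, set[str]] = {m: set() for m in mir_ids}
    features = list(lnc_ids) + list(mrna_ids)
    if config.target_density > 0:
        hits = rng.random((len(mir_ids), len(features))) < config.target_density
        for i, m in enumerate(mir_ids):
            targets[m].update(np.asarray(features)[hits[i]])
    for lnc, mrna, shared in truth.planted_triads:
        for m in shared:
            targets[m].update((lnc, mrna))
    return targets


def simulate_traits(
    lnc_expr: ExpressionMatrix,
    config: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Trait table (samples x traits) with planted lncRNA-trait correlations.

    A planted trait equals offset + scale * (r * z_expr + sqrt(1-r^2) * eta)
    where z_expr is the standardised log2 expression of its lncRNA, so the
    population correlation is exactly ``trait_effect_r`` (and the sample
    correlation is exactly 1 when |r| = 1). Returns (traits, trait_classes,
    truth); trait classes cover SFA/MUFA/PUFA and n-3/n-6 membership.
    """
    rng = np.random.default_rng(config.seed + 3)
    truth = truth if truth is not None else SimTruth()
    trait_names = list(TRAIT_CATALOG)[: config.n_traits]
    samples = lnc_expr.sample_ids
    n = len(samples)
    log_expr = np.log2(lnc_expr.values.to_numpy() + 1.0)

    planted_lncs = rng.choice(
        lnc_expr.feature_ids, size=min(config.n_planted_traits, len(trait_names)), replace=False
    )
    values = {}
    r = config.trait_effect_r
    for j, trait in enumerate(trait_names):
        if j < len(planted_lncs):
            lnc = str(planted_lncs[j])
            x = log_expr[lnc_expr.feature_ids.index(lnc)]
            sx = x.std()
            z = (x - x.mean()) / sx if sx > 0 else np.zeros(n)
            signal = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
            values[trait] = 10.0 + 1.0 * signal
            truth.planted_trait_pairs.add((lnc, trait, r))
        else:
            values[trait] = 10.0 + rng.standard_normal(n)
    traits = pd.DataFrame(values, index=pd.Index(samples, name="sample"))
    traits = traits.clip(lower=0.0)
    classes = pd.DataFrame(
        {
            "saturation_class": {t: TRAIT_CATALOG[t][0] for t in trait_names},
            "omega_class": {t: TRAIT_CATALOG[t][1] for t in trait_names},
        }
    )
    classes.index.name = "trait"
    return traits, classes, truth


def simulate_qpcr(
    expr: ExpressionMatrix,
    feature_ids: list[str] | None = None,
    config: SimConfig | None = None,
    ct_noise_sd: float = 0.0,
    c0: float = 30.0,
    reference_abundance: float = 256.0,
) -> pd.DataFrame:
    """Ct table for selected features: Ct = c0 - log2(abundance) + noise.

    Includes a constant-abundance reference gene ("beta-actin" analogue)
    whose Ct is identical across samples at zero noise. Output is tidy:
    sample_id, group, target_id, ct_target, ct_reference.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed + 4)
    feature_ids = feature_ids or expr.feature_ids[: min(4, len(expr.feature_ids))]
    rows = []
    for sample in expr.sample_ids:
        ct_ref = c0 - np.log2(reference_abundance) + (
            rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
        )
        group = expr.design.loc[sample, "stage"]
        for fid in feature_ids:
            abundance = float(expr.values.loc[fid, sample])
            noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample_id": sample,
                    "group": group,
                    "target_id": fid,
                    "ct_target": c0 - np.log2(abundance) + noise,
                    "ct_reference": ct_ref,
                }
            )
    return pd.DataFrame(rows)


def simulate_term_annotation(
    config: SimConfig,
    truth: SimTruth,
    mrna_ids: list[str],
    n_terms: int = 20,
    term_size: int = 10,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Toy term -> gene annotation with one term enriched for triad mRNAs.

    The first term collects the planted triads' mRNAs (plus fillers), so an
    over-representation test of the recovered network's mRNAs should rank
    it first; remaining terms are uniform draws.
    """
    rng = np.random.default_rng(config.seed + 5)
    triad_mrnas = sorted({m for _, m, _ in truth.planted_triads})
    annotation: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    fillers = [g for g in mrna_ids if g not in set(triad_mrnas)]
    planted = set(triad_mrnas[:term_size])
    if len(planted) < term_size and fillers:
        extra = rng.choice(fillers, size=min(term_size - len(planted), len(fillers)), replace=False)
        planted |= set(map(str, extra))
    annotation["TERM:0000"] = planted
    names["TERM:0000"] = "planted ceRNA pathway"
    for t in range(1, n_terms):
        term = f"TERM:{t:04d}"
        members = rng.choice(mrna_ids, size=min(term_size, len(mrna_ids)), replace=False)
        annotation[term] = set(map(str, members))
        names[term] = f"background set {t}"
    return annotation, names


def simulate_all(config: SimConfig) -> dict:
    """Run every generator stage off one config; returns a keyed bundle."""
    annotation, truth = simulate_annotation(config)
    lnc, mir, mrna, truth = simulate_expression(annotation, config, truth)
    sponge_sets = simulate_target_sets(
        config, truth, lnc.feature_ids, mrna.feature_ids, mir.feature_ids
    )
    traits, trait_classes, truth = simulate_traits(lnc, config, truth)
    qpcr = simulate_qpcr(lnc, feature_ids=lnc.feature_ids[:4], config=config)
    terms, term_names = simulate_term_annotation(config, truth, mrna.feature_ids)
    return {
        "annotation": annotation,
        "truth": truth,
        "lnc": lnc,
        "mir": mir,
        "mrna": mrna,
        "sponge_sets": sponge_sets,
        "traits": traits,
        "trait_classes": trait_classes,
        "qpcr": qpcr,
        "terms": terms,
        "term_names": term_names,
    }
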