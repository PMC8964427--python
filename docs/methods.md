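# Methods

## Scope and data model

The package analyses a staged bulk transcriptome design: `n_stages` groups
(default four growth stages labelled 4m, 1.5y, 3.5y, 6y) × `n_reps`
replicates (default 4), with three expression layers (lncRNA, miRNA, mRNA)
quantified as FPKM. Internal genomic coordinates are 0-based half-open
everywhere; GTF I/O converts to and from the 1-based inclusive convention
at the file boundary only, which keeps all window and overlap arithmetic
unambiguous. Unknown GTF attributes are carried verbatim so write∘read is
the identity.

## lncRNA identification

Six rules are evaluated independently for every candidate (no
short-circuiting), so the report lists every violated rule and the pass set
cannot depend on application order:

1. class code ∈ {i, j, x, u, c, e, o} (novel relative to reference);
2. transcript (mature) length > `min_length` (default 200 bp, strict:
   201 bp passes);
3. exon count ≥ `min_exons`. The conventional phrasing "more than 2 exons"
   is ambiguous between ≥ 2 and > 2; the default is ≥ 2 because 2-exon
   lncRNAs are routinely reported as reliable multi-exon transcripts, and a
   strict mode (`min_exons=3`) is available;
4. no exonic overlap (≥ 1 bp, same strand by default; any-strand mode
   available) with a protein-coding mRNA exon;
5. no match in protein/ncRNA annotation databases, modelled as a boolean
   `db_annotated` flag per transcript — database lookups are outside the
   package so runs are self-contained;
6. both coding-potential predictor calls (supplied externally per
   transcript) are noncoding — the intersection rule.

Positional classification uses a fixed precedence — sense-overlapping >
antisense > intronic > bidirectional > intergenic — because the five class
names alone do not determine the tie-breaks; the bidirectional window
(5′-end to opposite-strand 5′-end) defaults to 1,000 bp and is
configurable.

## Differential expression

FPKM = count · 10⁹ / (length_bp · library_size). The DE statistic is
pluggable; the default is Welch's two-sample t on log₂(FPKM + pseudocount),
chosen for transparency and small-n robustness at n = 4 per group, with
Benjamini–Hochberg correction across all features of a comparison. The
pseudocount defaults to 1.0, matching the log₁₀(FPKM+1) display convention
common in these studies; note it deliberately shrinks fold changes of
low-abundance features, so a planted log₂FC of 2 at FPKM ≈ 1 may be
reported below the |log₂FC| > 1 threshold — this is a property of
pseudocount thresholds, not a defect, and the pseudocount is a parameter.
Features with all-zero values in both groups are removed before testing
(undefined fold change; protects the FDR denominator). Degenerate
zero-variance groups: equal means give p = 1, unequal means p = 0.
Comparisons default to (4m, 1.5y), (1.5y, 3.5y), (3.5y, 6y), (4m, 6y).

## Target prediction

cis: span-gap ≤ window (default 100 kb), strand ignored, boundary
inclusive — the gap is max(0, max(starts) − min(ends)) under half-open
spans, so touching or overlapping loci have distance 0. Span gap (not
TSS-to-TSS) is used because the window itself is approximate and span gap
is the most common convention. trans: |r| > 0.999 strictly; Pearson on
log₂(FPKM+1) by default (Spearman available) — the correlation kind is a
genuinely open choice and Pearson matches the later lncRNA–mRNA screening.

## ceRNA network

Screens use strict inequalities at the quoted cuts (SCC < −0.7, PCC > 0.9).
Spearman uses average ranks for ties and is transform-invariant; Pearson is
computed on log₂(FPKM+1). Correlation denominators are computed as
√(SS_a·SS_b) rather than √SS_a·√SS_b so rational correlations on integer
data (e.g. exactly −0.7 from rank vectors) hit the boundary exactly and are
excluded deterministically.

A miRNA counts as a sponge of a gene only when it both appears in the
gene's target set *and* forms a retained negative pair with it — the
stricter of the two possible readings of "common miRNA sponges", adopted
because the screens are pipelined sequentially. The shared-sponge test is
the exact upper-tail hypergeometric P(X ≥ x) with population N (the
expressed-miRNA universe by default — conservative and self-contained;
configurable to the full annotated set), successes K (lncRNA sponges) and
draws M (mRNA sponges), computed through scipy's log-gamma implementation
(no normal approximation). Raw P < 0.05 is the default acceptance rule, as
is conventional for this screen; a BH-corrected mode exists and is off by
default. Pairs with x = 0 are discarded before testing (their p is 1 by
definition). The enrichment module calls the identical function, asserted
equal in the tests.

## Validation statistics

**2^−ΔΔCt**: ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the
calibrator group's mean ΔCt per target, so the calibrator's geometric mean
relative expression is exactly 1 and any global Ct shift cancels. The
calibrator defaults to the earliest stage. Amplification-efficiency
correction is out of scope.

**Trait correlations**: Pearson r with two-tailed p from
t = r√((n−2)/(1−r²)) on n−2 df; |r| = 1 maps to p = 0. Per-cell
significance stars at 0.05/0.01/0.001; no correction across the grid by
default (heat-map-style reporting), optional BH.

**Duncan's multiple range test**: one-way ANOVA pooled MSE with
df = N − k; harmonic-mean group size for unbalanced layouts; least
significant range LSR_p = q_{1−(1−α)^{p−1}}(p, df)·√(MSE/n_h) with
studentized-range quantiles computed numerically; protected step-down (a
non-significant range silences all its sub-ranges). The compact-letter
display exploits that the resulting non-separation relation is
interval-closed on the sorted means, so letters are maximal runs. If
MSE = 0 groups are separated iff their means differ at all.

**Fatty-acid ratios**: class sums (SFA/MUFA/PUFA) are plain totals of
member traits; PUFA/SFA and n-6/n-3 are per-sample ratios; zero
denominators yield missing values rather than errors.

## Synthetic data

The generator emulates the observable structure such a study reports,
at desk scale (defaults: 200 mRNAs, 10 known + 20 novel lncRNAs, 50
miRNAs, 4 stages × 4 replicates = 16 samples):

- **Annotation**: mRNAs 2–10 kb with 4–20 exons and ORFs ≈ length/3;
  lncRNAs 0.3–3 kb, 2–4 exons, ORFs < 300 nt — reproducing the
  shorter/fewer-exoned/low-ORF contrast. Gene anchors sit 1 Mb apart so
  placements relative to one gene cannot accidentally fall inside another
  gene's 100-kb window. Five lncRNAs are planted 10–90 kb from a gene
  (cis pairs), five at 150–250 kb (beyond-window decoys). Three decoys per
  identification rule each violate exactly that one rule, recorded in the
  truth ledger.
- **Expression**: log-normal abundances (multiplicative replicate noise on
  a strictly positive FPKM scale — the simplest model with those
  properties). Baseline log₂ means: mRNA U(3, 8), lncRNA U(0.5, 4), so
  lncRNAs sit below mRNAs. Planted DE features are mean-shifted by
  ±`de_log2fc` (default 2) in the second stage of their designated
  comparison; five per comparison by default. Each planted triad draws a
  standard-normal per-sample latent factor z; its lncRNA and mRNA add
  +λ·z and its 3 shared miRNAs add −λ·z on the log₂ scale, with λ =
  `triad_effect` (default 0.95). The induced pairwise log-scale
  correlation is λ²/(λ² + σ²) with σ = `noise_sd` (default 0.1), i.e.
  ≈ 0.989 at the defaults — comfortably above the 0.9 screen, reaching 1
  as noise → 0. Latent-factor triads (rather than explicit kinetics) are
  the minimal structure the correlation-based pipeline can see.
- **Target sets**: planted sponges target both triad partners; background
  targeting is uniform at density 0.02, low enough that spurious overlaps
  essentially never pass the sponge test.
- **Traits**: eleven fatty-acid/IMF traits around 10 g/100 g; each planted
  (lncRNA, trait) pair is offset + scale·(r·z_x + √(1−r²)·η) with z_x the
  standardised log₂ expression, so the population correlation is exactly
  `trait_effect_r` and |r| = 1 gives sample r = 1 exactly. Because z_x is
  standardised against the realised sample, the Fisher-z interval is
  slightly conservative (coverage above the nominal 95%).
- **qPCR**: Ct = 30 − log₂(abundance) + noise with a constant-abundance
  reference gene; at zero noise the ΔCt identities are exact.

One integer seed drives everything; per-stage generators are derived as
seed + k (k ≤ 5) so each stage is independently reproducible. Identical
configs give bit-identical outputs, files included.

**What the simulation does not emulate**: read-level sampling noise and
count discreteness, length biases in quantification, batch effects,
correlated miRNA families, sequence content, and realistic library-size
variation. Passing tests therefore demonstrate the correctness and
calibration of the screening logic under the stated noise model, not
performance on real libraries — in particular the headline counts of any
real study (which depend on its specific libraries) are not reproduced.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: the hypergeometric
implementation is checked against literal subset enumeration for every
configuration with N ≤ 12 (≤ 10 in the script) to 10⁻¹²; FDR control uses
200 null simulations of 100 features × (4 vs 4); correlation calibration
uses 10,000 null pairs (KS test) and 500 replicates of a planted r = 0.9
at n = 16 against the Fisher-z 95% interval. The full pipeline on the
default simulation runs in seconds. Studentized-range quantiles are the
slowest primitive (scipy's `studentized_range.ppf`) and are cached per
span. Correlation matrices clamp to [−1, 1] to absorb rounding overshoot;
degenerate (zero-variance) features are skipped with warnings rather than
propagating NaN silently.

## Known limitations

- The DE statistic is a two-group Welch t per comparison, not a
  negative-binomial count model; raw counts are accepted only through the
  FPKM conversion.
- Sequence-based miRNA target prediction is out of scope; target sets are
  inputs.
- Exact reproduction of any specific published study's counts is out of
  scope by design (no deposited data); the acceptance machinery measures
  recovery of planted structure instead.
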