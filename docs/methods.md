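# Methods

Statistical model, parameter choices, and known limitations of `lncsig`.

## Re-annotation (lncRNA catalog)

A probe set on a 3′ expression array is classified as lncRNA when it survives
a three-step filter:

1. **Exclusion** (dominant): if any term from a configurable exclusion map —
   pseudogene, microRNA/miRNA, rRNA, snRNA, snoRNA, tRNA, "small nucleolar",
   "small nuclear" — matches on *token boundaries* within the gene title or
   an Ensembl biotype string, the probe is excluded regardless of other
   evidence. Token-boundary matching prevents, e.g., `tRNA` firing inside
   unrelated words.
2. **RefSeq evidence**: any transcript id with the noncoding `NR_` prefix.
3. **Ensembl evidence**: any biotype in a whitelist (antisense,
   processed_transcript(s), sense_overlapping, non_sense_mediated_decay,
   sense_intronic, lincRNA, non_coding, misc_RNA, 3prime_overlapping_ncRNA),
   compared after normalizing case and `-`/space to `_`.

Retention categories record provenance: both sources, RefSeq-only (an `NR_`
probe whose biotype is `protein_coding` is treated as a coding conflict and
excluded; any other non-whitelisted biotype keeps it), or Ensembl-only. The
mRNA universe is every non-catalog probe with `NM_` or `protein_coding`
evidence. The whole step is a pure function of the annotation table —
deterministic and idempotent.

## Differential expression

Inputs are assumed background-corrected, normalized, log2-scale matrices
(e.g. RMA output); the loader only validates scale heuristically. Per probe
and contrast we use the pooled-variance two-sample Student t-test (the
classical microarray choice for small balanced groups, assuming approximate
normality and equal variances on the log2 scale) with
`df = n1 + n2 − 2`. Log2 fold change is the difference of group means.
Benjamini–Hochberg adjustment is applied *within one molecule-class family*
(all lncRNA probes of a view, or all mRNA probes), mirroring the two separate
families tested. Default calls require adjusted p < 0.05 and strict
|log2FC| > 1 (lncRNA) or > 2 (mRNA). Zero-pooled-variance degeneracies are
resolved explicitly (equal means → p = 1; unequal → p = 0) rather than
propagated as NaN.

## Co-expression networks and hub ranking

For each contrast, all (significant lncRNA) × (significant mRNA) pairs are
scored by Pearson correlation across the union of the contrast's two sample
groups. The p-value uses the exact null transformation
`t = r·√((n−2)/(1−r²))` on n−2 df. Edges require |r| > `r_cutoff` (default
0.8; 0.9 is conventional for the metastatic-vs-normal contrast, where the
larger separation inflates correlations) and p < 0.05, keeping the sign.
Candidate hubs are ranked by degree in a designated reference contrast
(default: the last, metastatic vs primary), with ties broken by |log2FC|
descending, adjusted p ascending, then probe id.

Note the structural caveat: when two groups differ strongly in mean, *any*
two probes DE in the same contrast correlate through the group indicator
alone. The cutoffs above do not remove this shift-driven component; degree is
only informative when within-group variation carries the co-regulation signal
(see the generator design below).

## Signature

Probes significant in all three contrasts form the triple overlap; all seven
Venn regions are counted. The reported signature is the direction-consistent
subset (same up/down call in all three contrasts). Signature tables sort
down-regulated first, then by |log2FC| of the third contrast descending.

## Over-representation analysis

Fisher: upper hypergeometric tail P(X ≥ k) for overlap k between query and a
gene set, both intersected with a user-supplied universe (set members outside
the universe do not count toward set size). EASE: the same tail at k−1, the
deliberately conservative DAVID variant. BH adjustment is per category (e.g.
GOBP and KEGG as separate families), matching how such services report.

## Survival screening

Patients are dichotomized at the median expression of each candidate (ties to
the low group). Survival curves are Kaplan–Meier product-limit estimates; the
two arms are compared with the Mantel–Haenszel log-rank test (1 df, no
continuity correction), via `lifelines`. The "worse" arm is the one with the
smaller area under its survival curve (restricted mean survival time) up to
the last event time shared by both arms — a robust summary that does not
require proportional hazards.

## Synthetic-data generator

`lncsig.synth` is part of the package's contract: it produces data whose
ground truth is known, so every downstream claim can be checked numerically.

**Expression model.** `value = baseline + group offset + σ·noise`, with
baselines uniform on [4, 10] (log2-like scale) and noise iid standard normal
except inside co-expression blocks. Planted patterns per molecule class:
triple-DE probes shift by ±d per disease step (N → PM → MM, so PM = ±d,
MM = ±2d with d = 2.2 for lncRNA, 3.0 for mRNA), and single-contrast probes
use a milder 1.5× the class cutoff arranged so only one contrast crosses it
(with strong triple effects a probe cannot simultaneously be far from normal
and close to both other groups, which is why the single-contrast patterns
need their own magnitude).

**Co-expression blocks.** Each block has one lncRNA driver and n members
sharing a per-sample latent factor: the driver's noise *is* the latent and
each member's noise is `λ·latent + √(1−λ²)·e` (default loading λ = 0.95), so
driver–member correlation approaches λ. The latent is centered *within each
group* so that shared co-regulation scatter never perturbs the planted group
means coherently across a block.

**Group sizes and noise (a deliberate design choice).** Defaults are
N = 20 / PM = 25 / MM = 20 with σ = 1.2. With many fewer samples per group
(8–12), any probe detectable at the class cutoffs is necessarily
near-collinear with the group indicator (|r| ≈ 0.85 with every other
detectable probe across the pooled groups), so hub degree is not identifiable
and shift-driven edges flood the network. At 20–25 per group with σ = 1.2,
detectability no longer forces collinearity, the planted blocks are the only
edges of the reference network, and the planted driver is ranked first by
degree across seeds. Empirically (20 seeds): lncRNA triple recovery ≥ 0.96,
mRNA recovery 1.0, driver first 20/20 with degree 60 vs runner-up ≤ 10.

**Survival model.** Expression is bimodal (low ≈ N(2, 0.5²), high ≈ N(8,
0.5²)) so the median split recovers the planted groups; death times are
exponential with the low arm at `hazard_ratio` (default 2.0) times the
baseline rate (baseline median 2000 days); censoring is independent with a
configurable fraction (default 0.3). Default cohort size 221.

**Determinism.** All randomness flows through one `numpy` `default_rng`
generator, and file writers use fixed `%.6f` formatting, so a fixed design +
seed reproduces byte-identical artifacts (hashed in the pipeline manifest).

**Realism limits.** The generator is a statistical caricature: no probe-level
cross-hybridization, no array batch effects, Gaussian noise with a single σ,
block structure limited to one latent factor per block, and exponential
survival with binary risk groups. It validates the pipeline's statistics, not
biology.

## Numerical choices

- BH via `statsmodels.multipletests(fdr_bh)`, validated in tests against a
  hand-written step-up.
- t tails via `scipy.stats`; tests compare against quadrature of the Student
  density written from its gamma-function definition (|Δ| < 1e−10).
- Hypergeometric tails via `scipy.stats.hypergeom.sf`; tests compare against
  exact `math.comb` enumeration.
- KM/log-rank via `lifelines`; tests compare against hand product-limit and
  O/E/V computations.
- Row-wise correlation by centered matrix products, clipped to [−1, 1].
- All sorts that can tie use stable mergesort with documented key orders.

## Limitations

- The pipeline starts from a normalized matrix; RMA/preprocessing is out of
  scope, so published results that depend on preprocessing details can only
  be approximated.
- Pooled-variance t assumes homoscedastic log2 intensities; no moderated
  (empirical-Bayes) variance shrinkage is applied.
- Pearson-based networks conflate group-shift and within-group co-regulation
  (see above); degree rankings should be read with that in mind.
- The survival screen tests each candidate marginally, without multiplicity
  control across candidates or covariate adjustment.
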