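# Methods

This note documents the models behind `pecknet`, the choices made where
the design was genuinely open, and what the synthetic cohorts do and do
not establish about real data.

## Synthetic cohorts

The generator reproduces the statistical structure of two chicken
populations divergently selected for feather pecking: an F2 cross
(default 817 birds, hatch fixed effect) and a half-sib population
(default 494 birds, hatch and line fixed effects, with brain expression
of 86 genes in a 167-bird subcohort).  One global seed expands into
independent per-component streams by fixed spawn keys, so each stage can
be regenerated on its own and every generator is a pure function of
(configuration, seed).

**Genotypes.**  Two marker panels are drawn per cohort: a "chip" panel
that carries the polygenic background and feeds the genomic relationship
matrix (GRM), and the tested "SV/TR" panel.  Within a panel, haplotype
alleles follow a first-order Markov chain along each chromosome: adjacent
variants receive Pearson correlation `min(ld_decay, Frechet bound)`,
where the Fréchet bound caps the attainable correlation between Bernoulli
variables of unequal frequency.  With allele frequencies drawn uniformly
from a wide interval the realized adjacent correlation is therefore
attenuated below `ld_decay` (e.g. ≈ 0.66 at `ld_decay = 0.9` over
MAF 0.05–0.5); with similar frequencies it attains the nominal value.
Haplotypes pair into dosages in {0, 1, 2}; missing genotypes use a −1
sentinel and are mean-imputed only inside the GRM and association
algebra.  The default `ld_decay = 0.5` gives moderate local LD.

The two panels are simulated on *independent* haplotypes.  This mirrors
the analysed design — the GRM comes from SNP-chip markers while the
tested variants are SVs/TRs — and it makes the null distribution of the
SV/TR scan exactly calibrated, because no tested variant tags the
polygenic background of its own chromosome (which the LOCO GRM cannot
absorb by construction).  Cross-panel LD, present in real data, is
deliberately not modelled; type-I-error results therefore quantify the
method's calibration under its own assumptions, not robustness to
LD leakage between panels.

**Phenotype.**  The trait is generated directly on the analysis scale
(the real phenotype is a Box–Cox-transformed peck count; the
transformation itself is out of scope).  `y` = hatch effects (SD 0.5) +
line contrast (0.5 in the HS design) + QTL effects + polygenic term +
Gaussian noise.  The polygenic term is an infinitesimal sum over all chip
markers, rescaled so its sample variance equals `h2` exactly — this makes
REML recovery targets well defined.  Heritability and per-QTL PVE are
defined relative to the fixed-effect-adjusted variance (target 1):
noise variance is `1 − h2 − Σ PVE`, and each QTL's effect is solved from
`PVE = β²Var(x)/Var(y)`.  Defaults: `h2 = 0.15`, one QTL with
PVE 0.047 — the heritability and lead-variant variance share reported for
the real trait.

**Expression.**  Gene expression is Gaussian (the study's normalization
upstream of the expression table is unspecified; the generator emits
already-normalized values).  Each gene has a cis-eQTL on a standardized
dosage (effect 1.0, noise SD 1.0); a transcription-factor hub gene
regulates 23 target genes (effect 0.8 × hub expression), so every
target's eGWAS hits the hub's variant — emulating the hub structure that
produces variants associated with ≥ 10 expression traits.  Two 12-gene
trans-hotspot blocks (genes sharing one regulatory variant) give the AWM
additional rows; both wiring choices are configurable.

**Caller outputs.**  True SV records (DEL/DUP/INV/TRA with strand pairs,
log-uniform sizes 50–5000 bp, population genotypes) are re-emitted per
caller with configurable false-negative rate, rounded Gaussian breakpoint
jitter, false positives at lower QUAL, and per-caller genotype
missingness.  Defaults (three callers, jitter SD 150 bp, FN 0.1, FP 0.05)
are plausible for short-read SV callers; they are not fitted to any
particular tool.

**Promoters.**  I.i.d. background sequence (default uniform base
composition, configurable because enrichment power depends on it) over
the scan window; designated foreground genes receive one consensus-sampled
motif instance at probability 0.6, background genes at 0.2, at a uniform
position and random strand.  The bundled ETS-like matrix is synthetic
(12 sharply peaked columns, GGAA core); with the default scan threshold a
random 2-kb window carries a chance hit with probability ≈ 1%, so
coverage is dominated by planted instances.

## Variant processing

Merging is greedy single-linkage seeded in sorted genome order: a record
joins the first cluster whose *seed* lies within `max_dist` (default
1000 bp) at both breakpoints with matching type and strands; each record
joins at most one cluster.  Clusters need `min_callers` (default 2)
distinct callers; intra-chromosomal representatives shorter than
`min_size` (default 30 bp) are dropped — translocations have no span and
are exempt.  The emitted representative is the member from the
highest-priority caller; the default priority is lexicographic caller id,
which (unlike input order) makes the merged output invariant to the order
in which call sets are supplied.  Consensus genotypes start from the
representative and fill missing entries from other members in priority
order.

Merged-variant filters retain QUAL ≥ 1000 and call rate ≥ 0.8.  TR
genotypes are masked when DP < 10 (inclusive: DP = 10 passes) or
Q ≤ 0.8 (strict: Q = 0.8 fails), then variants with call rate < 0.8 are
removed; the retain-≥ 0.8 direction is applied uniformly to SVs and TRs.
Multiallelic records split into one ref-vs-alt record per alternate
allele, with dosages equal to copies of that allele and deterministic
id suffixes.

## Mixed-model association

The GRM is the standardized cross-product
`A_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i))` over chip
markers off the tested chromosome (LOCO); monomorphic and zero-variance
markers are skipped, missing dosages mean-imputed.

REML is computed in the eigenbasis of the GRM: with `A = U D Uᵀ`, the
restricted likelihood is profiled over the variance ratio
`λ = σ²_g/σ²_e` and maximized on the log scale with bounded scalar
search (tolerance 1e-6), and the `σ²_g = 0` boundary is evaluated
explicitly and kept when it is not beaten.  This exact one-dimensional
profile was chosen over iterative average-information updates because the
two-component model admits it, it cannot step outside the parameter
space, and boundary nulls need no fallback logic.  Non-convergence flags
the result instead of raising.

Components are estimated once per LOCO chromosome, not per variant.
Each variant with MAF ≥ 0.01 and call rate ≥ 0.5 (the study does not
state a per-variant call-rate rule for association; this conservative cut
is the package's choice) is tested by GLS after projecting phenotype and
dosage orthogonal to the fixed effects in the V-metric:
`β̂ = x̃ᵀV⁻¹ỹ / x̃ᵀV⁻¹x̃`, `se² = 1/(x̃ᵀV⁻¹x̃)`, p from χ²(1).  With
`σ²_g` pinned to zero the scan reduces exactly to OLS, which the tests
verify against an independent least-squares oracle.

PVE is `β²Var(x)/Var(y)` clipped to [0, 1].  The genome-wide threshold is
`α/m` (the Bonferroni ratio; with m = 35,571 and α = 0.05 it reproduces
the printed 1.41 × 10⁻⁶).  Meta-analysis uses sample-size weighting:
`Z_i = Φ⁻¹(1 − p_i/2)·sign(β_i)`, `Z = Σ√n_i Z_i/√Σn_i`; single-study
variants carry through, zero p-values are clamped to the smallest
positive double.  Effect direction for split multiallelic records is
keyed on each split record's own alternate allele.

## AWM and PCIT

Variants enter the AWM when `p < 1e-4` for the main trait or in at least
10 expression scans.  AWM entries are `z = β/se`; a scan that lacks a
selected variant (filtered by MAF/call rate) contributes z = 0, so the
matrix is complete.  Row annotation assigns each variant the nearest TSS
on its chromosome.  Column standardization is an optional flag — the
network step is correlation-based and unaffected by it.

PCIT prunes the column-correlation matrix: for every trio (x, y, z) the
three first-order partial correlations define a local tolerance
ε = mean of the partial-to-direct ratios, and edge (x, y) is flagged
non-significant if some z gives `|r_xy| < ε|r_xz|` and
`|r_xy| < ε|r_yz|`.  Note the rule is magnitude-dependent: in a strong
multiplicative chain (r = 0.8, 0.8, 0.64) the indirect edge *survives*
(ε ≈ 0.52, 0.64 > 0.52·0.8), while a weak chain (0.5, 0.5, 0.25) is
pruned — the tests pin both cases and verify the full implementation
against an exhaustive O(n³) oracle.  Direct correlations below 1e-12 are
pruned outright; a trio containing a perfect (|r| = 1) correlation has
undefined partials and the affected edges are treated as dominated via
the perfect proxy.  Trio enumeration is exact and vectorized per
mediator; no approximation is used at the panel sizes involved
(≤ a few hundred traits).

## TFBS enrichment

JASPAR matrices are parsed with Biopython; log-odds are
`log2(((f + pc)/(colsum + 4pc))/bg)` with pseudocount 0.25 and uniform
background by default.  The scan window is `[TSS − 1500, TSS + 500)`;
both strands are scored by summing per-base log-odds, and a position is a
hit when its score reaches `min + threshold_frac·(max − min)` of the
matrix's attainable range.  `threshold_frac` (default 0.85) is this
package's scanning knob; the reference scanner's internal match-score
cut-off is not published, so no claim is made of reproducing its exact
p-values.

Coverage enrichment counts a gene as covered if it has ≥ 1 hit and tests
the covered/uncovered × foreground/background table with a one-sided
Fisher exact test (a two-sided flag exists);
`log2_enrichment = log2((cf/nf)/(cb/nb))`, with an infinity sentinel when
background coverage is zero.  Because the exact tail p-value of a
discrete table is conservative by construction, a `midp` option
implements the standard mid-p correction; the null-calibration test uses
it, while reported results and the hypergeometric-oracle comparison use
the exact tail.

## Problem sizes and numerical choices

Synthetic panels default to 5 chromosomes × 400 tested and 400 chip
markers — large enough for stable LOCO REML while keeping the full
pipeline around half a minute and the replicated acceptance suites within
minutes; the screening-panel arithmetic (thresholds, selection fractions)
uses the full 35,571-variant size since it costs nothing.  Cohort sizes,
heritability, PVE, expression dimensions and gene-set sizes are kept at
the study's values.  Ties and degenerate inputs: monomorphic tested
variants are skipped; constant-expression genes are excluded from the
eGWAS with a log entry; empty AWM selections produce empty outputs rather
than errors; merge ordering is made deterministic by full-key sorting.

## Limitations

- No cross-panel LD and no relatedness structure (half-sib families are
  not actually related in the generator); the GRM correction is therefore
  exercised for stratification-free data only.
- Phenotypes are Gaussian by construction; the Box–Cox step and its
  interaction with model calibration are untested.
- The caller error model is i.i.d. per record; real callers err
  systematically by SV type and size.
- PCIT is applied to correlations computed across selected variants;
  with few selected rows those correlations are noisy, and the network on
  the default synthetic cohort is illustrative rather than inferential.
- Enrichment power figures depend on the synthetic motif's information
  content and the uniform background composition.
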