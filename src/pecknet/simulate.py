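"""Synthetic cohorts with the statistical structure of the two study designs.

The generators emulate an F2 cross and a half-sib (HS) population of
chickens divergently selected for feather-pecking behaviour: diploid
genotypes with tunable adjacent-marker LD, a polygenic + single-QTL
phenotype on the Box-Cox scale (already Gaussian), eQTL-driven brain
expression for a panel of genes with a transcription-factor hub, noisy
multi-caller SV call sets over a shared truth set, and promoter sequences
with planted binding motifs.  Everything is a pure function of
(configuration, seed) so that every downstream stage of the pipeline can be
tested without external data.

Two marker panels are simulated per cohort: a dense "chip" panel that
carries the polygenic background and feeds the genomic relationship matrix,
and the tested "sv" panel of SV/TR dosages.  The panels are generated on
independent haplotypes (no cross-panel LD), which keeps the null
distribution of the SV/TR association clean while the chip GRM still
absorbs the polygenic background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MISSING, CallerRecord

logger = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])


class ConfigurationError(ValueError):
    """A simulation configuration is internally inconsistent."""


# fixed spawn keys: one global seed expands into per-component child streams
_COMPONENT_KEYS = {
    "genotypes_chip": 1,
    "genotypes_sv": 2,
    "truth": 3,
    "phenotype": 4,
    "expression": 5,
    "callers": 6,
    "promoters": 7,
    "annotation": 8,
}


def child_rng(seed: int, component: str, extra: int = 0) -> np.random.Generator:
    """Independent random stream for one generator component."""
    key = _COMPONENT_KEYS[component]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key, extra)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cohort.

    Defaults mirror the half-sib design: 494 phenotyped hens in 7 hatches
    from two divergently selected lines, heritability 0.15, one QTL
    explaining 4.7% of the (fixed-effect-adjusted) phenotypic variance,
    brain expression of 86 genes in 167 of the hens with a
    transcription-factor hub regulating 23 of them.
    """

    seed: int = 7
    n_samples: int = 494
    n_chromosomes: int = 5
    n_variants_per_chrom: int = 400
    n_chip_per_chrom: int = 400
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.5
    missing_rate: float = 0.0
    h2_polygenic: float = 0.15
    qtl_spec: tuple[tuple[int, float], ...] = ((200, 0.047),)
    n_hatches: int = 7
    two_lines: bool = True
    hatch_sd: float = 0.5
    line_effect: float = 0.5
    n_genes: int = 86
    n_expr_samples: int = 167
    eqtl_effect: float = 1.0
    expr_noise_sd: float = 1.0
    tf_hub: tuple[int, tuple[int, ...], float] = (0, tuple(range(1, 24)), 0.8)
    eqtl_hotspots: tuple[tuple[int, ...], ...] | None = None
    n_background_genes: int = 500
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    plant_prob_fore: float = 0.6
    plant_prob_back: float = 0.2
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_sv_truth: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0 <= self.ld_decay < 1):
            raise ConfigurationError("ld_decay must lie in [0, 1)")
        total_pve = sum(p for _, p in self.qtl_spec)
        if not (0 <= self.h2_polygenic < 1) or self.h2_polygenic + total_pve >= 1:
            raise ConfigurationError(
                "h2_polygenic plus total QTL PVE must stay below 1 "
                f"(got {self.h2_polygenic} + {total_pve})"
            )
        for name in (
            "n_samples",
            "n_chromosomes",
            "n_variants_per_chrom",
            "n_chip_per_chrom",
            "n_hatches",
            "n_genes",
            "n_expr_samples",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_expr_samples > self.n_samples:
            raise ConfigurationError("n_expr_samples cannot exceed n_samples")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if abs(sum(self.base_probs) - 1) > 1e-9 or min(self.base_probs) < 0:
            raise ConfigurationError("base_probs must be a probability vector")
        hub, targets, _ = self.tf_hub
        for g in (hub, *targets):
            if not (0 <= g < self.n_genes):
                raise ConfigurationError("tf_hub gene index out of range")
        for group in self.hotspot_groups():
            for g in group:
                if not (0 <= g < self.n_genes):
                    raise ConfigurationError("eqtl_hotspots gene index out of range")
        m_sv = self.n_chromosomes * self.n_variants_per_chrom
        for idx, pve in self.qtl_spec:
            if not (0 <= idx < m_sv):
                raise ConfigurationError(f"QTL index {idx} outside the sv panel")
            if pve < 0:
                raise ConfigurationError("QTL PVE must be non-negative")

    def hotspot_groups(self) -> tuple[tuple[int, ...], ...]:
        """Trans-eQTL hotspot gene groups; the default places two 12-gene
        blocks after the hub neighbourhood when the panel is large enough."""
        if self.eqtl_hotspots is not None:
            return self.eqtl_hotspots
        hub, targets, _ = self.tf_hub
        taken = {hub, *targets}
        free = [g for g in range(self.n_genes) if g not in taken]
        if len(free) < 24:
            return ()
        return (tuple(free[:12]), tuple(free[12:24]))


def hs_config(seed: int = 7, **overrides) -> SimConfig:
    """Half-sib design: line + hatch fixed effects, expression subset."""
    return SimConfig(seed=seed, n_samples=494, two_lines=True, **overrides)


def f2_config(seed: int = 7, **overrides) -> SimConfig:
    """F2-cross design: hatch is the only fixed effect."""
    return SimConfig(seed=seed, n_samples=817, two_lines=False, **overrides)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    ``dosages`` is int8 with values {0, 1, 2} and :data:`~pecknet.variants.MISSING`
    for no-calls.  ``variants`` carries id, chrom, pos, panel ("chip" or
    "sv") and the generative allele frequency.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def panel(self, name: str) -> "GenotypeMatrix":
        mask = (self.variants["panel"] == name).to_numpy()
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )

    def allele_freqs(self) -> np.ndarray:
        """Observed alternate-allele frequencies, ignoring missing calls."""
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def dosage_float(self, mean_impute: bool = True) -> np.ndarray:
        """Float dosages with missing entries NaN or mean-imputed."""
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        if mean_impute:
            col_mean = np.nanmean(d, axis=0)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d


def _simulate_haplotypes(
    rng: np.random.Generator, n_hap: int, freqs: np.ndarray, ld_decay: float
) -> np.ndarray:
    """Markov chain of allele indicators along one chromosome.

    Adjacent variants i, i+1 are given Pearson correlation
    min(ld_decay, Frechet bound for their frequencies); with equal
    frequencies the realized adjacent correlation equals ``ld_decay``
    exactly in expectation.
    """
    m = len(freqs)
    H = np.empty((n_hap, m), dtype=bool)
    H[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, m):
        p0, p1 = freqs[j - 1], freqs[j]
        cov_max = min(min(p0, p1) - p0 * p1, (1 - p0) * p1, p0 * (1 - p1))
        cov = min(ld_decay * np.sqrt(p0 * (1 - p0) * p1 * (1 - p1)), cov_max)
        cov = max(cov, 0.0)
        p_given1 = p1 + cov / p0
        p_given0 = p1 - cov / (1 - p0)
        probs = np.where(H[:, j - 1], p_given1, p_given0)
        H[:, j] = rng.random(n_hap) < probs
    return H


def _simulate_panel(
    rng: np.random.Generator, cfg: SimConfig, panel: str, m_per_chrom: int, spacing: int
) -> tuple[pd.DataFrame, np.ndarray]:
    lo, hi = cfg.maf_range
    rows = []
    blocks = []
    for c in range(1, cfg.n_chromosomes + 1):
        freqs = rng.uniform(lo, hi, m_per_chrom)
        H = _simulate_haplotypes(rng, 2 * cfg.n_samples, freqs, cfg.ld_decay)
        G = (H[0::2].astype(np.int8) + H[1::2].astype(np.int8))
        blocks.append(G)
        for j in range(m_per_chrom):
            rows.append(
                {
                    "id": f"{panel}_{c}_{j}",
                    "chrom": f"chr{c}",
                    "pos": (j + 1) * spacing,
                    "panel": panel,
                    "freq": freqs[j],
                }
            )
    dosages = np.concatenate(blocks, axis=1)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING
    return pd.DataFrame(rows), dosages


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate chip and SV/TR dosage panels for one cohort.

    Allele frequencies are uniform over ``cfg.maf_range``; within-panel LD
    follows a first-order Markov (AR(1)-style) process on haplotypes with
    adjacent-marker correlation ``cfg.ld_decay``; haplotypes pair into
    diplotype dosages in {0, 1, 2}.  Reproducible given ``cfg.seed``.
    """
    chip_meta, chip_dos = _simulate_panel(
        child_rng(cfg.seed, "genotypes_chip"), cfg, "chip", cfg.n_chip_per_chrom, 10_000
    )
    sv_meta, sv_dos = _simulate_panel(
        child_rng(cfg.seed, "genotypes_sv"), cfg, "sv", cfg.n_variants_per_chrom, 10_007
    )
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    variants = pd.concat([chip_meta, sv_meta], ignore_index=True)
    dosages = np.concatenate([chip_dos, sv_dos], axis=1)
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


@dataclass
class TruthSet:
    """Ground truth underlying one simulated cohort.

    Holds everything parameter-recovery tests need: polygenic effects on
    the chip panel, QTL effects on the sv panel, variance components, the
    eQTL map and hub wiring, true SV records for the caller simulator, and
    the designated/realized motif-carrying promoter sets.
    """

    polygenic_effects: np.ndarray  # per chip marker, on standardized dosages
    qtl: list[dict] = field(default_factory=list)  # sv_index, beta, target_pve
    sigma_g2: float = 0.0
    sigma_e2: float = 1.0
    realized: dict = field(default_factory=dict)
    eqtl: dict[int, tuple[int, float]] = field(default_factory=dict)  # gene -> (sv idx, beta)
    hub_gene: int = 0
    hub_targets: tuple[int, ...] = ()
    hub_effect: float = 0.0
    sv_records: list[CallerRecord] = field(default_factory=list)
    foreground_genes: set[str] = field(default_factory=set)
    background_genes: set[str] = field(default_factory=set)
    planted_genes: set[str] = field(default_factory=set)


def _random_sv_records(rng: np.random.Generator, cfg: SimConfig) -> list[CallerRecord]:
    records = []
    for i in range(cfg.n_sv_truth):
        sv_type = rng.choice(["DEL", "DUP", "INV", "TRA"], p=[0.54, 0.12, 0.25, 0.09])
        chrom = f"chr{rng.integers(1, cfg.n_chromosomes + 1)}"
        start = int(rng.integers(10_000, 10_000_000))
        if sv_type == "TRA":
            chrom2 = f"chr{rng.integers(1, cfg.n_chromosomes + 1)}"
            end = int(rng.integers(10_000, 10_000_000))
            start, end = (start, end) if chrom != chrom2 or start <= end else (end, start)
        else:
            chrom2 = chrom
            length = int(np.exp(rng.uniform(np.log(50), np.log(5000))))
            end = start + length - 1
        strands = tuple(rng.choice(["+", "-"], size=2))
        freq = rng.uniform(0.1, 0.5)
        gts = rng.binomial(2, freq, size=cfg.n_samples).astype(np.int8)
        records.append(
            CallerRecord(
                caller_id="truth",
                chrom=chrom,
                start=start,
                end=end,
                sv_type=str(sv_type),
                strands=(str(strands[0]), str(strands[1])),
                qual=float(rng.normal(2000, 300)),
                genotypes=gts,
                chrom2=chrom2,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def draw_truth(cfg: SimConfig, gt: GenotypeMatrix) -> TruthSet:
    """Draw all latent ground truth for a cohort (effects, eQTL map, SVs)."""
    rng = child_rng(cfg.seed, "truth")
    m_chip = cfg.n_chromosomes * cfg.n_chip_per_chrom
    poly = rng.normal(0.0, 1.0, m_chip)

    sv = gt.panel("sv")
    x = sv.dosage_float()
    qtl = []
    for idx, pve in cfg.qtl_spec:
        var_x = float(np.var(x[:, idx]))
        if var_x <= 0:
            raise ConfigurationError(f"QTL variant {idx} is monomorphic in this draw")
        beta = float(np.sqrt(pve / var_x))
        qtl.append({"sv_index": int(idx), "beta": beta, "target_pve": float(pve)})

    m_sv = sv.n_variants
    gene_ids = [f"EG{g:03d}" for g in range(cfg.n_genes)]
    eqtl = {g: (int(rng.integers(0, m_sv)), cfg.eqtl_effect) for g in range(cfg.n_genes)}
    # trans-eQTL hotspots: every gene in a group shares one regulatory variant
    for group in cfg.hotspot_groups():
        shared = int(rng.integers(0, m_sv))
        for g in group:
            eqtl[g] = (shared, cfg.eqtl_effect)
    hub_gene, hub_targets, hub_effect = cfg.tf_hub

    fore = {gene_ids[t] for t in hub_targets}
    back = {f"BG{b:04d}" for b in range(cfg.n_background_genes)}

    total_pve = sum(p for _, p in cfg.qtl_spec)
    return TruthSet(
        polygenic_effects=poly,
        qtl=qtl,
        sigma_g2=cfg.h2_polygenic,
        sigma_e2=1.0 - cfg.h2_polygenic - total_pve,
        eqtl=eqtl,
        hub_gene=hub_gene,
        hub_targets=tuple(hub_targets),
        hub_effect=hub_effect,
        sv_records=_random_sv_records(rng, cfg),
        foreground_genes=fore,
        background_genes=back,
    )


def simulate_phenotype(gt: GenotypeMatrix, cfg: SimConfig, truth: TruthSet) -> pd.DataFrame:
    """Simulate the Box-Cox-scale feather-pecking phenotype (FPD_BC).

    y = hatch effect (+ line effect in the HS design) + QTL effects +
    polygenic term + Gaussian noise.  The polygenic term is the sum of the
    chip-marker effects in ``truth`` on standardized dosages, rescaled so
    its sample variance is exactly ``cfg.h2_polygenic``; noise variance is
    1 - h2 - total QTL PVE, so heritability and per-QTL PVE are defined
    relative to the fixed-effect-adjusted phenotypic variance (target 1).
    Realized variance fractions are stored in ``truth.realized``.
    """
    rng = child_rng(cfg.seed, "phenotype")
    n = gt.n_samples

    chip = gt.panel("chip")
    z = chip.dosage_float()
    z = z - z.mean(axis=0)
    sd = z.std(axis=0)
    keep = sd > 0
    z[:, keep] = z[:, keep] / sd[keep]
    z[:, ~keep] = 0.0
    g_raw = z @ truth.polygenic_effects
    g_sd = g_raw.std()
    g = (
        g_raw * np.sqrt(cfg.h2_polygenic) / g_sd
        if cfg.h2_polygenic > 0 and g_sd > 0
        else np.zeros(n)
    )

    sv = gt.panel("sv")
    x = sv.dosage_float()
    q = np.zeros(n)
    for spec in truth.qtl:
        q += spec["beta"] * x[:, spec["sv_index"]]

    e = rng.normal(0.0, np.sqrt(truth.sigma_e2), n)

    hatches = rng.integers(0, cfg.n_hatches, n)
    hatch_effects = rng.normal(0.0, cfg.hatch_sd, cfg.n_hatches)
    fixed = hatch_effects[hatches]
    if cfg.two_lines:
        line = np.array(["HFP", "LFP"])[(np.arange(n) % 2)]
        fixed = fixed + np.where(line == "HFP", cfg.line_effect / 2, -cfg.line_effect / 2)
    else:
        line = np.array(["F2"] * n)

    y = fixed + g + q + e

    var_adj = np.var(g + q + e)
    truth.realized = {
        "var_polygenic": float(np.var(g)),
        "var_noise": float(np.var(e)),
        "var_adjusted": float(var_adj),
        "h2": float(np.var(g) / var_adj) if var_adj > 0 else 0.0,
        "qtl_pve": [
            float(spec["beta"] ** 2 * np.var(x[:, spec["sv_index"]]) / var_adj)
            for spec in truth.qtl
        ],
    }

    return pd.DataFrame(
        {
            "sample_id": gt.samples,
            "fpd_bc": y,
            "hatch": [f"H{h}" for h in hatches],
            "line": line,
        }
    )


def simulate_expression(gt: GenotypeMatrix, cfg: SimConfig, truth: TruthSet) -> pd.DataFrame:
    """Simulate normalized brain expression for the gene panel.

    Expression of each gene = cis-eQTL effect on its mapped variant
    (standardized dosage) + hub contribution (targets receive
    hub_effect x hub expression) + Gaussian noise.  The hub gene carries
    its own eQTL, so the eGWAS of every target hits the hub variant.
    Returns a samples x genes table for the expression subcohort.
    """
    rng = child_rng(cfg.seed, "expression")
    if not set(truth.hub_targets) <= set(range(cfg.n_genes)):
        raise ConfigurationError("tf_hub indices out of range")
    ns = cfg.n_expr_samples
    sv = gt.panel("sv")
    x = sv.dosage_float()[:ns]
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    x = np.divide(x, sd, out=np.zeros_like(x), where=sd > 0)

    expr = np.empty((ns, cfg.n_genes))
    noise = rng.normal(0.0, cfg.expr_noise_sd, (ns, cfg.n_genes))
    hub = truth.hub_gene
    v_hub, b_hub = truth.eqtl[hub]
    expr[:, hub] = b_hub * x[:, v_hub] + noise[:, hub]
    for g in range(cfg.n_genes):
        if g == hub:
            continue
        v, b = truth.eqtl[g]
        expr[:, g] = b * x[:, v] + noise[:, g]
        if g in truth.hub_targets:
            expr[:, g] += truth.hub_effect * expr[:, hub]

    genes = [f"EG{g:03d}" for g in range(cfg.n_genes)]
    return pd.DataFrame(expr, index=pd.Index(gt.samples[:ns], name="sample_id"), columns=genes)


def simulate_caller_outputs(
    truth: TruthSet,
    n_callers: int = 3,
    jitter_sd: float = 0.0,
    fn_rate_per_caller: float | list[float] = 0.0,
    fp_rate: float = 0.0,
    seed: int = 0,
    caller_missing_rate: float = 0.05,
) -> list[list[CallerRecord]]:
    """Emit noisy per-caller call sets over the shared SV truth set.

    Each caller reports each true SV with probability 1 - fn_rate, with
    breakpoints perturbed by rounded Gaussian jitter (sd ``jitter_sd``) and
    type/strands preserved; false positives are added at rate ``fp_rate``
    (relative to the truth-set size) with random type and position.  QUAL
    is drawn per record around the truth value; per-sample genotypes are
    carried over with caller-specific missingness.
    """
    if n_callers < 1:
        raise ConfigurationError("n_callers must be >= 1")
    if np.isscalar(fn_rate_per_caller):
        fn_rates = [float(fn_rate_per_caller)] * n_callers
    else:
        fn_rates = list(fn_rate_per_caller)
        if len(fn_rates) != n_callers:
            raise ConfigurationError("fn_rate_per_caller length must match n_callers")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_COMPONENT_KEYS["callers"],)))
    callsets: list[list[CallerRecord]] = []
    n_samples = len(truth.sv_records[0].genotypes) if truth.sv_records else 0
    for c in range(n_callers):
        caller_id = f"caller{c}"
        calls: list[CallerRecord] = []
        for rec in truth.sv_records:
            if rng.random() < fn_rates[c]:
                continue
            if jitter_sd > 0:
                ds, de = np.round(rng.normal(0.0, jitter_sd, 2)).astype(int)
            else:
                ds = de = 0
            start, end = rec.start + int(ds), rec.end + int(de)
            if rec.chrom == rec.chrom2 and start > end:
                start, end = end, start
            gts = rec.genotypes.copy()
            if caller_missing_rate > 0:
                gts[rng.random(len(gts)) < caller_missing_rate] = MISSING
            calls.append(
                CallerRecord(
                    caller_id=caller_id,
                    chrom=rec.chrom,
                    start=max(1, start),
                    end=max(1, end),
                    sv_type=rec.sv_type,
                    strands=rec.strands,
                    qual=float(max(0.0, rec.qual + rng.normal(0, 150))),
                    genotypes=gts,
                    chrom2=rec.chrom2,
                )
            )
        fp_chroms = sorted({r.chrom for r in truth.sv_records}) or ["chr1"]
        n_fp = rng.poisson(fp_rate * max(1, len(truth.sv_records)))
        for _ in range(n_fp):
            sv_type = str(rng.choice(["DEL", "DUP", "INV"]))
            chrom = str(rng.choice(fp_chroms))
            start = int(rng.integers(10_000, 10_000_000))
            end = start + int(rng.integers(30, 3000))
            calls.append(
                CallerRecord(
                    caller_id=caller_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    sv_type=sv_type,
                    strands=(str(rng.choice(["+", "-"])), str(rng.choice(["+", "-"]))),
                    qual=float(max(0.0, rng.normal(600, 200))),
                    genotypes=np.full(n_samples, MISSING, dtype=np.int8),
                    chrom2=chrom,
                )
            )
        calls.sort(key=lambda r: (r.chrom, r.start, r.end))
        callsets.append(calls)
    return callsets


def make_gene_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Gene annotation (gene_id, chrom, tss, strand) for expression and
    background genes; TSS positions are uniform over the simulated genome."""
    rng = child_rng(cfg.seed, "annotation")
    genes = [f"EG{g:03d}" for g in range(cfg.n_genes)] + [
        f"BG{b:04d}" for b in range(cfg.n_background_genes)
    ]
    rows = []
    for gid in genes:
        rows.append(
            {
                "gene_id": gid,
                "chrom": f"chr{rng.integers(1, cfg.n_chromosomes + 1)}",
                "tss": int(rng.integers(10_000, 10_000_000)),
                "strand": str(rng.choice(["+", "-"])),
            }
        )
    return pd.DataFrame(rows)


def simulate_promoters(
    genes: pd.DataFrame,
    pwm,
    cfg: SimConfig,
    motif_genes: set[str],
    truth: TruthSet | None = None,
) -> dict[str, str]:
    """Promoter windows with planted motifs.

    Each gene receives an i.i.d. background sequence of length
    upstream + downstream (composition ``cfg.base_probs``), oriented 5'->3'
    with the TSS at index ``cfg.promoter_upstream``.  Genes in
    ``motif_genes`` receive one consensus-sampled motif instance at a
    uniform position with probability ``plant_prob_fore``, all others with
    ``plant_prob_back``; insertion strand is random.  If ``truth`` is
    given, the realized planted set is recorded there.
    """
    from .tfbs import reverse_complement, sample_motif  # local import, no cycle at module load

    length = cfg.promoter_upstream + cfg.promoter_downstream
    if pwm.length > length:
        raise ConfigurationError("motif longer than the promoter window")
    rng = child_rng(cfg.seed, "promoters")
    probs = np.asarray(cfg.base_probs)
    gene_ids = list(genes["gene_id"])
    background = BASES[rng.choice(4, size=(len(gene_ids), length), p=probs)]
    seqs: dict[str, str] = {}
    planted: set[str] = set()
    for row, gid in enumerate(gene_ids):
        seq = background[row]
        p_plant = cfg.plant_prob_fore if gid in motif_genes else cfg.plant_prob_back
        if rng.random() < p_plant:
            instance = sample_motif(pwm, rng)
            if rng.random() < 0.5:
                instance = reverse_complement(instance)
            pos = int(rng.integers(0, length - pwm.length + 1))
            seq[pos : pos + pwm.length] = list(instance)
            planted.add(gid)
        seqs[gid] = "".join(seq)
    if truth is not None:
        truth.planted_genes = planted
    return seqs


def simulate_cohort(cfg: SimConfig):
    """Convenience wrapper: genotypes, truth, phenotype and expression."""
    gt = simulate_genotypes(cfg)
    truth = draw_truth(cfg, gt)
    pheno = simulate_phenotype(gt, cfg, truth)
    expr = simulate_expression(gt, cfg, truth)
    return gt, truth, pheno, expr
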