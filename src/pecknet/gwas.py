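"""Mixed-linear-model association with leave-one-chromosome-out GRMs.

The association model for each tested variant is

    y = W a + x b + u + e,     u ~ N(0, A s2_g),   e ~ N(0, I s2_e)

where W holds the fixed effects (intercept, hatch and, in the half-sib
design, line), x is the dosage vector of the tested variant, and A is a
genomic relationship matrix built from the chip-marker panel *excluding*
the chromosome being tested (LOCO), so that a variant never contributes to
its own correction term.  Variance components are estimated once per LOCO
chromosome by restricted maximum likelihood; each variant is then tested
with a generalized-least-squares Wald statistic against chi-square(1).

Also provided: the per-variant proportion of variance explained
(PVE = b^2 Var(x) / Var(y)), the Bonferroni genome-wide threshold, and the
sample-size-weighted Z-score meta-analysis used to combine the F2 and
half-sib designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

#: smallest p-value carried into meta-analysis Z conversion
P_FLOOR = 1e-300


class ComputationError(RuntimeError):
    pass


@dataclass
class GRM:
    """Genomic relationship matrix over a fixed sample order."""

    matrix: np.ndarray
    samples: list[str]
    m_markers: int
    excluded_chrom: str | None = None

    def __post_init__(self) -> None:
        a = self.matrix
        if not np.allclose(a, a.T, atol=1e-10):
            raise ComputationError("GRM must be symmetric")
        if not np.all(np.isfinite(a)):
            raise ComputationError("GRM contains non-finite entries")


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    log_likelihood: float
    converged: bool
    n_iterations: int

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def compute_grm(
    gt: GenotypeMatrix,
    exclude_chrom: str | None = None,
    panel: str | None = None,
) -> GRM:
    """Standardized-dosage GRM: A_jk = (1/m) sum_i z_ij z_ik with
    z_ij = (x_ij - 2 p_i) / sqrt(2 p_i (1 - p_i)).

    Missing dosages are mean-imputed (contribute 0 after centering);
    monomorphic markers and markers on ``exclude_chrom`` are skipped.
    """
    if panel is not None:
        gt = gt.panel(panel)
    variants = gt.variants
    mask = np.ones(len(variants), dtype=bool)
    if exclude_chrom is not None:
        mask &= (variants["chrom"] != exclude_chrom).to_numpy()
    x = gt.dosage_float(mean_impute=True)[:, mask]
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1) & (x.std(axis=0) > 0)
    if poly.sum() < 2:
        raise ComputationError("fewer than 2 polymorphic markers available for the GRM")
    x = x[:, poly]
    p = p[poly]
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    m = z.shape[1]
    a = (z @ z.T) / m
    return GRM(matrix=a, samples=list(gt.samples), m_markers=int(m), excluded_chrom=exclude_chrom)


def _restricted_loglik_rot(
    lam: float, yr: np.ndarray, wr: np.ndarray, d: np.ndarray
) -> tuple[float, float]:
    """Profile restricted log-likelihood in the eigenbasis of A.

    ``lam`` is the variance ratio s2_g / s2_e; returns (loglik, s2_e_hat).
    """
    n, c = wr.shape
    dv = lam * d + 1.0
    wd = wr / dv[:, None]
    wtw = wr.T @ wd
    wty = wd.T @ yr
    try:
        cho = linalg.cho_factor(wtw)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded by full-rank pre
        raise ComputationError("singular fixed-effect design") from exc
    alpha = linalg.cho_solve(cho, wty)
    resid_q = float(yr @ (yr / dv) - wty @ alpha)
    df = n - c
    s2e = max(resid_q / df, 1e-12)
    logdet_v = float(np.sum(np.log(dv)))
    logdet_wvw = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    ll = -0.5 * (logdet_v + logdet_wvw + df * (1.0 + np.log(2.0 * np.pi * s2e)))
    return ll, s2e


def fit_reml(
    y: np.ndarray,
    w: np.ndarray,
    grm: GRM | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
    _eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """REML estimates of (s2_g, s2_e) for y = W a + u + e, u ~ N(0, A s2_g).

    The GRM is eigendecomposed once; the restricted likelihood is profiled
    over the variance ratio s2_g/s2_e and maximized on the log scale by
    bounded scalar search, with the s2_g = 0 boundary checked explicitly.
    Non-convergence is flagged on the result, not raised.
    """
    a = grm.matrix if isinstance(grm, GRM) else np.asarray(grm)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    if np.linalg.matrix_rank(w) < w.shape[1]:
        raise ComputationError("fixed-effect design matrix is rank deficient")
    if len(y) != a.shape[0] or len(y) != w.shape[0]:
        raise ComputationError("dimension mismatch between y, W and the GRM")

    if _eig is None:
        d, u = linalg.eigh(a)
    else:
        d, u = _eig
    d = np.clip(d, 0.0, None)
    yr = u.T @ y
    wr = u.T @ w

    def neg_ll(t: float) -> float:
        return -_restricted_loglik_rot(np.exp(t), yr, wr, d)[0]

    res = optimize.minimize_scalar(
        neg_ll, bounds=(-25.0, 25.0), method="bounded", options={"xatol": tol, "maxiter": max_iter}
    )
    ll_zero, s2e_zero = _restricted_loglik_rot(0.0, yr, wr, d)
    ll_opt, s2e_opt = _restricted_loglik_rot(np.exp(res.x), yr, wr, d)
    if ll_zero >= ll_opt - 1e-10:
        sigma_g2, sigma_e2, ll = 0.0, s2e_zero, ll_zero
    else:
        lam = float(np.exp(res.x))
        sigma_g2, sigma_e2, ll = lam * s2e_opt, s2e_opt, ll_opt
    return VarianceComponents(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        log_likelihood=float(ll),
        converged=bool(res.success),
        n_iterations=int(res.nfev),
    )


def design_matrix(pheno: pd.DataFrame, covariates: tuple[str, ...] = ("hatch",)) -> np.ndarray:
    """Intercept plus full-rank indicator contrasts for the named factors."""
    cols = [np.ones(len(pheno))]
    for cov in covariates:
        levels = pd.unique(pheno[cov])
        if len(levels) < 2:
            continue  # constant factor carries no contrast
        dummies = pd.get_dummies(pheno[cov], drop_first=True).to_numpy(dtype=float)
        cols.append(dummies)
    return np.column_stack(cols)


class LocoContext:
    """Cached per-chromosome eigendecompositions of LOCO GRMs.

    Building the GRM and its eigendecomposition is the expensive part of a
    mixed-model scan; caching it lets many traits (the 86 expression
    phenotypes of the eGWAS) share one correction structure.
    """

    def __init__(self, grm_gt: GenotypeMatrix, chroms: list[str], grm_panel: str | None = "chip"):
        self.chroms = chroms
        self._eigs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._grms: dict[str, GRM] = {}
        for c in chroms:
            grm = compute_grm(grm_gt, exclude_chrom=c, panel=grm_panel)
            d, u = linalg.eigh(grm.matrix)
            self._grms[c] = grm
            self._eigs[c] = (np.clip(d, 0.0, None), u)

    def grm(self, chrom: str) -> GRM:
        return self._grms[chrom]

    def eig(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._eigs[chrom]


def _scan_chromosome(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    eig: tuple[np.ndarray, np.ndarray],
    vc: VarianceComponents,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS Wald scan of all columns of x under V = s2_g A + s2_e I."""
    d, u = eig
    dv = vc.sigma_g2 * d + vc.sigma_e2
    yr = (u.T @ y) / np.sqrt(dv)
    wr = (u.T @ w) / np.sqrt(dv)[:, None]
    xr = (u.T @ x) / np.sqrt(dv)[:, None]
    # project out fixed effects in the V-metric
    qw, _ = np.linalg.qr(wr)
    yt = yr - qw @ (qw.T @ yr)
    xt = xr - qw @ (qw.T @ xr)
    xtx = np.einsum("ij,ij->j", xt, xt)
    xty = xt.T @ yt
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xtx > 0, xty / xtx, np.nan)
        se = np.where(xtx > 0, np.sqrt(1.0 / xtx), np.nan)
    chi2 = (beta / se) ** 2
    p = stats.chi2.sf(chi2, df=1)
    return beta, se, p


def mlma_loco(
    gt: GenotypeMatrix,
    pheno: pd.DataFrame,
    covariates: tuple[str, ...] = ("hatch",),
    maf_min: float = 0.01,
    grm_gt: GenotypeMatrix | None = None,
    grm_panel: str | None = "chip",
    test_panel: str | None = "sv",
    trait: str = "fpd_bc",
    min_callrate: float = 0.5,
    var_components: tuple[float, float] | None = None,
    loco: "LocoContext | None" = None,
) -> pd.DataFrame:
    """Mixed-linear-model association with a LOCO GRM, one row per variant.

    For each chromosome the GRM excludes that chromosome's chip markers,
    variance components are re-estimated by REML (unless ``var_components``
    pins them, e.g. ``(0, s2)`` for the pure fixed-effects model), and each
    variant with MAF >= ``maf_min`` and call rate >= ``min_callrate`` is
    tested.  Returns columns chrom, pos, id, maf, n, beta, se, p.
    """
    if grm_gt is None:
        grm_gt = gt
    tested = gt.panel(test_panel) if test_panel is not None else gt
    if list(tested.samples) != list(pheno["sample_id"]):
        # allow pheno covering a subset (e.g. the expression subcohort)
        sample_idx = [tested.samples.index(s) for s in pheno["sample_id"]]
        tested = GenotypeMatrix(
            samples=list(pheno["sample_id"]),
            variants=tested.variants,
            dosages=tested.dosages[sample_idx],
        )
        grm_gt = GenotypeMatrix(
            samples=list(pheno["sample_id"]),
            variants=grm_gt.variants,
            dosages=grm_gt.dosages[sample_idx],
        )
        loco = None  # cached decompositions no longer match the sample subset

    y = pheno[trait].to_numpy(dtype=float)
    w = design_matrix(pheno, covariates)
    chroms = list(pd.unique(tested.variants["chrom"]))
    if loco is None:
        loco = LocoContext(grm_gt, chroms, grm_panel=grm_panel)

    n = tested.n_samples
    callrate = np.mean(tested.dosages != -1, axis=0)
    freqs = tested.allele_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    x_all = tested.dosage_float(mean_impute=True)

    out = []
    for c in chroms:
        on_c = (tested.variants["chrom"] == c).to_numpy()
        usable = on_c & (maf >= maf_min) & (callrate >= min_callrate)
        if not usable.any():
            logger.info("no variant on %s passes MAF %.3g; skipping", c, maf_min)
            continue
        eig = loco.eig(c)
        if var_components is not None:
            vc = VarianceComponents(var_components[0], var_components[1], np.nan, True, 0)
        else:
            vc = fit_reml(y, w, loco.grm(c), _eig=eig)
            if not vc.converged:
                logger.warning("REML did not converge for LOCO chromosome %s", c)
        beta, se, p = _scan_chromosome(x_all[:, usable], y, w, eig, vc)
        meta = tested.variants.loc[usable]
        out.append(
            pd.DataFrame(
                {
                    "chrom": meta["chrom"].to_numpy(),
                    "pos": meta["pos"].to_numpy(),
                    "id": meta["id"].to_numpy(),
                    "maf": maf[usable],
                    "n": n,
                    "beta": beta,
                    "se": se,
                    "p": p,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["chrom", "pos", "id", "maf", "n", "beta", "se", "p"])
    res = pd.concat(out, ignore_index=True)
    return res.dropna(subset=["beta", "se"]).reset_index(drop=True)


def estimate_pve(beta: float, var_x: float, var_y: float) -> float:
    """Proportion of phenotypic variance explained by one variant:
    PVE = beta^2 Var(x) / Var(y), with Var(y) = beta^2 Var(x) + sigma^2."""
    if var_x < 0:
        raise ValueError("var_x must be non-negative")
    if var_y <= 0:
        raise ValueError("var_y must be positive")
    return float(np.clip(beta**2 * var_x / var_y, 0.0, 1.0))


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def meta_sample_size(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Sample-size-weighted Z-score meta-analysis across studies.

    Per variant: Z_i = Phi^-1(1 - p_i / 2) * sign(beta_i), weight
    w_i = sqrt(n_i), combined Z = sum(w_i Z_i) / sqrt(sum w_i^2), combined
    p = 2 (1 - Phi(|Z|)).  Variants present in a single study carry that
    study's Z through.  Zero p-values are clamped to the smallest positive
    value before conversion.
    """
    if len(results) < 1:
        raise ValueError("at least one study result required")
    frames = []
    for i, res in enumerate(results):
        df = res[["id", "chrom", "pos", "beta", "p", "n"]].copy()
        p = df["p"].to_numpy(dtype=float)
        if np.any(p <= 0):
            logger.warning("study %d: clamping %d non-positive p-values", i, int((p <= 0).sum()))
            p = np.clip(p, P_FLOOR, 1.0)
        z = stats.norm.isf(p / 2.0) * np.sign(df["beta"].to_numpy())
        df["z"] = z
        df["w"] = np.sqrt(df["n"].to_numpy(dtype=float))
        frames.append(df)
    longf = pd.concat(frames, ignore_index=True)
    grouped = longf.groupby("id", sort=False)
    agg = grouped.apply(
        lambda g: pd.Series(
            {
                "chrom": g["chrom"].iloc[0],
                "pos": g["pos"].iloc[0],
                "z": np.sum(g["w"] * g["z"]) / np.sqrt(np.sum(g["w"] ** 2)),
                "n": g["n"].sum(),
                "n_studies": len(g),
            }
        ),
        include_groups=False,
    ).reset_index()
    agg["p"] = 2.0 * stats.norm.sf(np.abs(agg["z"].to_numpy(dtype=float)))
    agg["n"] = agg["n"].astype(int)
    agg["n_studies"] = agg["n_studies"].astype(int)
    return agg[["id", "chrom", "pos", "z", "p", "n", "n_studies"]]
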