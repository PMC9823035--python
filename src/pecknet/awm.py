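"""Association weight matrix and PCIT gene-network inference.

The association weight matrix (AWM) summarizes many association scans in
one signed z-score matrix: rows are variants selected for association with
the main phenotype or with many expression traits, columns are traits (the
main phenotype first, then one column per gene).  Correlating AWM columns
gives a trait-by-trait co-association matrix from which the PCIT
(partial correlation and information theory) algorithm prunes edges that
are explainable through a third trait, yielding a gene-gene interaction
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import LocoContext, mlma_loco
from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

#: direct correlations below this magnitude are pruned outright
TINY_CORR = 1e-12


def run_egwas(
    gt: GenotypeMatrix,
    expr: pd.DataFrame,
    covariates: tuple[str, ...] = ("hatch",),
    pheno: pd.DataFrame | None = None,
    **mlma_kwargs,
) -> dict[str, pd.DataFrame]:
    """One mixed-model association scan per expression trait.

    ``expr`` is a samples x genes table indexed by sample id; ``pheno``
    supplies the covariate levels for those samples (hatch by default).
    Genes with zero expression variance are skipped with a log entry.
    All scans share the variant panel and the LOCO correction structure.
    """
    if pheno is None:
        pheno = pd.DataFrame({"sample_id": expr.index, "hatch": "H0"})
        covariates = ()
    pheno = pheno.set_index("sample_id").loc[expr.index].reset_index()

    results: dict[str, pd.DataFrame] = {}
    sample_idx = [gt.samples.index(s) for s in expr.index]
    sub = GenotypeMatrix(
        samples=list(expr.index),
        variants=gt.variants,
        dosages=gt.dosages[sample_idx],
    )
    test_panel = mlma_kwargs.get("test_panel", "sv")
    grm_panel = mlma_kwargs.get("grm_panel", "chip")
    tested = sub.panel(test_panel) if test_panel is not None else sub
    chroms = list(pd.unique(tested.variants["chrom"]))
    shared_loco = LocoContext(sub, chroms, grm_panel=grm_panel)
    for gene in expr.columns:
        values = expr[gene].to_numpy(dtype=float)
        if np.var(values) == 0:
            logger.info("gene %s has zero expression variance; skipped", gene)
            continue
        p = pheno.copy()
        p[gene] = values
        results[gene] = mlma_loco(
            sub, p, covariates=covariates, trait=gene, loco=shared_loco, **mlma_kwargs
        )
    return results


def select_awm_variants(
    main: pd.DataFrame,
    egwas: dict[str, pd.DataFrame],
    p_thresh: float = 1e-4,
    min_egwas_hits: int = 10,
) -> list[str]:
    """Variants associated with the main trait or with many expression traits.

    A variant is selected when p_main < ``p_thresh`` OR its association
    p-value is below ``p_thresh`` in at least ``min_egwas_hits`` of the
    eGWAS scans.  The result is ordered by genome position.
    """
    main_hit = set(main.loc[main["p"] < p_thresh, "id"])
    counts: dict[str, int] = {}
    for res in egwas.values():
        for vid in res.loc[res["p"] < p_thresh, "id"]:
            counts[vid] = counts.get(vid, 0) + 1
    egwas_hit = {vid for vid, k in counts.items() if k >= min_egwas_hits}
    selected = main_hit | egwas_hit
    pos = main.set_index("id")
    order: list[tuple] = []
    for vid in selected:
        if vid in pos.index:
            row = pos.loc[vid]
            order.append(((row["chrom"], int(row["pos"])), vid))
        else:  # selected purely from eGWAS scans
            for res in egwas.values():
                hit = res.loc[res["id"] == vid]
                if len(hit):
                    order.append(((hit["chrom"].iloc[0], int(hit["pos"].iloc[0])), vid))
                    break
    order.sort()
    return [vid for _, vid in order]


@dataclass
class AWM:
    """Selected-variant x trait matrix of signed association z-scores."""

    z: pd.DataFrame  # rows: variant ids; columns: main trait then genes
    variant_gene: pd.Series  # row annotation: nearest/assigned gene per variant

    @property
    def traits(self) -> list[str]:
        return list(self.z.columns)


def assign_nearest_gene(variants: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Map each variant to the nearest annotated TSS on its chromosome."""
    out = {}
    for _, v in variants.iterrows():
        genes = annotation.loc[annotation["chrom"] == v["chrom"]]
        if genes.empty:
            out[v["id"]] = ""
            continue
        dist = (genes["tss"] - v["pos"]).abs()
        out[v["id"]] = genes.loc[dist.idxmin(), "gene_id"]
    return pd.Series(out, name="gene")


def build_awm(
    selected: list[str],
    main: pd.DataFrame,
    egwas: dict[str, pd.DataFrame],
    main_label: str = "FPD_BC",
    standardize: bool = False,
    annotation: pd.DataFrame | None = None,
) -> AWM:
    """Assemble the AWM: z = beta / se for every selected variant x trait.

    Scans that do not contain a selected variant (it fell below their MAF
    or call-rate cut) contribute z = 0, so the matrix has no missing
    entries.  With ``standardize`` each column is centred and scaled to
    unit variance (the PCIT step is correlation-based, so this only
    affects the exported matrix, not the network).
    """
    if not selected:
        raise ValueError("empty variant selection")
    cols = {}

    def z_of(res: pd.DataFrame) -> pd.Series:
        z = (res["beta"] / res["se"]).to_numpy()
        return pd.Series(z, index=res["id"]).reindex(selected).fillna(0.0)

    cols[main_label] = z_of(main)
    for gene, res in egwas.items():
        cols[gene] = z_of(res)
    z = pd.DataFrame(cols, index=pd.Index(selected, name="id"))
    if standardize:
        sd = z.std(axis=0, ddof=0).replace(0.0, 1.0)
        z = (z - z.mean(axis=0)) / sd
    if annotation is not None:
        meta = main.loc[main["id"].isin(selected), ["id", "chrom", "pos"]]
        gene_map = assign_nearest_gene(meta, annotation).reindex(selected).fillna("")
    else:
        gene_map = pd.Series("", index=z.index, name="gene")
    return AWM(z=z, variant_gene=gene_map)


def awm_correlation(awm: AWM) -> pd.DataFrame:
    """Pearson correlation between trait columns across selected variants."""
    z = awm.z.to_numpy(dtype=float)
    sd = z.std(axis=0)
    if np.any(sd == 0):
        logger.warning("constant AWM column(s); their correlations are set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(z, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=awm.traits, columns=awm.traits)


@dataclass
class GeneNetwork:
    """Undirected trait-trait network with PCIT significance flags."""

    nodes: list[str]
    edges: pd.DataFrame  # node_a, node_b (a < b by node order), weight, significant


def pcit(corr: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> GeneNetwork:
    """PCIT: prune correlation edges dominated through some third trait.

    For every trio (x, y, z) the three first-order partial correlations

        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

    define a local tolerance eps = mean of the three partial-to-direct
    ratios; the edge (x, y) is flagged non-significant if some z satisfies
    |r_xy| < eps |r_xz| and |r_xy| < eps |r_yz|.  Edges with |r| = 1 to a
    third trait make the partial undefined; such an edge pair is treated
    as dominated through the perfect proxy and pruned.  Direct
    correlations below ``TINY_CORR`` are pruned outright.
    """
    if isinstance(corr, pd.DataFrame):
        labels = list(corr.columns)
        c = corr.to_numpy(dtype=float)
    else:
        c = np.asarray(corr, dtype=float)
        if labels is None:
            labels = [f"T{i}" for i in range(c.shape[0])]
    n = c.shape[0]
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(np.abs(c) > 1 + 1e-8):
        raise ValueError("correlation entries must lie in [-1, 1]")
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)

    absc = np.abs(c)
    significant = np.ones((n, n), dtype=bool)
    significant[absc < TINY_CORR] = False

    if n >= 3:
        # ratio[a, b] given mediator z: |r_ab.z / r_ab|
        eye = np.eye(n, dtype=bool)
        for z in range(n):
            rz = c[:, z]
            denom2 = 1.0 - rz**2
            perfect = denom2 <= 0  # |r_xz| = 1 for some x
            perfect[z] = False  # the mediator's own unit self-correlation is not a proxy
            with np.errstate(divide="ignore", invalid="ignore"):
                pc_z = (c - np.outer(rz, rz)) / np.sqrt(np.outer(denom2, denom2))
                ratio_z = np.abs(pc_z) / np.maximum(absc, TINY_CORR)
            # ratios of the two edges that contain z, per (x, y) pair:
            # r_xz.y / r_xz as a function of (x, y)
            with np.errstate(divide="ignore", invalid="ignore"):
                num = rz[:, None] - c * rz[None, :]
                den = np.sqrt((1.0 - c**2) * denom2[None, :])
                pc_xz_y = num / den  # r_xz.y at entry [x, y]
                ratio_xz = np.abs(pc_xz_y) / np.maximum(np.abs(rz)[:, None], TINY_CORR)
            ratio_yz = ratio_xz.T  # r_yz.x / r_yz at entry [x, y]
            eps = (ratio_z + ratio_xz + ratio_yz) / 3.0
            dominated = (absc < eps * absc[:, [z]]) & (absc < eps * absc[[z], :])
            # |r_xz| = 1 or |r_yz| = 1: partials undefined -> dominated via proxy
            proxy = perfect[:, None] | perfect[None, :]
            if proxy.any():
                logger.warning("PCIT trio with |r| = 1 mediator; edges pruned via proxy")
            dominated |= proxy
            dominated[eye] = False
            dominated[z, :] = False
            dominated[:, z] = False
            significant &= ~dominated

    rows = []
    for a in range(n):
        for b in range(a + 1, n):
            rows.append(
                {
                    "node_a": labels[a],
                    "node_b": labels[b],
                    "weight": float(c[a, b]),
                    "significant": bool(significant[a, b]),
                }
            )
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "significant"])
    return GeneNetwork(nodes=list(labels), edges=edges)


def export_network(net: GeneNetwork, path, significant_only: bool = True) -> None:
    """Write the network as a viewer-loadable edge list:
    node_a <tab> interaction <tab> node_b <tab> weight, in deterministic order."""
    edges = net.edges
    if significant_only:
        edges = edges.loc[edges["significant"]]
    edges = edges.sort_values(["node_a", "node_b"], kind="stable")
    with open(path, "w") as fh:
        fh.write("node_a\tinteraction\tnode_b\tweight\n")
        for _, e in edges.iterrows():
            fh.write(f"{e['node_a']}\tcorr\t{e['node_b']}\t{e['weight']:.6g}\n")


def read_network(path) -> pd.DataFrame:
    """Read back an exported edge list."""
    return pd.read_csv(path, sep="\t")
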