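"""End-to-end orchestration: simulate -> merge -> GWAS -> meta -> eGWAS ->
AWM/PCIT -> TFBS enrichment, with a flat key-value run configuration and a
deterministic file manifest.

Stage defaults are the published analysis settings: breakpoint distance
1000 bp, 2 supporting callers, minimum SV size 30 bp, QUAL >= 1000, call
rate >= 0.8, TR depth >= 10 and quality > 0.8, MAF >= 0.01, variant
selection p < 1e-4 with >= 10 eGWAS hits, promoter window -1500/+500 and
enrichment alpha 0.05.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import awm as awm_mod
from . import gwas as gwas_mod
from . import io as io_mod
from . import simulate as sim_mod
from . import tfbs as tfbs_mod
from . import variants as var_mod

logger = logging.getLogger(__name__)

STAGES = ["simulate", "merge", "gwas", "meta", "egwas", "awm", "tfbs"]

#: key -> (type, default, (lo, hi) or allowed set or None)
SCHEMA: dict[str, tuple] = {
    "seed": (int, 7, (0, 2**31 - 1)),
    "outdir": (str, "pecknet_out", None),
    "simulate.enabled": (bool, True, None),
    "merge.enabled": (bool, True, None),
    "gwas.enabled": (bool, True, None),
    "meta.enabled": (bool, True, None),
    "egwas.enabled": (bool, True, None),
    "awm.enabled": (bool, True, None),
    "tfbs.enabled": (bool, True, None),
    "simulate.n_samples_hs": (int, 494, (2, 100_000)),
    "simulate.n_samples_f2": (int, 817, (2, 100_000)),
    "simulate.n_chromosomes": (int, 5, (1, 100)),
    "simulate.n_variants_per_chrom": (int, 400, (2, 1_000_000)),
    "simulate.n_chip_per_chrom": (int, 400, (2, 1_000_000)),
    "simulate.maf_lo": (float, 0.05, (0.0, 0.5)),
    "simulate.maf_hi": (float, 0.5, (0.0, 0.5)),
    "simulate.ld_decay": (float, 0.5, (0.0, 0.999)),
    "simulate.missing_rate": (float, 0.02, (0.0, 0.5)),
    "simulate.h2": (float, 0.15, (0.0, 0.99)),
    "simulate.qtl_pve": (float, 0.047, (0.0, 0.5)),
    "simulate.n_hatches": (int, 7, (1, 1000)),
    "simulate.n_genes": (int, 86, (2, 10_000)),
    "simulate.n_expr_samples": (int, 167, (2, 100_000)),
    "simulate.n_background_genes": (int, 500, (1, 100_000)),
    "simulate.n_sv_truth": (int, 200, (1, 100_000)),
    "simulate.jitter_sd": (float, 150.0, (0.0, 10_000.0)),
    "simulate.fn_rate": (float, 0.1, (0.0, 1.0)),
    "simulate.fp_rate": (float, 0.05, (0.0, 10.0)),
    "simulate.n_callers": (int, 3, (1, 20)),
    "merge.max_dist": (int, 1000, (1, 10_000_000)),
    "merge.min_callers": (int, 2, (1, 20)),
    "merge.min_size": (int, 30, (0, 10_000_000)),
    "merge.min_qual": (float, 1000.0, (0.0, 1e9)),
    "merge.min_callrate": (float, 0.8, (0.0, 1.0)),
    "merge.tr_min_dp": (int, 10, (0, 100_000)),
    "merge.tr_min_q": (float, 0.8, (0.0, 1.0)),
    "gwas.maf_min": (float, 0.01, (0.0, 0.5)),
    "awm.p_thresh": (float, 1e-4, (0.0, 1.0)),
    "awm.min_egwas_hits": (int, 10, (1, 10_000)),
    "tfbs.upstream": (int, 1500, (0, 1_000_000)),
    "tfbs.downstream": (int, 500, (0, 1_000_000)),
    "tfbs.threshold_frac": (float, 0.85, (0.0, 1.0)),
    "tfbs.alpha": (float, 0.05, (0.0, 1.0)),
    "tfbs.n_decoys": (int, 6, (0, 100)),
}


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


class DependencyError(RuntimeError):
    """An enabled stage is missing an upstream output."""


@dataclasses.dataclass
class RunConfig:
    params: dict

    def __getitem__(self, key: str):
        return self.params[key]

    @property
    def seed(self) -> int:
        return self.params["seed"]

    @property
    def outdir(self) -> Path:
        return Path(self.params["outdir"])

    def enabled(self, stage: str) -> bool:
        return bool(self.params[f"{stage}.enabled"])


def _coerce(key: str, raw: str, typ):
    if typ is bool:
        low = raw.strip().lower()
        if low in ("true", "1", "yes", "on"):
            return True
        if low in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"cannot parse boolean {raw!r}")
    return typ(raw)


def default_config(**overrides) -> RunConfig:
    params = {k: d for k, (_, d, _) in SCHEMA.items()}
    violations = []
    for k, v in overrides.items():
        if k not in SCHEMA:
            violations.append(f"unknown key {k!r}")
        else:
            params[k] = v
    violations.extend(_range_check(params))
    if violations:
        raise ConfigError(violations)
    return RunConfig(params)


def _range_check(params: dict) -> list[str]:
    violations = []
    for key, (typ, _, rng) in SCHEMA.items():
        val = params[key]
        if typ in (int, float) and rng is not None:
            lo, hi = rng
            if not (lo <= val <= hi):
                violations.append(f"{key}={val} outside [{lo}, {hi}]")
    if params["simulate.maf_lo"] > params["simulate.maf_hi"]:
        violations.append("simulate.maf_lo exceeds simulate.maf_hi")
    if params["simulate.h2"] + params["simulate.qtl_pve"] >= 1:
        violations.append("simulate.h2 + simulate.qtl_pve must stay below 1")
    if params["simulate.n_expr_samples"] > params["simulate.n_samples_hs"]:
        violations.append("simulate.n_expr_samples exceeds simulate.n_samples_hs")
    return violations


def validate_config(path: str | Path | None) -> RunConfig:
    """Parse and range-check a flat ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored; an empty or absent file
    yields the all-defaults configuration.  Every violation (unknown key,
    duplicate key, type error, out-of-range value) is collected and
    reported at once via :class:`ConfigError`.
    """
    params = {k: d for k, (_, d, _) in SCHEMA.items()}
    violations: list[str] = []
    if path is not None:
        seen: set[str] = set()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                violations.append(f"line {lineno}: expected 'key = value'")
                continue
            key, raw = (part.strip() for part in line.split("=", 1))
            if key in seen:
                violations.append(f"line {lineno}: duplicate key {key!r}")
                continue
            seen.add(key)
            if key not in SCHEMA:
                violations.append(f"line {lineno}: unknown key {key!r}")
                continue
            typ = SCHEMA[key][0]
            try:
                params[key] = _coerce(key, raw, typ)
            except ValueError:
                violations.append(f"line {lineno}: cannot parse {key!r} as {typ.__name__}")
    violations.extend(_range_check(params))
    if violations:
        raise ConfigError(violations)
    return RunConfig(params)


def _sim_config(cfg: RunConfig, design: str) -> sim_mod.SimConfig:
    p = cfg.params
    m_sv = p["simulate.n_chromosomes"] * p["simulate.n_variants_per_chrom"]
    qtl_idx = m_sv // 2
    n_targets = min(24, p["simulate.n_genes"])
    common = dict(
        tf_hub=(0, tuple(range(1, n_targets)), 0.8),
        n_chromosomes=p["simulate.n_chromosomes"],
        n_variants_per_chrom=p["simulate.n_variants_per_chrom"],
        n_chip_per_chrom=p["simulate.n_chip_per_chrom"],
        maf_range=(p["simulate.maf_lo"], p["simulate.maf_hi"]),
        ld_decay=p["simulate.ld_decay"],
        missing_rate=p["simulate.missing_rate"],
        h2_polygenic=p["simulate.h2"],
        qtl_spec=((qtl_idx, p["simulate.qtl_pve"]),),
        n_hatches=p["simulate.n_hatches"],
        n_genes=p["simulate.n_genes"],
        n_background_genes=p["simulate.n_background_genes"],
        n_sv_truth=p["simulate.n_sv_truth"],
        promoter_upstream=p["tfbs.upstream"],
        promoter_downstream=p["tfbs.downstream"],
    )
    if design == "hs":
        return sim_mod.SimConfig(
            seed=cfg.seed,
            n_samples=p["simulate.n_samples_hs"],
            two_lines=True,
            n_expr_samples=p["simulate.n_expr_samples"],
            **common,
        )
    return sim_mod.SimConfig(
        seed=cfg.seed + 101,
        n_samples=p["simulate.n_samples_f2"],
        two_lines=False,
        n_expr_samples=2,
        **common,
    )


def _require(outdir: Path, stage: str, *names: str) -> list[Path]:
    paths = [outdir / n for n in names]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise DependencyError(
            f"stage '{stage}' is missing upstream output(s): {', '.join(missing)}"
        )
    return paths


def _stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params
    files: dict[str, str] = {}
    rows: dict[str, int] = {}

    cohorts = {}
    for design in ("hs", "f2"):
        scfg = _sim_config(cfg, design)
        gt, truth, pheno, expr = sim_mod.simulate_cohort(scfg)
        cohorts[design] = (scfg, gt, truth, pheno, expr)
        io_mod.write_genotypes(gt, outdir / f"genotypes_{design}")
        io_mod.write_phenotypes(pheno, outdir / f"pheno_{design}.tsv")
        io_mod.write_truth(truth, outdir / f"truth_{design}.json")
        files[f"genotypes_{design}"] = str(outdir / f"genotypes_{design}.dosages.tsv")
        files[f"pheno_{design}"] = str(outdir / f"pheno_{design}.tsv")
        rows[f"genotypes_{design}"] = gt.n_samples

    scfg_hs, gt_hs, truth_hs, _, expr = cohorts["hs"]
    io_mod.write_expression(expr, outdir / "expression.tsv")
    files["expression"] = str(outdir / "expression.tsv")
    rows["expression"] = len(expr)

    callsets = sim_mod.simulate_caller_outputs(
        truth_hs,
        n_callers=p["simulate.n_callers"],
        jitter_sd=p["simulate.jitter_sd"],
        fn_rate_per_caller=p["simulate.fn_rate"],
        fp_rate=p["simulate.fp_rate"],
        seed=cfg.seed,
    )
    for i, calls in enumerate(callsets):
        path = outdir / f"callset_{i}.tsv"
        io_mod.write_callset(calls, gt_hs.samples, path)
        files[f"callset_{i}"] = str(path)
        rows[f"callset_{i}"] = len(calls)

    annotation = sim_mod.make_gene_annotation(scfg_hs)
    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    files["annotation"] = str(outdir / "annotation.tsv")

    pwm = tfbs_mod.ets_like_pwm()
    tfbs_mod.write_jaspar(pwm, outdir / "motif_planted.jaspar")
    files["motif_planted"] = str(outdir / "motif_planted.jaspar")
    for i in range(p["tfbs.n_decoys"]):
        decoy = tfbs_mod.random_pwm(f"SYN_DECOY{i+1}", seed=1000 + i)
        tfbs_mod.write_jaspar(decoy, outdir / f"motif_decoy{i+1}.jaspar")
        files[f"motif_decoy{i+1}"] = str(outdir / f"motif_decoy{i+1}.jaspar")

    seqs = sim_mod.simulate_promoters(
        annotation, pwm, scfg_hs, truth_hs.foreground_genes, truth=truth_hs
    )
    io_mod.write_fasta(seqs, outdir / "promoters.fasta")
    files["promoters"] = str(outdir / "promoters.fasta")
    rows["promoters"] = len(seqs)
    # rewrite truth with the realized planted set
    io_mod.write_truth(truth_hs, outdir / "truth_hs.json")
    (outdir / "foreground_genes.tsv").write_text(
        "\n".join(sorted(truth_hs.foreground_genes)) + "\n"
    )
    files["foreground_genes"] = str(outdir / "foreground_genes.tsv")
    return {"files": files, "rows": rows}


def _stage_merge(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params
    n_callers = p["simulate.n_callers"]
    paths = _require(outdir, "merge", *[f"callset_{i}.tsv" for i in range(n_callers)])
    callsets = []
    samples: list[str] = []
    for path in paths:
        calls, samples = io_mod.read_callset(path)
        callsets.append(calls)
    merged = var_mod.merge_callsets(
        callsets,
        max_dist=p["merge.max_dist"],
        min_callers=p["merge.min_callers"],
        min_size=p["merge.min_size"],
    )
    filtered = var_mod.filter_merged(
        merged, min_qual=p["merge.min_qual"], min_callrate=p["merge.min_callrate"]
    )
    io_mod.write_merged(filtered, samples, outdir / "merged.tsv")
    io_mod.write_merged_vcf(filtered, samples, outdir / "merged.vcf")
    return {
        "files": {"merged": str(outdir / "merged.tsv"), "merged_vcf": str(outdir / "merged.vcf")},
        "rows": {"merged_raw": len(merged), "merged_filtered": len(filtered)},
    }


def _stage_gwas(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params
    files = {}
    rows = {}
    for design, covs in (("hs", ("hatch", "line")), ("f2", ("hatch",))):
        _require(outdir, "gwas", f"genotypes_{design}.dosages.tsv", f"pheno_{design}.tsv")
        gt = io_mod.read_genotypes(outdir / f"genotypes_{design}")
        pheno = io_mod.read_phenotypes(outdir / f"pheno_{design}.tsv")
        res = gwas_mod.mlma_loco(gt, pheno, covariates=covs, maf_min=p["gwas.maf_min"])
        io_mod.write_assoc(res, outdir / f"assoc_{design}.tsv")
        files[f"assoc_{design}"] = str(outdir / f"assoc_{design}.tsv")
        rows[f"assoc_{design}"] = len(res)
    return {"files": files, "rows": rows}


def _stage_meta(cfg: RunConfig, outdir: Path) -> dict:
    paths = _require(outdir, "meta", "assoc_hs.tsv", "assoc_f2.tsv")
    results = [io_mod.read_assoc(path) for path in paths]
    combined = gwas_mod.meta_sample_size(results)
    combined.to_csv(outdir / "assoc_meta.tsv", sep="\t", index=False)
    return {
        "files": {"assoc_meta": str(outdir / "assoc_meta.tsv")},
        "rows": {"assoc_meta": len(combined)},
    }


def _stage_egwas(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params
    _require(outdir, "egwas", "genotypes_hs.dosages.tsv", "pheno_hs.tsv", "expression.tsv")
    gt = io_mod.read_genotypes(outdir / "genotypes_hs")
    pheno = io_mod.read_phenotypes(outdir / "pheno_hs.tsv")
    expr = io_mod.read_expression(outdir / "expression.tsv")
    results = awm_mod.run_egwas(gt, expr, covariates=("hatch",), pheno=pheno,
                                maf_min=p["gwas.maf_min"])
    frames = []
    for gene, res in results.items():
        df = res.copy()
        df.insert(0, "gene", gene)
        frames.append(df)
    longf = pd.concat(frames, ignore_index=True)
    longf.to_csv(outdir / "egwas.tsv", sep="\t", index=False)
    return {
        "files": {"egwas": str(outdir / "egwas.tsv")},
        "rows": {"egwas_scans": len(results), "egwas_rows": len(longf)},
    }


def _read_egwas(path: Path) -> dict[str, pd.DataFrame]:
    longf = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {str(gene): df.drop(columns="gene").reset_index(drop=True)
            for gene, df in longf.groupby("gene", sort=False)}


def _stage_awm(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params
    _require(outdir, "awm", "assoc_hs.tsv", "egwas.tsv", "annotation.tsv")
    main = io_mod.read_assoc(outdir / "assoc_hs.tsv")
    egwas = _read_egwas(outdir / "egwas.tsv")
    annotation = pd.read_csv(outdir / "annotation.tsv", sep="\t")
    selected = awm_mod.select_awm_variants(
        main, egwas, p_thresh=p["awm.p_thresh"], min_egwas_hits=p["awm.min_egwas_hits"]
    )
    if not selected:
        logger.warning("AWM selection is empty; writing empty outputs")
        (outdir / "awm.tsv").write_text("id\n")
        awm_mod.export_network(
            awm_mod.GeneNetwork(nodes=[], edges=pd.DataFrame(
                columns=["node_a", "node_b", "weight", "significant"])),
            outdir / "network.tsv",
        )
        return {"files": {"awm": str(outdir / "awm.tsv"),
                          "network": str(outdir / "network.tsv")},
                "rows": {"selected_variants": 0, "network_edges": 0}}
    awm = awm_mod.build_awm(selected, main, egwas, annotation=annotation)
    out = awm.z.copy()
    out.insert(0, "gene", awm.variant_gene)
    out.to_csv(outdir / "awm.tsv", sep="\t")
    corr = awm_mod.awm_correlation(awm)
    net = awm_mod.pcit(corr)
    awm_mod.export_network(net, outdir / "network.tsv")
    n_sig = int(net.edges["significant"].sum())
    return {
        "files": {"awm": str(outdir / "awm.tsv"), "network": str(outdir / "network.tsv")},
        "rows": {"selected_variants": len(selected), "network_edges": n_sig},
    }


def _stage_tfbs(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params
    _require(outdir, "tfbs", "promoters.fasta", "motif_planted.jaspar", "foreground_genes.tsv")
    seqs = io_mod.read_fasta(outdir / "promoters.fasta")
    fore_genes = set(
        (outdir / "foreground_genes.tsv").read_text().split()
    )
    back_genes = {g for g in seqs if g.startswith("BG")}
    fore_seqs = {g: s for g, s in seqs.items() if g in fore_genes}
    back_seqs = {g: s for g, s in seqs.items() if g in back_genes}
    pwms = [tfbs_mod.load_jaspar(outdir / "motif_planted.jaspar")]
    for i in range(p["tfbs.n_decoys"]):
        path = outdir / f"motif_decoy{i+1}.jaspar"
        if path.exists():
            pwms.append(tfbs_mod.load_jaspar(path))
    results = tfbs_mod.multi_motif_panel(
        pwms,
        fore_seqs,
        back_seqs,
        tss_offset=p["tfbs.upstream"],
        upstream=p["tfbs.upstream"],
        downstream=p["tfbs.downstream"],
        threshold_frac=p["tfbs.threshold_frac"],
    )
    table = tfbs_mod.enrichment_table(results)
    table["significant"] = table["p_value"] <= p["tfbs.alpha"]
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return {
        "files": {"enrichment": str(outdir / "enrichment.tsv")},
        "rows": {"motifs_tested": len(table),
                 "significant_motifs": int(table["significant"].sum())},
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "merge": _stage_merge,
    "gwas": _stage_gwas,
    "meta": _stage_meta,
    "egwas": _stage_egwas,
    "awm": _stage_awm,
    "tfbs": _stage_tfbs,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns (and writes to ``<outdir>/manifest.json``) a manifest mapping
    each executed stage to its output files, row counts and the parameter
    block it ran with.
    """
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    logfile = outdir / "run.log"
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pecknet")
    root.addHandler(handler)
    try:
        manifest: dict = {"seed": cfg.seed, "stages": {}}
        for stage in STAGES:
            if not cfg.enabled(stage):
                continue
            logger.info("running stage %s", stage)
            result = _STAGE_FUNCS[stage](cfg, outdir)
            prefix = f"{stage}."
            result["params"] = {
                k: v for k, v in cfg.params.items()
                if k.startswith(prefix) and not k.endswith(".enabled")
            }
            manifest["stages"][stage] = result
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
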