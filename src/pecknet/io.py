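"""Plain-text file contracts shared by the pipeline stages.

Everything the pipeline writes is a small TSV, FASTA or JSON file:
dosage matrices (samples x variants) with a variant metadata sidecar,
phenotype/covariate tables, expression tables, VCF-like caller call sets,
merged SV sets (TSV and a minimal VCF), association results and promoter
FASTA.  Readers are exact inverses of the writers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix
from .variants import MISSING, CallerRecord, MergedVariant

ASSOC_COLUMNS = ["chrom", "pos", "id", "maf", "n", "beta", "se", "p"]


def write_genotypes(gt: GenotypeMatrix, prefix: Path) -> tuple[Path, Path]:
    """Write dosages to ``<prefix>.dosages.tsv`` (samples x variants, -1 for
    missing) and variant metadata to ``<prefix>.variants.tsv``."""
    prefix = Path(prefix)
    dos_path = prefix.with_suffix(".dosages.tsv")
    var_path = prefix.with_suffix(".variants.tsv")
    df = pd.DataFrame(gt.dosages, index=pd.Index(gt.samples, name="sample_id"),
                      columns=gt.variants["id"])
    df.to_csv(dos_path, sep="\t")
    gt.variants.to_csv(var_path, sep="\t", index=False)
    return dos_path, var_path


def read_genotypes(prefix: Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".dosages.tsv"), sep="\t", index_col="sample_id")
    variants = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t")
    return GenotypeMatrix(
        samples=list(df.index),
        variants=variants,
        dosages=df.to_numpy(dtype=np.int8),
    )


def write_phenotypes(pheno: pd.DataFrame, path: Path) -> Path:
    pheno.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_phenotypes(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(expr: pd.DataFrame, path: Path) -> Path:
    expr.to_csv(path, sep="\t")
    return Path(path)


def read_expression(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_callset(calls: list[CallerRecord], samples: list[str], path: Path) -> Path:
    """VCF-like TSV: chrom, pos, end, chrom2, type, strands, qual, per-sample GT."""
    rows = []
    for rec in calls:
        row = {
            "chrom": rec.chrom,
            "pos": rec.start,
            "end": rec.end,
            "chrom2": rec.chrom2,
            "type": rec.sv_type,
            "strand1": rec.strands[0],
            "strand2": rec.strands[1],
            "qual": rec.qual,
            "caller": rec.caller_id,
        }
        gts = rec.genotypes if rec.genotypes is not None else np.full(len(samples), MISSING)
        for s, g in zip(samples, gts):
            row[s] = "." if g == MISSING else int(g)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_callset(path: Path) -> tuple[list[CallerRecord], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "chrom2": str})
    fixed = ["chrom", "pos", "end", "chrom2", "type", "strand1", "strand2", "qual", "caller"]
    samples = [c for c in df.columns if c not in fixed]
    calls = []
    for _, row in df.iterrows():
        gts = np.array(
            [MISSING if str(row[s]) == "." else int(float(row[s])) for s in samples],
            dtype=np.int8,
        )
        calls.append(
            CallerRecord(
                caller_id=str(row["caller"]),
                chrom=str(row["chrom"]),
                start=int(row["pos"]),
                end=int(row["end"]),
                sv_type=str(row["type"]),
                strands=(str(row["strand1"]), str(row["strand2"])),
                qual=float(row["qual"]),
                genotypes=gts,
                chrom2=str(row["chrom2"]),
            )
        )
    return calls, samples


def write_merged(merged: list[MergedVariant], samples: list[str], path: Path) -> Path:
    rows = []
    for v in merged:
        row = {
            "chrom": v.chrom,
            "pos": v.start,
            "end": v.end,
            "chrom2": v.chrom2,
            "type": v.sv_type,
            "strand1": v.strands[0],
            "strand2": v.strands[1],
            "qual": v.qual,
            "supp": len(v.supporting_callers),
            "callers": ",".join(sorted(v.supporting_callers)),
        }
        gts = v.genotypes if v.genotypes is not None else np.full(len(samples), MISSING)
        for s, g in zip(samples, gts):
            row[s] = "." if g == MISSING else int(g)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def write_merged_vcf(merged: list[MergedVariant], samples: list[str], path: Path) -> Path:
    """Minimal VCF 4.2 with SVTYPE, END and SUPP INFO keys and GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Supporting callers">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i, v in enumerate(merged):
            info = f"SVTYPE={v.sv_type};END={v.end};SUPP={len(v.supporting_callers)}"
            gts = v.genotypes if v.genotypes is not None else np.full(len(samples), MISSING)
            gt_str = "\t".join(gt_code.get(int(g), "./.") for g in gts)
            fh.write(
                f"{v.chrom}\t{v.start}\tsv_{i}\tN\t<{v.sv_type}>\t{v.qual:.0f}\tPASS\t{info}\tGT\t{gt_str}\n"
            )
    return Path(path)


def write_assoc(res: pd.DataFrame, path: Path) -> Path:
    res.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_assoc(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_fasta(seqs: dict[str, str], path: Path, width: int = 70) -> Path:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return Path(path)


def read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_truth(truth, path: Path) -> Path:
    """Serialize the parts of the truth set needed downstream as JSON."""
    payload = {
        "sigma_g2": truth.sigma_g2,
        "sigma_e2": truth.sigma_e2,
        "qtl": truth.qtl,
        "realized": truth.realized,
        "eqtl": {str(g): [int(v), float(b)] for g, (v, b) in truth.eqtl.items()},
        "hub_gene": truth.hub_gene,
        "hub_targets": list(truth.hub_targets),
        "hub_effect": truth.hub_effect,
        "n_sv_records": len(truth.sv_records),
        "foreground_genes": sorted(truth.foreground_genes),
        "background_genes": sorted(truth.background_genes),
        "planted_genes": sorted(truth.planted_genes),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return Path(path)
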