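"""Structural-variant call-set merging and genotype-level filtering.

Multi-caller SV discovery produces partially overlapping call sets whose
breakpoints disagree by up to a few hundred base pairs.  This module merges
per-caller records into a high-confidence consensus set (breakpoint
clustering with type/strand awareness, minimum caller support, minimum SV
size), applies QUAL / call-rate filters to the merged variants, filters
tandem-repeat genotypes on per-sample depth and quality, and splits
multiallelic records into biallelic ones for association testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV", "TRA", "INS")

#: sentinel for a missing genotype in integer dosage arrays
MISSING = -1


class RecordValidationError(ValueError):
    """An individual variant record failed validation."""


@dataclass
class CallerRecord:
    """One SV record as emitted by a single caller.

    ``genotypes`` holds per-sample alternate-allele dosages (0/1/2) with
    :data:`MISSING` for no-calls.  ``chrom2`` differs from ``chrom`` only for
    inter-chromosomal translocations.
    """

    caller_id: str
    chrom: str
    start: int
    end: int
    sv_type: str
    strands: tuple[str, str] = ("+", "-")
    qual: float = 0.0
    genotypes: np.ndarray | None = None
    chrom2: str | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise RecordValidationError(f"unknown SV type {self.sv_type!r}")
        if self.chrom2 is None:
            self.chrom2 = self.chrom
        if self.chrom == self.chrom2 and self.start > self.end:
            raise RecordValidationError(
                f"start > end for intra-chromosomal record at "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def size(self) -> int:
        """Span in bp (1-based inclusive); meaningless for translocations."""
        return self.end - self.start + 1


@dataclass
class MergedVariant:
    """Consensus record for one cluster of caller records."""

    chrom: str
    start: int
    end: int
    sv_type: str
    strands: tuple[str, str]
    supporting_callers: frozenset[str]
    qual: float
    genotypes: np.ndarray | None
    chrom2: str | None = None
    members: tuple[CallerRecord, ...] = field(default=(), repr=False)

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def call_rate(self) -> float:
        if self.genotypes is None or len(self.genotypes) == 0:
            return 0.0
        return float(np.mean(np.asarray(self.genotypes) != MISSING))


@dataclass
class TandemRepeatCall:
    """A genotyped tandem repeat: per-sample copy number, depth and quality."""

    chrom: str
    pos: int
    motif: str
    genotypes: np.ndarray  # copy-number dosage per sample, MISSING for no-call
    dp: np.ndarray  # per-sample read depth
    q: np.ndarray  # per-sample genotype quality in [0, 1]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.dp = np.asarray(self.dp)
        self.q = np.asarray(self.q)
        if np.any(self.dp < 0):
            raise RecordValidationError("negative read depth")
        if np.any((self.q < 0) | (self.q > 1)):
            raise RecordValidationError("quality outside [0, 1]")

    @property
    def call_rate(self) -> float:
        return float(np.mean(self.genotypes != MISSING))


@dataclass
class MultiallelicVariant:
    """A variant with one or more alternate alleles.

    ``genotypes`` is an (n_samples, 2) integer array of allele indices
    (0 = reference, k >= 1 = the k-th alternate), with :data:`MISSING`
    marking missing allele calls.
    """

    variant_id: str
    chrom: str
    pos: int
    alt_alleles: tuple[str, ...]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if len(self.alt_alleles) < 1:
            raise RecordValidationError("variant needs at least one alt allele")


@dataclass
class BiallelicVariant:
    """A single ref-vs-alt record produced by :func:`split_multiallelic`."""

    variant_id: str
    chrom: str
    pos: int
    alt_allele: str
    dosages: np.ndarray  # copies of this alt per sample, MISSING for no-call


def _breakpoints_match(a: CallerRecord, b: CallerRecord, max_dist: int) -> bool:
    return (
        a.chrom == b.chrom
        and a.chrom2 == b.chrom2
        and abs(a.start - b.start) <= max_dist
        and abs(a.end - b.end) <= max_dist
    )


def merge_callsets(
    callsets: list[list[CallerRecord]],
    max_dist: int = 1000,
    min_callers: int = 2,
    type_aware: bool = True,
    strand_aware: bool = True,
    min_size: int = 30,
    caller_priority: list[str] | None = None,
) -> list[MergedVariant]:
    """Merge per-caller SV call sets into a consensus set.

    Records are clustered greedily in genome order by single linkage to the
    cluster seed (the first record of the cluster in sorted order): a record
    joins the first cluster whose seed lies within ``max_dist`` at both
    breakpoints and, if the corresponding flags are set, shares SV type and
    strand pair.  Each record joins at most one cluster.  Clusters supported
    by fewer than ``min_callers`` distinct callers are dropped, as are
    intra-chromosomal variants shorter than ``min_size`` bp (translocations
    have no meaningful span and are exempt).

    The emitted representative record is the member from the
    highest-priority caller (``caller_priority``; default: lexicographic
    caller id, which makes the merge invariant to the order in which caller
    sets are supplied).  Consensus genotypes start from the representative
    and fill missing entries from the remaining members in priority order.
    """
    if not callsets:
        raise ValueError("no call sets supplied")
    if max_dist < 0 or min_callers < 1 or min_size < 0:
        raise ValueError("merge parameters must be positive")

    records: list[CallerRecord] = []
    for callset in callsets:
        for rec in callset:
            if rec.sv_type not in SV_TYPES:  # defensive: record-level skip
                logger.warning("skipping record with unknown SV type: %r", rec)
                continue
            records.append(rec)

    order = sorted(
        range(len(records)),
        key=lambda i: (
            records[i].chrom,
            records[i].start,
            records[i].end,
            records[i].sv_type,
            records[i].strands,
            records[i].caller_id,
        ),
    )

    clusters: list[list[CallerRecord]] = []
    # seeds of currently open clusters, scanned in genome order
    for idx in order:
        rec = records[idx]
        placed = False
        for cluster in clusters:
            seed = cluster[0]
            if type_aware and rec.sv_type != seed.sv_type:
                continue
            if strand_aware and rec.strands != seed.strands:
                continue
            if _breakpoints_match(rec, seed, max_dist):
                cluster.append(rec)
                placed = True
                break
        if not placed:
            clusters.append([rec])

    if caller_priority is None:
        all_ids = sorted({r.caller_id for r in records})
        caller_priority = all_ids
    prio = {cid: i for i, cid in enumerate(caller_priority)}

    merged: list[MergedVariant] = []
    for cluster in clusters:
        callers = frozenset(r.caller_id for r in cluster)
        if len(callers) < min_callers:
            continue
        members = sorted(cluster, key=lambda r: (prio.get(r.caller_id, len(prio)), r.start))
        rep = members[0]
        if rep.sv_type != "TRA" and rep.size < min_size:
            continue
        genotypes = None
        if rep.genotypes is not None:
            genotypes = np.asarray(rep.genotypes).copy()
            for other in members[1:]:
                if other.genotypes is None:
                    continue
                fill = (genotypes == MISSING) & (np.asarray(other.genotypes) != MISSING)
                genotypes[fill] = np.asarray(other.genotypes)[fill]
        merged.append(
            MergedVariant(
                chrom=rep.chrom,
                start=rep.start,
                end=rep.end,
                sv_type=rep.sv_type,
                strands=rep.strands,
                supporting_callers=callers,
                qual=rep.qual,
                genotypes=genotypes,
                chrom2=rep.chrom2,
                members=tuple(members),
            )
        )

    merged.sort(key=lambda v: (v.chrom, v.start, v.end, v.sv_type))
    return merged


def filter_merged(
    merged: list[MergedVariant],
    min_qual: float = 1000.0,
    min_callrate: float = 0.8,
) -> list[MergedVariant]:
    """Keep merged variants with QUAL >= ``min_qual`` and call rate >= ``min_callrate``.

    Input order is preserved; the filter is idempotent.
    """
    return [
        v
        for v in merged
        if v.qual >= min_qual and v.call_rate >= min_callrate
    ]


def filter_tr(
    calls: list[TandemRepeatCall],
    min_dp: int = 10,
    min_q: float = 0.8,
    min_callrate: float = 0.8,
) -> list[TandemRepeatCall]:
    """Filter tandem-repeat genotypes and drop low-call-rate variants.

    Per-sample genotypes with depth below ``min_dp`` (inclusive threshold:
    DP >= 10 passes) or quality not strictly above ``min_q`` are set
    missing; variants whose resulting call rate drops below
    ``min_callrate`` are removed.
    """
    kept: list[TandemRepeatCall] = []
    for call in calls:
        bad = (call.dp < min_dp) | (call.q <= min_q)
        genotypes = call.genotypes.copy()
        genotypes[bad] = MISSING
        filtered = replace(call, genotypes=genotypes)
        if filtered.call_rate >= min_callrate:
            kept.append(filtered)
    return kept


def split_multiallelic(
    variants: list[MultiallelicVariant],
) -> list[BiallelicVariant]:
    """Convert k-allelic variants into k ref-vs-alt biallelic records.

    Each alternate allele yields one record whose per-sample dosage is the
    number of copies of that allele; genotypes with any missing allele call
    become missing in every split record.  Record ids are suffixed with the
    1-based alternate index (``id_1``, ``id_2``, ...) unless the input is
    already biallelic, in which case the id passes through unchanged.
    """
    out: list[BiallelicVariant] = []
    for var in variants:
        gts = var.genotypes
        any_missing = np.any(gts == MISSING, axis=1)
        k = len(var.alt_alleles)
        for alt_idx, alt in enumerate(var.alt_alleles, start=1):
            dosage = np.sum(gts == alt_idx, axis=1).astype(np.int64)
            dosage[any_missing] = MISSING
            vid = var.variant_id if k == 1 else f"{var.variant_id}_{alt_idx}"
            out.append(
                BiallelicVariant(
                    variant_id=vid,
                    chrom=var.chrom,
                    pos=var.pos,
                    alt_allele=alt,
                    dosages=dosage,
                )
            )
    return out
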