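"""The six haplotype-level methylation measurements over a block.

Given the reads clipped to a block's CpGs, the package computes:

AMF
    Average methylation fraction — methylated CpG calls over all CpG calls.
MHL (and MHL3)
    Methylated haplotype load. For substring length ``l`` let ``P(M_l)`` be
    the count-weighted fraction of fully methylated length-``l`` contiguous
    substrings among all length-``l`` contiguous substrings of the clipped
    read patterns. Then ``MHL = sum_l w_l P(M_l) / sum_l w_l`` with weights
    ``w_l = l**k`` — linear weights (k = 1) for MHL, cubic (k = 3) for MHL3.
    ``l`` ranges over the lengths with at least one observed substring, and
    the normaliser sums the weights over exactly those lengths. Substrings are
    enumerated within reads only, never across reads: haplotype load is
    defined on observed co-methylation, not imputed.
UMHL (and UMHL3)
    The unmethylated analogue — fully *un*methylated substrings. Equivalently
    MHL of the bit-complemented patterns.
PDR
    Proportion of discordant reads — the count-weighted fraction of eligible
    reads (clipped pattern covering at least ``min_cpgs_per_read`` CpGs) that
    contain both a methylated and an unmethylated call.

Coverage is the mean per-CpG read depth across the block's CpGs (the "X"
unit), not the raw read count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from bldm._sites import SiteIndex
from bldm.blocks import MHB
from bldm.io import CpGSite, HaplotypeRecord, Cohort

logger = logging.getLogger(__name__)

METRIC_NAMES = ("amf", "mhl", "umhl", "mhl3", "umhl3", "pdr")
DEFAULT_PDR_MIN_CPGS = 3
NA_TOKEN = "NA"


@dataclass(slots=True)
class BlockHaplotypes:
    """Clipped read patterns of one sample over one block.

    ``patterns`` maps (offset, pattern) -> count, where ``offset`` is the index
    of the pattern's first CpG within the block's 0..L-1 CpG indices, and the
    pattern covers the contiguous index range [offset, offset + len(pattern)).
    """

    block_id: str
    L: int
    patterns: dict[tuple[int, str], int] = field(default_factory=dict)

    def add(self, offset: int, pattern: str, count: int) -> None:
        if count < 1:
            raise ValueError(f"{self.block_id}: count must be >= 1")
        if offset < 0 or offset + len(pattern) > self.L:
            raise ValueError(f"{self.block_id}: pattern outside block index range")
        key = (offset, pattern)
        self.patterns[key] = self.patterns.get(key, 0) + count

    @property
    def n_reads(self) -> int:
        return sum(self.patterns.values())

    def complement(self) -> "BlockHaplotypes":
        flipped = {
            (off, pat.translate(str.maketrans("01", "10"))): c
            for (off, pat), c in self.patterns.items()
        }
        return BlockHaplotypes(self.block_id, self.L, flipped)


def extract_block_haplotypes(
    haplotypes: Iterable[HaplotypeRecord],
    mhb: MHB,
    reference_sites: Sequence[CpGSite] | SiteIndex,
) -> BlockHaplotypes:
    """Clip a sample's reads to the CpGs of one block.

    Each read overlapping the block contributes its pattern restricted to the
    block CpGs it covers; reads covering no block CpG contribute nothing.
    """
    index = reference_sites if isinstance(reference_sites, SiteIndex) else SiteIndex(reference_sites)
    b0 = index.locate(mhb.chrom, mhb.cpg_positions[0])
    b1 = index.locate(mhb.chrom, mhb.cpg_positions[-1]) + 1
    if b1 - b0 != mhb.n_cpgs:
        raise ValueError(
            f"{mhb.block_id}: block CpGs are not contiguous in the reference site set"
        )
    bh = BlockHaplotypes(mhb.block_id, mhb.n_cpgs)
    for rec in haplotypes:
        if rec.chrom != mhb.chrom:
            continue
        i0, i1 = index.record_span(rec)
        lo, hi = max(i0, b0), min(i1, b1)
        if lo >= hi:
            continue
        clipped = rec.pattern[lo - i0 : hi - i0]
        bh.add(lo - b0, clipped, rec.count)
    return bh


def _haplotype_load(bh: BlockHaplotypes, weight_exponent: float, state: str) -> float | None:
    """Shared MHL/UMHL engine: length-weighted load of all-``state`` substrings."""
    if weight_exponent < 1:
        raise ValueError("weight_exponent must be >= 1")
    if not bh.patterns:
        return None
    total = np.zeros(bh.L + 1, dtype=np.float64)  # total[l]: substrings of length l
    full = np.zeros(bh.L + 1, dtype=np.float64)  # full[l]: all-`state` substrings
    for (_, pat), count in bh.patterns.items():
        n = len(pat)
        for l in range(1, n + 1):
            total[l] += (n - l + 1) * count
        # runs of the target state of length r contribute r-l+1 substrings per l
        run = 0
        for ch in pat + "x":  # sentinel flushes the final run
            if ch == state:
                run += 1
            else:
                for l in range(1, run + 1):
                    full[l] += (run - l + 1) * count
                run = 0
    lengths = np.nonzero(total)[0]
    weights = lengths.astype(np.float64) ** weight_exponent
    return float(np.sum(weights * full[lengths] / total[lengths]) / np.sum(weights))


def compute_mhl(block_haplotypes: BlockHaplotypes, weight_exponent: float = 1) -> float | None:
    """Methylated haplotype load; ``None`` for an empty block."""
    return _haplotype_load(block_haplotypes, weight_exponent, "1")


def compute_umhl(block_haplotypes: BlockHaplotypes, weight_exponent: float = 1) -> float | None:
    """Unmethylated haplotype load; equals MHL of the complemented patterns."""
    return _haplotype_load(block_haplotypes, weight_exponent, "0")


def compute_amf(block_haplotypes: BlockHaplotypes) -> float | None:
    """Average methylation fraction: methylated calls / all calls, count-weighted."""
    calls = 0
    meth = 0
    for (_, pat), count in block_haplotypes.patterns.items():
        calls += len(pat) * count
        meth += pat.count("1") * count
    if calls == 0:
        return None
    return meth / calls


def compute_pdr(
    block_haplotypes: BlockHaplotypes, min_cpgs_per_read: int = DEFAULT_PDR_MIN_CPGS
) -> float | None:
    """Proportion of discordant reads among reads with enough block CpGs.

    A read is eligible iff its clipped pattern covers at least
    ``min_cpgs_per_read`` CpGs; it is discordant iff the pattern contains both
    0 and 1. ``None`` when no read is eligible.
    """
    eligible = 0
    discordant = 0
    for (_, pat), count in block_haplotypes.patterns.items():
        if len(pat) < min_cpgs_per_read:
            continue
        eligible += count
        if "0" in pat and "1" in pat:
            discordant += count
    if eligible == 0:
        return None
    return discordant / eligible


def block_coverage(block_haplotypes: BlockHaplotypes, L: int | None = None) -> float:
    """Mean per-CpG read depth over the block's ``L`` CpGs (count-weighted)."""
    if L is None:
        L = block_haplotypes.L
    if L <= 0:
        return 0.0
    depth = np.zeros(L, dtype=np.float64)
    for (off, pat), count in block_haplotypes.patterns.items():
        depth[off : off + len(pat)] += count
    return float(depth.mean())


def metric_vector(
    bh: BlockHaplotypes,
    mhl3_exponent: float = 3,
    pdr_min_cpgs: int = DEFAULT_PDR_MIN_CPGS,
) -> dict[str, float | None]:
    """All six measurements plus coverage for one (sample, block)."""
    return {
        "amf": compute_amf(bh),
        "mhl": compute_mhl(bh, 1),
        "umhl": compute_umhl(bh, 1),
        "mhl3": compute_mhl(bh, mhl3_exponent),
        "umhl3": compute_umhl(bh, mhl3_exponent),
        "pdr": compute_pdr(bh, pdr_min_cpgs),
        "coverage": block_coverage(bh),
    }


@dataclass
class MetricMatrix:
    """Samples x (block, metric) values in [0, 1] plus a coverage side table.

    ``values`` has a two-level column index (block_id, metric) and NaN for
    missing entries in memory; exported files encode missing as the explicit
    token ``NA``. ``coverage`` is samples x block_id mean per-CpG depth.
    """

    values: pd.DataFrame
    coverage: pd.DataFrame
    mhl3_exponent: float = 3
    pdr_min_cpgs: int = DEFAULT_PDR_MIN_CPGS

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def block_ids(self) -> list[str]:
        return list(self.coverage.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MetricMatrix":
        return MetricMatrix(
            self.values.loc[list(sample_ids)],
            self.coverage.loc[list(sample_ids)],
            self.mhl3_exponent,
            self.pdr_min_cpgs,
        )

    def to_tsv(self, values_path: str | Path, coverage_path: str | Path | None = None) -> None:
        flat = self.values.copy()
        flat.columns = [f"{b}:{m}" for b, m in self.values.columns]
        flat.to_csv(values_path, sep="\t", na_rep=NA_TOKEN, index_label="sample_id")
        if coverage_path is not None:
            self.coverage.to_csv(coverage_path, sep="\t", na_rep=NA_TOKEN, index_label="sample_id")

    @classmethod
    def from_tsv(
        cls,
        values_path: str | Path,
        coverage_path: str | Path,
        mhl3_exponent: float = 3,
        pdr_min_cpgs: int = DEFAULT_PDR_MIN_CPGS,
    ) -> "MetricMatrix":
        flat = pd.read_csv(values_path, sep="\t", index_col="sample_id", na_values=[NA_TOKEN])
        flat.columns = pd.MultiIndex.from_tuples([tuple(c.rsplit(":", 1)) for c in flat.columns])
        cov = pd.read_csv(coverage_path, sep="\t", index_col="sample_id", na_values=[NA_TOKEN])
        return cls(flat, cov, mhl3_exponent, pdr_min_cpgs)


def build_metric_matrix(
    cohort: Cohort,
    mhbs: Sequence[MHB],
    reference_sites: Sequence[CpGSite] | SiteIndex,
    mhl3_exponent: float = 3,
    pdr_min_cpgs: int = DEFAULT_PDR_MIN_CPGS,
) -> MetricMatrix:
    """One MetricVector per (sample, block), deterministically ordered.

    Samples without any haplotype records produce an all-missing row and a
    warning. Missing metrics stay NaN in memory; writers emit ``NA``.
    """
    index = reference_sites if isinstance(reference_sites, SiteIndex) else SiteIndex(reference_sites)
    sample_ids = [s.sample_id for s in cohort.samples]
    columns = pd.MultiIndex.from_tuples(
        [(b.block_id, m) for b in mhbs for m in METRIC_NAMES], names=["block_id", "metric"]
    )
    values = np.full((len(sample_ids), len(columns)), np.nan)
    coverage = np.zeros((len(sample_ids), len(mhbs)))

    # map blocks onto global site-index ranges so each read is routed to the
    # block(s) it overlaps in O(log n_blocks) instead of scanning all blocks
    b_start = np.empty(len(mhbs), dtype=np.int64)
    b_end = np.empty(len(mhbs), dtype=np.int64)
    for bi, mhb in enumerate(mhbs):
        g0 = index.global_index(mhb.chrom, index.locate(mhb.chrom, mhb.cpg_positions[0]))
        b_start[bi] = g0
        b_end[bi] = g0 + mhb.n_cpgs
    order = np.argsort(b_start, kind="stable")
    b_start_sorted = b_start[order]
    b_end_sorted = b_end[order]

    for si, sid in enumerate(sample_ids):
        records = cohort.haplotypes.get(sid, [])
        if not records:
            logger.warning("sample %s has no haplotype records; all metrics missing", sid)
            continue
        per_block: dict[int, list[HaplotypeRecord]] = {}
        for rec in records:
            i0, i1 = index.record_span(rec)
            g0 = index.global_index(rec.chrom, i0)
            g1 = g0 + (i1 - i0)
            j = int(np.searchsorted(b_end_sorted, g0, side="right"))
            while j < len(order) and b_start_sorted[j] < g1:
                per_block.setdefault(int(order[j]), []).append(rec)
                j += 1
        for bi, recs in per_block.items():
            bh = extract_block_haplotypes(recs, mhbs[bi], index)
            vec = metric_vector(bh, mhl3_exponent, pdr_min_cpgs)
            for mi, m in enumerate(METRIC_NAMES):
                v = vec[m]
                values[si, bi * len(METRIC_NAMES) + mi] = np.nan if v is None else v
            coverage[si, bi] = vec["coverage"]

    return MetricMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=columns),
        coverage=pd.DataFrame(coverage, index=sample_ids, columns=[b.block_id for b in mhbs]),
        mhl3_exponent=mhl3_exponent,
        pdr_min_cpgs=pdr_min_cpgs,
    )
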