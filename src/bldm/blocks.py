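"""Methylation haplotype block (MHB) calling.

An MHB is a run of adjacent CpGs whose binary methylation states are strongly
co-inherited on individual reads. Analogous to genetic linkage disequilibrium,
co-methylation between two CpGs is measured as r² — the squared Pearson
correlation of the two 0/1 state vectors over the reads covering both sites,
weighted by read multiplicity. Blocks are maximal stretches in which every
*consecutive* CpG pair has a defined r² at or above a threshold.

The calling statistic operates on reads pooled over the discovery cohort;
the resulting block set is frozen and reused for downstream cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from bldm._sites import SiteIndex
from bldm.io import CpGSite, HaplotypeRecord, Region, chrom_sort_key

DEFAULT_R2_MIN = 0.5
DEFAULT_MIN_CPGS = 3
DEFAULT_MIN_PAIRS = 10
DEFAULT_MAX_GAP_BP = 200


@dataclass(frozen=True, slots=True)
class LDEstimate:
    """Pairwise methylation-LD estimate between two CpGs.

    ``r2`` is ``None`` (flagged undefined) when fewer than ``min_pairs`` reads
    cover both sites or either site is constant across the covering reads.
    """

    site_a: CpGSite
    site_b: CpGSite
    n_pairs: int
    r2: float | None

    @property
    def defined(self) -> bool:
        return self.r2 is not None


@dataclass(frozen=True, slots=True)
class MHB:
    """A called methylation haplotype block.

    ``start``/``end`` span the first to last member CpG (half-open, C position
    + 1); ``cpg_positions`` are the ordered member site positions.
    """

    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]
    block_id: str

    def __post_init__(self) -> None:
        if len(self.cpg_positions) < 1:
            raise ValueError(f"{self.block_id}: empty block")
        if list(self.cpg_positions) != sorted(set(self.cpg_positions)):
            raise ValueError(f"{self.block_id}: CpG positions must be strictly increasing")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    def as_region(self) -> Region:
        return Region(self.chrom, self.start, self.end, self.block_id)


def _pair_tables(
    records: Iterable[HaplotypeRecord], index: SiteIndex
) -> dict[tuple[str, int], np.ndarray]:
    """Count-weighted 2x2 joint state tables for every adjacent site pair.

    Key (chrom, i) covers the pair of local site indices (i, i+1); table[a, b]
    is the weighted number of reads with state a at site i and b at site i+1.
    """
    tables: dict[tuple[str, int], np.ndarray] = {}
    for rec in records:
        i0, i1 = index.record_span(rec)
        pat = rec.pattern
        for j in range(i1 - i0 - 1):
            key = (rec.chrom, i0 + j)
            tab = tables.get(key)
            if tab is None:
                tab = np.zeros((2, 2), dtype=np.int64)
                tables[key] = tab
            tab[int(pat[j]), int(pat[j + 1])] += rec.count
    return tables


def _r2_from_table(tab: np.ndarray) -> float | None:
    """phi² of a 2x2 table == squared Pearson correlation of the 0/1 vectors."""
    n = tab.sum()
    row = tab.sum(axis=1)
    col = tab.sum(axis=0)
    denom = row[0] * row[1] * col[0] * col[1]
    if denom == 0:
        return None  # a constant site: correlation undefined
    num = tab[1, 1] * tab[0, 0] - tab[1, 0] * tab[0, 1]
    return float(num) ** 2 / float(denom)


def pairwise_r2(
    haplotypes: Iterable[HaplotypeRecord],
    site_a: CpGSite,
    site_b: CpGSite,
    reference_sites: Sequence[CpGSite],
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> LDEstimate:
    """Methylation LD between two reference CpGs over pooled reads.

    Only reads covering both sites contribute, weighted by their count. The
    estimate is flagged undefined when support is below ``min_pairs`` or either
    site is constant.
    """
    index = reference_sites if isinstance(reference_sites, SiteIndex) else SiteIndex(reference_sites)
    if site_a.chrom != site_b.chrom:
        return LDEstimate(site_a, site_b, 0, None)
    ia = index.locate(site_a.chrom, site_a.pos)
    ib = index.locate(site_b.chrom, site_b.pos)
    tab = np.zeros((2, 2), dtype=np.int64)
    for rec in haplotypes:
        if rec.chrom != site_a.chrom:
            continue
        i0, i1 = index.record_span(rec)
        if i0 <= ia < i1 and i0 <= ib < i1:
            tab[int(rec.pattern[ia - i0]), int(rec.pattern[ib - i0])] += rec.count
    n_pairs = int(tab.sum())
    if n_pairs < min_pairs:
        return LDEstimate(site_a, site_b, n_pairs, None)
    return LDEstimate(site_a, site_b, n_pairs, _r2_from_table(tab))


def segment_candidate_runs(
    reference_sites: Sequence[CpGSite],
    haplotypes: Iterable[HaplotypeRecord],
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> list[list[CpGSite]]:
    """Split the reference into maximal runs of jointly covered adjacent CpGs.

    Two consecutive reference CpGs stay in the same run iff they are on the
    same chromosome, at most ``max_gap_bp`` apart, and at least one read covers
    both (RRBS coverage is patchy, so the block search is restricted to runs
    with joint read support).
    """
    index = reference_sites if isinstance(reference_sites, SiteIndex) else SiteIndex(reference_sites)
    tables = _pair_tables(haplotypes, index)
    runs: list[list[CpGSite]] = []
    seen_chroms: list[str] = []
    for s in index.sites:
        if s.chrom not in seen_chroms:
            seen_chroms.append(s.chrom)
    for chrom in seen_chroms:
        pos = index.positions(chrom)
        current: list[CpGSite] = [CpGSite(chrom, int(pos[0]))]
        for i in range(1, len(pos)):
            gap_ok = pos[i] - pos[i - 1] <= max_gap_bp
            support = tables.get((chrom, i - 1))
            covered = support is not None and support.sum() > 0
            if gap_ok and covered:
                current.append(CpGSite(chrom, int(pos[i])))
            else:
                runs.append(current)
                current = [CpGSite(chrom, int(pos[i]))]
        runs.append(current)
    return runs


def call_mhbs(
    haplotypes: Sequence[HaplotypeRecord],
    reference_sites: Sequence[CpGSite],
    r2_min: float = DEFAULT_R2_MIN,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    block_id_prefix: str = "MHB",
) -> list[MHB]:
    """Call methylation haplotype blocks from pooled reads.

    Within each candidate run, blocks are the maximal stretches in which every
    consecutive CpG pair has a *defined* r² >= ``r2_min`` (an undefined pair —
    low support or a constant site — conservatively breaks the block). Only
    stretches with at least ``min_cpgs`` member CpGs are emitted. Output is
    deterministic given the input; emitted blocks are disjoint.
    """
    index = SiteIndex(reference_sites)
    if len(index) == 0:
        return []
    tables = _pair_tables(haplotypes, index)
    runs = segment_candidate_runs(index, haplotypes, max_gap_bp=max_gap_bp)

    blocks: list[MHB] = []
    for run in runs:
        if len(run) < min_cpgs:
            continue
        chrom = run[0].chrom
        local0 = index.locate(chrom, run[0].pos)
        # pair_ok[j] for the pair (run[j], run[j+1])
        pair_ok: list[bool] = []
        for j in range(len(run) - 1):
            tab = tables.get((chrom, local0 + j))
            if tab is None or tab.sum() < min_pairs:
                pair_ok.append(False)
                continue
            r2 = _r2_from_table(tab)
            pair_ok.append(r2 is not None and r2 >= r2_min)
        # greedy left-to-right maximal extension over True-stretches
        start = 0
        for j in range(len(run)):
            last = j == len(run) - 1
            if last or not pair_ok[j]:
                stretch = run[start : j + 1]
                if len(stretch) >= min_cpgs:
                    positions = tuple(s.pos for s in stretch)
                    blocks.append(
                        MHB(
                            chrom=chrom,
                            start=positions[0],
                            end=positions[-1] + 1,
                            cpg_positions=positions,
                            block_id="",  # assigned below in genomic order
                        )
                    )
                start = j + 1
    blocks.sort(key=lambda b: (chrom_sort_key(b.chrom), b.start))
    width = max(5, len(str(len(blocks))))
    out = []
    for i, b in enumerate(blocks, start=1):
        out.append(
            MHB(b.chrom, b.start, b.end, b.cpg_positions, f"{block_id_prefix}_{i:0{width}d}")
        )
    return out


def blocks_from_regions(
    regions: Sequence[Region], reference_sites: Sequence[CpGSite]
) -> list[MHB]:
    """Materialise MHBs from BED regions by attaching the reference CpGs they contain."""
    index = SiteIndex(reference_sites)
    out: list[MHB] = []
    for i, reg in enumerate(regions, start=1):
        pos = index.positions(reg.chrom)
        inside = pos[(pos >= reg.start) & (pos < reg.end)]
        if len(inside) == 0:
            continue
        name = reg.name or f"MHB_{i:05d}"
        out.append(
            MHB(
                chrom=reg.chrom,
                start=int(inside[0]),
                end=int(inside[-1]) + 1,
                cpg_positions=tuple(int(p) for p in inside),
                block_id=name,
            )
        )
    return out
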