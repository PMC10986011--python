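"""Internal index over a reference CpG set.

Maps haplotype records onto consecutive CpG indices so that block calling and
metric extraction can work with integer site indices rather than coordinates.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from bldm.io import CpGSite, FormatError, HaplotypeRecord, chrom_sort_key


class SiteIndex:
    """Ordered reference CpG set with fast interval-to-index mapping."""

    def __init__(self, sites: Sequence[CpGSite]):
        ordered = sorted(set(sites), key=lambda s: (chrom_sort_key(s.chrom), s.pos))
        self.sites: list[CpGSite] = ordered
        self._pos: dict[str, np.ndarray] = {}
        self._offset: dict[str, int] = {}
        off = 0
        chrom_order: list[str] = []
        for s in ordered:
            if s.chrom not in self._pos:
                chrom_order.append(s.chrom)
        for chrom in chrom_order:
            pos = np.array([s.pos for s in ordered if s.chrom == chrom], dtype=np.int64)
            self._pos[chrom] = pos
            self._offset[chrom] = off
            off += len(pos)

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def global_index(self, chrom: str, local_index: int) -> int:
        return self._offset[chrom] + local_index

    def site_at(self, chrom: str, local_index: int) -> CpGSite:
        return CpGSite(chrom, int(self._pos[chrom][local_index]))

    def locate(self, chrom: str, pos: int) -> int:
        """Local index of the site at (chrom, pos); KeyError if absent."""
        arr = self.positions(chrom)
        i = int(np.searchsorted(arr, pos))
        if i >= len(arr) or arr[i] != pos:
            raise KeyError(f"no reference CpG at {chrom}:{pos}")
        return i

    def record_span(self, rec: HaplotypeRecord) -> tuple[int, int]:
        """Local index range [i0, i1) of reference CpGs inside the record.

        Raises FormatError when the pattern length disagrees with the number
        of reference CpGs in the record interval.
        """
        arr = self.positions(rec.chrom)
        i0 = int(np.searchsorted(arr, rec.start, side="left"))
        i1 = int(np.searchsorted(arr, rec.end, side="left"))
        if i1 - i0 != len(rec.pattern):
            raise FormatError(
                f"record {rec.chrom}:{rec.start}-{rec.end}: pattern length "
                f"{len(rec.pattern)} vs {i1 - i0} reference CpGs in interval"
            )
        return i0, i1
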