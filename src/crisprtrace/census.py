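"""Spacer repertoire statistics: totals, unique counts, duplicated blocks
and cross-array repertoire overlap.

Spacer identity throughout this module is exact string equality after
reverse-complement folding (a spacer and its reverse complement are the
same acquisition event read from the other strand), which makes every
statistic invariant under reverse-complementing the input genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .arrays import CrisprArray
from .seqio import revcomp


def canonical(seq: str) -> str:
    """Orientation-folded representative: the lexicographic min of seq and its RC."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def _round2(x: float) -> float:
    # round-half-up to 2 decimals, the convention of printed unique/total ratios
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DuplicatedBlock:
    """A maximal run of >=1 spacer occurring >=2 times (non-overlapping) in one array."""

    sequences: tuple[str, ...]
    count: int
    positions: tuple[int, ...]  # 0-based index of the first spacer of each occurrence

    @property
    def length(self) -> int:
        return len(self.sequences)


@dataclass
class CensusReport:
    per_array: pd.DataFrame
    duplicated_blocks: dict[str, list[DuplicatedBlock]]
    pairwise_overlap: pd.DataFrame

    @property
    def total_spacers(self) -> int:
        return int(self.per_array["n_total"].sum())

    @property
    def total_unique(self) -> int:
        return int(self.per_array["n_unique"].sum())


def census_arrays(arrays: list[CrisprArray]) -> CensusReport:
    """Per-array repertoire census plus duplicated blocks and overlap matrix.

    Uniqueness is judged within each array; grand totals are sums of the
    per-array rows.
    """
    if not arrays:
        raise ValueError("census_arrays requires at least one array")
    rows = []
    blocks: dict[str, list[DuplicatedBlock]] = {}
    for arr in arrays:
        seqs = arr.spacer_sequences()
        canon = [canonical(s) for s in seqs]
        lens = [len(s) for s in seqs]
        n_total = len(seqs)
        n_unique = len(set(canon))
        rows.append(
            {
                "locus_tag": arr.locus_tag,
                "dr_length": len(arr.dr_consensus),
                "dr_consensus": arr.dr_consensus,
                "spacer_len_min": min(lens) if lens else 0,
                "spacer_len_max": max(lens) if lens else 0,
                "n_total": n_total,
                "n_unique": n_unique,
                "ratio": _round2(n_unique / n_total) if n_total else 0.0,
            }
        )
        blocks[arr.locus_tag] = find_duplicated_blocks(arr)
    per_array = pd.DataFrame(rows)
    overlap = repertoire_overlap({a.locus_tag: [a] for a in arrays})
    return CensusReport(per_array=per_array, duplicated_blocks=blocks, pairwise_overlap=overlap)


def find_duplicated_blocks(array: CrisprArray) -> list[DuplicatedBlock]:
    """Maximal repeated contiguous spacer runs within one array.

    An occurrence set counts only non-overlapping placements (greedy
    left-to-right); a block is suppressed when every one of its
    occurrences lies inside an occurrence of a longer reported block.
    """
    seqs = [canonical(s) for s in array.spacer_sequences()]
    n = len(seqs)
    found: list[DuplicatedBlock] = []
    raw_seqs = array.spacer_sequences()
    for length in range(n // 2, 0, -1):
        tuples: dict[tuple[str, ...], list[int]] = {}
        for i in range(n - length + 1):
            tuples.setdefault(tuple(seqs[i : i + length]), []).append(i)
        for tup, starts in tuples.items():
            # greedy non-overlapping occurrence count
            occ: list[int] = []
            for s in starts:
                if not occ or s >= occ[-1] + length:
                    occ.append(s)
            if len(occ) < 2:
                continue
            covered = all(
                any(
                    b.length > length and any(p <= s and s + length <= p + b.length for p in b.positions)
                    for b in found
                )
                for s in occ
            )
            if not covered:
                found.append(
                    DuplicatedBlock(
                        sequences=tuple(raw_seqs[occ[0] : occ[0] + length]),
                        count=len(occ),
                        positions=tuple(occ),
                    )
                )
    found.sort(key=lambda b: (-b.length, b.positions))
    return found


def repertoire_overlap(groups: dict[str, list[CrisprArray]]) -> pd.DataFrame:
    """Shared unique-spacer counts between labelled groups of arrays.

    Entry (i, j) is the size of the intersection of the groups' canonical
    spacer sets; the diagonal is each group's own unique count.
    """
    labels = list(groups)
    sets = {
        lab: {canonical(s) for arr in arrs for s in arr.spacer_sequences()}
        for lab, arrs in groups.items()
    }
    mat = [
        [len(sets[a] & sets[b]) if a != b else len(sets[a]) for b in labels]
        for a in labels
    ]
    return pd.DataFrame(mat, index=labels, columns=labels)
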