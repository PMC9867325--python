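"""Self-targeting spacers (STS) and prophage attachment-core location.

A spacer that matches its own host chromosome outside any detected CRISPR
array is a self-target — in lysogens these typically fall inside an
integrated prophage, a potential autoimmunity conflict.  The prophage's
integration site is marked by a short sequence duplicated at both
prophage boundaries (the att core), which :func:`locate_att_core`
recovers as the longest exact direct repeat straddling the two
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from .arrays import CrisprArray
from .matching import MatchParams, ProtospacerHit, match_spacers
from .seqio import FeatureRegion, GenomeRecord


@dataclass(frozen=True)
class StsRecord:
    """A self-targeting hit with the host features it falls in."""

    hit: ProtospacerHit
    overlapping_features: tuple[str, ...]

    @property
    def spacer_ref(self) -> str:
        return self.hit.spacer_ref


@dataclass(frozen=True)
class AttCore:
    """A duplicated attachment core flanking an integrated prophage."""

    sequence: str
    left_copy: tuple[int, int]
    right_copy: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.sequence)


def find_self_targets(
    arrays: list[CrisprArray],
    host: GenomeRecord,
    params: MatchParams | None = None,
) -> list[StsRecord]:
    """Search all array spacers against the full host genome.

    Hits that fall inside any detected array interval (padded by one
    repeat length, to absorb boundary jitter) are the spacers' own loci
    and are excluded; the rest are reported with every overlapping host
    feature label (any-overlap, >=1 shared base).
    """
    params = params or MatchParams()
    bad = [a.locus_tag for a in arrays if a.genome_id != host.id]
    if bad:
        raise ValueError(
            f"arrays {bad} were not detected on host genome {host.id!r}"
        )
    spacers = [sp for a in arrays for sp in a.spacers]
    hits = match_spacers(spacers, [host], params)

    zones = [
        (a.start - len(a.dr_consensus), a.end + len(a.dr_consensus)) for a in arrays
    ]
    records: list[StsRecord] = []
    for h in hits:
        if any(h.target_start < z_end and z_start < h.target_end for z_start, z_end in zones):
            continue  # the spacer's own array locus, not an STS
        labels = tuple(
            f.label
            for f in host.features
            if f.overlaps(h.target_start, h.target_end)
        )
        records.append(StsRecord(hit=h, overlapping_features=labels))
    return records


def locate_att_core(
    host: GenomeRecord,
    prophage: FeatureRegion,
    min_core_len: int = 12,
    window: int = 200,
) -> AttCore | None:
    """Longest exact direct repeat with one copy near each prophage boundary.

    Each boundary window spans `window` nt on both sides of the prophage
    start/end.  Ties are broken by the leftmost left copy, then the
    leftmost right copy; repeats shorter than min_core_len yield None.
    """
    if prophage.end > len(host.sequence):
        raise ValueError("prophage region exceeds host genome")
    seq = host.sequence
    l_lo = max(0, prophage.start - window)
    l_hi = min(len(seq), prophage.start + window)
    r_lo = max(0, prophage.end - window)
    r_hi = min(len(seq), prophage.end + window)
    left = seq[l_lo:l_hi]
    right = seq[r_lo:r_hi]

    best: tuple[int, int, int] | None = None  # (length, left_start, right_start) local
    m, n = len(left), len(right)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        ci = left[i - 1]
        for j in range(1, n + 1):
            if ci == right[j - 1]:
                length = prev[j - 1] + 1
                cur[j] = length
                cand = (length, i - length, j - length)
                if (
                    best is None
                    or length > best[0]
                    or (length == best[0] and (cand[1], cand[2]) < (best[1], best[2]))
                ):
                    best = cand
        prev = cur

    if best is None or best[0] < min_core_len:
        return None
    length, li, rj = best
    left_start = l_lo + li
    right_start = r_lo + rj
    if right_start < left_start + length:
        # degenerate: the boundary windows overlap and the "two copies"
        # share genomic bases
        return None
    return AttCore(
        sequence=seq[left_start : left_start + length],
        left_copy=(left_start, left_start + length),
        right_copy=(right_start, right_start + length),
    )
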