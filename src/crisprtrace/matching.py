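"""Spacer-to-protospacer matching, PAM inference and recency classification.

Matching aligns every spacer end-to-end against both strands of every
target replicon and reports all loci passing the identity and
query-coverage thresholds (85% / 90% by default).  The spacer is never
clipped: identity is computed over the full spacer so that the mismatch
count of an ungapped hit is exactly its Hamming distance.  Gaps are
allowed within the aligned span and are scored like mismatches toward
identity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .arrays import CrisprArray, Spacer
from .seqio import GenomeRecord, revcomp

logger = logging.getLogger(__name__)

_FLANK_RC = str.maketrans("ACGTN.", "TGCAN.")


def _revcomp_flank(s: str) -> str:
    """Reverse complement that preserves '.' contig-end padding."""
    return s.translate(_FLANK_RC)[::-1]


@dataclass(frozen=True)
class MatchParams:
    """Thresholds and scores for the spacer-vs-MGE search."""

    min_identity: float = 0.85
    min_query_coverage: float = 0.90
    match_score: int = 1
    mismatch_score: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    flank_len: int = 10
    # ungapped by default: the per-hit mismatch count (the readout that
    # matters downstream) is only well-defined without indels; gapped
    # alignments can be rescued on request
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        for t in (self.min_identity, self.min_query_coverage):
            if not (0.0 < t <= 1.0):
                raise ValueError("thresholds must lie in (0, 1]")
        if self.flank_len < 3:
            raise ValueError("flank_len must be >= 3")

    def max_substitutions(self, spacer_len: int) -> int:
        """Largest ungapped mismatch count admitted at full coverage."""
        return int(math.floor((1.0 - self.min_identity) * spacer_len + 1e-9))


@dataclass(frozen=True)
class ProtospacerHit:
    """One spacer-to-target match; coordinates on the target forward strand."""

    spacer_ref: str
    spacer_len: int
    target_id: str
    target_start: int
    target_end: int
    strand: str
    aligned_len: int
    n_match: int
    n_mismatch: int
    n_gap: int
    upstream_flank: str
    downstream_flank: str

    @property
    def identity(self) -> float:
        return self.n_match / self.aligned_len

    @property
    def query_coverage(self) -> float:
        # the spacer aligns end-to-end, so the aligned query span is the
        # full spacer; kept as a property for reporting symmetry
        return 1.0


@dataclass
class PamResult:
    side: str
    motif: str
    support: int
    position_freqs: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def empty(self) -> bool:
        return self.support == 0


@dataclass(frozen=True)
class RecencyClass:
    spacer_ref: str
    index: int
    p: float
    label: str  # leader_proximal | middle | leader_distal


@dataclass
class HitDistribution:
    table: pd.DataFrame
    fraction_with_hit: float


def _hamming_scan(target: np.ndarray, pattern: np.ndarray, max_d: int) -> list[tuple[int, int]]:
    """All offsets where the pattern matches within max_d substitutions.

    Returns (offset, distance) pairs; this IS the ungapped search, not a
    heuristic: every qualifying locus is found.
    """
    L = len(pattern)
    if len(target) < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(target, L)
    dists = (windows != pattern).sum(axis=1)
    offs = np.nonzero(dists <= max_d)[0]
    return [(int(o), int(dists[o])) for o in offs]


def _affine_counts(query: str, infix: str, params: MatchParams) -> tuple[int, int, int, int]:
    """(aligned_len, n_match, n_mismatch, n_gap) of a global affine alignment."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aln = aligner.align(infix, query)[0]
    counts = aln.counts()
    aligned_len = counts.gaps + counts.identities + counts.mismatches
    return aligned_len, counts.identities, counts.mismatches, counts.gaps


def _extract_flanks(
    tseq: str, start: int, end: int, strand: str, flank: int
) -> tuple[str, str]:
    """Flanks of flank_len read in protospacer orientation, '.'-padded at contig ends."""
    left = tseq[max(0, start - flank) : start].rjust(flank, ".")
    right = tseq[end : end + flank].ljust(flank, ".")
    if strand == "+":
        return left, right
    return _revcomp_flank(right), _revcomp_flank(left)


def match_spacers(
    spacers: list[Spacer],
    targets: list[GenomeRecord],
    params: MatchParams | None = None,
) -> list[ProtospacerHit]:
    """Search every spacer against both strands of every target.

    All loci passing both thresholds are reported; per (spacer, target,
    strand, locus) only the best alignment (highest identity, then
    leftmost) is kept.  Spacers containing N are skipped with a warning.
    """
    params = params or MatchParams()
    if not targets:
        raise ValueError("match_spacers requires at least one target")
    hits: list[ProtospacerHit] = []
    target_arrays = {
        t.id: np.frombuffer(t.sequence.encode(), dtype=np.uint8) for t in targets
    }
    for spacer in spacers:
        if "N" in spacer.sequence:
            logger.warning("spacer %s contains N; skipped from matching", spacer.name)
            continue
        L = len(spacer.sequence)
        max_d = params.max_substitutions(L)
        for target in targets:
            t_arr = target_arrays[target.id]
            for strand in ("+", "-"):
                pattern = spacer.sequence if strand == "+" else revcomp(spacer.sequence)
                p_arr = np.frombuffer(pattern.encode(), dtype=np.uint8)
                found: list[ProtospacerHit] = []
                for off, d in _hamming_scan(t_arr, p_arr, max_d):
                    up, down = _extract_flanks(
                        target.sequence, off, off + L, strand, params.flank_len
                    )
                    found.append(
                        ProtospacerHit(
                            spacer_ref=spacer.name,
                            spacer_len=L,
                            target_id=target.id,
                            target_start=off,
                            target_end=off + L,
                            strand=strand,
                            aligned_len=L,
                            n_match=L - d,
                            n_mismatch=d,
                            n_gap=0,
                            upstream_flank=up,
                            downstream_flank=down,
                        )
                    )
                if params.allow_gaps:
                    found.extend(
                        _gapped_rescue(spacer, pattern, target, strand, max_d, params, found)
                    )
                hits.extend(_dedup_locus(found))
    hits.sort(key=lambda h: (h.spacer_ref, h.target_id, h.target_start, h.strand))
    return hits


def _gapped_rescue(
    spacer: Spacer,
    pattern: str,
    target: GenomeRecord,
    strand: str,
    max_d: int,
    params: MatchParams,
    existing: list[ProtospacerHit],
) -> list[ProtospacerHit]:
    """Recover gapped hits at the target's optimal edit-distance locus.

    The exhaustive scan above already finds every ungapped locus; this
    pass only adds indel-containing alignments, and only at loci the
    scan did not already explain.
    """
    res = edlib.align(pattern, target.sequence, mode="HW", task="locations", k=max_d)
    if res["editDistance"] < 0:
        return []
    out: list[ProtospacerHit] = []
    L = len(pattern)
    for s, e in res["locations"] or []:
        e += 1  # edlib end is inclusive
        if any(h.target_start < e and s < h.target_end for h in existing + out):
            continue
        infix = target.sequence[s:e]
        aligned_len, n_match, n_mm, n_gap = _affine_counts(pattern, infix, params)
        hit = ProtospacerHit(
            spacer_ref=spacer.name,
            spacer_len=L,
            target_id=target.id,
            target_start=s,
            target_end=e,
            strand=strand,
            aligned_len=aligned_len,
            n_match=n_match,
            n_mismatch=n_mm,
            n_gap=n_gap,
            upstream_flank=_extract_flanks(target.sequence, s, e, strand, params.flank_len)[0],
            downstream_flank=_extract_flanks(target.sequence, s, e, strand, params.flank_len)[1],
        )
        if hit.identity >= params.min_identity and hit.query_coverage >= params.min_query_coverage:
            out.append(hit)
    return out


def _dedup_locus(found: list[ProtospacerHit]) -> list[ProtospacerHit]:
    """One hit per locus: overlapping same-strand hits keep the best identity, then leftmost."""
    kept: list[ProtospacerHit] = []
    for h in sorted(found, key=lambda h: (-h.identity, h.target_start)):
        if all(
            h.target_end <= k.target_start or k.target_end <= h.target_start
            for k in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: h.target_start)
    return kept


def infer_pam(
    hits: list[ProtospacerHit],
    side: str = "upstream",
    k: int = 3,
    agreement: float = 0.75,
) -> PamResult:
    """Consensus motif in the k flank positions adjacent to the protospacer.

    A position is resolved when its majority base reaches the agreement
    fraction; the motif is the maximal resolved run touching the
    protospacer.  Hits whose flank window runs off the contig ('.') are
    ignored; with no usable hit an empty-result marker is returned.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be upstream or downstream, got {side!r}")
    windows = []
    for h in hits:
        flank = h.upstream_flank if side == "upstream" else h.downstream_flank
        win = flank[-k:] if side == "upstream" else flank[:k]
        if len(win) == k and "." not in win:
            windows.append(win)
    if not windows:
        return PamResult(side=side, motif="", support=0)

    freqs = []
    resolved: list[str | None] = []
    for i in range(k):
        counts = pd.Series([w[i] for w in windows]).value_counts()
        freq = counts / len(windows)
        freqs.append(freq.to_dict())
        base = freq.index[0]
        resolved.append(base if freq.iloc[0] >= agreement else None)

    # maximal resolved run adjacent to the protospacer
    if side == "upstream":
        run: list[str] = []
        for b in reversed(resolved):  # walk away from the protospacer
            if b is None:
                break
            run.append(b)
        motif = "".join(reversed(run))
    else:
        run = []
        for b in resolved:
            if b is None:
                break
            run.append(b)
        motif = "".join(run)

    table = pd.DataFrame(freqs).fillna(0.0)
    table.index = (
        range(-k, 0) if side == "upstream" else range(1, k + 1)
    )
    return PamResult(side=side, motif=motif, support=len(windows), position_freqs=table)


def classify_recency(
    array: CrisprArray,
    spacer_indices: list[int] | None = None,
    proximal_max: float = 0.20,
    distal_min: float = 2.0 / 3.0,
) -> list[RecencyClass]:
    """Position-based acquisition-recency class for spacers of one array.

    p = (index - 1)/(n - 1) measures distance from the leader; newly
    acquired spacers sit leader-proximal (small p).
    """
    n = array.n_spacers
    if spacer_indices is None:
        spacer_indices = [sp.index for sp in array.spacers]
    out = []
    for idx in spacer_indices:
        if not (1 <= idx <= n):
            raise ValueError(f"spacer index {idx} out of range 1..{n}")
        p = 0.0 if n == 1 else (idx - 1) / (n - 1)
        if p <= proximal_max:
            label = "leader_proximal"
        elif p >= distal_min:
            label = "leader_distal"
        else:
            label = "middle"
        out.append(
            RecencyClass(
                spacer_ref=f"SP_{array.locus_tag}_{idx}", index=idx, p=p, label=label
            )
        )
    return out


def hit_distribution(
    hits: list[ProtospacerHit], targets: list[GenomeRecord]
) -> HitDistribution:
    """Per-target protospacer load and the fraction of targets with >=1 hit."""
    by_target: dict[str, list[ProtospacerHit]] = {t.id: [] for t in targets}
    for h in hits:
        by_target.setdefault(h.target_id, []).append(h)
    rows = []
    n_with = 0
    for t in targets:
        th = by_target[t.id]
        spacer_mm = {}
        for h in th:
            prev = spacer_mm.get(h.spacer_ref)
            if prev is None or h.n_mismatch < prev:
                spacer_mm[h.spacer_ref] = h.n_mismatch
        if th:
            n_with += 1
        rows.append(
            {
                "target_id": t.id,
                "n_distinct_spacers": len(spacer_mm),
                "n_hits": len(th),
                "spacer_mismatches": ";".join(
                    f"{s}:{m}" for s, m in sorted(spacer_mm.items())
                ),
            }
        )
    frac = n_with / len(targets) if targets else 0.0
    return HitDistribution(table=pd.DataFrame(rows), fraction_with_hit=frac)
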