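"""De novo CRISPR array detection.

An array is a run of near-identical direct repeats (DRs) separated by
unique spacers.  Detection seeds on exact repeated words whose spacing is
compatible with a repeat+spacer period, chains colinear word occurrences,
then fixes the repeat boundaries as the maximal extent conserved across
the chained instances.  Spacers are emitted leader-anchored; see
:func:`orient_array` for how the leader end is chosen.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import edlib

from .seqio import FeatureRegion, GenomeRecord


@dataclass(frozen=True)
class ArrayFinderParams:
    """Tunables for de novo array detection.

    Length windows bracket the DR (23-47 nt) and spacer (20-60 nt) sizes
    seen in lactic-acid-bacteria arrays with margin; at least three
    repeats are required to call an array.
    """

    seed_k: int = 8
    dr_len_min: int = 23
    dr_len_max: int = 47
    spacer_len_min: int = 20
    spacer_len_max: int = 60
    min_repeats: int = 3
    max_dr_mismatch_frac: float = 0.2
    max_spacer_pair_identity: float = 0.60

    def __post_init__(self) -> None:
        if self.dr_len_min > self.dr_len_max:
            raise ValueError("dr_len_min > dr_len_max")
        if self.spacer_len_min > self.spacer_len_max:
            raise ValueError("spacer_len_min > spacer_len_max")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")
        for f in (self.max_dr_mismatch_frac, self.max_spacer_pair_identity):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def period_min(self) -> int:
        return self.dr_len_min + self.spacer_len_min

    @property
    def period_max(self) -> int:
        return self.dr_len_max + self.spacer_len_max


@dataclass(frozen=True)
class Spacer:
    """One spacer, named SP_<locusTag>_<index> with index 1-based from the leader."""

    array_ref: str
    index: int
    sequence: str
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"SP_{self.array_ref}_{self.index}"


@dataclass
class CrisprArray:
    genome_id: str
    locus_tag: str
    start: int
    end: int
    dr_consensus: str
    repeats: list[tuple[int, int, str]]
    spacers: list[Spacer]
    leader_end: str = "left"
    orientation_resolved: bool = False

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.repeats) - 1:
            raise ValueError(
                f"array {self.locus_tag}: {len(self.repeats)} repeats require "
                f"{len(self.repeats) - 1} spacers, got {len(self.spacers)}"
            )

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    def spacer_sequences(self) -> list[str]:
        return [sp.sequence for sp in self.spacers]

    def as_feature(self) -> FeatureRegion:
        return FeatureRegion(
            label=self.locus_tag,
            start=self.start,
            end=self.end,
            strand=".",
            kind="array",
            seqid=self.genome_id,
        )


def build_consensus(repeats: list[str]) -> str:
    """Per-column majority consensus of left-anchored repeat instances.

    The consensus length is the modal repeat length (smallest mode on a
    tie); column ties are broken by the alphabetically smallest base.
    """
    if not repeats:
        raise ValueError("build_consensus requires at least one repeat instance")
    lengths = Counter(len(r) for r in repeats)
    top = max(lengths.values())
    modal_len = min(length for length, c in lengths.items() if c == top)
    cols = []
    for i in range(modal_len):
        counts = Counter(r[i] for r in repeats if len(r) > i)
        best = max(counts.values())
        cols.append(min(b for b, c in counts.items() if c == best))
    return "".join(cols)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))


def _pair_identity(a: str, b: str) -> float:
    """Global alignment identity approximation: 1 - editdist / max(len)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _allowed_deviant_rows(n_rows: int) -> int:
    # quorum for boundary extension: at most 1 deviant row for shallow
    # stacks, ~10% for deep ones; keeps chance extension into random
    # flanks negligible at >=8 repeats
    return max(1, n_rows // 10)


def find_crispr_arrays(
    genome: GenomeRecord, params: ArrayFinderParams | None = None
) -> list[CrisprArray]:
    """Detect CRISPR arrays in one genome.

    Returns arrays sorted by start coordinate; an empty list is a valid
    result.  Overlapping candidate solutions are merged by keeping the
    highest-repeat-count candidate.
    """
    params = params or ArrayFinderParams()
    seq = genome.sequence
    if len(seq) < params.dr_len_min * params.min_repeats:
        return []

    chains = _candidate_chains(seq, params)
    # richest chains first; chains fully inside an accepted solution are redundant
    chains.sort(key=lambda c: (-len(c), c[0]))
    candidates: list[CrisprArray] = []
    for anchors in chains:
        lo, hi = anchors[0], anchors[-1] + params.seed_k
        if any(c.start <= lo and hi <= c.end for c in candidates):
            continue
        arr = _chain_to_array(seq, genome.id, anchors, params)
        if arr is not None:
            candidates.append(arr)

    merged = _merge_overlapping(candidates)
    merged.sort(key=lambda a: a.start)
    out = []
    for i, arr in enumerate(merged, start=1):
        tag = f"{genome.id}_{i}"
        out.append(_retag(arr, tag))
    return out


def _candidate_chains(seq: str, params: ArrayFinderParams) -> list[list[int]]:
    k = params.seed_k
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" not in word:
            index[word].append(i)

    lo, hi = params.period_min, params.period_max
    chains: list[list[int]] = []
    for positions in index.values():
        if len(positions) < params.min_repeats:
            continue
        chain = [positions[0]]
        for pos in positions[1:]:
            delta = pos - chain[-1]
            if lo <= delta <= hi:
                chain.append(pos)
            elif delta > hi:
                if len(chain) >= params.min_repeats:
                    chains.append(chain)
                chain = [pos]
            # delta < lo: word recurs within the same unit; ignore
        if len(chain) >= params.min_repeats:
            chains.append(chain)
    return chains


def _extend_boundary(seq: str, anchors: list[int], offset0: int, step: int, limit: int) -> int:
    """Number of conserved columns from the anchors in direction `step`."""
    n = len(anchors)
    allowed = _allowed_deviant_rows(n)
    extent = 0
    while extent < limit:
        d = offset0 + step * (extent + 1) if step > 0 else offset0 - (extent + 1)
        cols = []
        for p in anchors:
            j = p + d
            if 0 <= j < len(seq):
                cols.append(seq[j])
        if len(cols) < n:
            break
        counts = Counter(cols)
        if n - max(counts.values()) > allowed:
            break
        extent += 1
    return extent


def _chain_to_array(
    seq: str, genome_id: str, anchors: list[int], params: ArrayFinderParams
) -> CrisprArray | None:
    k = params.seed_k
    # conserved extent left of the anchor word and right of its end
    max_ext = params.dr_len_max - k
    left = _extend_boundary(seq, anchors, 0, -1, max_ext)
    right = _extend_boundary(seq, [p + k - 1 for p in anchors], 0, +1, max_ext - left)
    rep_len = k + left + right
    if not (params.dr_len_min <= rep_len <= params.dr_len_max):
        return None

    intervals = [(p - left, p - left + rep_len) for p in anchors]
    if intervals[0][0] < 0 or intervals[-1][1] > len(seq):
        return None

    # split at spacer gaps outside the allowed window, keep the best piece
    pieces: list[list[tuple[int, int]]] = [[intervals[0]]]
    for prev, cur in zip(intervals, intervals[1:]):
        gap = cur[0] - prev[1]
        if params.spacer_len_min <= gap <= params.spacer_len_max:
            pieces[-1].append(cur)
        else:
            pieces.append([cur])
    best = max(pieces, key=len)
    if len(best) < params.min_repeats:
        return None

    # rescue adjacent full-length repeats whose seed word was mutated,
    # then re-derive the repeat boundaries from the full stack: a deep
    # column quorum is far more specific than the seeding chain's
    intervals = _rescue_terminal(seq, best, _majority(seq, best), params, full_only=True)
    intervals = _refine_intervals(seq, intervals, params)
    if intervals is None:
        return None

    repeats = [(s, e, seq[s:e]) for s, e in intervals]
    consensus = build_consensus([r[2] for r in repeats])
    budget = int(params.max_dr_mismatch_frac * len(consensus))

    # trim terminal repeats too far from consensus (eroded ends)
    while len(repeats) > params.min_repeats and _hamming(repeats[0][2], consensus) > budget:
        repeats = repeats[1:]
        consensus = build_consensus([r[2] for r in repeats])
        budget = int(params.max_dr_mismatch_frac * len(consensus))
    while len(repeats) > params.min_repeats and _hamming(repeats[-1][2], consensus) > budget:
        repeats = repeats[:-1]
        consensus = build_consensus([r[2] for r in repeats])
        budget = int(params.max_dr_mismatch_frac * len(consensus))
    if any(_hamming(r[2], consensus) > budget for r in repeats):
        return None

    # partial (>=50%-length) terminal repeats are recorded as repeats; the
    # gap before them becomes an ordinary spacer, keeping alternation
    intervals = _rescue_terminal(
        seq, [(s, e) for s, e, _ in repeats], consensus, params, full_only=False
    )
    repeats = [(s, e, seq[s:e]) for s, e in intervals]

    spacers = []
    for i, (prev, cur) in enumerate(zip(repeats, repeats[1:]), start=1):
        s, e = prev[1], cur[0]
        spacers.append(Spacer(array_ref="?", index=i, sequence=seq[s:e], start=s, end=e))

    if len(spacers) >= 2:
        seqs = [sp.sequence for sp in spacers]
        pairs = [(a, b) for i, a in enumerate(seqs) for b in seqs[i + 1 :]]
        mean_ident = sum(_pair_identity(a, b) for a, b in pairs) / len(pairs)
        if mean_ident > params.max_spacer_pair_identity:
            return None  # tandem repeat region, not a CRISPR array

    return CrisprArray(
        genome_id=genome_id,
        locus_tag="?",
        start=repeats[0][0],
        end=repeats[-1][1],
        dr_consensus=consensus,
        repeats=repeats,
        spacers=spacers,
    )


def _majority(seq: str, intervals: list[tuple[int, int]]) -> str:
    return build_consensus([seq[s:e] for s, e in intervals])


def _rescue_terminal(
    seq: str,
    intervals: list[tuple[int, int]],
    consensus: str,
    params: ArrayFinderParams,
    full_only: bool,
) -> list[tuple[int, int]]:
    """Extend the array with terminal repeats the seeding chain missed.

    With full_only, only complete consensus copies are added (repeats
    whose seed word carried a substitution); otherwise partial terminal
    copies down to 50% of the consensus length are also accepted.
    """
    clen = len(consensus)
    min_partial = clen if full_only else (clen + 1) // 2

    def best_candidate(side: str):
        found = None  # (partial_len, gap, start)
        for gap in range(params.spacer_len_min, params.spacer_len_max + 1):
            for plen in range(clen, min_partial - 1, -1):
                if side == "right":
                    s = intervals[-1][1] + gap
                    e = s + plen
                    ref = consensus[:plen]
                else:
                    e = intervals[0][0] - gap
                    s = e - plen
                    ref = consensus[-plen:]
                if s < 0 or e > len(seq):
                    continue
                frag = seq[s:e]
                if "N" in frag:
                    continue
                if _hamming(frag, ref) <= int(params.max_dr_mismatch_frac * plen):
                    if found is None or plen > found[0]:
                        found = (plen, gap, s)
                    break  # longest for this gap found
        return found

    changed = True
    while changed:
        changed = False
        cand = best_candidate("right")
        if cand is not None:
            plen, _gap, s = cand
            intervals = intervals + [(s, s + plen)]
            changed = True
        cand = best_candidate("left")
        if cand is not None:
            plen, _gap, s = cand
            intervals = [(s, s + plen)] + intervals
            changed = True
    return intervals


def _refine_intervals(
    seq: str, intervals: list[tuple[int, int]], params: ArrayFinderParams
) -> list[tuple[int, int]] | None:
    """Re-derive repeat boundaries from the full repeat stack.

    The initial extent comes from a seeding chain that may hold only a
    few instances; with all instances aligned, the column quorum is far
    more specific.  Edge columns failing the quorum are shaved off and
    conserved columns just outside are annexed (within the configured
    length windows).
    """
    n = len(intervals)
    allowed = _allowed_deviant_rows(n)
    starts = [s for s, _ in intervals]
    ends = [e for _, e in intervals]

    def conserved(idxs) -> bool:
        cols = []
        for i in idxs:
            if not (0 <= i < len(seq)):
                return False
            cols.append(seq[i])
        return n - max(Counter(cols).values()) <= allowed

    def width() -> int:
        return ends[0] - starts[0]

    def min_gap() -> int:
        return min((s - e for s, e in zip(starts[1:], ends[:-1])), default=10**9)

    while width() > params.dr_len_min and not conserved(starts):
        starts = [s + 1 for s in starts]
    while (
        width() < params.dr_len_max
        and min(starts) > 0
        and min_gap() > params.spacer_len_min
        and conserved([s - 1 for s in starts])
    ):
        starts = [s - 1 for s in starts]
    while width() > params.dr_len_min and not conserved([e - 1 for e in ends]):
        ends = [e - 1 for e in ends]
    while (
        width() < params.dr_len_max
        and max(ends) < len(seq)
        and min_gap() > params.spacer_len_min
        and conserved(ends)
    ):
        ends = [e + 1 for e in ends]

    if not (params.dr_len_min <= width() <= params.dr_len_max):
        return None
    gaps = [s - e for s, e in zip(starts[1:], ends[:-1])]
    if any(g < params.spacer_len_min or g > params.spacer_len_max for g in gaps):
        return None
    return list(zip(starts, ends))


def _conservation_cost(arr: CrisprArray) -> int:
    return sum(_hamming(r[2], arr.dr_consensus) for r in arr.repeats)


def _merge_overlapping(candidates: list[CrisprArray]) -> list[CrisprArray]:
    """One solution per overlapping group: most repeats, best conservation, leftmost."""
    chosen: list[CrisprArray] = []
    for arr in sorted(
        candidates,
        key=lambda a: (-a.n_repeats, _conservation_cost(a), a.start, a.end - a.start),
    ):
        if all(arr.end <= c.start or c.end <= arr.start for c in chosen):
            chosen.append(arr)
    return chosen


def _retag(arr: CrisprArray, tag: str) -> CrisprArray:
    spacers = [replace(sp, array_ref=tag) for sp in arr.spacers]
    return replace(arr, locus_tag=tag, spacers=spacers)


def set_locus_tag(arr: CrisprArray, tag: str) -> CrisprArray:
    """Return a copy of the array under a caller-chosen locus tag."""
    return _retag(arr, tag)


def repeat_mismatches(arr: CrisprArray) -> list[int]:
    """Mismatch count of each repeat instance against the array consensus."""
    return [_hamming(r[2], arr.dr_consensus) for r in arr.repeats]


def orient_array(
    arr: CrisprArray, cas_hint: FeatureRegion | None = None, hint_margin: int = 2000
) -> CrisprArray:
    """Fix the leader-proximal end and renumber spacers from it.

    Priority: a cas-operon hint adjacent to one flank places the leader on
    that side; otherwise a degenerate terminal repeat (more consensus
    mismatches than the interior mean, or truncated) marks the trailing
    (leader-distal) end.  With neither signal the leader defaults to the
    left end and the orientation is flagged unresolved.
    """
    leader = None
    if cas_hint is not None:
        if cas_hint.end <= arr.start and arr.start - cas_hint.end <= hint_margin:
            leader = "left"
        elif cas_hint.start >= arr.end and cas_hint.start - arr.end <= hint_margin:
            leader = "right"

    if leader is None and arr.n_repeats >= 3:
        clen = len(arr.dr_consensus)
        mism = repeat_mismatches(arr)
        trunc = [clen - (r[1] - r[0]) for r in arr.repeats]
        degeneracy = [m + max(t, 0) for m, t in zip(mism, trunc)]
        interior = degeneracy[1:-1]
        mean_interior = sum(interior) / len(interior) if interior else 0.0
        left_deg = degeneracy[0] > mean_interior and degeneracy[0] >= 1
        right_deg = degeneracy[-1] > mean_interior and degeneracy[-1] >= 1
        if right_deg and not left_deg:
            leader = "left"
        elif left_deg and not right_deg:
            leader = "right"

    resolved = leader is not None
    if leader is None:
        leader = "left"

    spacers = []
    n = arr.n_spacers
    for sp in arr.spacers:
        genomic_pos = sp.index if arr.leader_end == "left" else n - sp.index + 1
        new_index = genomic_pos if leader == "left" else n - genomic_pos + 1
        spacers.append(replace(sp, index=new_index))
    spacers.sort(key=lambda s: s.index)
    return replace(
        arr, leader_end=leader, orientation_resolved=resolved, spacers=spacers
    )


def find_orphan_repeats(
    genome: GenomeRecord,
    consensus: str,
    arrays: list[CrisprArray] | None = None,
    max_mismatch_frac: float = 0.2,
) -> list[FeatureRegion]:
    """Locate isolated copies of a DR consensus outside detected arrays.

    A lone DR is the footprint left behind by a deleted array; it is
    reported as a feature, never as an array.
    """
    arrays = arrays or []
    L = len(consensus)
    budget = int(max_mismatch_frac * L)
    hits: list[FeatureRegion] = []
    seq = genome.sequence
    occupied = [(a.start, a.end) for a in arrays]
    i = 0
    while i <= len(seq) - L:
        if _hamming(seq[i : i + L], consensus) <= budget:
            if not any(s < i + L and i < e for s, e in occupied):
                hits.append(
                    FeatureRegion(
                        label=f"orphan_repeat_{i}",
                        start=i,
                        end=i + L,
                        kind="other",
                        seqid=genome.id,
                    )
                )
            i += L
        else:
            i += 1
    return hits
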