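"""Rapid phage typing by per-category protein clustering and six-slot barcodes.

Six marker functions — integrase (Int), lysogeny maintenance (LM),
replication (Rep), small terminase (TerS), tape measure protein (TMP) and
a moron-module toxin (Doc) — are each clustered at >90% global identity.
A phage's barcode is the combination of its class in the first five
categories plus presence/absence of Doc; distinct barcodes dereplicate a
phage collection into patterns.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import edlib
from Bio import SeqIO

CATEGORIES = ("INT", "LM", "REP", "TERS", "TMP", "DOC")

LABEL_PREFIX = {
    "INT": "Int",
    "LM": "LM",
    "REP": "Rep",
    "TERS": "TerS",
    "TMP": "TMP",
    "DOC": "Doc",
}

_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinSeq:
    phage_id: str
    category: str
    sequence: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if len(self.sequence) < 30:
            raise ValueError(
                f"{self.phage_id}|{self.category}: protein shorter than 30 residues"
            )
        bad = set(self.sequence) - _AA
        if bad:
            raise ValueError(
                f"{self.phage_id}|{self.category}: illegal residue(s) {sorted(bad)!r}"
            )

    @property
    def seq_id(self) -> str:
        return f"{self.phage_id}|{self.category}"


@dataclass
class ClassAssignment:
    category: str
    class_label: str
    member_phage_ids: list[str]
    centroid_id: str
    centroid_sequence: str


@dataclass(frozen=True)
class Barcode:
    """Six-slot phage type; the string form is a bijection of the tuple."""

    phage_id: str
    int_type: str | None
    lm: str | None
    rep: str | None
    ters: str | None
    tmp: str | None
    doc_present: bool

    def __str__(self) -> str:
        slots = [
            self.int_type or "Int-",
            self.lm or "LM-",
            self.rep or "Rep-",
            self.ters or "TerS-",
            self.tmp or "TMP-",
            "Doc+" if self.doc_present else "Doc-",
        ]
        return "|".join(slots)


@dataclass
class PatternCensus:
    patterns: dict[str, list[str]]
    representatives: dict[str, str] = field(default_factory=dict)

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)


def global_identity(a: str, b: str) -> float:
    """Matched columns / total columns of an edit-distance-optimal global alignment."""
    res = edlib.align(a, b, mode="NW", task="path")
    cols = matches = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches / cols if cols else 0.0


def cluster_category(
    seqs: list[ProteinSeq], threshold: float = 0.90
) -> list[ClassAssignment]:
    """Greedy centroid clustering of one category's proteins.

    Sequences are processed by descending length (ties by id) and join
    the first existing centroid exceeding the identity threshold
    (strictly >), else found a new class.  Class labels are numbered by
    descending cluster size, ties by smallest member id.
    """
    if not seqs:
        return []
    cats = {s.category for s in seqs}
    if len(cats) != 1:
        raise ValueError(f"cluster_category got mixed categories {sorted(cats)}")
    category = cats.pop()
    ordered = sorted(seqs, key=lambda s: (-len(s.sequence), s.seq_id))
    centroids: list[ProteinSeq] = []
    members: list[list[str]] = []
    for s in ordered:
        for i, c in enumerate(centroids):
            if global_identity(s.sequence, c.sequence) > threshold:
                members[i].append(s.phage_id)
                break
        else:
            centroids.append(s)
            members.append([s.phage_id])

    order = sorted(
        range(len(centroids)), key=lambda i: (-len(members[i]), min(members[i]))
    )
    prefix = LABEL_PREFIX[category]
    out = []
    for rank, i in enumerate(order, start=1):
        out.append(
            ClassAssignment(
                category=category,
                class_label=f"{prefix}{rank}",
                member_phage_ids=sorted(members[i]),
                centroid_id=centroids[i].seq_id,
                centroid_sequence=centroids[i].sequence,
            )
        )
    return out


def assign_barcode(
    phage_id: str, assignments: dict[str, list[ClassAssignment]]
) -> Barcode:
    """Look up a phage's class in every category and build its barcode.

    A missing category gives an "absent" slot; Doc reduces to
    presence/absence.  A phage carried twice within one category is an
    error — poly-protein phages must be pre-split.
    """
    slot: dict[str, str | None] = {}
    doc_present = False
    for cat in CATEGORIES:
        classes = assignments.get(cat, [])
        hits = [
            c.class_label
            for c in classes
            for pid in c.member_phage_ids
            if pid == phage_id
        ]
        if len(hits) > 1:
            raise ValueError(
                f"phage {phage_id!r} has {len(hits)} proteins in category {cat}"
            )
        if cat == "DOC":
            doc_present = bool(hits)
        else:
            slot[cat] = hits[0] if hits else None
    return Barcode(
        phage_id=phage_id,
        int_type=slot["INT"],
        lm=slot["LM"],
        rep=slot["REP"],
        ters=slot["TERS"],
        tmp=slot["TMP"],
        doc_present=doc_present,
    )


def pattern_census(barcodes: list[Barcode]) -> PatternCensus:
    """Group phages by barcode string; representative = smallest phage id."""
    if not barcodes:
        raise ValueError("pattern_census requires at least one barcode")
    seen = Counter(b.phage_id for b in barcodes)
    dup = [p for p, c in seen.items() if c > 1]
    if dup:
        raise ValueError(f"duplicate barcode(s) for phage(s) {dup}")
    patterns: dict[str, list[str]] = defaultdict(list)
    for b in barcodes:
        patterns[str(b)].append(b.phage_id)
    patterns = {k: sorted(v) for k, v in sorted(patterns.items())}
    reps = {k: v[0] for k, v in patterns.items()}
    return PatternCensus(patterns=patterns, representatives=reps)


def conserved_blocks(
    assignment: ClassAssignment,
    seqs: list[ProteinSeq],
    min_len: int = 15,
) -> list[tuple[int, int]]:
    """Centroid-coordinate runs (>= min_len) identical across all members.

    Auxiliary output for downstream primer design; positions are 0-based
    half-open on the centroid sequence.
    """
    centroid = assignment.centroid_sequence
    invariant = [True] * len(centroid)
    by_id = {s.phage_id: s for s in seqs}
    for pid in assignment.member_phage_ids:
        s = by_id[pid]
        res = edlib.align(s.sequence, centroid, mode="NW", task="path")
        pos = 0  # centroid coordinate
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch == "=":
                pos += n
            elif ch in ("X", "D"):  # D consumes the target (centroid)
                for j in range(pos, min(pos + n, len(centroid))):
                    invariant[j] = False
                pos += n
            elif ch == "I":
                if 0 <= pos < len(centroid):
                    invariant[pos] = False
    blocks = []
    start = None
    for i, ok in enumerate(invariant + [False]):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_len:
                blocks.append((start, i))
            start = None
    return blocks


def read_protein_fasta(path: str | Path, category: str) -> list[ProteinSeq]:
    """Read one category's proteins; headers are `phageID|category` or plain ids."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id.split("|")[0]
        out.append(
            ProteinSeq(phage_id=pid, category=category, sequence=str(rec.seq).upper())
        )
    if not out:
        raise ValueError(f"no protein records in {path}")
    return out


def write_protein_fasta(seqs: list[ProteinSeq], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.seq_id}\n{s.sequence}\n")
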