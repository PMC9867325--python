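"""Sequence and feature-table I/O with the pipeline's coordinate conventions.

All coordinates inside the package are 0-based half-open on the forward
strand of the replicon they refer to.  Conversion to 1-based inclusive
happens only when GFF3 is serialized.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = ("prophage", "tRNA", "array", "gene", "other")

#: fixed column order of the TSV feature-table dialect
FEATURE_TSV_COLUMNS = ("seqid", "label", "start", "end", "strand", "kind")


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the pipeline's input contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FeatureRegion:
    """A labelled genomic interval, 0-based half-open."""

    label: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"
    seqid: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.label!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.label!r}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.label!r}: unknown kind {self.kind!r}")

    def overlaps(self, start: int, end: int) -> bool:
        """Any-overlap test (>=1 shared base) against another half-open interval."""
        return self.start < end and start < self.end

    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A replicon (chromosome, plasmid or phage genome) plus optional features."""

    id: str
    sequence: str
    description: str = ""
    features: list[FeatureRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: illegal character(s) {sorted(bad)!r}"
            )
        for feat in self.features:
            if feat.end > len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: feature {feat.label!r} exceeds sequence length"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Upper-case, map U->T, and reject characters outside {A,C,G,T,N}."""
    seq = str(raw).upper().replace("U", "T")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise FastaFormatError(
            f"record {record_id!r}: illegal character(s) {sorted(bad)!r}"
        )
    return seq


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file of DNA into GenomeRecords.

    Sequences are upper-cased and U is mapped to T.  An empty file,
    duplicate ids, or characters outside {A,C,G,T,N} raise
    :class:`FastaFormatError` naming the offending record.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(GenomeRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else (
                f"{rec.id} {rec.description}"
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_spacer_fasta(spacers, path: str | Path) -> None:
    """Write spacers as FASTA with SP_<locusTag>_<index> headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for sp in spacers:
            fh.write(f">{sp.name}\n{sp.sequence}\n")


def write_feature_table(
    regions: Iterable[FeatureRegion], path: str | Path, format: str = "tsv"
) -> None:
    """Serialize feature regions as GFF3 (1-based inclusive) or TSV (0-based half-open).

    The TSV dialect round-trips exactly through :func:`read_feature_table`.
    """
    regions = list(regions)
    path = Path(path)
    if format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in regions:
                attrs = f"ID={r.label};kind={r.kind}"
                fh.write(
                    "\t".join(
                        [
                            r.seqid or ".",
                            "crisprtrace",
                            _gff3_type(r.kind),
                            str(r.start + 1),
                            str(r.end),
                            ".",
                            r.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
    elif format == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(FEATURE_TSV_COLUMNS)
            for r in regions:
                writer.writerow([r.seqid, r.label, r.start, r.end, r.strand, r.kind])
    else:
        raise ValueError(f"unknown feature-table format {format!r}")


def _gff3_type(kind: str) -> str:
    return {
        "prophage": "prophage",
        "tRNA": "tRNA",
        "array": "repeat_region",
        "gene": "gene",
        "other": "region",
    }[kind]


def read_feature_table(path: str | Path) -> list[FeatureRegion]:
    """Read feature regions from the TSV dialect or from GFF3."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff-version"):
        return _read_gff3(path)
    regions: list[FeatureRegion] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(FEATURE_TSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: feature TSV missing column(s) {sorted(missing)}")
        for row in reader:
            regions.append(
                FeatureRegion(
                    seqid=row["seqid"],
                    label=row["label"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    kind=row["kind"],
                )
            )
    return regions


def _read_gff3(path: Path) -> list[FeatureRegion]:
    kind_back = {
        "prophage": "prophage",
        "tRNA": "tRNA",
        "repeat_region": "array",
        "gene": "gene",
        "region": "other",
    }
    regions: list[FeatureRegion] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start1, end1, _score, strand, _phase, attrs = cols
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            regions.append(
                FeatureRegion(
                    seqid="" if seqid == "." else seqid,
                    label=attr_map.get("ID", ftype),
                    start=int(start1) - 1,
                    end=int(end1),
                    strand=strand,
                    kind=attr_map.get("kind", kind_back.get(ftype, "other")),
                )
            )
    return regions


def translate_frame(seq: str) -> str:
    """Translate a DNA string in frame 0 (helper for synthetic proteomes)."""
    return str(Seq(seq).translate())
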