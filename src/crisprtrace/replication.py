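"""Optional replication of the real-genome study numbers.

The published census, protospacer matches, self-targets and typing
patterns were computed on GenBank genomes (three *Oenococcus* host
chromosomes, an MGE database of oenophages and plasmids, and per-category
phage protein sets).  Those sequences are not distributed with this
package; this module runs the full pipeline on a user-supplied copy and
reports the same summary quantities so they can be compared with the
published ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import arrays as _arrays
from . import census as _census
from .matching import MatchParams, hit_distribution, match_spacers
from .phagetyping import (
    CATEGORIES,
    assign_barcode,
    cluster_category,
    pattern_census,
    read_protein_fasta,
)
from .seqio import read_fasta
from .selftarget import find_self_targets


class ReplicationDataMissing(FileNotFoundError):
    """Raised when the user has not supplied the external genome set."""


@dataclass
class ReplicationInputs:
    """Paths to the user-supplied external data.

    hosts: FASTA files of host chromosomes to scan for arrays;
    mge_db: one FASTA of phage + plasmid target genomes;
    protein_dir: directory with <category>.faa files (int.faa, lm.faa, ...).
    """

    hosts: list[Path] = field(default_factory=list)
    mge_db: Path | None = None
    protein_dir: Path | None = None

    @classmethod
    def from_dir(cls, root: str | Path) -> "ReplicationInputs":
        root = Path(root)
        return cls(
            hosts=sorted(root.glob("hosts/*.fasta")) + sorted(root.glob("hosts/*.fa")),
            mge_db=(root / "mge.fasta") if (root / "mge.fasta").exists() else None,
            protein_dir=(root / "proteins") if (root / "proteins").is_dir() else None,
        )


def run_replication(inputs: ReplicationInputs) -> dict:
    """Recompute the study-level summaries on user-supplied genomes.

    Returns a dict with the census totals, the number of spacers with MGE
    matches, per-host self-target counts, the fraction of targets hit,
    and the number of distinct typing patterns (for whichever inputs were
    supplied).  Raises :class:`ReplicationDataMissing` when no usable
    input is present.
    """
    if not inputs.hosts and inputs.protein_dir is None:
        raise ReplicationDataMissing(
            "replication requires the external genome set: place host FASTAs "
            "under hosts/, the MGE database as mge.fasta and per-category "
            "protein FASTAs under proteins/ (none were found)"
        )
    report: dict = {}

    all_arrays = []
    hosts = []
    for path in inputs.hosts:
        for genome in read_fasta(path):
            hosts.append(genome)
            found = _arrays.find_crispr_arrays(genome)
            all_arrays.extend(_arrays.orient_array(a) for a in found)
    if all_arrays:
        rep = _census.census_arrays(all_arrays)
        report["n_arrays"] = len(all_arrays)
        report["total_spacers"] = rep.total_spacers
        report["unique_spacers"] = rep.total_unique

    if all_arrays and inputs.mge_db is not None:
        targets = read_fasta(inputs.mge_db)
        spacers = [sp for a in all_arrays for sp in a.spacers]
        hits = match_spacers(spacers, targets, MatchParams())
        report["spacers_with_mge_match"] = len({h.spacer_ref for h in hits})
        report["target_fraction_with_hit"] = hit_distribution(hits, targets).fraction_with_hit
        sts_total = 0
        for genome in hosts:
            mine = [a for a in all_arrays if a.genome_id == genome.id]
            if mine:
                sts_total += len(find_self_targets(mine, genome))
        report["self_targeting_spacers"] = sts_total

    if inputs.protein_dir is not None:
        assignments = {}
        phages: set[str] = set()
        for cat in CATEGORIES:
            faa = Path(inputs.protein_dir) / f"{cat.lower()}.faa"
            if not faa.exists():
                continue
            seqs = read_protein_fasta(faa, cat)
            assignments[cat] = cluster_category(seqs)
            phages.update(s.phage_id for s in seqs)
        if assignments:
            barcodes = [assign_barcode(p, assignments) for p in sorted(phages)]
            report["typing_patterns"] = pattern_census(barcodes).n_patterns

    if not report:
        raise ReplicationDataMissing(
            "replication inputs were present but empty; nothing to compute"
        )
    return report
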