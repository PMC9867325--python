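"""Seeded simulator of host genomes, MGE databases and phage proteomes
with fully recorded planted ground truth.

Every downstream stage can be scored exactly against the emitted
:class:`SynthTruth`: planted arrays (coordinates, DR, spacer sequences),
planted protospacers (locus, substitution count, strand, PAM), the
prophage with its duplicated att core and self-targeting spacer copies,
and the per-protein family assignment behind the typing barcodes.

One integer seed drives everything; independent sub-streams are derived
per element (background, each array, prophage, each target, each
category) so adding one more target leaves earlier targets byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phagetyping import CATEGORIES, ProteinSeq
from .seqio import FeatureRegion, GenomeRecord, revcomp

_BASES = np.array(list("ACGT"))
_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# Published direct-repeat consensus sequences of the four Oenococcus
# arrays; handy defaults for realistic planted arrays.
DR_KITAHARAE_IIA = "GCTTCAGATGTGTGTCAGATCAATGAGGTAGAACCC"
DR_SICERAE_IIA = "GGGTGTCACCCCATTAATCTGACATACAACTGAAGC"
DR_SICERAE_IE = "AGGATCACCCCCGCTTGTGCGGGGAATAC"
DR_ALCOHOL_IIA = "GCTTCAGATGTGTGTCAGATCAATGAGGTAGAACC"


@dataclass(frozen=True)
class ArraySpec:
    """One planted CRISPR array: a DR repeated n times around unique spacers."""

    dr: str
    n_repeats: int
    spacer_len: int = 32
    repeat_mutations: tuple[int, ...] = ()  # per-repeat substitution counts

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("an array needs at least 2 repeats")
        if self.repeat_mutations and len(self.repeat_mutations) != self.n_repeats:
            raise ValueError("repeat_mutations must list one count per repeat")

    @property
    def total_len(self) -> int:
        return self.n_repeats * len(self.dr) + (self.n_repeats - 1) * self.spacer_len


@dataclass(frozen=True)
class ProtospacerPlant:
    """Plant one spacer copy in a target with an exact substitution count."""

    spacer: int  # 0-based index into the flattened planted spacer list
    target: int  # 0-based target index
    n_substitutions: int = 0
    strand: str = "+"
    pam: str | None = "TTA"  # written 5' of the protospacer in its orientation


@dataclass(frozen=True)
class ProphageSpec:
    length: int = 9000
    att_core_len: int = 16
    sts_spacers: tuple[int, ...] = ()  # flat spacer indices copied into the body
    pam: str | None = "TTA"  # written immediately 5' of every STS copy


@dataclass(frozen=True)
class FamilySpec:
    """Planted protein-family structure for one typing category."""

    n_families: int
    protein_len: int = 200
    within_identity: float = 0.96
    between_identity: float = 0.60
    # per-phage family index (None = phage lacks this protein); empty = round-robin
    assignment: tuple[int | None, ...] = ()


@dataclass(frozen=True)
class SimParams:
    seed: int
    genome_len: int = 60000
    gc: float = 0.40
    arrays: tuple[ArraySpec, ...] = ()
    n_targets: int = 0
    target_len: int = 8000
    protospacer_plants: tuple[ProtospacerPlant, ...] = ()
    prophage: ProphageSpec | None = None
    protein_families: dict[str, FamilySpec] = field(default_factory=dict)
    phage_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        for cat in self.protein_families:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown protein category {cat!r}")


@dataclass
class PlantedArray:
    start: int
    end: int
    dr: str
    repeat_intervals: list[tuple[int, int]]
    spacers: list[tuple[str, int, int]]  # (sequence, start, end)

    @property
    def spacer_sequences(self) -> list[str]:
        return [s for s, _, _ in self.spacers]


@dataclass
class PlantedHit:
    spacer: int
    target_id: str
    start: int
    end: int
    strand: str
    n_substitutions: int
    pam: str | None


@dataclass
class SynthTruth:
    arrays: list[PlantedArray] = field(default_factory=list)
    spacers: list[str] = field(default_factory=list)  # flattened, array-major
    hits: list[PlantedHit] = field(default_factory=list)
    prophage: FeatureRegion | None = None
    att_core: str | None = None
    att_copies: list[tuple[int, int]] = field(default_factory=list)
    sts_spacers: list[int] = field(default_factory=list)
    family_of: dict[str, int | None] = field(default_factory=dict)  # "phage|CAT" -> family
    patterns: dict[str, list[str]] = field(default_factory=dict)  # pattern key -> phages

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=default)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *stream])


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=p))


def mutate_sequence(seq: str, n: int, rng: np.random.Generator, alphabet: str = "ACGT") -> str:
    """Substitute exactly n distinct positions, each to a different symbol.

    The result is at Hamming distance exactly n from the input.
    """
    if n > len(seq):
        raise ValueError(f"cannot place {n} substitutions in a {len(seq)}-mer")
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        choices = [c for c in alphabet if c != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _assemble_array(spec: ArraySpec, rng: np.random.Generator, gc: float):
    """Returns (sequence, repeat offsets, spacer (seq, offset) list) relative to array start."""
    muts = spec.repeat_mutations or (0,) * spec.n_repeats
    parts: list[str] = []
    rep_off: list[int] = []
    spacer_off: list[tuple[str, int]] = []
    pos = 0
    spacers = []
    for i in range(spec.n_repeats - 1):
        while True:
            s = _random_dna(spec.spacer_len, gc, rng)
            if s not in spacers:
                spacers.append(s)
                break
    for i in range(spec.n_repeats):
        rep = mutate_sequence(spec.dr, muts[i], rng)
        rep_off.append(pos)
        parts.append(rep)
        pos += len(rep)
        if i < spec.n_repeats - 1:
            spacer_off.append((spacers[i], pos))
            parts.append(spacers[i])
            pos += spec.spacer_len
    return "".join(parts), rep_off, spacer_off


def _sharpen_boundaries(genome: list[str], planted: list[PlantedArray], rng) -> None:
    """Resample flank columns so each planted repeat boundary is unambiguous.

    If the column immediately outside the repeats happens to be
    near-identical across instances, the true boundary of the planted
    array is genuinely ill-defined; the generator resamples such columns
    so the planted truth is exact by construction.
    """
    for arr in planted:
        n = len(arr.repeat_intervals)
        quorum_allowed = max(1, n // 10)
        for side in ("left", "right"):
            while True:
                idxs = [
                    (s - 1 if side == "left" else e)
                    for s, e in arr.repeat_intervals
                ]
                if any(i < 0 or i >= len(genome) for i in idxs):
                    break
                # skip columns inside neighbouring repeats of the same array
                cols = [genome[i] for i in idxs]
                counts = {}
                for c in cols:
                    counts[c] = counts.get(c, 0) + 1
                top_char, top = max(counts.items(), key=lambda kv: kv[1])
                if n - top > quorum_allowed:
                    break
                # resample one majority-holding mutable column
                for i in idxs:
                    if genome[i] == top_char:
                        choices = [c for c in "ACGT" if c != top_char]
                        genome[i] = choices[int(rng.integers(3))]
                        break


def simulate_host(params: SimParams) -> tuple[GenomeRecord, SynthTruth]:
    """Build a host chromosome with planted arrays and an optional prophage.

    The prophage sits between two exact copies of a random att core at
    the 3' end of a marked tRNA feature and carries exact copies of the
    designated self-targeting spacers.  Same seed, same bytes.
    """
    truth = SynthTruth()
    elements: list[tuple[str, object]] = [("array", a) for a in params.arrays]
    if params.prophage is not None:
        elements.append(("prophage", params.prophage))

    el_lens = []
    for kind, spec in elements:
        if kind == "array":
            el_lens.append(spec.total_len)
        else:
            el_lens.append(spec.length + 2 * spec.att_core_len)
    n_el = len(elements)
    gap = (params.genome_len - sum(el_lens)) // (n_el + 1) if n_el else params.genome_len
    if n_el and gap < 600:
        raise ValueError(
            f"infeasible packing: {sum(el_lens)} nt of planted elements in a "
            f"{params.genome_len} nt genome leaves gaps of only {gap} nt"
        )

    bg_rng = _rng(params.seed, 0)
    chunks: list[str] = []
    pos = 0
    for i, (kind, spec) in enumerate(elements):
        chunks.append(_random_dna(gap, params.gc, bg_rng))
        pos += gap
        if kind == "array":
            arr_rng = _rng(params.seed, 1, i)
            seq, rep_off, spacer_off = _assemble_array(spec, arr_rng, params.gc)
            truth.arrays.append(
                PlantedArray(
                    start=pos,
                    end=pos + len(seq),
                    dr=spec.dr,
                    repeat_intervals=[
                        (pos + o, pos + o + len(spec.dr)) for o in rep_off
                    ],
                    spacers=[
                        (s, pos + o, pos + o + len(s)) for s, o in spacer_off
                    ],
                )
            )
            chunks.append(seq)
            pos += len(seq)
        else:
            ph_rng = _rng(params.seed, 2)
            core = _random_dna(spec.att_core_len, params.gc, ph_rng)
            flat = [s for a in truth.arrays for s in a.spacer_sequences]
            body_len = spec.length
            body = list(_random_dna(body_len, params.gc, ph_rng))
            # drop STS copies at evenly spread, non-overlapping offsets
            n_sts = len(spec.sts_spacers)
            sts_meta = []
            if n_sts:
                slot = body_len // (n_sts + 1)
                pam = spec.pam or ""
                for k, sp_idx in enumerate(spec.sts_spacers, start=1):
                    if sp_idx >= len(flat):
                        raise ValueError(
                            f"sts spacer index {sp_idx} out of range (have {len(flat)})"
                        )
                    sp_seq = flat[sp_idx]
                    off = slot * k
                    body[off - len(pam) : off] = list(pam)
                    body[off : off + len(sp_seq)] = list(sp_seq)
                    sts_meta.append((sp_idx, off))
            body_str = "".join(body)
            seq = core + body_str + core
            truth.att_core = core
            truth.att_copies = [
                (pos, pos + len(core)),
                (pos + len(core) + body_len, pos + 2 * len(core) + body_len),
            ]
            truth.prophage = FeatureRegion(
                label="prophage_1",
                start=pos,
                end=pos + len(seq),
                kind="prophage",
            )
            for sp_idx, off in sts_meta:
                truth.sts_spacers.append(sp_idx)
                truth.hits.append(
                    PlantedHit(
                        spacer=sp_idx,
                        target_id="host",
                        start=pos + len(core) + off,
                        end=pos + len(core) + off + len(flat[sp_idx]),
                        strand="+",
                        n_substitutions=0,
                        pam=spec.pam,
                    )
                )
            chunks.append(seq)
            pos += len(seq)
    chunks.append(_random_dna(params.genome_len - pos, params.gc, bg_rng))

    genome_chars = list("".join(chunks))
    _sharpen_boundaries(genome_chars, truth.arrays, _rng(params.seed, 5))
    # write back possibly-resampled spacer sequences into the truth ...
    for arr in truth.arrays:
        arr.spacers = [
            ("".join(genome_chars[s:e]), s, e) for _, s, e in arr.spacers
        ]
    truth.spacers = [s for a in truth.arrays for s in a.spacer_sequences]
    # ... and refresh the prophage STS copies so they stay exact copies
    for h in truth.hits:
        genome_chars[h.start : h.end] = list(truth.spacers[h.spacer])
    if truth.att_copies:
        # make sure the duplicated att core cannot be extended by chance
        # agreement of its neighbouring bases, so the planted core is the
        # unique longest boundary repeat
        (l_s, l_e), (r_s, r_e) = truth.att_copies
        fix_rng = _rng(params.seed, 7)
        for a, b in ((l_s - 1, r_s - 1), (l_e, r_e)):
            while 0 <= a and b < len(genome_chars) and genome_chars[a] == genome_chars[b]:
                genome_chars[b] = "ACGT"[int(fix_rng.integers(4))]
    genome_str = "".join(genome_chars)

    features = []
    if truth.prophage is not None:
        features.append(truth.prophage)
        t_end = truth.prophage.start
        features.append(
            FeatureRegion(label="tRNA-Leu", start=t_end - 80, end=t_end, kind="tRNA")
        )
    host = GenomeRecord(
        id="host",
        sequence=genome_str,
        description="synthetic host chromosome",
        features=[dataclasses.replace(f, seqid="host") for f in features],
    )
    return host, truth


def simulate_phage_db(
    params: SimParams, spacers: list[str] | None = None
) -> tuple[list[GenomeRecord], dict[str, list[ProteinSeq]], SynthTruth]:
    """Build the target MGE database and per-category proteomes.

    `spacers` is the flattened planted spacer list from
    :func:`simulate_host`; when omitted the host is simulated internally
    from the same params.  Each protospacer plant is a spacer copy at an
    exact Hamming distance, preceded (in protospacer orientation) by its
    PAM; protein families are planted by mutating family ancestors to the
    stated within/between identities.
    """
    truth = SynthTruth()
    if spacers is None:
        _, host_truth = simulate_host(params)
        spacers = host_truth.spacers
    truth.spacers = list(spacers)

    plants_by_target: dict[int, list[ProtospacerPlant]] = {}
    for plant in params.protospacer_plants:
        if plant.target >= params.n_targets:
            raise ValueError(f"plant target {plant.target} out of range")
        if plant.spacer >= len(spacers):
            raise ValueError(f"plant spacer {plant.spacer} out of range")
        if plant.n_substitutions > len(spacers[plant.spacer]):
            raise ValueError("n_substitutions exceeds spacer length")
        plants_by_target.setdefault(plant.target, []).append(plant)

    targets: list[GenomeRecord] = []
    for t in range(params.n_targets):
        rng = _rng(params.seed, 3, t)
        seq = list(_random_dna(params.target_len, params.gc, rng))
        used: list[tuple[int, int]] = []
        for plant in plants_by_target.get(t, []):
            sp = spacers[plant.spacer]
            pam = plant.pam or ""
            unit_len = len(sp) + len(pam)
            margin = 20
            for _attempt in range(200):
                off = int(rng.integers(margin, params.target_len - unit_len - margin))
                if all(off + unit_len + 5 <= s or e + 5 <= off for s, e in used):
                    break
            else:
                raise ValueError(f"cannot place plant {plant} in target {t}")
            used.append((off, off + unit_len))
            proto = mutate_sequence(sp, plant.n_substitutions, rng)
            if plant.strand == "+":
                seq[off : off + unit_len] = list(pam + proto)
                start = off + len(pam)
            else:
                seq[off : off + unit_len] = list(revcomp(pam + proto))
                start = off
            truth.hits.append(
                PlantedHit(
                    spacer=plant.spacer,
                    target_id=f"phage_{t + 1}",
                    start=start,
                    end=start + len(sp),
                    strand=plant.strand,
                    n_substitutions=plant.n_substitutions,
                    pam=plant.pam,
                )
            )
        targets.append(
            GenomeRecord(
                id=f"phage_{t + 1}",
                sequence="".join(seq),
                description="synthetic MGE target",
            )
        )

    proteins = simulate_proteomes(params, truth)
    return targets, proteins, truth


def simulate_proteomes(
    params: SimParams, truth: SynthTruth | None = None
) -> dict[str, list[ProteinSeq]]:
    """Planted protein families per typing category.

    Family ancestors diverge from a category root so that between-family
    identity sits near the configured level; members are each a bounded
    number of substitutions from their ancestor, guaranteeing pairwise
    within-family identity >= within_identity.
    """
    truth = truth if truth is not None else SynthTruth()
    out: dict[str, list[ProteinSeq]] = {}
    phage_ids = list(params.phage_ids)
    for c, cat in enumerate(CATEGORIES):
        fam = params.protein_families.get(cat)
        if fam is None:
            continue
        rng = _rng(params.seed, 4, c)
        L = fam.protein_len
        root = "".join(rng.choice(_AA20, size=L))
        k_between = int(round((1.0 - fam.between_identity) * L))
        ancestors = [
            mutate_sequence(root, k_between, rng, alphabet="".join(_AA20))
            for _ in range(fam.n_families)
        ]
        k_within = int((1.0 - fam.within_identity) / 2 * L)
        assignment = fam.assignment or tuple(
            i % fam.n_families for i in range(len(phage_ids))
        )
        if len(assignment) != len(phage_ids):
            raise ValueError(
                f"{cat}: assignment length {len(assignment)} != {len(phage_ids)} phages"
            )
        seqs: list[ProteinSeq] = []
        for pid, fam_idx in zip(phage_ids, assignment):
            truth.family_of[f"{pid}|{cat}"] = fam_idx
            if fam_idx is None:
                continue
            protein = mutate_sequence(
                ancestors[fam_idx], int(rng.integers(0, k_within + 1)),
                rng, alphabet="".join(_AA20),
            )
            seqs.append(ProteinSeq(phage_id=pid, category=cat, sequence=protein))
        out[cat] = seqs
    if truth is not None and phage_ids:
        patterns: dict[str, list[str]] = {}
        for pid in phage_ids:
            key = "|".join(
                str(truth.family_of.get(f"{pid}|{cat}", None))
                for cat in CATEGORIES
            )
            patterns.setdefault(key, []).append(pid)
        truth.patterns = patterns
    return out


def interaction_panel_params(
    seed: int,
    n_targets: int = 34,
    n_with_hit: int = 22,
    spacer_len: int = 32,
) -> SimParams:
    """A host-vs-MGE scenario at the scale of a real oenophage panel.

    One deep type I-E-like array (31 repeats), a 9 kb prophage carrying
    five self-targeting spacer copies, and n_targets MGE genomes of which
    n_with_hit carry one detectable protospacer (0-4 substitutions on a
    32-nt spacer, shared upstream PAM "TTA", both strands used).  One
    additional target carries only an over-threshold plant (5
    substitutions) and must stay hit-free.
    """
    n_spacers = 30
    plants = []
    for t in range(n_with_hit):
        plants.append(
            ProtospacerPlant(
                spacer=t % (n_spacers - 8),
                target=t,
                n_substitutions=t % 5,
                strand="+" if t % 2 == 0 else "-",
                pam="TTA",
            )
        )
    # the decoy: 5 substitutions breach the 85% identity rule on a 32-mer
    plants.append(
        ProtospacerPlant(
            spacer=n_spacers - 1, target=n_with_hit, n_substitutions=5,
            strand="+", pam="TTA",
        )
    )
    return SimParams(
        seed=seed,
        genome_len=60_000,
        arrays=(ArraySpec(dr=DR_SICERAE_IE, n_repeats=n_spacers + 1, spacer_len=spacer_len),),
        prophage=ProphageSpec(length=9000, att_core_len=16, sts_spacers=(22, 24, 25, 27, 29)),
        n_targets=n_targets,
        target_len=8000,
        protospacer_plants=tuple(plants),
    )


def typing_panel_params(
    n_phages: int = 193, n_patterns: int = 27, seed: int = 0, protein_len: int = 120
) -> SimParams:
    """SimParams describing a phage panel falling into exactly n_patterns barcodes.

    Category class counts mirror a realistic temperate-phage collection:
    6 integrase types (strictly lytic phages lack one), 6 LM, 5 Rep,
    7 TerS and 7 TMP classes, and an occasional Doc toxin.
    """
    rng = _rng(seed, 6)
    n_classes = {"INT": 6, "LM": 6, "REP": 5, "TERS": 7, "TMP": 7}
    patterns: list[tuple] = []
    seen = set()
    while len(patterns) < n_patterns:
        pat = tuple(
            (None if (cat == "INT" and rng.random() < 0.15)
             else int(rng.integers(n_classes[cat])))
            for cat in ("INT", "LM", "REP", "TERS", "TMP")
        ) + (bool(rng.random() < 0.25),)
        if pat not in seen:
            seen.add(pat)
            patterns.append(pat)
    # every pattern gets one phage; the rest are spread at random
    alloc = [1] * n_patterns
    for _ in range(n_phages - n_patterns):
        alloc[int(rng.integers(n_patterns))] += 1
    phage_ids = []
    assignment: dict[str, list[int | None]] = {
        cat: [] for cat in ("INT", "LM", "REP", "TERS", "TMP", "DOC")
    }
    i = 0
    for pat, count in zip(patterns, alloc):
        for _ in range(count):
            i += 1
            phage_ids.append(f"phi{i:03d}")
            for j, cat in enumerate(("INT", "LM", "REP", "TERS", "TMP")):
                assignment[cat].append(pat[j])
            assignment["DOC"].append(0 if pat[5] else None)
    families = {
        cat: FamilySpec(
            n_families=n_classes[cat],
            protein_len=protein_len,
            assignment=tuple(assignment[cat]),
        )
        for cat in ("INT", "LM", "REP", "TERS", "TMP")
    }
    families["DOC"] = FamilySpec(
        n_families=1, protein_len=protein_len, assignment=tuple(assignment["DOC"])
    )
    return SimParams(
        seed=seed, protein_families=families, phage_ids=tuple(phage_ids)
    )
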