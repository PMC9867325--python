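"""Shared fixtures: published direct-repeat consensus sequences and helpers
to build arrays and simulated scenarios programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from crisprtrace import ArraySpec, CrisprArray, ProphageSpec, ProtospacerPlant, SimParams, Spacer

from crisprtrace import (  # noqa: F401  (re-exported for the test modules)
    DR_ALCOHOL_IIA,
    DR_KITAHARAE_IIA,
    DR_SICERAE_IE,
    DR_SICERAE_IIA,
)

ATT_CORE_16 = "ACTCCTGTTCGGGGCA"


def make_array(tag: str, spacer_seqs: list[str], dr: str = DR_SICERAE_IE) -> CrisprArray:
    """Assemble a CrisprArray object directly from spacer sequences."""
    repeats = []
    spacers = []
    pos = 0
    for i, seq in enumerate(spacer_seqs):
        repeats.append((pos, pos + len(dr), dr))
        pos += len(dr)
        spacers.append(
            Spacer(array_ref=tag, index=i + 1, sequence=seq, start=pos, end=pos + len(seq))
        )
        pos += len(seq)
    repeats.append((pos, pos + len(dr), dr))
    pos += len(dr)
    return CrisprArray(
        genome_id="g",
        locus_tag=tag,
        start=0,
        end=pos,
        dr_consensus=dr,
        repeats=repeats,
        spacers=spacers,
    )


def random_spacers(n: int, length: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        s = "".join(rng.choice(list("ACGT"), size=length))
        if s not in out:
            out.append(s)
    return out


@pytest.fixture
def standard_sim_params() -> SimParams:
    """Two planted arrays, a prophage carrying 5 STS copies, 6 MGE targets."""
    return SimParams(
        seed=11,
        genome_len=60000,
        arrays=(
            ArraySpec(dr=DR_KITAHARAE_IIA, n_repeats=12, spacer_len=30),
            ArraySpec(dr=DR_SICERAE_IE, n_repeats=14, spacer_len=32),
        ),
        prophage=ProphageSpec(length=9000, att_core_len=16, sts_spacers=(12, 14, 16, 18, 20)),
        n_targets=6,
        protospacer_plants=(
            ProtospacerPlant(spacer=11, target=0, n_substitutions=0, strand="+"),
            ProtospacerPlant(spacer=13, target=1, n_substitutions=2, strand="-"),
            ProtospacerPlant(spacer=15, target=2, n_substitutions=4, strand="+"),
        ),
    )
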