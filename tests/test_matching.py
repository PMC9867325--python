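"""Protospacer matching, PAM inference, recency classes, hit distribution."""

import math

import numpy as np
import pytest

from crisprtrace import (
    GenomeRecord,
    MatchParams,
    ProtospacerHit,
    Spacer,
    classify_recency,
    hit_distribution,
    infer_pam,
    match_spacers,
    revcomp,
)

from .conftest import make_array, random_spacers


def mk_spacer(seq, name="S", idx=1):
    return Spacer(array_ref=name, index=idx, sequence=seq, start=0, end=len(seq))


def plant(target_seq, pos, insert):
    return target_seq[:pos] + insert + target_seq[pos + len(insert) :]


def rand_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(seq, positions, seed=0):
    rng = np.random.default_rng(seed)
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def hamming_oracle(spacer, targets, params):
    """Exhaustive two-strand full-length sliding scan; the independent reference."""
    L = len(spacer.sequence)
    max_d = int(math.floor((1 - params.min_identity) * L + 1e-9))
    found = []
    for t in targets:
        for strand in "+-":
            pat = spacer.sequence if strand == "+" else revcomp(spacer.sequence)
            for off in range(len(t.sequence) - L + 1):
                d = sum(a != b for a, b in zip(t.sequence[off : off + L], pat))
                if d <= max_d:
                    found.append((t.id, strand, off, d))
    return sorted(found)


class TestMatchSpacers:
    def test_exact_substring_hit(self):
        sp = mk_spacer(rand_dna(32, 1))
        t = GenomeRecord(id="t", sequence=plant(rand_dna(2000, 2), 700, sp.sequence))
        (hit,) = match_spacers([sp], [t])
        assert hit.identity == 1.0
        assert hit.query_coverage == 1.0
        assert hit.n_mismatch == 0
        assert (hit.target_start, hit.target_end) == (700, 732)

    def test_four_substitutions_accepted_five_rejected(self):
        base = rand_dna(32, 3)
        sp = mk_spacer(base)
        bg = rand_dna(3000, 4)
        t4 = GenomeRecord(id="t4", sequence=plant(bg, 800, mutate(base, [0, 7, 15, 31])))
        t5 = GenomeRecord(
            id="t5", sequence=plant(bg, 800, mutate(base, [0, 7, 15, 22, 31]))
        )
        hits4 = match_spacers([sp], [t4])
        assert len(hits4) == 1
        assert hits4[0].identity == pytest.approx(28 / 32)
        assert match_spacers([sp], [t5]) == []

    def test_reverse_complement_plant(self):
        base = rand_dna(30, 5)
        bg = rand_dna(2000, 6)
        t = GenomeRecord(id="t", sequence=plant(bg, 500, revcomp(base)))
        (hit,) = match_spacers([mk_spacer(base)], [t])
        assert hit.strand == "-"
        assert (hit.target_start, hit.target_end) == (500, 530)
        # upstream flank in protospacer orientation = RC of bases 3' of the plant
        assert hit.upstream_flank == revcomp(t.sequence[530:540])
        assert hit.downstream_flank == revcomp(t.sequence[490:500])

    def test_matches_exhaustive_hamming_oracle(self):
        params = MatchParams()
        rng = np.random.default_rng(8)
        for trial in range(5):
            base = rand_dna(32, 100 + trial)
            bg = rand_dna(5000, 200 + trial)
            # several plants at varying distances, both strands
            bg = plant(bg, 300, mutate(base, [1, 5]))
            bg = plant(bg, 1500, revcomp(mutate(base, [2, 9, 17], seed=1)))
            bg = plant(bg, 2500, base)
            bg = plant(bg, 4000, mutate(base, [0, 8, 16, 24, 30]))  # below threshold
            t = GenomeRecord(id=f"t{trial}", sequence=bg)
            sp = mk_spacer(base)
            got = sorted(
                (h.target_id, h.strand, h.target_start, h.n_mismatch)
                for h in match_spacers([sp], [t], params)
            )
            assert got == hamming_oracle(sp, [t], params)

    def test_threshold_algebra_exhaustive(self):
        """Full-coverage ungapped hits accept exactly n_mismatch <= floor(0.15 L)."""
        params = MatchParams()
        for L in range(20, 61):
            k = params.max_substitutions(L)
            assert (L - k) / L >= 0.85
            assert (L - (k + 1)) / L < 0.85

    def test_strand_symmetry_of_matching(self):
        base = rand_dna(32, 9)
        bg = plant(rand_dna(3000, 10), 1200, mutate(base, [3, 11]))
        t_fwd = GenomeRecord(id="t", sequence=bg)
        t_rc = GenomeRecord(id="t", sequence=revcomp(bg))
        h_fwd = match_spacers([mk_spacer(base)], [t_fwd])
        h_rc = match_spacers([mk_spacer(base)], [t_rc])
        assert len(h_fwd) == len(h_rc) == 1
        assert h_fwd[0].strand != h_rc[0].strand
        assert h_fwd[0].n_mismatch == h_rc[0].n_mismatch
        assert h_rc[0].target_start == len(bg) - h_fwd[0].target_end

    def test_n_containing_spacer_skipped_with_warning(self, caplog):
        spacers = [mk_spacer("ACGTN" + rand_dna(27, 11))]
        t = GenomeRecord(id="t", sequence=rand_dna(500, 12))
        with caplog.at_level("WARNING"):
            assert match_spacers(spacers, [t]) == []
        assert "contains N" in caplog.text

    def test_flank_padding_at_contig_edge(self):
        base = rand_dna(30, 13)
        t = GenomeRecord(id="t", sequence=base + rand_dna(100, 14))
        (hit,) = match_spacers([mk_spacer(base)], [t])
        assert hit.upstream_flank == "." * 10

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            match_spacers([mk_spacer(rand_dna(30, 15))], [])

    def test_gapped_hit_needs_opt_in(self):
        base = rand_dna(40, 16)
        deleted = base[:20] + base[21:]  # one deletion inside the protospacer
        t = GenomeRecord(id="t", sequence=plant(rand_dna(2000, 17), 900, deleted))
        sp = mk_spacer(base)
        assert match_spacers([sp], [t]) == []
        (hit,) = match_spacers([sp], [t], MatchParams(allow_gaps=True))
        assert hit.n_gap == 1
        assert hit.n_mismatch == 0
        assert hit.aligned_len == 40
        assert hit.identity == pytest.approx(39 / 40)


class TestInferPam:
    def hit_with_flank(self, up, down="GGGGGGGGGG", ref="S"):
        return ProtospacerHit(
            spacer_ref=ref, spacer_len=32, target_id="t", target_start=0,
            target_end=32, strand="+", aligned_len=32, n_match=32, n_mismatch=0,
            n_gap=0, upstream_flank=up, downstream_flank=down,
        )

    def test_five_identical_upstream_trimers(self):
        hits = [self.hit_with_flank("GCAGCAGTTA", ref=f"S{i}") for i in range(5)]
        res = infer_pam(hits, side="upstream", k=3)
        assert res.motif == "TTA"
        assert res.support == 5

    def test_single_hit(self):
        res = infer_pam([self.hit_with_flank("AAAAAAAGGC")], side="upstream", k=3)
        assert res.motif == "GGC"
        assert res.support == 1

    def test_agreement_boundary_three_of_four(self):
        ups = ["AAAAAAATTA"] * 3 + ["AAAAAAATTG"]
        res = infer_pam(
            [self.hit_with_flank(u, ref=f"S{i}") for i, u in enumerate(ups)],
            side="upstream", k=3, agreement=0.75,
        )
        assert res.motif == "TTA"

    def test_unresolved_positions_truncate_motif(self):
        ups = ["AAAAAAACTA", "AAAAAAAGTA", "AAAAAAATTA", "AAAAAAAATA"]
        res = infer_pam(
            [self.hit_with_flank(u, ref=f"S{i}") for i, u in enumerate(ups)],
            side="upstream", k=3,
        )
        assert res.motif == "TA"  # position -3 disagrees; adjacent run is TA

    def test_dot_padded_flanks_excluded(self):
        hits = [self.hit_with_flank("." * 10), self.hit_with_flank("AAAAAAATTA")]
        res = infer_pam(hits, side="upstream", k=3)
        assert res.support == 1

    def test_no_usable_hits_gives_empty_marker(self):
        res = infer_pam([self.hit_with_flank("." * 10)], side="upstream", k=3)
        assert res.empty
        assert res.motif == ""

    def test_downstream_side(self):
        res = infer_pam([self.hit_with_flank("A" * 10, down="CATGGGGGGG")], side="downstream", k=3)
        assert res.motif == "CAT"


class TestClassifyRecency:
    def test_published_position_classes(self):
        cases = [
            (57, 2, "leader_proximal"),
            (57, 9, "leader_proximal"),
            (57, 15, "middle"),
            (23, 1, "leader_proximal"),
            (102, 5, "leader_proximal"),
            (102, 7, "leader_proximal"),
            (102, 43, "middle"),
            (102, 46, "middle"),
            (102, 78, "leader_distal"),
            (102, 89, "leader_distal"),
        ]
        for n, idx, expected in cases:
            arr = make_array("t", random_spacers(n, 30, n))
            (rc,) = classify_recency(arr, [idx])
            assert rc.label == expected, (n, idx)

    def test_single_spacer_array_is_proximal(self):
        arr = make_array("t", random_spacers(1, 30, 40))
        (rc,) = classify_recency(arr)
        assert rc.p == 0.0
        assert rc.label == "leader_proximal"

    def test_out_of_range_index_rejected(self):
        arr = make_array("t", random_spacers(5, 30, 41))
        with pytest.raises(ValueError):
            classify_recency(arr, [6])


class TestHitDistribution:
    def targets(self, n):
        return [GenomeRecord(id=f"t{i}", sequence=rand_dna(300, 50 + i)) for i in range(n)]

    def test_no_hits(self):
        dist = hit_distribution([], self.targets(3))
        assert dist.fraction_with_hit == 0.0
        assert (dist.table.n_hits == 0).all()

    def test_fraction_22_of_34(self):
        targets = self.targets(34)
        hits = []
        for i in range(22):
            hits.append(
                ProtospacerHit(
                    spacer_ref="S1", spacer_len=30, target_id=f"t{i}", target_start=0,
                    target_end=30, strand="+", aligned_len=30, n_match=30,
                    n_mismatch=0, n_gap=0, upstream_flank="A" * 10, downstream_flank="A" * 10,
                )
            )
        dist = hit_distribution(hits, targets)
        assert dist.fraction_with_hit == pytest.approx(22 / 34)

    def test_one_spacer_two_targets_counted_once_each(self):
        targets = self.targets(2)
        mk = lambda t: ProtospacerHit(
            spacer_ref="S1", spacer_len=30, target_id=t, target_start=0,
            target_end=30, strand="+", aligned_len=30, n_match=28, n_mismatch=2,
            n_gap=0, upstream_flank="A" * 10, downstream_flank="A" * 10,
        )
        dist = hit_distribution([mk("t0"), mk("t1")], targets)
        assert list(dist.table.n_distinct_spacers) == [1, 1]
        assert dist.fraction_with_hit == 1.0
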