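"""Protein clustering, barcodes and pattern census."""

import numpy as np
import pytest

from crisprtrace import (
    FamilySpec,
    ProteinSeq,
    SimParams,
    assign_barcode,
    cluster_category,
    pattern_census,
    simulate_proteomes,
    typing_panel_params,
)
from crisprtrace.phagetyping import global_identity


def rand_protein(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


def protein(pid, cat, seq):
    return ProteinSeq(phage_id=pid, category=cat, sequence=seq)


class TestClusterCategory:
    def test_identical_proteins_one_class(self):
        seq = rand_protein(150, 1)
        classes = cluster_category([protein(f"p{i}", "TMP", seq) for i in range(3)])
        assert len(classes) == 1
        assert sorted(classes[0].member_phage_ids) == ["p0", "p1", "p2"]

    def test_pair_below_threshold_two_classes(self):
        a = rand_protein(100, 2)
        # mutate 15 positions -> ~85% identity, below the >90% rule
        rng = np.random.default_rng(3)
        b = list(a)
        for p in rng.choice(100, size=15, replace=False):
            b[p] = "W" if b[p] != "W" else "Y"
        b = "".join(b)
        assert global_identity(a, b) < 0.90
        classes = cluster_category([protein("p1", "INT", a), protein("p2", "INT", b)])
        assert len(classes) == 2

    def test_seven_planted_families_give_seven_classes(self):
        params = SimParams(
            seed=7,
            protein_families={
                "TMP": FamilySpec(n_families=7, protein_len=180, within_identity=0.95,
                                  between_identity=0.60)
            },
            phage_ids=tuple(f"p{i:02d}" for i in range(28)),
        )
        proteins = simulate_proteomes(params)
        classes = cluster_category(proteins["TMP"])
        assert len(classes) == 7
        assert sum(len(c.member_phage_ids) for c in classes) == 28

    def test_greedy_centroid_property(self):
        """Every member exceeds threshold to its centroid; no member fits an earlier one."""
        params = SimParams(
            seed=8,
            protein_families={
                "TERS": FamilySpec(n_families=5, protein_len=120, between_identity=0.55)
            },
            phage_ids=tuple(f"p{i:02d}" for i in range(40)),
        )
        seqs = simulate_proteomes(params)["TERS"]
        by_id = {s.phage_id: s for s in seqs}
        classes = cluster_category(seqs, threshold=0.90)
        # reconstruct centroid creation order (greedy processing order)
        ordered = sorted(seqs, key=lambda s: (-len(s.sequence), s.seq_id))
        creation = []
        for s in ordered:
            if any(s.seq_id == c.centroid_id for c in classes):
                creation.append(next(c for c in classes if c.centroid_id == s.seq_id))
        for c in classes:
            for pid in c.member_phage_ids:
                assert global_identity(by_id[pid].sequence, c.centroid_sequence) > 0.90 \
                    or by_id[pid].seq_id == c.centroid_id
        for c_idx, c in enumerate(creation):
            for pid in c.member_phage_ids:
                if by_id[pid].seq_id == c.centroid_id:
                    continue
                for earlier in creation[:c_idx]:
                    assert global_identity(by_id[pid].sequence, earlier.centroid_sequence) <= 0.90

    def test_mixed_categories_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            cluster_category(
                [protein("p1", "TMP", rand_protein(100, 4)),
                 protein("p2", "INT", rand_protein(100, 5))]
            )

    def test_labels_numbered_by_descending_size(self):
        big = rand_protein(100, 6)
        small = rand_protein(100, 7)
        seqs = [protein(f"a{i}", "LM", big) for i in range(3)] + [protein("z9", "LM", small)]
        classes = cluster_category(seqs)
        assert classes[0].class_label == "LM1"
        assert len(classes[0].member_phage_ids) == 3
        assert classes[1].class_label == "LM2"


class TestBarcodes:
    def assignments(self):
        mk = lambda cat, label, members: __import__("crisprtrace").ClassAssignment(
            category=cat, class_label=label, member_phage_ids=members,
            centroid_id=f"{members[0]}|{cat}", centroid_sequence="A" * 40,
        )
        return {
            "INT": [mk("INT", "IntA", ["phi1", "phi2"])],
            "LM": [mk("LM", "LM1", ["phi1", "phi2", "phi3"])],
            "REP": [mk("REP", "Rep1", ["phi1", "phi3"])],
            "TERS": [mk("TERS", "TerS2", ["phi1"])],
            "TMP": [mk("TMP", "TMP1", ["phi1", "phi3"])],
            "DOC": [mk("DOC", "Doc1", ["phi3"])],
        }

    def test_full_barcode_string(self):
        b = assign_barcode("phi1", self.assignments())
        assert str(b) == "IntA|LM1|Rep1|TerS2|TMP1|Doc-"

    def test_missing_integrase_absent_slot(self):
        b = assign_barcode("phi3", self.assignments())
        assert b.int_type is None
        assert str(b).startswith("Int-|")
        assert str(b).endswith("|Doc+")

    def test_identical_memberships_identical_strings(self):
        a = self.assignments()
        assert str(assign_barcode("phi1", a)) == str(assign_barcode("phi1", a))

    def test_two_proteins_one_category_rejected(self):
        a = self.assignments()
        a["TMP"][0].member_phage_ids.append("phi1")
        with pytest.raises(ValueError, match="phi1"):
            assign_barcode("phi1", a)


class TestPatternCensus:
    def barcodes(self, pairs):
        import crisprtrace as ct

        return [
            ct.Barcode(phage_id=p, int_type=t, lm="LM1", rep="Rep1", ters="TerS1",
                       tmp="TMP1", doc_present=False)
            for p, t in pairs
        ]

    def test_all_same_one_pattern(self):
        cens = pattern_census(self.barcodes([(f"p{i}", "IntA") for i in range(10)]))
        assert cens.n_patterns == 1
        assert list(cens.representatives.values()) == ["p0"]

    def test_permutation_invariance(self):
        pairs = [("p3", "IntA"), ("p1", "IntB"), ("p2", "IntA")]
        a = pattern_census(self.barcodes(pairs))
        b = pattern_census(self.barcodes(pairs[::-1]))
        assert a.patterns == b.patterns
        assert a.representatives == b.representatives

    def test_monotone_in_phages(self):
        pairs = [("p1", "IntA"), ("p2", "IntB"), ("p3", "IntA"), ("p4", "IntC")]
        counts = [
            pattern_census(self.barcodes(pairs[:k])).n_patterns
            for k in range(1, len(pairs) + 1)
        ]
        assert counts == sorted(counts)

    def test_panel_of_193_phages_27_patterns(self):
        params = typing_panel_params(n_phages=193, n_patterns=27, seed=2)
        proteins = simulate_proteomes(params)
        assignments = {cat: cluster_category(seqs) for cat, seqs in proteins.items()}
        barcodes = [assign_barcode(p, assignments) for p in params.phage_ids]
        cens = pattern_census(barcodes)
        assert cens.n_patterns == 27
        assert sum(len(v) for v in cens.patterns.values()) == 193


class TestProteinSeq:
    def test_short_protein_rejected(self):
        with pytest.raises(ValueError, match="30"):
            ProteinSeq(phage_id="p", category="TMP", sequence="MKV")

    def test_illegal_residue_rejected(self):
        with pytest.raises(ValueError):
            ProteinSeq(phage_id="p", category="TMP", sequence="M*" + "A" * 40)
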