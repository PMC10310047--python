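"""NSAF arithmetic, greedy filtering, and the two-pass ranking."""

import numpy as np
import pytest

from support import oracle_two_pass_retained, random_counts_instance
from tagsieve.abundance_ranking import (
    compute_abundance, greedy_filter, joint_rank, organism_marginals,
    rank_by_protein, run_two_pass,
)
from tagsieve.sequence_db import ProteinRecord
from tagsieve.tag_store import SpectrumKey


def make_counts(spec):
    """{'A': {'s1': ['x','y']}} → SpectralCounts."""
    return {acc: {s: {SpectrumKey(s, i) for i in ids}
                  for s, ids in per.items()}
            for acc, per in spec.items()}


class TestComputeAbundance:
    def test_saf_nsaf_forced_arithmetic(self):
        counts = make_counts({
            "A": {"s1": [f"a{i}" for i in range(10)]},
            "B": {"s1": [f"b{i}" for i in range(10)]},
        })
        rows = {r.accession: r for r in
                compute_abundance(counts, {"A": 100, "B": 200})}
        assert rows["A"].saf["s1"] == pytest.approx(0.1)
        assert rows["B"].saf["s1"] == pytest.approx(0.05)
        assert rows["A"].nsaf["s1"] == pytest.approx(2 / 3)
        assert rows["B"].nsaf["s1"] == pytest.approx(1 / 3)

    def test_p_protein_across_two_samples(self):
        # NSAF vectors (2/3, 1/3) and (1/2, 1/2) → p (7/12, 5/12)
        counts = make_counts({
            "A": {"s1": [f"a{i}" for i in range(10)],
                  "s2": [f"c{i}" for i in range(10)]},
            "B": {"s1": [f"b{i}" for i in range(10)],
                  "s2": [f"d{i}" for i in range(20)]},
        })
        rows = {r.accession: r for r in
                compute_abundance(counts, {"A": 100, "B": 200})}
        assert rows["A"].nsaf_sum == pytest.approx(7 / 6)
        assert rows["B"].nsaf_sum == pytest.approx(5 / 6)
        assert rows["A"].p_protein == pytest.approx(7 / 12)
        assert rows["B"].p_protein == pytest.approx(5 / 12)
        assert rows["A"].p_protein + rows["B"].p_protein == pytest.approx(1.0)

    def test_single_protein_has_probability_one(self):
        counts = make_counts({"A": {"s1": ["x"]}})
        (row,) = compute_abundance(counts, {"A": 123})
        assert row.p_protein == pytest.approx(1.0)

    def test_zero_saf_sample_guard(self, caplog):
        counts = make_counts({"A": {"s1": ["x"], "s2": []}})
        with caplog.at_level("WARNING"):
            (row,) = compute_abundance(counts, {"A": 100})
        assert row.nsaf["s2"] == 0.0
        assert "zero total SAF" in caplog.text


class TestGreedyFilter:
    def test_hand_walked_example(self):
        counts = make_counts({"A": {"s1": ["s1", "s2"]},
                              "B": {"s1": ["s2"]},
                              "C": {"s1": ["s3"]}})
        rows = compute_abundance(counts, {"A": 10, "B": 10, "C": 10})
        ranked = rank_by_protein(rows)
        assert [rp.accession for rp in ranked][:1] == ["A"]  # 2 spectra
        retained = greedy_filter(ranked, counts)
        assert [rp.accession for rp in retained] == ["A", "C"]
        by_acc = {rp.accession: rp for rp in retained}
        assert {k.spectrum_id for k in by_acc["A"].unique_spectra} == {"s1", "s2"}
        assert {k.spectrum_id for k in by_acc["C"].unique_spectra} == {"s3"}

    def test_isoform_pair_collapses_to_shorter(self):
        counts = make_counts({"LONG": {"s1": ["x", "y"]},
                              "SHRT": {"s1": ["x", "y"]}})
        rows = compute_abundance(counts, {"LONG": 101, "SHRT": 100})
        retained = greedy_filter(rank_by_protein(rows), counts)
        assert [rp.accession for rp in retained] == ["SHRT"]

    def test_single_protein_retained(self):
        counts = make_counts({"A": {"s1": ["x"]}})
        rows = compute_abundance(counts, {"A": 10})
        assert len(greedy_filter(rank_by_protein(rows), counts)) == 1


class TestOrganismMarginals:
    def test_forced_arithmetic(self):
        counts = make_counts({
            "A1": {"s1": [f"a{i}" for i in range(6)]},
            "A2": {"s1": ["b1", "b2"]},
            "B1": {"s1": ["d1", "d2"]},
        })
        rows = compute_abundance(counts, {"A1": 10, "A2": 10, "B1": 10})
        retained = greedy_filter(rank_by_protein(rows), counts)
        profile = organism_marginals(retained, rows,
                                     {"A1": "X", "A2": "X", "B1": "Y"})
        assert profile["X"] == pytest.approx(0.8)
        assert profile["Y"] == pytest.approx(0.2)

    def test_single_organism_is_one(self):
        counts = make_counts({"A": {"s1": ["x"]}, "B": {"s1": ["y"]}})
        rows = compute_abundance(counts, {"A": 10, "B": 10})
        retained = greedy_filter(rank_by_protein(rows), counts)
        profile = organism_marginals(retained, rows, {"A": "X", "B": "X"})
        assert profile == {"X": pytest.approx(1.0)}

    def test_organism_only_in_excluded_proteins_gets_zero(self):
        # B shares A's spectrum exactly and loses the tie on length
        counts = make_counts({"A": {"s1": ["x"]}, "B": {"s1": ["x"]},
                              "C": {"s1": ["y"]}})
        rows = compute_abundance(counts, {"A": 10, "B": 20, "C": 10})
        retained = greedy_filter(rank_by_protein(rows), counts)
        organisms = {"A": "X", "B": "Z", "C": "X"}
        profile = organism_marginals(retained, rows, organisms)
        assert "Z" not in profile
        ranked2 = joint_rank(rows, profile, organisms)
        assert next(rp for rp in ranked2 if rp.accession == "B").joint == 0.0


class TestJointRank:
    def test_product(self):
        counts = make_counts({"A": {"s1": ["x"]}})
        rows = compute_abundance(counts, {"A": 10})
        rows[0].p_protein = 0.5
        ranked = joint_rank(rows, {"X": 0.5}, {"A": "X"})
        assert ranked[0].joint == pytest.approx(0.25)

    def test_zero_organism_annihilates(self):
        counts = make_counts({"A": {"s1": ["x"]}})
        rows = compute_abundance(counts, {"A": 10})
        ranked = joint_rank(rows, {}, {"A": "X"})
        assert ranked[0].joint == 0.0

    def test_dominant_organism_promotes_low_abundance_protein(self):
        counts = make_counts({"A": {"s1": ["x"]}, "B": {"s1": ["y"]}})
        rows = compute_abundance(counts, {"A": 10, "B": 10})
        for row in rows:
            row.p_protein = 0.01
        ranked = joint_rank(rows, {"BIG": 0.9, "RARE": 0.05},
                            {"A": "BIG", "B": "RARE"})
        assert [rp.accession for rp in ranked] == ["A", "B"]
        assert ranked[0].joint == pytest.approx(0.009)
        assert ranked[1].joint == pytest.approx(0.0005)


class TestTwoPass:
    def records_for(self, lengths, organisms):
        return [ProteinRecord(a, f"{a} OS={organisms[a]} OX=1", "A" * n)
                for a, n in lengths.items()]

    def test_single_organism_passes_agree(self):
        counts = make_counts({"A": {"s1": ["x", "y"]}, "B": {"s1": ["y"]},
                              "C": {"s1": ["z"]}})
        lengths = {"A": 10, "B": 10, "C": 10}
        records = self.records_for(lengths, dict.fromkeys(lengths, "Same"))
        res = run_two_pass(records, counts)
        assert [r.accession for r in res.retained] == \
            [r.accession for r in res.pass1_retained]

    def test_degenerate_shared_spectrum_set_keeps_one(self):
        ids = ["x", "y", "z"]
        counts = make_counts({a: {"s1": ids} for a in "ABCD"})
        lengths = {"A": 40, "B": 30, "C": 20, "D": 10}
        records = self.records_for(lengths, dict.fromkeys(lengths, "O"))
        res = run_two_pass(records, counts)
        assert [r.accession for r in res.retained] == ["D"]  # shortest

    def test_empty_counts_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            res = run_two_pass([], {})
        assert res.retained == []
        assert "no mapped spectra" in caplog.text

    def test_pass2_changes_representative_toward_dominant_organism(self):
        """Pass 2 can promote a dominant organism's homologue above a rare
        organism's competitor for a shared spectrum; checked against the
        independent oracle."""
        counts = make_counts({
            "X1": {"s1": ["a", "b", "c", "d"]},
            "X2": {"s1": ["e", "f", "g"]},
            "X3": {"s1": ["h", "shared"]},
            "Y1": {"s1": ["shared", "i"]},
            "X4": {"s1": ["shared"]},
        })
        lengths = {"X1": 10, "X2": 10, "X3": 30, "Y1": 20, "X4": 25}
        organisms = {"X1": "X", "X2": "X", "X3": "X", "Y1": "Y", "X4": "X"}
        records = self.records_for(lengths, organisms)
        res = run_two_pass(records, counts)
        o_pass1, _, o_final = oracle_two_pass_retained(counts, lengths,
                                                       organisms)
        assert [r.accession for r in res.pass1_retained] == o_pass1
        assert [r.accession for r in res.retained] == o_final

    def test_randomized_against_oracle(self):
        """Pass-1/pass-2 retained lists and organism profile match the
        independent numpy + retained-above oracle."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            counts, lengths, organisms = random_counts_instance(rng)
            records = self.records_for(lengths, organisms)
            res = run_two_pass(records, counts)
            o_pass1, o_porg, o_final = oracle_two_pass_retained(
                counts, lengths, organisms)
            assert [r.accession for r in res.pass1_retained] == o_pass1
            assert [r.accession for r in res.retained] == o_final
            for org, p in res.organism_profile.items():
                assert p == pytest.approx(o_porg[org], abs=1e-12)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        counts, lengths, organisms = random_counts_instance(rng)
        records = self.records_for(lengths, organisms)
        res_a = run_two_pass(records, counts)
        shuffled = dict(reversed(list(counts.items())))
        res_b = run_two_pass(list(reversed(records)), shuffled)
        assert [r.accession for r in res_a.retained] == \
            [r.accession for r in res_b.retained]
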