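import numpy as np
import pytest

from marinerscan._align import alignment_identity, nt_aligner
from marinerscan.consensus import (build_consensus, divergence_from_consensus,
                                   estimate_copy_number, progressive_align,
                                   species_representative, ConsensusElement)
from marinerscan.io import AlignmentSet
from marinerscan.simulate import _random_nt, plant_elements


def _mutated(seq, n_sub, rng):
    s = list(seq)
    for i in rng.choice(len(s), size=n_sub, replace=False):
        s[i] = "ACGT".replace(s[i], "")[rng.integers(3)]
    return "".join(s)


class TestProgressiveAlign:
    def test_identical_pair_gap_free(self):
        aln = progressive_align({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert aln.rows == ["ACGTACGT", "ACGTACGT"]

    def test_single_gap_example(self):
        # exhaustive NW optimum for ACGT vs ACT (match 1/mismatch -1/gap -2)
        # is one gap column and three matches
        aln = progressive_align({"a": "ACGT", "b": "ACT"})
        assert aln.length == 4
        gaps = sum(c == "-" for row in aln.rows for c in row)
        matches = sum(x == y != "-" for x, y in zip(*aln.rows))
        assert (gaps, matches) == (1, 3)

    def test_pairwise_score_matches_nw_oracle(self):
        # profile alignment of two single sequences must reach the same
        # optimum as an independent pairwise global aligner
        rng = np.random.default_rng(60)
        a = _random_nt(300, rng)
        b = _mutated(a, 30, rng)
        b = b[:100] + b[140:]  # one 40-nt deletion
        aln = progressive_align({"a": a, "b": b})
        score = sum(
            1.0 if (x == y and "-" not in (x, y)) else
            (-2.0 if "-" in (x, y) else -1.0)
            for x, y in zip(*aln.rows))
        oracle = nt_aligner("global").align(a, b).score
        assert score == pytest.approx(oracle)

    def test_column_count_bounded_on_simulated_copies(self, master):
        rng = np.random.default_rng(61)
        copies = {f"c{i}": _mutated(master.sequence, 61, rng)
                  for i in range(5)}
        aln = progressive_align(copies)
        assert aln.length <= 1.1 * len(master.sequence)
        assert aln.taxa == list(copies)

    def test_single_sequence_passthrough(self):
        aln = progressive_align({"only": "ACGT"})
        assert aln.rows == ["ACGT"] and aln.n_taxa == 1

    def test_deterministic(self, master):
        rng = np.random.default_rng(62)
        copies = {f"c{i}": _mutated(master.sequence, 50, rng)
                  for i in range(6)}
        assert progressive_align(copies).rows == progressive_align(copies).rows


class TestBuildConsensus:
    def test_private_substitutions_vote_out(self):
        rows = ["ACGTACGT", "ACGAACGT", "ACGTACCT", "TCGTACGT"]
        aln = AlignmentSet(taxa=list("abcd"), rows=rows)
        assert build_consensus(aln).sequence == "ACGTACGT"

    def test_gap_column_rules(self):
        # {A,A,-} keeps A; {-,-,C} is majority-gap and is deleted
        aln = AlignmentSet(taxa=list("abc"), rows=["A-G", "A-G", "-CG"])
        cons = build_consensus(aln)
        assert cons.sequence == "AG"

    def test_tie_broken_by_first_row(self):
        aln = AlignmentSet(taxa=list("abcd"), rows=["G", "A", "A", "G"])
        assert build_consensus(aln).sequence == "G"

    def test_idempotent(self, master):
        cons = build_consensus(progressive_align({"m": master.sequence}))
        again = build_consensus(progressive_align({"c": cons.sequence}))
        assert again.sequence == cons.sequence

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_consensus(AlignmentSet(taxa=["a"], rows=["---"]))

    def test_recovers_master_from_diverged_copies(self, master):
        genome, truth = plant_elements(260_000, master, 20,
                                       mean_divergence=0.10, seed=63)
        copies = {f"c{i}": r.sequence for i, r in enumerate(truth.records)}
        cons = build_consensus(progressive_align(copies))
        aln = nt_aligner("global").align(master.sequence, cons.sequence)[0]
        ident, comp = alignment_identity(aln, master.sequence, cons.sequence)
        assert ident / comp >= 0.99


@pytest.fixture(scope="module")
def planted(master):
    genome, truth = plant_elements(
        240_000, master, 15, mean_divergence=0.05, seed=64,
        extra_copies=[
            {"status": "free", "exact_diff_frac": 0.15},
            {"status": "truncated", "exact_diff_frac": 0.02,
             "truncate_to": 900},
        ])
    cons = ConsensusElement(species="sp", sequence=master.sequence,
                            n_support=15)
    return genome, truth, cons


class TestEstimateCopyNumber:
    def test_counts_planted_copies_exactly(self, planted):
        genome, truth, cons = planted
        n, hits = estimate_copy_number(cons, genome, 1000, 0.90)
        assert n == 15  # the 85%-identity and the 900-bp copies are excluded

    def test_monotone_in_thresholds(self, planted):
        genome, truth, cons = planted
        n_base, _ = estimate_copy_number(cons, genome, 1000, 0.90)
        n_lower_ident, _ = estimate_copy_number(cons, genome, 1000, 0.80)
        n_shorter, _ = estimate_copy_number(cons, genome, 700, 0.90)
        assert n_lower_ident >= n_base
        assert n_shorter >= n_base

    def test_short_consensus_rejected(self, master):
        from marinerscan.io import GenomeAssembly
        cons = ConsensusElement(species="s", sequence="ACGT" * 50,
                                n_support=1)
        with pytest.raises(ValueError):
            estimate_copy_number(cons, GenomeAssembly(records={"c": "ACGT" * 1000}))


class TestDivergenceFromConsensus:
    def test_identical_copies(self, master):
        cons = ConsensusElement(species="s", sequence=master.sequence,
                                n_support=3)
        d = divergence_from_consensus([master.sequence] * 3, cons)
        assert d.mean_divergence == pytest.approx(0.0)
        assert d.se == pytest.approx(0.0)

    def test_single_copy_undefined(self, master):
        cons = ConsensusElement(species="s", sequence=master.sequence,
                                n_support=1)
        assert divergence_from_consensus([master.sequence], cons) is None

    def test_mean_recovers_truth(self, master):
        # copies at true divergence 5%: sample mean within 3 SE of 5.0
        rng = np.random.default_rng(65)
        from marinerscan._align import encode_nt, decode_nt, sample_substitution
        enc = encode_nt(master.sequence)
        copies = [decode_nt(sample_substitution(enc, 0.05, 2.0, rng))
                  for _ in range(200)]
        cons = ConsensusElement(species="s", sequence=master.sequence,
                                n_support=200)
        d = divergence_from_consensus(copies, cons)
        assert d.n == 200
        assert abs(d.mean_divergence - 5.0) <= 3 * max(d.se, 1e-9)


def test_species_representative_rule(master):
    from marinerscan.io import GenomeAssembly
    genome = GenomeAssembly(records={"c": master.sequence})
    few = {f"c{i}": master.sequence for i in range(3)}
    rep = species_representative(few, genome, "sp", consensus_min_copies=10,
                                 best_hit=master.sequence)
    assert rep.is_best_hit_representative and rep.n_support == 3
    many = {f"c{i}": master.sequence for i in range(10)}
    rep2 = species_representative(many, genome, "sp", consensus_min_copies=10)
    assert not rep2.is_best_hit_representative and rep2.n_support == 10
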