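import math
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pytest

from marinerscan._align import decode_nt, sample_substitution
from marinerscan.distances import (DistanceMatrix, identity_matrix,
                                   jc_distance, k2p_distance,
                                   mcl_distance_matrix, tn93_distance)
from marinerscan.io import AlignmentSet


def _pair_with_counts(n, n_ts, n_tv):
    """Aligned pair with exactly n sites, n_ts transitions (A->G) and
    n_tv transversions (A->C)."""
    a = "A" * n
    b = "G" * n_ts + "C" * n_tv + "A" * (n - n_ts - n_tv)
    return a, b


class TestK2P:
    def test_identical(self):
        r = k2p_distance("ACGTACGT", "ACGTACGT")
        assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)

    def test_closed_form_value(self):
        # P=0.1, Q=0.05 at n=1000: d = -1/2 ln((1-2P-Q) sqrt(1-2Q))
        a, b = _pair_with_counts(1000, 100, 50)
        r = k2p_distance(a, b)
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert r.d == pytest.approx(expected, abs=1e-9)
        assert r.d == pytest.approx(0.17018, abs=5e-6)
        # delta-method variance
        w1, w2 = 1 - 0.2 - 0.05, 1 - 0.1
        aa, bb = 1 / w1, 0.5 * (1 / w1 + 1 / w2)
        v = (aa * aa * 0.1 + bb * bb * 0.05
             - (aa * 0.1 + bb * 0.05) ** 2) / 1000
        assert r.variance == pytest.approx(v, abs=1e-12)

    def test_domain_boundary_saturated(self):
        a, b = _pair_with_counts(100, 50, 0)  # 1 - 2P - Q = 0
        r = k2p_distance(a, b)
        assert not r.defined and math.isnan(r.d)

    def test_pairwise_deletion(self):
        r = k2p_distance("ACGT-NAC", "ACGAANAC")
        assert r.n_sites == 6  # gap and N columns dropped

    def test_collapses_to_jc_when_q_is_2p(self):
        # transitions at 1/3 of differences (Q = 2P) is the JC regime
        a, b = _pair_with_counts(900, 60, 120)
        r = k2p_distance(a, b)
        d_jc, _ = jc_distance(a, b)
        assert r.d == pytest.approx(d_jc, abs=1e-12)

    def test_unaligned_inputs_are_aligned_first(self):
        r = k2p_distance("ACGTACGTACGT", "ACGTACGTACG", aligned=False)
        assert r.defined and r.d == pytest.approx(0.0)


class TestMCL:
    def test_zero_difference_pair(self):
        aln = AlignmentSet(taxa=["a", "b"], rows=["ACGT" * 100] * 2)
        dm = mcl_distance_matrix(aln)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_two_taxon_matches_tn93_closed_form(self):
        rng = np.random.default_rng(70)
        root = rng.integers(0, 4, size=20_000)
        a = decode_nt(sample_substitution(root, 0.08, 2.5, rng))
        b = decode_nt(sample_substitution(root, 0.08, 2.5, rng))
        d_mcl = tn93_distance(a, b)
        # closed-form TN93 (method-of-moments) oracle
        d_cf = _tn93_closed_form(a, b)
        assert d_mcl == pytest.approx(d_cf, abs=0.003)

    def test_collapses_to_jc_under_equal_rates(self):
        rng = np.random.default_rng(71)
        root = rng.integers(0, 4, size=10_000)
        a = decode_nt(sample_substitution(root, 0.05, 1.0, rng))
        b = decode_nt(sample_substitution(root, 0.05, 1.0, rng))
        dm = mcl_distance_matrix(AlignmentSet(taxa=["a", "b"], rows=[a, b]))
        d_jc, v_jc = jc_distance(a, b)
        assert abs(dm.d[0, 1] - d_jc) <= 2 * math.sqrt(v_jc)

    def test_saturated_pair_flagged(self):
        rng = np.random.default_rng(72)
        a = decode_nt(rng.integers(0, 4, size=2000))
        b = decode_nt(rng.integers(0, 4, size=2000))
        aln = AlignmentSet(taxa=["a", "b", "c"], rows=[a, b, a])
        dm = mcl_distance_matrix(aln)
        assert math.isnan(dm.d[0, 1]) or dm.d[0, 1] > 1.0
        assert dm.d[0, 2] == pytest.approx(0.0, abs=1e-5)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(73)
        root = rng.integers(0, 4, size=5000)
        rows = [decode_nt(sample_substitution(root, t, 2.0, rng))
                for t in (0.02, 0.05, 0.08)]
        aln = AlignmentSet(taxa=["a", "b", "c"], rows=rows)
        perm = AlignmentSet(taxa=["c", "a", "b"],
                            rows=[rows[2], rows[0], rows[1]])
        d1 = mcl_distance_matrix(aln)
        d2 = mcl_distance_matrix(perm)
        assert d1.value("a", "b") == pytest.approx(d2.value("a", "b"), abs=1e-4)
        assert d1.value("b", "c") == pytest.approx(d2.value("b", "c"), abs=1e-4)


def _tn93_closed_form(a, b):
    """Tamura-Nei 1993 moment estimator, written independently."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    n = np.zeros((4, 4))
    for x, y in zip(a, b):
        if x in idx and y in idx:
            n[idx[x], idx[y]] += 1
    total = n.sum()
    f = (n + n.T) / (2 * total)
    pi = f.sum(axis=1)
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    P1 = f[0, 2] * 2          # purine transitions
    P2 = f[1, 3] * 2          # pyrimidine transitions
    Q = 2 * (f[0, 1] + f[0, 3] + f[2, 1] + f[2, 3])
    k1 = 2 * piA * piG / piR
    k2 = 2 * piC * piT / piY
    k3 = 2 * (piR * piY - piA * piG * piY / piR - piC * piT * piR / piY)
    w1 = 1 - P1 / k1 - Q / (2 * piR)
    w2 = 1 - P2 / k2 - Q / (2 * piY)
    w3 = 1 - Q / (2 * piR * piY)
    return (-k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3))


@pytest.fixture(scope="module")
def pair():
    rng = np.random.default_rng(74)
    root = rng.integers(0, 4, size=8000)
    a = decode_nt(sample_substitution(root, 0.07, 2.0, rng))
    b = decode_nt(sample_substitution(root, 0.07, 2.0, rng))
    return a, b


class TestAgainstRApe:
    """Independent oracle: ape::dist.dna on the same alignment."""

    def _ape(self, a, b, model):
        with tempfile.TemporaryDirectory() as td:
            fa = Path(td) / "pair.fa"
            fa.write_text(f">a\n{a}\n>b\n{b}\n")
            out = subprocess.run(
                ["Rscript", "-e",
                 f'suppressMessages(library(ape));'
                 f'x <- read.dna("{fa}", format="fasta");'
                 f'cat(sprintf("%.12f", dist.dna(x, model="{model}")[1]))'],
                capture_output=True, text=True, check=True)
        return float(out.stdout.strip())

    def test_k2p_matches_ape_k80(self, pair):
        a, b = pair
        assert k2p_distance(a, b).d == pytest.approx(
            self._ape(a, b, "K80"), abs=1e-9)

    def test_jc_matches_ape_jc69(self, pair):
        a, b = pair
        assert jc_distance(a, b)[0] == pytest.approx(
            self._ape(a, b, "JC69"), abs=1e-9)

    def test_mcl_close_to_ape_tn93(self, pair):
        a, b = pair
        assert tn93_distance(a, b) == pytest.approx(
            self._ape(a, b, "TN93"), abs=0.003)


class TestIdentityMatrix:
    def test_identical_pair(self):
        dm = identity_matrix({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert dm.value("a", "b") == pytest.approx(100.0)

    def test_three_quarters(self):
        dm = identity_matrix({"a": "AAAA", "b": "AAAT"})
        assert dm.value("a", "b") == pytest.approx(75.0)

    def test_gap_columns_excluded_in_aligned_mode(self):
        aln = AlignmentSet(taxa=["a", "b"], rows=["AC-T", "ACGT"])
        dm = identity_matrix(aln)
        assert dm.value("a", "b") == pytest.approx(100.0)

    def test_recent_transfer_means_high_identity(self, master):
        # ten consensus-like sequences 2% diverged from one source
        rng = np.random.default_rng(75)
        from marinerscan._align import encode_nt
        enc = encode_nt(master.sequence)
        seqs = {f"s{i}": decode_nt(sample_substitution(enc, 0.01, 2.0, rng))
                for i in range(10)}
        dm = identity_matrix(seqs)
        assert (dm.offdiag() >= 95.0).all()


def test_distance_matrix_tsv_roundtrip(tmp_path):
    d = np.array([[0.0, 0.1], [0.1, 0.0]])
    dm = DistanceMatrix(taxa=["x", "y"], d=d)
    p = tmp_path / "dm.tsv"
    dm.to_tsv(p)
    back = DistanceMatrix.from_tsv(p)
    assert back.taxa == ["x", "y"]
    np.testing.assert_allclose(back.d, d)
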