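import numpy as np
import pytest

from marinerscan.annotation import (CatalyticTriad, annotate_copy, check_tsd,
                                    classify_status, detect_triad, find_longest_orf,
                                    find_tirs, refine_boundaries, scan_grpr)
from marinerscan.io import revcomp
from marinerscan.mining import (ElementCopy, dedupe_copies,
                                extract_with_flanks, translated_search)
from marinerscan.references import build_protein
from marinerscan.simulate import _backtranslate, _random_nt, plant_elements


def _copy(seq, left="", right=""):
    return ElementCopy(contig="c", start=0, end=len(seq), strand="+",
                       sequence=seq, left_flank=left, right_flank=right)


# --- TIR detection ---------------------------------------------------------

def _tir_oracle(seq, min_len, max_frac, window, slack=5, penalty=2.0):
    """Exhaustive enumeration of anchored ungapped terminal alignments."""
    n = len(seq)
    w = min(window, n // 2)
    best = None
    for a in range(slack + 1):
        for b in range(slack + 1):
            for L in range(1, min(w - a, w - b) + 1):
                left = seq[a:a + L]
                right = revcomp(seq[n - b - L:n - b])
                mism = sum(1 for x, y in zip(left, right)
                           if x == "N" or x != y)
                score = (L - mism) - penalty * mism
                key = (score, -mism, L, -a, -b)
                if best is None or key > best[0]:
                    best = (key, a, b, L, mism)
    if best is None:
        return None
    _, a, b, L, mism = best
    if L < min_len or mism > max_frac * L:
        return None
    return (a, b, L, mism)


def test_planted_perfect_29bp_tirs(master):
    tir = find_tirs(master.sequence)
    assert (tir.length, tir.mismatches) == (29, 0)
    assert tir.left_start_offset == 0 and tir.right_end_offset == 0


def test_planted_28bp_tirs_with_two_mismatches():
    rng = np.random.default_rng(40)
    t = list(_random_nt(28, rng))
    right = revcomp("".join(t))
    for k in (10, 17):  # interior mismatches survive local trimming
        t[k] = "ACGT".replace(t[k], "")[rng.integers(3)]
    seq = "".join(t) + _random_nt(500, rng) + right
    tir = find_tirs(seq, min_len=20, max_mismatch_frac=0.1)
    assert tir is not None
    assert (tir.length, tir.mismatches) == (28, 2)


def test_unrelated_termini_absent():
    rng = np.random.default_rng(41)
    seq = _random_nt(800, rng)
    assert find_tirs(seq, 20, 0.1, 150) is None
    assert _tir_oracle(seq, 20, 0.1, 150) is None  # brute-force agreement


@pytest.mark.parametrize("seed,tir_len,n_mism", [
    (50, 24, 0), (51, 32, 1), (52, 20, 2), (53, 40, 0),
])
def test_find_tirs_matches_exhaustive_oracle(seed, tir_len, n_mism):
    rng = np.random.default_rng(seed)
    t = list(_random_nt(tir_len, rng))
    right = revcomp("".join(t))
    for k in rng.choice(range(3, tir_len - 3), size=n_mism, replace=False):
        t[k] = "ACGT".replace(t[k], "")[rng.integers(3)]
    seq = "".join(t) + _random_nt(700, rng) + right
    got = find_tirs(seq, 20, 0.1, 150)
    expect = _tir_oracle(seq, 20, 0.1, 150)
    assert expect is not None and got is not None
    assert (got.left_start_offset, got.right_end_offset,
            got.length, got.mismatches) == expect


def test_find_tirs_too_short_element():
    assert find_tirs("ACGTACGT", min_len=20) is None


# --- TSD -------------------------------------------------------------------

def test_tsd_ta():
    tsd = check_tsd(_copy("ACGT", left="CCGTTA", right="TACCGG"))
    assert tsd.is_TA and tsd.left_copy == "TA" and tsd.right_copy == "TA"


def test_tsd_not_ta():
    tsd = check_tsd(_copy("ACGT", left="CCGTCG", right="TACCGG"))
    assert not tsd.is_TA


def test_tsd_missing_flank_warns():
    with pytest.warns(UserWarning):
        assert check_tsd(_copy("ACGT", left="", right="TACC")) is None


# --- ORF -------------------------------------------------------------------

def test_master_orf_is_346_aa(master):
    orf = find_longest_orf(master.sequence, min_aa=300)
    assert orf == master.protein
    assert len(orf) == 346


def test_no_atg_means_no_orf():
    assert find_longest_orf("GGCGGCGGCGGC" * 30, min_aa=1) is None


def test_longest_of_two_orfs_wins():
    rng = np.random.default_rng(42)
    aa = np.array(list("ACDEFGHIKLNPQRSTVWY"))  # no M: starts controlled
    short = "M" + "".join(rng.choice(aa, size=339))
    long = "M" + "".join(rng.choice(aa, size=349))
    seq = _backtranslate(short, rng) + "TT" + _backtranslate(long, rng)
    orf = find_longest_orf(seq, min_aa=300)
    assert len(orf) == 350


# --- triad + GRPR ----------------------------------------------------------

def test_triad_transfer_dd36e(refs):
    rng = np.random.default_rng(43)
    prot, _ = build_protein(spacer2=36, third_residue="E",
                            mutate_frac=0.1, rng=rng)
    triad = detect_triad(prot, refs)
    assert triad.family_label == "DD36E"
    assert triad.spacer2 == 36


def test_triad_transfer_dd34e(refs):
    rng = np.random.default_rng(44)
    prot, _ = build_protein(spacer2=34, third_residue="E",
                            mutate_frac=0.1, rng=rng)
    assert detect_triad(prot, refs).family_label == "DD34E"


def test_triad_absent_when_residue_wrong(refs):
    ref = refs[0]
    e3 = ref.triad.e3_pos
    broken = ref.sequence[:e3] + "K" + ref.sequence[e3 + 1:]
    assert detect_triad(broken, refs) is None


def test_triad_self_consistency_on_references(refs):
    for ref in refs:
        t = detect_triad(ref.sequence, refs)
        assert (t.d1_pos, t.d2_pos, t.e3_pos) == \
               (ref.triad.d1_pos, ref.triad.d2_pos, ref.triad.e3_pos)
        assert t.family_label == ref.triad.family_label


def test_triad_invariants():
    with pytest.raises(ValueError):
        CatalyticTriad(d1_pos=10, d2_pos=5, e3_pos=20, third_residue="E")
    t = CatalyticTriad(d1_pos=150, d2_pos=243, e3_pos=280, third_residue="E")
    assert t.family_label == "DD36E"
    assert t.spacer2 == 280 - 243 - 1


def test_scan_grpr():
    assert scan_grpr("AAGRPRDD") == [2]
    assert scan_grpr("AAGRKRDD") == [2]   # GRPR-like
    assert scan_grpr("AAAAAA") == []
    assert scan_grpr("GRPRGRKR") == [0, 4]


# --- status classification -------------------------------------------------

def _statused(seq_len, tir, orf_aa, family):
    c = _copy("A" * seq_len)
    c.tir = tir
    c.orf_aa = "M" * orf_aa if orf_aa else None
    c.family_label = family
    return c


def test_status_definitions():
    from marinerscan.annotation import TIRPair
    tir = TIRPair(0, 0, 29, 0)
    assert classify_status(_statused(1225, tir, 346, "DD36E")) == "intact"
    assert classify_status(_statused(1225, tir, 150, None)) == "full_length"
    assert classify_status(_statused(810, tir, 190, None)) == "MITE"
    assert classify_status(_statused(600, None, 150, None)) == "truncated"


def test_status_total_and_exclusive():
    from marinerscan.annotation import TIRPair
    statuses = set()
    for tir in (None, TIRPair(0, 0, 29, 0)):
        for orf_aa in (0, 190, 346):
            for fam in (None, "DD36E"):
                for length in (500, 810, 1225):
                    statuses.add(classify_status(
                        _statused(length, tir, orf_aa, fam)))
    assert statuses <= {"intact", "full_length", "MITE", "truncated"}


def test_planted_statuses_recovered_end_to_end(master, refs):
    """Mine -> refine -> annotate recovers >= 95% of planted labels at
    10% per-copy divergence."""
    genome, truth = plant_elements(
        220_000, master, 20, mean_divergence=0.10,
        frac_truncated=0.2, frac_mite=0.3, seed=77)
    hits = translated_search(master.protein, genome)
    copies = dedupe_copies([
        refine_boundaries(extract_with_flanks(h, genome, 2000))
        for h in hits])
    for c in copies:
        annotate_copy(c, refs)
    matched = 0
    for rec in truth.records:
        overlapping = [c for c in copies
                       if min(c.end, rec.end) - max(c.start, rec.start) >
                       0.5 * (rec.end - rec.start)]
        assert len(overlapping) == 1, f"copy at {rec.start} not uniquely found"
        if overlapping[0].status == rec.status:
            matched += 1
    assert matched >= 0.95 * len(truth.records)
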