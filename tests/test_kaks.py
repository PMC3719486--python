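"""NG86 counting against an exact enumeration oracle, window arithmetic,
and the Kruskal-Wallis contrast."""

from fractions import Fraction
from itertools import product

import numpy as np
import pytest

from famwave.kaks import (
    kaks_from_codon_indices,
    kaks_pair,
    kruskal_wallis,
    ng86_codon_sites,
    ng86_pair_diffs,
    region_kaks,
    sliding_window,
)
from famwave.synthetic import SENSE_CODONS

# -- independent oracle: exact rational arithmetic, Biopython genetic code


def _aa(codon):
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


_STOPS = {c for c in ("".join(p) for p in product("TCAG", repeat=3)) if _aa(c) == "*"}


def oracle_sites(codon):
    s = Fraction(0)
    for pos in range(3):
        syn, valid = 0, 0
        for b in "TCAG":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in _STOPS:
                continue
            valid += 1
            if _aa(alt) == _aa(codon):
                syn += 1
        if valid:
            s += Fraction(syn, valid)
    return s, 3 - s


def oracle_diffs(a, b):
    """Average (syn, nonsyn) steps over stop-free orderings, enumerated
    recursively; falls back to all orderings if every path hits a stop."""
    positions = [i for i in range(3) if a[i] != b[i]]
    paths = []

    def rec(cur, todo, steps, blocked):
        if not todo:
            paths.append((steps, blocked))
            return
        for pos in todo:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            step_is_syn = _aa(nxt) == _aa(cur)
            rec(
                nxt,
                [p for p in todo if p != pos],
                steps + [step_is_syn],
                blocked or nxt in _STOPS,
            )

    rec(a, positions, [], False)
    usable = [p for p in paths if not p[1]] or paths
    syn = Fraction(sum(sum(s for s in steps if s) for steps, _ in usable), len(usable))
    nonsyn = Fraction(
        sum(sum(1 for s in steps if not s) for steps, _ in usable), len(usable)
    )
    return syn, nonsyn


def test_site_counts_match_oracle_for_all_sense_codons():
    for codon in SENSE_CODONS:
        s, n = ng86_codon_sites(codon)
        es, en = oracle_sites(codon)
        assert abs(s - float(es)) < 1e-12 and abs(n - float(en)) < 1e-12


def test_difference_counts_match_oracle_for_all_ordered_pairs():
    for a in SENSE_CODONS:
        for b in SENSE_CODONS:
            sd, nd = ng86_pair_diffs(a, b)
            es, en = oracle_diffs(a, b)
            assert abs(sd - float(es)) < 1e-12, (a, b)
            assert abs(nd - float(en)) < 1e-12, (a, b)


@pytest.mark.parametrize(
    "codon,s,n",
    [
        ("TTT", 1 / 3, 8 / 3),
        ("CTT", 1.0, 2.0),
        ("TGG", 0.0, 3.0),  # stop-creating changes excluded from denominators
    ],
)
def test_site_examples(codon, s, n):
    got = ng86_codon_sites(codon)
    assert got[0] == pytest.approx(s) and got[1] == pytest.approx(n)


def test_stop_or_ambiguous_codon_rejected():
    with pytest.raises(ValueError):
        ng86_codon_sites("TAA")
    with pytest.raises(ValueError):
        ng86_codon_sites("ANT")


# -- pairwise estimates ---------------------------------------------------


def test_identical_sequences_have_zero_rates():
    r = kaks_pair("ATGAAA", "ATGAAA")
    assert r.ka == 0 and r.ks == 0 and not r.ratio_defined


def test_single_codon_hand_example():
    r = kaks_pair("TTT", "TTA")
    assert r.syn_diffs == 0 and r.nonsyn_diffs == 1
    assert r.syn_sites == pytest.approx(0.5)
    assert r.nonsyn_sites == pytest.approx(2.5)
    assert r.ks == 0
    assert r.ka == pytest.approx(0.5716, abs=2e-4)
    assert not r.ratio_defined  # Ks = 0 -> undefined, not infinity arithmetic


def test_kaks_symmetric():
    a = "ATGTTTCTGAAA"
    b = "ATGTTACTCAAG"
    ra = kaks_pair(a, b)
    rb = kaks_pair(b, a)
    for field in ("syn_sites", "nonsyn_sites", "syn_diffs", "nonsyn_diffs", "ka"):
        assert getattr(ra, field) == pytest.approx(getattr(rb, field))
    assert ra.ratio_defined == rb.ratio_defined
    assert ra.saturated == rb.saturated


def test_sites_sum_to_alignment_length():
    rng = np.random.default_rng(0)
    idx_a = rng.integers(0, 61, size=50)
    idx_b = rng.integers(0, 61, size=50)
    a = "".join(SENSE_CODONS[i] for i in idx_a)
    b = "".join(SENSE_CODONS[i] for i in idx_b)
    r = kaks_pair(a, b)
    assert r.syn_sites + r.nonsyn_sites == pytest.approx(len(a))
    fast = kaks_from_codon_indices(idx_a, idx_b)
    assert fast.syn_diffs == pytest.approx(r.syn_diffs)
    assert fast.nonsyn_diffs == pytest.approx(r.nonsyn_diffs)


def test_length_not_divisible_by_three_rejected():
    with pytest.raises(ValueError):
        kaks_pair("ATGA", "ATGA")


def test_gappy_codons_are_pairwise_deleted():
    r = kaks_pair("ATG---AAA", "ATGTTTAAA")
    assert r.n_codons == 2


def test_internal_stop_rejected_terminal_tolerated():
    with pytest.raises(ValueError, match="stop"):
        kaks_pair("TAAATG", "TACATG")
    r = kaks_pair("ATGTAA", "ATGTAA")
    assert r.n_codons == 1


# -- windows --------------------------------------------------------------


def test_window_count_arithmetic():
    a = "ATG" * 100
    prof = sliding_window(a, a, window=150, step=9)
    assert len(prof.windows) == (300 - 150) // 9 + 1 == 17


def test_identical_sequences_flat_profile():
    a = "ATGGCT" * 50
    prof = sliding_window(a, a)
    assert all(w.result.ka == 0 and w.result.ks == 0 for w in prof.windows)


def test_single_difference_localised_to_overlapping_windows():
    a = list("ATG" * 100)
    b = list(a)
    # nonsynonymous change in codon 67 (bp 199-201): ATG -> CTG (M -> L)
    b[198] = "C"
    prof = sliding_window("".join(a), "".join(b), window=150, step=9)
    for w in prof.windows:
        overlaps = w.start <= 199 and w.end >= 199
        assert (w.result.ka > 0) == overlaps


def test_window_must_be_codon_aligned():
    a = "ATG" * 100
    with pytest.raises(ValueError):
        sliding_window(a, a, window=100, step=9)
    with pytest.raises(ValueError):
        sliding_window(a, a, window=150, step=10)


# -- regions --------------------------------------------------------------


def test_whole_alignment_region_equals_kaks_pair():
    a = "ATGAAACCCGGGACGTTT"
    b = "ATGAAGCCCGGGACGTAT"
    whole = kaks_pair(a, b)
    region = region_kaks(a, b, (0, 6))
    assert whole.ratio_defined and region == whole


def test_disjoint_region_counts_are_additive():
    rng = np.random.default_rng(1)
    a = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 40))
    b = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 40))
    whole = kaks_pair(a, b)
    r1 = region_kaks(a, b, (0, 25))
    r2 = region_kaks(a, b, (25, 40))
    assert r1.syn_diffs + r2.syn_diffs == pytest.approx(whole.syn_diffs)
    assert r1.nonsyn_diffs + r2.nonsyn_diffs == pytest.approx(whole.nonsyn_diffs)


def test_empty_region_rejected():
    with pytest.raises(ValueError):
        region_kaks("ATG", "ATG", (1, 1))


# -- Kruskal-Wallis -------------------------------------------------------


def test_kruskal_hand_example():
    h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
    assert h == pytest.approx(12 / 42 * 87 - 21, abs=1e-9)  # 3.857...


def test_kruskal_identical_groups():
    h, p = kruskal_wallis([2, 2, 2], [2, 2, 2])
    assert h == 0 and p == 1


def test_kruskal_invariant_under_monotone_transform():
    g1 = [0.1, 0.5, 1.2, 2.0]
    g2 = [0.3, 0.8, 1.6, 3.0]
    h1, _ = kruskal_wallis(g1, g2)
    h2, _ = kruskal_wallis(np.exp(g1), np.exp(g2))
    assert h1 == pytest.approx(h2)


def test_kruskal_drops_undefined_ratios():
    h1, _ = kruskal_wallis([1, 2, float("nan")], [4, 5, 6])
    h2, _ = kruskal_wallis([1, 2], [4, 5, 6])
    assert h1 == pytest.approx(h2)
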