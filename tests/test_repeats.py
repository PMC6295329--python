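"""Tandem-array detection, unit decomposition, microsatellites and stems."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitocr import (decompose_unit, find_stems, find_tandem_repeats,
                    microsat_scan, unit_identity)

from conftest import random_dna
from oracles import edit_distance_dp, stems_exhaustive


def mutate(rng, s, rate):
    out = list(s)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[rng.integers(0, 4)]
    return "".join(out)


def mutate_strict(rng, s, rate):
    """Substitute to a guaranteed-different base (true divergence = rate)."""
    out = list(s)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT".replace(out[i], "")[rng.integers(0, 3)]
    return "".join(out)


# -- unit_identity -----------------------------------------------------------

def test_identity_of_identical_units_is_one(rng):
    u = random_dna(rng, 75)
    assert unit_identity(u, u) == 1.0


def test_single_substitution_identity():
    assert unit_identity("AAAA", "AATA") == 0.75


def test_identity_matches_dp_oracle():
    rng = np.random.default_rng(3)
    for _ in range(40):
        a = random_dna(rng, int(rng.integers(5, 60)))
        b = mutate(rng, a, 0.3)[: int(rng.integers(5, 60))]
        if not b:
            continue
        expected = 1 - edit_distance_dp(a, b) / max(len(a), len(b))
        assert unit_identity(a, b) == pytest.approx(expected)
        assert unit_identity(b, a) == pytest.approx(expected)  # symmetric


# -- find_tandem_repeats -----------------------------------------------------

def test_exact_repeat_detected_with_smallest_unit():
    arrays = find_tandem_repeats("ACGT" * 10, min_unit=4, max_unit=40)
    assert len(arrays) == 1
    a = arrays[0]
    assert (a.unit_length, a.copy_number) == (4, 10)
    assert all(i == 1.0 for i in a.adjacent_identity)
    assert a.consensus == "ACGT"


def test_config_error_when_min_exceeds_max():
    with pytest.raises(ValueError):
        find_tandem_repeats("ACGT" * 10, min_unit=50, max_unit=10)


def test_planted_75bp_array_recovered():
    rng = np.random.default_rng(7)
    unit = random_dna(rng, 75)
    copies = [mutate(rng, unit, 0.05) for _ in range(6)]
    seq = random_dna(rng, 120) + "".join(copies) + random_dna(rng, 120)
    arrays = find_tandem_repeats(seq)
    assert len(arrays) == 1
    a = arrays[0]
    assert a.unit_length == 75 and a.copy_number == 6
    assert abs(a.start - 120) < 75  # phase-anchored at the array start


def test_planted_225bp_array_of_diverged_subunits():
    """Two copies of a 225-bp unit made of three ~40%-diverged 75-mers are
    reported at period 225, not at the sub-unit period."""
    rng = np.random.default_rng(8)
    sub = random_dna(rng, 75)
    unit = sub + mutate_strict(rng, sub, 0.4) + mutate_strict(rng, sub, 0.4)
    seq = random_dna(rng, 100) + unit + mutate(rng, unit, 0.03) + random_dna(rng, 100)
    arrays = find_tandem_repeats(seq, max_unit=300)
    assert [(a.unit_length, a.copy_number) for a in arrays] == [(225, 2)]


def test_adjacent_identities_respect_threshold(default_genome):
    genome, truth = default_genome
    from mitocr import extract_cr
    cr, _ = extract_cr(genome)
    arrays = find_tandem_repeats(cr, min_identity=0.7)
    assert arrays, "no array found in synthetic CR"
    for a in arrays:
        assert all(i >= 0.7 for i in a.adjacent_identity)
        assert a.copy_number >= 2


# -- decompose_unit ----------------------------------------------------------

def test_225_unit_decomposes_into_three_75mers(rng):
    unit = random_dna(rng, 225)
    res = decompose_unit(unit, 75)
    assert len(res.sub_units) == 3 and res.remainder == ""
    assert "".join(res.sub_units) == unit


def test_decomposition_keeps_remainder(rng):
    unit = random_dna(rng, 80)
    res = decompose_unit(unit, 75)
    assert len(res.sub_units) == 1 and len(res.remainder) == 5
    assert "".join(res.sub_units) + res.remainder == unit


def test_box_like_flag_for_diverged_third_subunit():
    rng = np.random.default_rng(11)
    a = random_dna(rng, 75)
    b = mutate(rng, a, 0.02)          # near-identical pair
    c = mutate(rng, a, 0.5)           # heavily diverged "box-like" copy
    res = decompose_unit(a + b + c, 75)
    assert res.pairwise_identity[0][1] >= 0.9
    assert res.box_like == (False, False, True)


def test_decompose_rejects_bad_base_length(rng):
    with pytest.raises(ValueError):
        decompose_unit(random_dna(rng, 75), 0)


# -- microsatellites ---------------------------------------------------------

def test_ta_run_detected_with_count():
    hits = microsat_scan("GGTATATATAGG")
    assert [(h.motif, h.start, h.repeat_count) for h in hits] == [("TA", 2, 4)]


def test_run_below_min_repeats_ignored():
    assert microsat_scan("CACACA", min_repeats=4) == []


def test_planted_ca_run_recovered_exactly():
    rng = np.random.default_rng(5)
    left, right = random_dna(rng, 200), random_dna(rng, 200)
    seq = left + "G" + "CA" * 7 + "G" + right
    hits = [h for h in microsat_scan(seq) if h.motif == "CA"]
    assert (len(left) + 1, 7) in {(h.start, h.repeat_count) for h in hits}


@given(st.text(alphabet="ACGT", min_size=8, max_size=120))
def test_reported_runs_are_maximal(seq):
    for h in microsat_scan(seq, min_repeats=2):
        m = len(h.motif)
        assert seq[h.start:h.end] == h.motif * h.repeat_count
        assert seq[h.start - m:h.start] != h.motif  # not left-extendable
        assert seq[h.end:h.end + m] != h.motif      # not right-extendable


# -- stems -------------------------------------------------------------------

def test_constructed_palindrome_forms_a_stem():
    hits = find_stems("GGGGCAAAAGCCCC", min_arm=5, max_loop=10)
    assert [(h.arm_start, h.arm_length, h.loop_length, h.arm_identity)
            for h in hits] == [(0, 5, 4, 1.0)]


def test_homopolymer_has_no_stem():
    assert find_stems("A" * 12, min_arm=4, max_loop=6) == []


def test_stems_match_exhaustive_oracle():
    rng = np.random.default_rng(9)
    for _ in range(5):
        stem_arm = random_dna(rng, 10)
        from mitocr.formats import reverse_complement
        seq = (random_dna(rng, 15) + stem_arm + random_dna(rng, 8)
               + reverse_complement(stem_arm) + random_dna(rng, 15))
        got = {(h.arm_start, h.arm_length, h.loop_length)
               for h in find_stems(seq, min_arm=6, max_loop=12, min_arm_identity=0.9)}
        want = stems_exhaustive(seq, min_arm=6, max_loop=12, min_identity=0.9)
        assert got == want
        assert any(s[1] >= 10 for s in got)  # the planted 10-bp stem is found


def test_stem_hits_sorted_by_arm_length_descending(rng):
    seq = random_dna(rng, 75)
    hits = find_stems(seq, min_arm=4, max_loop=20, min_arm_identity=0.75)
    arms = [h.arm_length for h in hits]
    assert arms == sorted(arms, reverse=True)
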