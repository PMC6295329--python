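"""Type I template, gene-order extraction, and rearrangement classification."""

import numpy as np
import pytest

from mitocr import (GeneFeature, MitoGenome, NucSequence, canonical_type1_order,
                    classify_rearrangement, extract_gene_order, type_census)
from mitocr.gene_order import GeneOrder
from mitocr.synthetic_data import (TYPE_EVENTS, apply_block_duplication,
                                   apply_deletion, apply_duplication,
                                   apply_extra_OL, apply_translocation,
                                   order_for_type)


def genes_only(order):
    return [(l, s) for l, s in order.tokens if l not in ("OL", "CR")]


def test_template_has_37_genes_plus_ol_and_cr():
    order = canonical_type1_order()
    assert len(order) == 39
    assert len(genes_only(order)) == 37


def test_template_strand_counts_28_heavy_9_light():
    counts = {"H": 0, "L": 0}
    for _, strand in genes_only(canonical_type1_order()):
        counts[strand] += 1
    assert counts == {"H": 28, "L": 9}


def test_cr_is_flanked_by_trnp_and_trnf():
    labels = canonical_type1_order().labels()
    i = labels.index("CR")
    assert labels[i - 1] == "trnP"
    assert labels[(i + 1) % len(labels)] == "trnF"


def test_wancy_cluster_contains_ol():
    labels = canonical_type1_order().labels()
    i = labels.index("trnW")
    assert labels[i:i + 6] == ("trnW", "trnA", "trnN", "OL", "trnC", "trnY")


def test_template_classifies_as_type_I_with_no_events():
    call = classify_rearrangement(canonical_type1_order())
    assert call.type == "I" and call.events == ()


@pytest.mark.parametrize("order_type, kinds", [
    ("II", {"duplication"}),
    ("III", {"extra_OL"}),
    ("IV", {"translocation"}),
    ("V", {"deletion"}),
    ("VI", {"duplication"}),
])
def test_each_defined_event_is_inverted_by_classifier(order_type, kinds):
    call = classify_rearrangement(order_for_type(order_type))
    assert call.type == order_type
    assert {k for k, _ in call.events} == kinds


def test_only_the_template_maps_to_type_I():
    for t in ("II", "III", "IV", "V", "VI"):
        assert classify_rearrangement(order_for_type(t)).type != "I"


def test_trne_deletion_gives_length_38_order():
    order = apply_deletion(canonical_type1_order(), "trnE")
    assert len(order) == 38
    assert classify_rearrangement(order).type == "V"


def test_compound_rearrangement_is_novel_not_silently_typed():
    order = apply_extra_OL(canonical_type1_order())
    order = apply_deletion(order, "trnE")
    assert classify_rearrangement(order).type == "novel"


def test_unknown_labels_are_flagged_and_ignored():
    toks = tuple(("unknown", s) if l == "ND3" else (l, s)
                 for l, s in canonical_type1_order().tokens)
    call = classify_rearrangement(GeneOrder(toks))
    assert "unknown-labels-ignored" in call.flags
    assert call.type == "novel"  # ND3 now appears deleted


def test_extraction_is_rotation_invariant_on_toy_genome():
    labels = ["trnF", "ND1", "trnP", "CR", "trnW", "COI"]
    feats = [GeneFeature(l, i * 40, (i + 1) * 40) for i, l in enumerate(labels)]
    g = MitoGenome(NucSequence("toy", "ACGT" * 60, circular=True), feats)
    base = extract_gene_order(g)
    for off in range(0, 240, 40):
        assert extract_gene_order(g.rotated(off)).tokens == base.tokens


def test_extraction_without_trnf_warns_and_anchors_on_first_feature():
    feats = [GeneFeature("ND1", 0, 40), GeneFeature("COI", 40, 80)]
    g = MitoGenome(NucSequence("toy", "ACGT" * 20, circular=True), feats)
    with pytest.warns(UserWarning):
        order = extract_gene_order(g)
    assert order.labels() == ("ND1", "COI")


def test_classification_is_rotation_invariant_for_all_types():
    for t in ("I", "II", "III", "IV", "V", "VI"):
        toks = order_for_type(t).tokens
        calls = {classify_rearrangement(GeneOrder(toks[i:] + toks[:i])).type
                 for i in range(len(toks))}
        assert calls == {t}


def test_classifier_round_trip_on_randomized_instances():
    """Forward-simulate each event class with random parameters and random
    rotations; the classifier must recover the generating type every time."""
    rng = np.random.default_rng(7)
    template = canonical_type1_order()
    block_labels = ["ND4", "trnH", "trnS(AGY)", "trnL(CUN)", "ND5", "ND6",
                    "trnE", "Cytb", "trnT", "trnP"]
    n_per_type = 25  # the full 100-per-type sweep runs in the acceptance suite
    for t in ("I", "II", "III", "IV", "V", "VI"):
        for _ in range(n_per_type):
            if t == "III":
                order = apply_extra_OL(template, n=int(rng.integers(1, 4)))
            elif t == "VI":
                i = int(rng.integers(0, len(block_labels)))
                j = int(rng.integers(i, len(block_labels)))
                order = apply_block_duplication(template, block_labels[i], block_labels[j])
            else:
                order = order_for_type(t)
            toks = order.tokens
            k = int(rng.integers(0, len(toks)))
            assert classify_rearrangement(GeneOrder(toks[k:] + toks[:k])).type == t


def test_census_counts_and_percentages():
    calls = [classify_rearrangement(canonical_type1_order()) for _ in range(4)]
    census = type_census(calls)
    assert census == {"I": {"count": 4, "percent": 100.0}}


def test_census_on_published_cohort_distribution():
    """25 of the 30 surveyed gecko mitogenomes carry the canonical order."""
    types = ["I"] * 25 + ["II", "III", "IV", "V", "VI"]
    from mitocr.gene_order import RearrangementCall
    census = type_census([RearrangementCall(t) for t in types])
    assert census["I"]["count"] == 25
    assert census["I"]["percent"] == 83.3
    assert sum(v["count"] for v in census.values()) == 30


def test_census_empty_rejected():
    with pytest.raises(ValueError):
        type_census([])


def test_event_operators_are_pure():
    template = canonical_type1_order()
    before = template.tokens
    apply_deletion(template, "trnE")
    apply_duplication(template, ("trnQ", "ND4"))
    apply_translocation(template, "trnE", "trnP")
    assert template.tokens == before
    with pytest.raises(ValueError):
        apply_deletion(template, "nonexistent")
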