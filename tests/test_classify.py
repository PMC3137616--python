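import itertools

import numpy as np
import pandas as pd
import pytest

from trimevol.classify import (
    DomainVocabularyError,
    call_like_variants,
    classify_architecture,
    classify_table,
    detect_novel_combinations,
)


@pytest.mark.parametrize(
    "domains,expected_class",
    [
        (["RING", "BBOX", "CC", "B30.2"], "IV"),
        (["RING", "BBOX", "CC"], "V"),
        (["RING", "BBOX", "CC", "COS", "FN3", "B30.2"], "I"),
        (["RING", "BBOX", "CC", "COS"], "II"),
        (["RING", "BBOX", "CC", "COS", "FN3"], "III"),
        (["RING", "BBOX", "CC", "PHD", "BROMO"], "VI"),
        (["RING", "BBOX", "CC", "FILAMIN", "NHL"], "VII"),
        (["RING", "BBOX", "CC", "MATH"], "VIII"),
        (["RING", "BBOX", "CC", "ARF"], "IX"),
    ],
)
def test_canonical_architectures(domains, expected_class):
    call = classify_architecture("p", domains)
    assert call.trim_class == expected_class
    assert "novel_combination" not in call.flags


def test_non_trim_without_ring_or_bbox():
    assert classify_architecture("p", ["FN3"]).trim_class == "non-TRIM"
    assert classify_architecture("p", []).trim_class == "non-TRIM"
    call = classify_architecture("p", ["B30.2"])
    assert call.trim_class == "non-TRIM"  # B30.2-only is not counted as class IV
    assert "B30.2_only" in call.flags


def test_ring_tm_b302_is_class_iv_candidate_with_flags():
    call = classify_architecture("btr31", ["RING", "TM", "B30.2"])
    assert call.trim_class == "IV"
    assert {"missing_BBOX", "missing_CC", "novel_combination"} <= call.flags


def test_incomplete_rbcc_still_classified():
    call = classify_architecture("p", ["BBOX", "CC", "B30.2"])
    assert call.trim_class == "IV"
    assert "missing_RING" in call.flags


def test_unknown_token_rejected():
    with pytest.raises(DomainVocabularyError):
        classify_architecture("p", ["RING", "WD40"])


def test_classification_depends_only_on_start_sorted_order():
    rows = [("B30.2", 300, 400), ("RING", 10, 60), ("CC", 150, 200), ("BBOX", 70, 110)]
    calls = {
        classify_architecture("p", list(perm)).architecture
        for perm in itertools.permutations(rows)
    }
    assert calls == {"RING,BBOX,CC,B30.2"}


def test_novel_combination_report_names_known_patterns():
    table = pd.DataFrame(
        [
            ("ftr06", "RING", 1, 50),
            ("ftr06", "BBOX", 60, 100),
            ("ftr06", "CC", 120, 180),
            ("ftr06", "CHROMO", 200, 260),
            ("ftr52", "RING", 1, 50),
            ("ftr52", "BBOX", 60, 100),
            ("ftr52", "CC", 120, 180),
            ("ftr52", "RANBD", 200, 300),
            ("ftr52", "CYPA", 310, 420),
            ("btr31", "RING", 1, 50),
            ("btr31", "TM", 60, 90),
            ("btr31", "B30.2", 100, 280),
            ("trim1", "RING", 1, 50),
            ("trim1", "BBOX", 60, 100),
            ("trim1", "CC", 120, 180),
            ("trim1", "B30.2", 200, 380),
        ],
        columns=["protein_id", "domain", "start", "end"],
    )
    calls = classify_table(table)
    report = detect_novel_combinations(calls)
    patterns = dict(zip(report["architecture"], report["pattern"]))
    assert patterns["RING,BBOX,CC,CHROMO"] == "chromodomain_gain"
    assert patterns["RING,BBOX,CC,RANBD,CYPA"] == "cypA_gain"
    assert patterns["RING,TM,B30.2"] == "ring_tm_b30.2"
    assert "RING,BBOX,CC,B30.2" not in patterns  # canonical input not reported


def test_canonical_only_input_gives_empty_novel_report():
    calls = [classify_architecture("p1", ["RING", "BBOX", "CC", "B30.2"])]
    assert len(detect_novel_combinations(calls)) == 0


def _identity_frame(ids, values):
    return pd.DataFrame(values, index=ids, columns=ids)


def test_like_variant_pairing_above_and_below_threshold():
    calls = [
        classify_architecture("full", ["RING", "BBOX", "CC", "B30.2"]),
        classify_architecture("trunc", ["RING", "BBOX", "CC"]),
        classify_architecture("far", ["RING", "BBOX", "CC"]),
    ]
    idm = _identity_frame(
        ["full", "trunc", "far"],
        [[1.0, 0.92, 0.30], [0.92, 1.0, 0.28], [0.30, 0.28, 1.0]],
    )
    pairs, ties = call_like_variants(calls, idm, threshold=0.7)
    assert pairs == [("trunc", "full")]
    assert not ties
    by_id = {c.protein_id: c for c in calls}
    assert "like_variant" in by_id["trunc"].flags
    assert "like_variant" not in by_id["far"].flags  # 0.30 < threshold


def test_like_variant_tie_break_matches_exhaustive_enumeration():
    rng = np.random.default_rng(8)
    full_ids = ["fullB", "fullA", "fullC"]
    calls = [
        classify_architecture(f, ["RING", "BBOX", "CC", "B30.2"]) for f in full_ids
    ] + [classify_architecture("trunc", ["RING", "BBOX", "CC"])]
    ids = full_ids + ["trunc"]
    vals = np.eye(4)
    sims = [0.9, 0.9, 0.4]  # tie between fullB and fullA
    for i, s in enumerate(sims):
        vals[i, 3] = vals[3, i] = s
    idm = _identity_frame(ids, vals)
    pairs, ties = call_like_variants(calls, idm, threshold=0.7)
    # oracle: enumerate all (candidate, similarity) pairs, keep max, smallest id
    best = max(s for s in sims)
    expected = sorted(f for f, s in zip(full_ids, sims) if s == best)[0]
    assert pairs == [("trunc", expected)]
    assert ties and ties[0][0] == "trunc"


def test_asymmetric_identity_matrix_rejected():
    calls = [classify_architecture("a", ["RING", "BBOX", "CC"])]
    idm = _identity_frame(["a", "b"], [[1.0, 0.5], [0.4, 1.0]])
    with pytest.raises(ValueError):
        call_like_variants(calls, idm)
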