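"""Applied/basic classification rule and its all-or-nothing propagation."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exclink import ResearchClass, classify_entity, classify_publication
from exclink.classify import ClassificationError, classify_publications


@pytest.mark.parametrize(
    "drug_ids, target_ids, expected",
    [
        ({"D1"}, set(), ResearchClass.APPLIED),
        (set(), {"T1"}, ResearchClass.BASIC),
        # a drug match dominates any simultaneous target match
        ({"D1"}, {"T1"}, ResearchClass.APPLIED),
    ],
)
def test_publication_rule(drug_ids, target_ids, expected):
    assert classify_publication(drug_ids, target_ids) is expected


def test_publication_with_no_match_is_an_error():
    with pytest.raises(ClassificationError):
        classify_publication(set(), set())


@pytest.mark.parametrize(
    "classes, expected",
    [
        ([ResearchClass.BASIC, ResearchClass.BASIC], ResearchClass.BASIC),
        ([ResearchClass.BASIC, ResearchClass.APPLIED], ResearchClass.APPLIED),
        ([ResearchClass.APPLIED], ResearchClass.APPLIED),
        (["basic", "applied"], ResearchClass.APPLIED),  # string values accepted
    ],
)
def test_entity_fold(classes, expected):
    assert classify_entity(classes) is expected


def test_entity_with_no_publications_is_an_error():
    with pytest.raises(ClassificationError):
        classify_entity([])


@given(st.lists(st.sampled_from([ResearchClass.APPLIED, ResearchClass.BASIC]), min_size=1))
@settings(deadline=None)
def test_entity_fold_is_basic_iff_all_basic(classes):
    folded = classify_entity(classes)
    if all(c is ResearchClass.BASIC for c in classes):
        assert folded is ResearchClass.BASIC
    else:
        assert folded is ResearchClass.APPLIED


@given(st.lists(st.sampled_from([ResearchClass.APPLIED, ResearchClass.BASIC]), min_size=1))
@settings(deadline=None)
def test_adding_an_applied_publication_never_flips_to_basic(classes):
    before = classify_entity(classes)
    after = classify_entity(classes + [ResearchClass.APPLIED])
    assert after is ResearchClass.APPLIED
    assert not (before is ResearchClass.APPLIED and after is ResearchClass.BASIC)


def test_vectorised_classification_matches_scalar_rule():
    pubs = pd.DataFrame(
        {
            "pmid": ["P1", "P2", "P3"],
            "matched_drug_ids": [frozenset({"D1"}), frozenset(), frozenset({"D1"})],
            "matched_target_ids": [frozenset(), frozenset({"T1"}), frozenset({"T1"})],
        }
    )
    classes = classify_publications(pubs)
    assert classes.tolist() == ["applied", "basic", "applied"]
    assert classes.index.tolist() == ["P1", "P2", "P3"]
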