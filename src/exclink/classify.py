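"""Applied/basic research classification and its propagation.

A publication found by a drug-name search is *applied research*; one found
only by a target search is *basic research*. The label propagates upward by
an all-or-nothing rule: a project year, project, or patent is basic only if
every publication in its evidence set is basic — a single applied
publication makes the whole entity applied.
"""

from __future__ import annotations

from typing import Collection, Iterable

import pandas as pd

from .model import ResearchClass


class ClassificationError(ValueError):
    pass


def classify_publication(
    matched_drug_ids: Collection[str], matched_target_ids: Collection[str]
) -> ResearchClass:
    """Class of a single publication from its search provenance.

    Applied iff the drug-name search matched (regardless of any target
    match); basic iff only a target search matched.
    """
    if matched_drug_ids:
        return ResearchClass.APPLIED
    if matched_target_ids:
        return ResearchClass.BASIC
    raise ClassificationError("publication matched neither a drug nor a target search")


def classify_publications(publications: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_publication` over the publications table.

    Returns a Series of class *values* ("applied"/"basic") indexed by pmid.
    """
    empty_both = (publications["matched_drug_ids"].map(len) == 0) & (
        publications["matched_target_ids"].map(len) == 0
    )
    if empty_both.any():
        bad = publications.loc[empty_both, "pmid"].head(10).tolist()
        raise ClassificationError(f"publications with no search match: {bad}")
    is_applied = publications["matched_drug_ids"].map(len) > 0
    out = pd.Series(
        pd.Series(is_applied).map(
            {True: ResearchClass.APPLIED.value, False: ResearchClass.BASIC.value}
        ).values,
        index=publications["pmid"].values,
        name="research_class",
    )
    out.index.name = "pmid"
    return out


def classify_entity(pmid_classes: Iterable[ResearchClass | str]) -> ResearchClass:
    """Fold publication classes onto an owning entity.

    Basic iff *all* associated publications are basic; any applied
    publication forces applied. An empty evidence set is an error: an entity
    with no associated publications has no research class.
    """
    seen = False
    for c in pmid_classes:
        seen = True
        value = c.value if isinstance(c, ResearchClass) else c
        if value == ResearchClass.APPLIED.value:
            return ResearchClass.APPLIED
        if value != ResearchClass.BASIC.value:
            raise ClassificationError(f"unknown research class: {c!r}")
    if not seen:
        raise ClassificationError("cannot classify an entity with no publications")
    return ResearchClass.BASIC
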