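"""Mobile-genetic-element evidence for retained hits.

Spacers derive from past invaders, so only hits attributable to an MGE are
biologically meaningful for PAM inference. Three evidence routes are checked
in fixed precedence order:

1. subject title contains a keyword (default: phage, plasmid);
2. the hit overlaps a predicted prophage interval;
3. an overlapping feature annotation contains a keyword
   (default: transposase, phage, integrase, terminase).

Keyword matching is substring and case-insensitive (so "prophage" matches
"phage"); overlap means at least one shared base of half-open intervals.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .model import GenomeRecord
from .search import MgeEvidence, SpacerHit

log = logging.getLogger(__name__)

TITLE_KEYWORDS = frozenset({"phage", "plasmid"})
FEATURE_KEYWORDS = frozenset({"transposase", "phage", "integrase", "terminase"})


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_hit(
    hit: SpacerHit,
    subject: GenomeRecord,
    keywords_title: Iterable[str] = TITLE_KEYWORDS,
    keywords_feature: Iterable[str] = FEATURE_KEYWORDS,
    keyword_set_version: str = "default",
) -> MgeEvidence:
    """Evaluate the three evidence routes in order; first success wins."""
    title = subject.title.lower()
    for kw in sorted(keywords_title):
        if kw.lower() in title:
            return MgeEvidence("title_keyword", kw, keyword_set_version)
    for interval in subject.prophage_intervals:
        if _overlap(hit.interval, interval):
            return MgeEvidence(
                "prophage_interval", f"[{interval[0]},{interval[1]})",
                keyword_set_version,
            )
    for feat in subject.features:
        if _overlap(hit.interval, (feat.start, feat.end)):
            label = feat.label.lower()
            for kw in sorted(keywords_feature):
                if kw.lower() in label:
                    return MgeEvidence("feature_keyword", kw, keyword_set_version)
    return MgeEvidence("none", "", keyword_set_version)


def filter_mge_hits(
    hits: Sequence[SpacerHit],
    subjects: Sequence[GenomeRecord],
    keywords_title: Iterable[str] = TITLE_KEYWORDS,
    keywords_feature: Iterable[str] = FEATURE_KEYWORDS,
) -> tuple[list[SpacerHit], list[SpacerHit]]:
    """Partition hits into (kept with evidence set, discarded), order preserved."""
    by_id = {r.id: r for r in subjects}
    kept, discarded = [], []
    for hit in hits:
        subject = by_id.get(hit.subject_id)
        if subject is None:
            raise ValueError(f"hit references unknown subject {hit.subject_id!r}")
        hit.mge = classify_hit(hit, subject, keywords_title, keywords_feature)
        if hit.mge.category == "none":
            log.info("hit %s@%s%s dropped: not_mge", hit.spacer_id,
                     hit.subject_id, hit.interval)
            discarded.append(hit)
        else:
            kept.append(hit)
    return kept, discarded
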