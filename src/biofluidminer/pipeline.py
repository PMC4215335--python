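"""End-to-end orchestration of the mining stages for one or more pairs.

The flow per disease–biofluid pair is: parse the positive and negative
MEDLINE corpora, clean the text, tag entity mentions (dictionary matching,
or an externally produced tagged-SGML file), normalize mentions to consensus
symbols, compute document frequencies and z-scores, apply the significance
threshold, and — when a known-marker list is supplied — partition the
significant markers into known and new and summarize the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import corpus as corpus_io
from . import entities, scoring, verification

__all__ = ["PairResult", "score_pair"]


@dataclass
class PairResult:
    """All outputs of the pipeline for one disease–biofluid pair."""

    disease: str
    biofluid: str
    pair: corpus_io.CorpusPair
    records: list[scoring.ScoreRecord]
    stats: scoring.ScoreSetStats
    significant: list[scoring.ScoreRecord]
    summary: verification.BiofluidResultSummary | None = None
    known_significant: set[str] = field(default_factory=set)
    new_significant: set[str] = field(default_factory=set)
    #: record counts at each stage, for logging
    stage_counts: dict[str, int] = field(default_factory=dict)


def _tag_records(
    records,
    dictionary: entities.EntityDictionary,
    tagger: str,
    sgml_text: str | None,
    include_title: bool,
) -> list[entities.Mention]:
    if tagger == "sgml":
        if sgml_text is None:
            raise ValueError("tagger 'sgml' requires a tagged SGML input")
        mentions = entities.parse_abner_corpus(sgml_text)
        return entities.filter_entity_classes(mentions)
    if tagger == "dictionary":
        out: list[entities.Mention] = []
        for rec in records:
            out.extend(
                entities.dictionary_match(rec, dictionary, include_title=include_title)
            )
        return out
    raise ValueError(f"unknown tagger {tagger!r} (expected 'sgml' or 'dictionary')")


def score_pair(
    s1_text: str,
    s2_text: str,
    dictionary: entities.EntityDictionary,
    known: verification.KnownMarkerList | None = None,
    tagger: str = "dictionary",
    sgml_s1: str | None = None,
    sgml_s2: str | None = None,
    tau: float = scoring.DEFAULT_TAU,
    disease: str = "",
    biofluid: str = "",
    include_title: bool = True,
) -> PairResult:
    """Run the full pipeline on one pair of MEDLINE corpus texts."""
    parsed1 = corpus_io.parse_medline(
        s1_text, corpus_io.SetLabel.POSITIVE, disease, biofluid
    )
    parsed2 = corpus_io.parse_medline(
        s2_text, corpus_io.SetLabel.NEGATIVE, disease, biofluid
    )
    s1 = [corpus_io.clean_text(r) for r in parsed1.records]
    s2 = [corpus_io.clean_text(r) for r in parsed2.records]
    pair = corpus_io.assemble_corpus_pair(s1, s2, disease, biofluid)

    m1 = _tag_records(pair.s1, dictionary, tagger, sgml_s1, include_title)
    m2 = _tag_records(pair.s2, dictionary, tagger, sgml_s2, include_title)
    norm1 = entities.normalize_mentions(m1, dictionary)
    norm2 = entities.normalize_mentions(m2, dictionary)

    freqs = scoring.count_document_frequencies(
        norm1.mentions, norm2.mentions, pair
    )
    records, stats = scoring.score_markers(freqs, pair.n1, pair.n2)
    significant = scoring.apply_threshold(records, tau)

    result = PairResult(
        disease=disease,
        biofluid=biofluid,
        pair=pair,
        records=records,
        stats=stats,
        significant=significant,
        stage_counts={
            "s1_parsed": len(parsed1.records),
            "s1_skipped": parsed1.n_skipped,
            "s2_parsed": len(parsed2.records),
            "s2_skipped": parsed2.n_skipped,
            "s2_duplicates_removed": pair.n_duplicates_removed,
            "s1_mentions": len(m1),
            "s2_mentions": len(m2),
            "s1_mentions_dropped": norm1.n_dropped,
            "s2_mentions_dropped": norm2.n_dropped,
            "markers_scored": len(records),
            "markers_significant": len(significant),
        },
    )
    if known is not None:
        sig_symbols = {r.symbol for r in significant}
        known_sig, new_sig = verification.partition_significant(sig_symbols, known)
        result.known_significant = known_sig
        result.new_significant = new_sig
        result.summary = verification.summarize_pair(
            disease,
            biofluid,
            scored_symbols=(r.symbol for r in records),
            significant_symbols=sig_symbols,
            known=known,
        )
    return result
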