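"""Synthetic MEDLINE corpora with controlled marker-mention probabilities.

The generator emulates the statistical structure the scoring model assumes:
each marker is mentioned in a positive-set abstract with per-abstract
probability ``p1`` and in a negative-set abstract with probability ``p2``.
An enriched marker has p1 >> p2; background markers have p1 = p2.  When a
marker is mentioned in an abstract it is injected 1–3 times, which exercises
the count-once-per-abstract rule downstream.  Filler text is drawn from a
background vocabulary that includes decoy near-miss tokens (substrings of
marker aliases) to exercise token-boundary matching.

Everything is deterministic under the config seed, and a ground-truth
manifest records the realized document frequencies and every injected
mention with its character span, so parsers, taggers and the scoring
pipeline can all be checked against known truth.

No attempt is made to mimic natural-language syntax, MeSH indexing, or
realistic abstract-length distributions.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import AbstractRecord, SetLabel, serialize_medline
from .entities import DictionaryEntry, EntityDictionary
from .scoring import DegenerateScoreSetError

__all__ = [
    "MarkerSpec",
    "SyntheticCorpusConfig",
    "InjectedMention",
    "GroundTruthManifest",
    "SyntheticCorpus",
    "default_background_vocab",
    "generate_corpus",
    "generate_sgml",
    "end_to_end_expected_scores",
    "recovery_design",
]


@dataclass(frozen=True)
class MarkerSpec:
    """One synthetic marker: consensus symbol, aliases, mention probabilities."""

    symbol: str
    p1: float
    p2: float
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2):
            if not 0.0 <= p <= 1.0:
                raise ValueError("mention probabilities must lie in [0, 1]")

    @property
    def surfaces(self) -> tuple[str, ...]:
        return (self.symbol, *self.aliases)


def default_background_vocab() -> tuple[str, ...]:
    """Filler tokens, including decoy substrings of typical marker aliases."""
    return (
        "patients", "levels", "measured", "samples", "analysis", "clinical",
        "study", "cohort", "expression", "significant", "elevated", "control",
        "detected", "assay", "protein", "results", "observed", "compared",
        "increase", "decrease", "diagnostic", "candidate", "screening",
        "concentration", "followup", "baseline", "prospective", "biopsy",
        # decoys: near-miss substrings that must NOT match at token level
        "brca", "mk1", "bg", "cea1x", "her",
    )


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Generation parameters for one positive/negative corpus pair."""

    n1: int
    n2: int
    markers: tuple[MarkerSpec, ...]
    seed: int
    background_vocab: tuple[str, ...] = field(default_factory=default_background_vocab)
    disease: str = "breast cancer"
    biofluid: str = "serum"
    tokens_per_abstract: tuple[int, int] = (25, 50)

    def __post_init__(self) -> None:
        if self.n1 < 1:
            raise ValueError("n1 must be >= 1 (the positive set cannot be empty)")
        if self.n2 < 0:
            raise ValueError("n2 must be >= 0")
        if not self.background_vocab:
            raise ValueError("background vocabulary must be non-empty")

    def dictionary(self) -> EntityDictionary:
        """Entity dictionary covering exactly the configured markers."""
        entries = [
            DictionaryEntry(
                hprd_id=f"{i + 1:05d}",
                symbol=m.symbol,
                refseq_id=f"NM_{i + 1:06d}",
                aliases=m.aliases,
            )
            for i, m in enumerate(self.markers)
        ]
        return EntityDictionary(entries=entries)


@dataclass(frozen=True)
class InjectedMention:
    """Ground truth for one injected marker occurrence (span in the body)."""

    pmid: str
    symbol: str
    surface: str
    start: int
    end: int


@dataclass
class GroundTruthManifest:
    """Realized counts and injection sites for a generated corpus pair."""

    df1: dict[str, int]
    df2: dict[str, int]
    mentions_by_pmid: dict[str, list[InjectedMention]]
    sp: set[str]

    def dft(self, symbol: str) -> int:
        return self.df1.get(symbol, 0) + self.df2.get(symbol, 0)

    def all_mentions(self) -> list[InjectedMention]:
        out: list[InjectedMention] = []
        for pmid in self.mentions_by_pmid:
            out.extend(self.mentions_by_pmid[pmid])
        return out

    def to_json(self) -> str:
        payload = {
            "df1": self.df1,
            "df2": self.df2,
            "sp": sorted(self.sp),
            "mentions": [
                {
                    "pmid": m.pmid,
                    "symbol": m.symbol,
                    "surface": m.surface,
                    "start": m.start,
                    "end": m.end,
                }
                for m in self.all_mentions()
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticCorpus:
    """A generated corpus pair plus its ground truth."""

    config: SyntheticCorpusConfig
    s1: list[AbstractRecord]
    s2: list[AbstractRecord]
    manifest: GroundTruthManifest

    def medline_s1(self) -> str:
        return serialize_medline(self.s1)

    def medline_s2(self) -> str:
        return serialize_medline(self.s2)


def _make_abstract(
    rng: random.Random,
    config: SyntheticCorpusConfig,
    pmid: str,
    label: SetLabel,
) -> tuple[AbstractRecord, list[InjectedMention]]:
    lo, hi = config.tokens_per_abstract
    n_tokens = rng.randint(lo, hi)
    # slots hold either a filler string or a (surface, symbol) injection
    slots: list[object] = [rng.choice(config.background_vocab) for _ in range(n_tokens)]
    for marker in config.markers:
        p = marker.p1 if label is SetLabel.POSITIVE else marker.p2
        if rng.random() < p:
            for _ in range(rng.randint(1, 3)):
                surface = rng.choice(marker.surfaces)
                pos = rng.randint(0, len(slots))
                slots.insert(pos, (surface, marker.symbol))
    body_parts: list[str] = []
    mentions: list[InjectedMention] = []
    offset = 0
    for slot in slots:
        if body_parts:
            offset += 1  # joining space
        if isinstance(slot, tuple):
            surface, symbol = slot
            mentions.append(
                InjectedMention(
                    pmid=pmid,
                    symbol=symbol,
                    surface=surface,
                    start=offset,
                    end=offset + len(surface),
                )
            )
            body_parts.append(surface)
            offset += len(surface)
        else:
            body_parts.append(slot)
            offset += len(slot)
    title_tokens = [rng.choice(config.background_vocab) for _ in range(4)]
    record = AbstractRecord(
        pmid=pmid,
        title=" ".join(title_tokens),
        body=" ".join(body_parts),
        set_label=label,
        disease=config.disease,
        biofluid=config.biofluid,
    )
    return record, mentions


def generate_corpus(config: SyntheticCorpusConfig) -> SyntheticCorpus:
    """Generate the S1/S2 corpora and their ground-truth manifest.

    Per abstract and marker, one Bernoulli draw (p1 in S1, p2 in S2) decides
    whether the marker is mentioned; a mentioned marker is injected 1–3
    times at random token positions.  Output is byte-identical for a fixed
    seed.
    """
    rng = random.Random(config.seed)
    df1: dict[str, int] = {}
    df2: dict[str, int] = {}
    mentions_by_pmid: dict[str, list[InjectedMention]] = {}

    def build_set(n: int, label: SetLabel, pmid_base: int) -> list[AbstractRecord]:
        records = []
        df = df1 if label is SetLabel.POSITIVE else df2
        for i in range(n):
            pmid = str(pmid_base + i)
            record, mentions = _make_abstract(rng, config, pmid, label)
            records.append(record)
            if mentions:
                mentions_by_pmid[pmid] = mentions
            for symbol in {m.symbol for m in mentions}:
                df[symbol] = df.get(symbol, 0) + 1
        return records

    s1 = build_set(config.n1, SetLabel.POSITIVE, 1_000_001)
    s2 = build_set(config.n2, SetLabel.NEGATIVE, 2_000_001)
    manifest = GroundTruthManifest(
        df1=df1, df2=df2, mentions_by_pmid=mentions_by_pmid, sp=set(df1)
    )
    return SyntheticCorpus(config=config, s1=s1, s2=s2, manifest=manifest)


def generate_sgml(corpus: SyntheticCorpus, which: str = "s1") -> str:
    """Render one generated set in the tagged-SGML dialect.

    Every injected marker surface is wrapped in ``<PROTEIN>`` tags at its
    recorded span; filler text is untouched.  Documents are blank-line
    separated blocks headed by a ``PMID- <id>`` line, matching what
    :func:`biofluidminer.entities.parse_abner_corpus` consumes.
    """
    records = corpus.s1 if which == "s1" else corpus.s2
    blocks: list[str] = []
    for rec in records:
        mentions = sorted(
            corpus.manifest.mentions_by_pmid.get(rec.pmid, []),
            key=lambda m: m.start,
        )
        parts: list[str] = []
        cursor = 0
        for m in mentions:
            parts.append(rec.body[cursor : m.start])
            parts.append(f"<PROTEIN>{rec.body[m.start:m.end]}</PROTEIN>")
            cursor = m.end
        parts.append(rec.body[cursor:])
        blocks.append(f"PMID- {rec.pmid}\n{''.join(parts)}")
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def end_to_end_expected_scores(
    manifest: GroundTruthManifest, config: SyntheticCorpusConfig
) -> dict[str, dict[str, float]]:
    """Independent straight-line scoring of the manifest counts.

    Recomputes ex/ev/f/z for every Sp member directly from the manifest's
    realized document frequencies using nothing but arithmetic, for oracle
    comparison with the scoring pipeline.  Raises
    :class:`DegenerateScoreSetError` when every f is identical, and
    ``ValueError`` for fewer than two Sp members — the same error contract
    as the pipeline.
    """
    symbols = sorted(manifest.sp)
    if len(symbols) < 2:
        raise ValueError("z-scores require at least 2 markers in Sp")
    n1, n2 = config.n1, config.n2
    rows: dict[str, dict[str, float]] = {}
    f_values: list[float] = []
    for s in symbols:
        df1 = manifest.df1.get(s, 0)
        df2 = manifest.df2.get(s, 0)
        dft = df1 + df2
        ex = dft / (n1 + n2) * n1
        ev = df1
        f = (ev - ex) / dft
        rows[s] = {"df1": df1, "df2": df2, "dft": dft, "ex": ex, "ev": ev, "f": f}
        f_values.append(f)
    mean_f = sum(f_values) / len(f_values)
    sd_f = math.sqrt(
        sum((v - mean_f) ** 2 for v in f_values) / (len(f_values) - 1)
    )
    if sd_f == 0.0:
        raise DegenerateScoreSetError(
            "all f values are identical (SD = 0); z-scores are undefined"
        )
    for s in symbols:
        rows[s]["z"] = (rows[s]["f"] - mean_f) / sd_f
    return rows


def recovery_design(
    seed: int,
    n1: int = 200,
    n2: int = 2000,
    p1_enriched: float = 0.3,
    p2_enriched: float = 0.001,
    n_background: int = 10,
    p_background: float = 0.01,
) -> SyntheticCorpusConfig:
    """The standard parameter-recovery design.

    One enriched marker mentioned with per-abstract probability
    ``p1_enriched`` in S1 versus ``p2_enriched`` in S2, against
    ``n_background`` background markers mentioned equally often
    (``p_background``) in both sets.  A correct scoring pipeline should
    flag the enriched marker as significant in nearly every replicate while
    background markers stay non-significant.
    """
    markers = [
        MarkerSpec(
            symbol="MARKER1",
            p1=p1_enriched,
            p2=p2_enriched,
            aliases=("mk1-alias",),
        )
    ]
    markers.extend(
        MarkerSpec(symbol=f"BG{i + 1:02d}", p1=p_background, p2=p_background)
        for i in range(n_background)
    )
    return SyntheticCorpusConfig(
        n1=n1, n2=n2, markers=tuple(markers), seed=seed
    )
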