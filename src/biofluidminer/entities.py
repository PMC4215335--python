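"""Named-entity mentions and their normalization to consensus gene symbols.

Two taggers are supported:

* an SGML reader for the output dialect of external biomedical NER taggers
  that wrap entity spans in inline tags naming one of five classes
  (``PROTEIN``, ``DNA``, ``RNA``, ``CELL_LINE``, ``CELL_TYPE``); and
* a bundled dictionary (gazetteer) tagger that matches alias occurrences at
  token boundaries, case-insensitively, longest-match-first.

Aliases come from a protein-nomenclature dictionary whose rows carry an id,
a gene symbol, a RefSeq id and a semicolon-separated alias list.  The gene
symbol is the *consensus* name: every alias hit is counted under it.  An
alias shared by several entries (e.g. ``CEA`` carried by both CEACAM5 and
CEACAM8) fans out to every symbol; the resulting double counting is retained
deliberately, since it cannot be resolved from the mention alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

from .corpus import AbstractRecord

__all__ = [
    "EntityClass",
    "DEFAULT_KEEP_CLASSES",
    "Mention",
    "NormalizedMention",
    "NormalizationResult",
    "DictionaryEntry",
    "EntityDictionary",
    "SgmlParseError",
    "load_dictionary",
    "normalize_alias_text",
    "parse_abner_sgml",
    "parse_abner_corpus",
    "filter_entity_classes",
    "dictionary_match",
    "normalize_mentions",
    "write_mention_table",
]


class EntityClass(str, Enum):
    PROTEIN = "PROTEIN"
    DNA = "DNA"
    RNA = "RNA"
    CELL_LINE = "CELL_LINE"
    CELL_TYPE = "CELL_TYPE"


#: Classes retained by default: gene/protein-like entities only.
DEFAULT_KEEP_CLASSES = frozenset(
    {EntityClass.PROTEIN, EntityClass.DNA, EntityClass.RNA}
)


@dataclass(frozen=True)
class Mention:
    """One tagged entity occurrence.

    ``start``/``end`` delimit the surface in the untagged text of ``source``
    (0-based, half-open); ``source`` is ``"body"`` or ``"title"``.
    """

    pmid: str
    surface: str
    entity_class: EntityClass
    start: int
    end: int
    source: str = "body"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("mention span must be non-empty (end > start)")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class NormalizedMention:
    """A mention resolved to a consensus gene symbol."""

    pmid: str
    symbol: str
    source_surface: str
    entity_class: EntityClass


@dataclass
class NormalizationResult:
    """Normalized mentions plus the count of mentions with no dictionary hit."""

    mentions: list[NormalizedMention]
    n_dropped: int = 0

    def __iter__(self):
        return iter(self.mentions)

    def __len__(self) -> int:
        return len(self.mentions)


def normalize_alias_text(s: str) -> str:
    """Canonical alias form: lowercase, stripped, inner whitespace collapsed."""
    return " ".join(s.split()).lower()


@dataclass(frozen=True)
class DictionaryEntry:
    hprd_id: str
    symbol: str
    refseq_id: str = ""
    aliases: tuple[str, ...] = ()


@dataclass
class EntityDictionary:
    """Alias -> consensus-symbol dictionary with multi-mapping allowed."""

    entries: list[DictionaryEntry]
    alias_index: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.alias_index:
            index: dict[str, set[str]] = {}
            for entry in self.entries:
                for alias in (entry.symbol, *entry.aliases):
                    key = normalize_alias_text(alias)
                    if key:
                        index.setdefault(key, set()).add(entry.symbol)
            self.alias_index = {k: frozenset(v) for k, v in index.items()}

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(e.symbol for e in self.entries)

    def lookup(self, surface: str) -> frozenset[str]:
        return self.alias_index.get(normalize_alias_text(surface), frozenset())

    # compiled matcher is cached because CLI runs tag thousands of abstracts
    _matcher: re.Pattern | None = field(default=None, repr=False, compare=False)

    def matcher(self) -> re.Pattern:
        if self._matcher is None:
            aliases = sorted(self.alias_index, key=lambda a: (-len(a), a))
            parts = [re.escape(a).replace(r"\ ", r"\s+") for a in aliases]
            pattern = (
                r"(?<![0-9A-Za-z-])(?:" + "|".join(parts) + r")(?![0-9A-Za-z-])"
            )
            object.__setattr__(self, "_matcher", re.compile(pattern, re.IGNORECASE))
        return self._matcher


def load_dictionary(source: str | TextIO) -> EntityDictionary:
    """Load a protein-nomenclature dictionary file.

    Each line holds: id, gene symbol, RefSeq id, semicolon-separated aliases.
    Columns are tab-delimited; when a line contains no tab, runs of
    whitespace are accepted as delimiters.  The symbol itself is always
    indexed as one of its own aliases.
    """
    text = source.read() if hasattr(source, "read") else source
    entries: list[DictionaryEntry] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split(None, 3)
        cols = [c.strip() for c in cols]
        if len(cols) < 2 or not cols[0] or not cols[1]:
            raise ValueError(
                f"dictionary line {lineno}: expected at least 2 columns (id, symbol)"
            )
        alias_field = cols[3] if len(cols) > 3 else ""
        aliases = tuple(a.strip() for a in alias_field.split(";") if a.strip())
        entries.append(
            DictionaryEntry(
                hprd_id=cols[0],
                symbol=cols[1],
                refseq_id=cols[2] if len(cols) > 2 else "",
                aliases=aliases,
            )
        )
    return EntityDictionary(entries=entries)


class SgmlParseError(ValueError):
    """Raised on unbalanced or unknown tags in tagged-entity SGML."""


_TAG_RE = re.compile(r"<(/?)([A-Za-z_]+)>")


def parse_abner_sgml(text: str, pmid: str = "") -> list[Mention]:
    """Parse inline-tagged SGML text into mentions, in document order.

    Tags must be non-nested and balanced; spans are reported in the
    coordinates of the untagged text.  Tag names are matched
    case-insensitively against the five entity classes.
    """
    mentions: list[Mention] = []
    out: list[str] = []
    out_len = 0
    pos = 0
    open_tag: EntityClass | None = None
    open_start = 0
    for m in _TAG_RE.finditer(text):
        chunk = text[pos : m.start()]
        out.append(chunk)
        out_len += len(chunk)
        closing, name = m.group(1), m.group(2).upper()
        try:
            cls = EntityClass[name]
        except KeyError:
            raise SgmlParseError(
                f"unknown entity tag <{m.group(2)}> at offset {m.start()}"
            ) from None
        if not closing:
            if open_tag is not None:
                raise SgmlParseError(
                    f"nested <{name}> tag at offset {m.start()} (tags must not nest)"
                )
            open_tag = cls
            open_start = out_len
        else:
            if open_tag is not cls:
                raise SgmlParseError(
                    f"unbalanced </{name}> tag at offset {m.start()}"
                )
            surface = "".join(out)[open_start:]
            if not surface:
                raise SgmlParseError(f"empty <{name}> span at offset {m.start()}")
            mentions.append(
                Mention(
                    pmid=pmid,
                    surface=surface,
                    entity_class=cls,
                    start=open_start,
                    end=out_len,
                )
            )
            open_tag = None
        pos = m.end()
    if open_tag is not None:
        raise SgmlParseError(f"unclosed <{open_tag.value}> tag at end of text")
    return mentions


def parse_abner_corpus(source: str | TextIO) -> list[Mention]:
    """Parse a multi-document tagged SGML file.

    Documents are blank-line-separated blocks whose first line is
    ``PMID- <id>``; the remaining lines are the tagged abstract body.
    """
    text = source.read() if hasattr(source, "read") else source
    mentions: list[Mention] = []
    for block in re.split(r"\n\s*\n", text):
        if not block.strip():
            continue
        lines = block.strip("\n").splitlines()
        header = lines[0]
        if not header.startswith("PMID- "):
            raise SgmlParseError(
                f"document block must start with 'PMID- ', got {header[:20]!r}"
            )
        pmid = header[len("PMID- ") :].strip()
        body = " ".join(lines[1:])
        mentions.extend(parse_abner_sgml(body, pmid=pmid))
    return mentions


def filter_entity_classes(
    mentions: Iterable[Mention],
    keep: frozenset[EntityClass] | set[EntityClass] = DEFAULT_KEEP_CLASSES,
) -> list[Mention]:
    """Keep only mentions of the requested classes, order preserved."""
    return [m for m in mentions if m.entity_class in keep]


def dictionary_match(
    record: AbstractRecord,
    dictionary: EntityDictionary,
    include_title: bool = True,
) -> list[Mention]:
    """Tag every dictionary alias occurring in a cleaned record.

    Matching is case-insensitive and anchored at token boundaries (a token
    character is a letter, digit or hyphen), so ``CAT`` does not fire inside
    ``catalytic``.  Overlapping candidates are resolved longest-match-first,
    then leftmost.  All matches are emitted with class PROTEIN; spans refer
    to the field (title or body) they were found in and are non-overlapping
    within each field.
    """
    if not dictionary.alias_index:
        return []
    matcher = dictionary.matcher()
    fields = [("title", record.title), ("body", record.body)] if include_title else [
        ("body", record.body)
    ]
    mentions: list[Mention] = []
    for source, text in fields:
        if not text:
            continue
        for m in matcher.finditer(text):
            mentions.append(
                Mention(
                    pmid=record.pmid,
                    surface=m.group(0),
                    entity_class=EntityClass.PROTEIN,
                    start=m.start(),
                    end=m.end(),
                    source=source,
                )
            )
    return mentions


def normalize_mentions(
    mentions: Iterable[Mention], dictionary: EntityDictionary
) -> NormalizationResult:
    """Map mention surfaces to consensus symbols.

    A surface carried by several dictionary entries fans out to one
    :class:`NormalizedMention` per symbol (in sorted symbol order), so shared
    aliases are counted under every entry holding them.  Mentions whose
    surface is not in the dictionary are dropped and counted.
    """
    out: list[NormalizedMention] = []
    dropped = 0
    for m in mentions:
        symbols = dictionary.lookup(m.surface)
        if not symbols:
            dropped += 1
            continue
        for symbol in sorted(symbols):
            out.append(
                NormalizedMention(
                    pmid=m.pmid,
                    symbol=symbol,
                    source_surface=m.surface,
                    entity_class=m.entity_class,
                )
            )
    return NormalizationResult(mentions=out, n_dropped=dropped)


def write_dictionary(dictionary: EntityDictionary, stream: TextIO) -> None:
    """Write dictionary entries back out as tab-delimited nomenclature lines."""
    for e in dictionary.entries:
        stream.write(
            f"{e.hprd_id}\t{e.symbol}\t{e.refseq_id}\t{';'.join(e.aliases)}\n"
        )


def write_mention_table(
    mentions: Iterable[NormalizedMention], stream: TextIO
) -> None:
    """Write normalized mentions as TSV: pmid, symbol, surface, class."""
    stream.write("pmid\tsymbol\tsurface\tclass\n")
    for m in mentions:
        stream.write(
            f"{m.pmid}\t{m.symbol}\t{m.source_surface}\t{m.entity_class.value}\n"
        )
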