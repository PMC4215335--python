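"""Reading, cleaning and pairing of MEDLINE abstract corpora.

The unit of analysis is a single PubMed abstract.  For each disease–biofluid
pair two corpora are assembled: a *positive set* S1 retrieved with the query
``<disease> AND <biofluid>`` and a *negative set* S2 retrieved with
``<biofluid> NOT <disease>``.  The negative set estimates the background
mention frequency of each marker, which is what lets the scoring stage
separate disease-associated markers from ubiquitously discussed ones.

Corpora are consumed as PubMed flat-text (MEDLINE) exports.  Parsing is
delegated to :mod:`Bio.Medline`; this module adds record filtering (entries
without an abstract body are skipped), text cleaning, and the S1/S2
bookkeeping that scoring relies on.
"""

from __future__ import annotations

import io
import string
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping, TextIO

from Bio import Medline

__all__ = [
    "SetLabel",
    "AbstractRecord",
    "QuerySpec",
    "CorpusPair",
    "CleaningRules",
    "MedlineParseError",
    "ParsedCorpus",
    "parse_medline",
    "serialize_medline",
    "clean_string",
    "clean_text",
    "assemble_corpus_pair",
    "load_biofluid_synonyms",
    "write_cleaned_corpus",
    "read_cleaned_corpus",
]


class SetLabel(str, Enum):
    """Membership of an abstract in the positive (S1) or negative (S2) set."""

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


class MedlineParseError(ValueError):
    """Raised when a stream contains no recognizable MEDLINE record."""


@dataclass(frozen=True)
class AbstractRecord:
    """One abstract: PubMed id, title, body text, and its corpus labels."""

    pmid: str
    title: str
    body: str
    set_label: SetLabel
    disease: str = ""
    biofluid: str = ""

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("AbstractRecord requires a non-empty pmid")


@dataclass(frozen=True)
class QuerySpec:
    """A PubMed query definition, kept as metadata only (no live querying).

    The positive query for a pair is ``<disease> AND <biofluid>``; the
    negative query is ``<biofluid> NOT <disease>``.
    """

    disease: str
    biofluid: str
    polarity: SetLabel
    biofluid_synonyms: tuple[str, ...] = ()
    query_string: str = ""

    def __post_init__(self) -> None:
        if not self.query_string:
            if self.polarity is SetLabel.POSITIVE:
                q = f"{self.disease} AND {self.biofluid}"
            else:
                q = f"{self.biofluid} NOT {self.disease}"
            object.__setattr__(self, "query_string", q)


@dataclass
class ParsedCorpus:
    """Parse result: the retained records plus a skip counter.

    ``n_skipped`` counts entries that had a PMID but no abstract body
    (title-only PubMed entries), which are excluded from analysis.
    """

    records: list[AbstractRecord]
    n_skipped: int = 0

    def __iter__(self) -> Iterator[AbstractRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CorpusPair:
    """The S1/S2 corpora for one disease–biofluid pair."""

    s1: list[AbstractRecord]
    s2: list[AbstractRecord]
    disease: str = ""
    biofluid: str = ""
    n_duplicates_removed: int = 0

    @property
    def n1(self) -> int:
        return len(self.s1)

    @property
    def n2(self) -> int:
        return len(self.s2)


def parse_medline(
    source: str | TextIO,
    set_label: SetLabel = SetLabel.POSITIVE,
    disease: str = "",
    biofluid: str = "",
) -> ParsedCorpus:
    """Parse a MEDLINE flat-text export into :class:`AbstractRecord` objects.

    Supports the PubMed export dialect: 4-character field tags followed by
    ``- `` (``PMID- ``, ``TI  - ``, ``AB  - ``) with continuation lines
    indented; multi-line fields are joined with single spaces.  One record is
    produced per entry carrying both a PMID and a non-empty abstract body;
    entries without a body are skipped and counted in ``n_skipped``.

    Raises
    ------
    MedlineParseError
        If the stream has content but no recognizable PMID field anywhere.
    ValueError
        If one PMID occurs twice in the same stream.
    """
    text = source.read() if hasattr(source, "read") else source
    records: list[AbstractRecord] = []
    n_skipped = 0
    seen: set[str] = set()
    saw_pmid = False
    for raw in Medline.parse(io.StringIO(text)):
        pmid = (raw.get("PMID") or "").strip()
        if not pmid:
            n_skipped += 1
            continue
        saw_pmid = True
        body = (raw.get("AB") or "").strip()
        if not body:
            n_skipped += 1
            continue
        if pmid in seen:
            raise ValueError(f"duplicate PMID {pmid!r} within one corpus file")
        seen.add(pmid)
        records.append(
            AbstractRecord(
                pmid=pmid,
                title=(raw.get("TI") or "").strip(),
                body=body,
                set_label=set_label,
                disease=disease,
                biofluid=biofluid,
            )
        )
    if not saw_pmid and text.strip():
        for lineno, line in enumerate(text.splitlines(), start=1):
            if line.strip():
                raise MedlineParseError(
                    f"no PMID field found in stream (first content at line {lineno})"
                )
    return ParsedCorpus(records=records, n_skipped=n_skipped)


def serialize_medline(records: Iterable[AbstractRecord]) -> str:
    """Serialize records back to the MEDLINE flat-text dialect.

    Titles and bodies are emitted on single (unwrapped) lines, which the
    parser accepts, so ``parse -> serialize -> parse`` is the identity on the
    supported dialect.
    """
    lines: list[str] = []
    for rec in records:
        lines.append(f"PMID- {rec.pmid}")
        if rec.title:
            lines.append(f"TI  - {rec.title}")
        lines.append(f"AB  - {rec.body}")
        lines.append("")
    return "\n".join(lines)


@dataclass(frozen=True)
class CleaningRules:
    """Configurable punctuation-stripping rules.

    By default every ASCII punctuation character is replaced by a space,
    except hyphens *inside* tokens (``HER-2`` survives, a trailing dash does
    not), and whitespace runs are collapsed to single spaces.
    """

    punctuation: str = string.punctuation
    keep_internal_hyphens: bool = True


_DEFAULT_RULES = CleaningRules()


def clean_string(text: str, rules: CleaningRules = _DEFAULT_RULES) -> str:
    """Apply punctuation removal and whitespace collapsing to ``text``."""
    drop = set(rules.punctuation)
    if rules.keep_internal_hyphens and "-" in drop:
        drop.remove("-")
        # a hyphen survives only when flanked by word characters on both sides
        out: list[str] = []
        for i, ch in enumerate(text):
            if ch == "-":
                prev_ok = i > 0 and text[i - 1].isalnum()
                next_ok = i + 1 < len(text) and text[i + 1].isalnum()
                out.append("-" if prev_ok and next_ok else " ")
            else:
                out.append(ch)
        text = "".join(out)
    text = text.translate({ord(c): " " for c in drop})
    return " ".join(text.split())


def clean_text(record: AbstractRecord, rules: CleaningRules = _DEFAULT_RULES) -> AbstractRecord:
    """Return a copy of ``record`` with title and body cleaned.

    The PMID and all labels are unchanged; cleaning is idempotent.
    """
    return replace(
        record,
        title=clean_string(record.title, rules),
        body=clean_string(record.body, rules),
    )


def assemble_corpus_pair(
    s1_records: Iterable[AbstractRecord],
    s2_records: Iterable[AbstractRecord],
    disease: str = "",
    biofluid: str = "",
) -> CorpusPair:
    """Combine parsed positive and negative records into a :class:`CorpusPair`.

    A PMID appearing in both inputs is kept only in S1 (positive membership
    wins); the number of records removed from S2 this way is reported in
    ``n_duplicates_removed``.  An empty positive set is an error because the
    enrichment score is undefined without it.
    """
    s1 = [replace(r, set_label=SetLabel.POSITIVE) for r in s1_records]
    if not s1:
        raise ValueError("positive set S1 is empty; scoring is undefined")
    s1_pmids = {r.pmid for r in s1}
    s2: list[AbstractRecord] = []
    removed = 0
    for r in s2_records:
        if r.pmid in s1_pmids:
            removed += 1
            continue
        s2.append(replace(r, set_label=SetLabel.NEGATIVE))
    return CorpusPair(
        s1=s1,
        s2=s2,
        disease=disease,
        biofluid=biofluid,
        n_duplicates_removed=removed,
    )


def load_biofluid_synonyms(source: str | TextIO) -> dict[str, list[str]]:
    """Load a two-column delimited synonym list: canonical name, synonym.

    Lines starting with ``#`` and blank lines are skipped.  Returns a mapping
    from canonical biofluid name to its synonym list (canonical name
    included first).
    """
    text = source.read() if hasattr(source, "read") else source
    table: dict[str, list[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"synonym file line {lineno}: expected 2 columns")
        canonical, synonym = (p.strip() for p in parts)
        bucket = table.setdefault(canonical, [canonical])
        if synonym not in bucket:
            bucket.append(synonym)
    return table


def write_cleaned_corpus(records: Iterable[AbstractRecord], stream: TextIO) -> None:
    """Write records as tab-separated ``pmid, set_label, text`` lines."""
    for rec in records:
        text = f"{rec.title} {rec.body}".strip()
        stream.write(f"{rec.pmid}\t{rec.set_label.value}\t{text}\n")


def read_cleaned_corpus(
    source: str | TextIO, disease: str = "", biofluid: str = ""
) -> list[AbstractRecord]:
    """Read the tab-separated cleaned-corpus format back into records."""
    text = source.read() if hasattr(source, "read") else source
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"cleaned corpus line {lineno}: expected 3 columns")
        pmid, label, body = parts
        records.append(
            AbstractRecord(
                pmid=pmid,
                title="",
                body=body,
                set_label=SetLabel(label),
                disease=disease,
                biofluid=biofluid,
            )
        )
    return records
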