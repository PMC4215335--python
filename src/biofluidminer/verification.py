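"""Verification of significant markers against curated known-marker lists.

Significant markers are split into *known* (present in at least one curated
disease-marker source and in the entity dictionary) and *new* (putative
novel discoveries).  Summary percentages per disease–biofluid pair, the
cross-biofluid specificity matrix, and true-positive rates from manual
abstract checks are computed here.

Source tags on known-marker entries identify the curated list an entry came
from: O (OMIM), C (CAGE), G (Genes & Disease), E (EDRN), X (expert-provided
list), P (published marker list).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .entities import EntityDictionary

__all__ = [
    "SOURCE_TAGS",
    "KnownMarkerList",
    "BiofluidResultSummary",
    "SpecificityMatrix",
    "ManualVerificationRecord",
    "load_known_markers",
    "partition_significant",
    "round_half_up",
    "pct_new_discoveries",
    "known_significance_rate",
    "new_marker_significance_rate",
    "build_specificity_matrix",
    "load_manual_verification",
    "true_positive_rate",
    "write_summary_table",
]

#: Valid known-marker source tags.
SOURCE_TAGS = frozenset("OCGEXP")


@dataclass
class KnownMarkerList:
    """Curated known markers for one disease: symbol -> source-tag set."""

    disease: str
    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries


def load_known_markers(
    source: str | TextIO,
    dictionary: EntityDictionary,
    disease: str = "",
) -> tuple[KnownMarkerList, list[str]]:
    """Load a known-marker list, keeping only dictionary-mapped symbols.

    File format: one marker per line, ``symbol<TAB>comma-joined source tags``
    (whitespace accepted when no tab is present).  Duplicate symbols merge
    their tag sets.  Returns the list plus the symbols dropped because they
    are absent from the dictionary — only markers present in both a curated
    source and the dictionary count as verifiable.
    """
    text = source.read() if hasattr(source, "read") else source
    valid = dictionary.symbols
    entries: dict[str, set[str]] = {}
    dropped: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        symbol = parts[0].strip()
        tag_field = parts[1] if len(parts) > 1 else ""
        tags = {t.strip().upper() for t in tag_field.split(",") if t.strip()}
        for tag in tags:
            if tag not in SOURCE_TAGS:
                raise ValueError(
                    f"known-marker line {lineno}: unknown source tag {tag!r} "
                    f"(expected one of {''.join(sorted(SOURCE_TAGS))})"
                )
        if symbol not in valid:
            dropped.append(symbol)
            continue
        entries.setdefault(symbol, set()).update(tags)
    known = KnownMarkerList(
        disease=disease,
        entries={s: frozenset(t) for s, t in entries.items()},
    )
    return known, dropped


def partition_significant(
    significant: Iterable[str], known: KnownMarkerList | Iterable[str]
) -> tuple[set[str], set[str]]:
    """Split significant symbols into (known, new) — a disjoint cover."""
    known_set = known.symbols if isinstance(known, KnownMarkerList) else set(known)
    sig = set(significant)
    known_sig = sig & set(known_set)
    return known_sig, sig - known_sig


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as spreadsheet-printed percentages do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def pct_new_discoveries(new_significant: int, n_significant: int) -> float | None:
    """Percentage of significant markers that are new: 100·new/significant.

    Undefined (``None``, printed blank) when nothing is significant.
    Reported to 2 decimals, round-half-up.
    """
    if n_significant == 0:
        return None
    return round_half_up(100.0 * new_significant / n_significant, 2)


def known_significance_rate(known_significant: int, known_found: int) -> float | None:
    """Share of the known markers found that scored significant, in percent."""
    if known_found == 0:
        return None
    return round_half_up(100.0 * known_significant / known_found, 2)


def new_marker_significance_rate(
    new_significant: int, total_found: int, known_found: int
) -> float | None:
    """Share of the *new* (non-known) markers found that scored significant.

    Denominator is total_found − known_found; undefined when no new markers
    were found at all.
    """
    denom = total_found - known_found
    if denom <= 0:
        return None
    return round_half_up(100.0 * new_significant / denom, 2)


@dataclass(frozen=True)
class BiofluidResultSummary:
    """The per-pair count summary and its derived percentages."""

    disease: str
    biofluid: str
    total_found: int
    known_found: int
    n_significant: int
    known_significant: int
    new_significant: int
    pct_new_discoveries: float | None
    known_significance_rate: float | None
    new_marker_significance_rate: float | None

    @classmethod
    def from_counts(
        cls,
        disease: str,
        biofluid: str,
        total_found: int,
        known_found: int,
        n_significant: int,
        known_significant: int,
    ) -> "BiofluidResultSummary":
        """Derive every percentage column from the four integer counts."""
        if known_significant > known_found:
            raise ValueError("known_significant cannot exceed known_found")
        if n_significant > total_found:
            raise ValueError("n_significant cannot exceed total_found")
        new_significant = n_significant - known_significant
        return cls(
            disease=disease,
            biofluid=biofluid,
            total_found=total_found,
            known_found=known_found,
            n_significant=n_significant,
            known_significant=known_significant,
            new_significant=new_significant,
            pct_new_discoveries=pct_new_discoveries(new_significant, n_significant),
            known_significance_rate=known_significance_rate(
                known_significant, known_found
            ),
            new_marker_significance_rate=new_marker_significance_rate(
                new_significant, total_found, known_found
            ),
        )


def summarize_pair(
    disease: str,
    biofluid: str,
    scored_symbols: Iterable[str],
    significant_symbols: Iterable[str],
    known: KnownMarkerList,
) -> BiofluidResultSummary:
    """Build the summary for one pair from scored/significant symbol sets."""
    scored = set(scored_symbols)
    significant = set(significant_symbols)
    known_sig, _ = partition_significant(significant, known)
    return BiofluidResultSummary.from_counts(
        disease=disease,
        biofluid=biofluid,
        total_found=len(scored),
        known_found=len(scored & known.symbols),
        n_significant=len(significant),
        known_significant=len(known_sig),
    )


@dataclass
class SpecificityMatrix:
    """Marker × biofluid membership of known-and-significant markers.

    ``matrix`` holds 0/1 membership; ``multiplicity`` (the row sums) counts
    in how many biofluids each marker was significant; ``histogram`` maps a
    multiplicity k to the number of markers with exactly k biofluids.
    """

    matrix: pd.DataFrame
    multiplicity: pd.Series
    histogram: dict[int, int]


def build_specificity_matrix(
    sets_by_biofluid: Mapping[str, Iterable[str]]
) -> SpecificityMatrix:
    """Cross biofluid membership sets into a specificity matrix.

    Rows are the union of the per-biofluid symbol sets (sorted), columns the
    biofluids (sorted); every row has multiplicity >= 1 by construction.
    """
    sets = {b: set(symbols) for b, symbols in sets_by_biofluid.items()}
    biofluids = sorted(sets)
    markers = sorted(set().union(*sets.values()) if sets else set())
    data = {
        b: [1 if m in sets[b] else 0 for m in markers] for b in biofluids
    }
    matrix = pd.DataFrame(data, index=markers, columns=biofluids, dtype=int)
    multiplicity = matrix.sum(axis=1)
    histogram: dict[int, int] = (
        multiplicity.value_counts().sort_index().to_dict() if markers else {}
    )
    return SpecificityMatrix(
        matrix=matrix, multiplicity=multiplicity, histogram=histogram
    )


@dataclass(frozen=True)
class ManualVerificationRecord:
    """One manually checked marker–disease–biofluid claim.

    The claim passes only when the abstract genuinely mentions all three of
    marker, disease and biofluid (synonyms and root words accepted by the
    human judge).
    """

    disease: str
    biofluid: str
    symbol: str
    pmids: tuple[str, ...]
    marker_ok: bool
    disease_ok: bool
    biofluid_ok: bool

    @property
    def passed(self) -> bool:
        return self.marker_ok and self.disease_ok and self.biofluid_ok

    @property
    def outcome(self) -> str:
        return "pass" if self.passed else "fail"


_TRUTHY = {"1", "true", "yes", "y", "pass"}
_FALSY = {"0", "false", "no", "n", "fail"}


def _parse_bool(token: str, lineno: int) -> bool:
    t = token.strip().lower()
    if t in _TRUTHY:
        return True
    if t in _FALSY:
        return False
    raise ValueError(f"manual verification line {lineno}: bad boolean {token!r}")


def load_manual_verification(source: str | TextIO) -> list[ManualVerificationRecord]:
    """Read a manual-verification table.

    TSV columns: disease, biofluid, symbol, semicolon-joined pmids,
    marker_ok, disease_ok, biofluid_ok.  A header line is permitted.
    """
    text = source.read() if hasattr(source, "read") else source
    records: list[ManualVerificationRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if lineno == 1 and line.lower().startswith("disease\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(
                f"manual verification line {lineno}: expected 7 columns"
            )
        records.append(
            ManualVerificationRecord(
                disease=parts[0],
                biofluid=parts[1],
                symbol=parts[2],
                pmids=tuple(p for p in parts[3].split(";") if p),
                marker_ok=_parse_bool(parts[4], lineno),
                disease_ok=_parse_bool(parts[5], lineno),
                biofluid_ok=_parse_bool(parts[6], lineno),
            )
        )
    return records


def true_positive_rate(
    records: Sequence[ManualVerificationRecord],
    grouping: str = "per_biofluid_mean",
) -> float:
    """True-positive rate (percent) from manual pass/fail judgments.

    ``per_biofluid_mean`` (default): compute the error rate within each
    biofluid, average those rates, and report 100 minus the average — the
    biofluids are the averaging unit.  ``pooled``: plain 100·passes/total
    over all records.
    """
    if not records:
        raise ValueError("no manual verification records supplied")
    if grouping == "pooled":
        return 100.0 * sum(r.passed for r in records) / len(records)
    if grouping == "per_biofluid_mean":
        by_fluid: dict[str, list[ManualVerificationRecord]] = {}
        for r in records:
            by_fluid.setdefault(r.biofluid, []).append(r)
        error_rates = [
            100.0 * sum(not r.passed for r in group) / len(group)
            for group in by_fluid.values()
        ]
        return 100.0 - sum(error_rates) / len(error_rates)
    raise ValueError(f"unknown grouping {grouping!r}")


def write_summary_table(
    summaries: Sequence[BiofluidResultSummary], stream: TextIO
) -> None:
    """Write per-pair summaries as TSV; undefined percentages print blank."""

    def fmt(v: float | None) -> str:
        return "" if v is None else f"{v:.2f}"

    stream.write(
        "disease\tbiofluid\ttotal_found\tknown_found\tn_significant\t"
        "known_significant\tnew_significant\tpct_new_discoveries\t"
        "known_significance_rate\tnew_marker_significance_rate\n"
    )
    for s in summaries:
        stream.write(
            f"{s.disease}\t{s.biofluid}\t{s.total_found}\t{s.known_found}\t"
            f"{s.n_significant}\t{s.known_significant}\t{s.new_significant}\t"
            f"{fmt(s.pct_new_discoveries)}\t{fmt(s.known_significance_rate)}\t"
            f"{fmt(s.new_marker_significance_rate)}\n"
        )
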