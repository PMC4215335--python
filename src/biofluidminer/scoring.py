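"""Document-frequency enrichment scoring of markers in S1 versus S2.

For every marker P in Sp (the set of dictionary-mapped markers mentioned at
least once in the positive set S1) the score contrasts how often P is
discussed in S1 against how often it would be discussed if its mentions were
spread uniformly over S1 ∪ S2:

    df1(P) = number of distinct S1 abstracts mentioning P
    df2(P) = number of distinct S2 abstracts mentioning P
    dft(P) = df1(P) + df2(P)
    ex(P)  = dft(P) / (|S1| + |S2|) * |S1|      (expected S1 document count)
    ev(P)  = df1(P)                              (observed S1 document count)
    f(P)   = (ev(P) - ex(P)) / dft(P)            (normalized difference, in [-1, 1])
    Z(P)   = (f(P) - mean(f)) / SD(f)            (standardized over Sp)

Counting is at the abstract level: any number of mentions of a marker inside
one abstract contributes exactly 1 to its document frequency.  SD(f) is the
sample standard deviation (divisor n−1).  Markers with Z above a threshold
(default 1.0, strict inequality) are called significant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .corpus import CorpusPair
from .entities import NormalizedMention

__all__ = [
    "MarkerDocFrequencies",
    "ScoreRecord",
    "ScoreSetStats",
    "DegenerateScoreSetError",
    "count_document_frequencies",
    "expectation",
    "normalized_difference",
    "zscores",
    "score_markers",
    "apply_threshold",
    "threshold_sweep",
    "write_score_table",
]

#: Default significance cut-off on Z.
DEFAULT_TAU = 1.0


class DegenerateScoreSetError(ValueError):
    """All f values identical: SD(f) = 0 and z-scores are undefined."""


@dataclass(frozen=True)
class MarkerDocFrequencies:
    """Per-marker document frequencies with supporting S1 PMIDs."""

    symbol: str
    df1: int
    df2: int
    s1_pmids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.df1 < 1:
            raise ValueError("df1 must be >= 1: Sp members are found in S1")
        if self.df2 < 0:
            raise ValueError("df2 must be >= 0")

    @property
    def dft(self) -> int:
        return self.df1 + self.df2


@dataclass(frozen=True)
class ScoreRecord:
    """Full score row for one marker."""

    symbol: str
    df1: int
    df2: int
    ex: float
    ev: int
    f: float
    z: float
    s1_pmids: frozenset[str] = frozenset()

    @property
    def dft(self) -> int:
        return self.df1 + self.df2


@dataclass(frozen=True)
class ScoreSetStats:
    """Summary of the f distribution over Sp used for standardization."""

    mean_f: float
    sd_f: float
    n_markers: int


def count_document_frequencies(
    s1_mentions: Iterable[NormalizedMention],
    s2_mentions: Iterable[NormalizedMention],
    pair: CorpusPair | None = None,
) -> list[MarkerDocFrequencies]:
    """Count distinct-abstract document frequencies per marker.

    Within one abstract a marker counts once no matter how many times it is
    mentioned.  Only markers with df1 >= 1 (members of Sp) are returned,
    sorted by symbol; markers seen only in S2 are excluded.  When ``pair``
    is given the counts are validated against the corpus sizes.
    """
    s1_docs: dict[str, set[str]] = {}
    for m in s1_mentions:
        s1_docs.setdefault(m.symbol, set()).add(m.pmid)
    s2_docs: dict[str, set[str]] = {}
    for m in s2_mentions:
        s2_docs.setdefault(m.symbol, set()).add(m.pmid)
    if not s1_docs:
        warnings.warn("no markers found in the positive set; Sp is empty")
        return []
    out = []
    for symbol in sorted(s1_docs):
        pmids1 = s1_docs[symbol]
        df1 = len(pmids1)
        df2 = len(s2_docs.get(symbol, ()))
        if pair is not None:
            if df1 > pair.n1 or df2 > pair.n2:
                raise ValueError(
                    f"{symbol}: document frequencies exceed corpus sizes"
                )
        out.append(
            MarkerDocFrequencies(
                symbol=symbol, df1=df1, df2=df2, s1_pmids=frozenset(pmids1)
            )
        )
    return out


def expectation(dft: int, n1: int, n2: int) -> float:
    """Expected S1 document count under uniform spread: dft * n1 / (n1 + n2)."""
    if n1 + n2 <= 0:
        raise ValueError("n1 + n2 must be positive")
    if n1 < 1:
        raise ValueError("positive set size n1 must be >= 1")
    if dft < 1:
        raise ValueError("dft must be >= 1")
    return dft * n1 / (n1 + n2)


def normalized_difference(ev: int, ex: float, dft: int) -> float:
    """Normalized observed-minus-expected difference (ev - ex) / dft."""
    if dft < 1:
        raise ValueError("dft must be >= 1")
    if not 0 <= ev <= dft:
        raise ValueError("ev must lie in [0, dft]")
    return (ev - ex) / dft


def zscores(
    f_by_symbol: Mapping[str, float]
) -> tuple[dict[str, float], ScoreSetStats]:
    """Standardize f values over Sp.

    Returns z per symbol (ordered by z descending, ties broken by symbol
    ascending) and the mean/SD used.  SD is the sample standard deviation
    (divisor n−1).  Fewer than two markers, or all f equal, is an error: the
    standardization is undefined and failing loudly beats fabricating scores.
    """
    n = len(f_by_symbol)
    if n < 2:
        raise ValueError("z-scores require at least 2 markers in Sp")
    values = list(f_by_symbol.values())
    mean_f = sum(values) / n
    sd_f = math.sqrt(sum((v - mean_f) ** 2 for v in values) / (n - 1))
    if sd_f == 0.0:
        raise DegenerateScoreSetError(
            "all f values are identical (SD = 0); z-scores are undefined"
        )
    z = {s: (v - mean_f) / sd_f for s, v in f_by_symbol.items()}
    ordered = dict(sorted(z.items(), key=lambda kv: (-kv[1], kv[0])))
    return ordered, ScoreSetStats(mean_f=mean_f, sd_f=sd_f, n_markers=n)


def score_markers(
    frequencies: Sequence[MarkerDocFrequencies], n1: int, n2: int
) -> tuple[list[ScoreRecord], ScoreSetStats]:
    """Run the df -> ex/ev -> f -> z pipeline over one corpus pair.

    Output is sorted by z descending, ties broken by symbol ascending.
    """
    f_by_symbol: dict[str, float] = {}
    parts: dict[str, tuple[MarkerDocFrequencies, float]] = {}
    for freq in frequencies:
        ex = expectation(freq.dft, n1, n2)
        f = normalized_difference(freq.df1, ex, freq.dft)
        f_by_symbol[freq.symbol] = f
        parts[freq.symbol] = (freq, ex)
    z_by_symbol, stats = zscores(f_by_symbol)
    records = [
        ScoreRecord(
            symbol=symbol,
            df1=parts[symbol][0].df1,
            df2=parts[symbol][0].df2,
            ex=parts[symbol][1],
            ev=parts[symbol][0].df1,
            f=f_by_symbol[symbol],
            z=z,
            s1_pmids=parts[symbol][0].s1_pmids,
        )
        for symbol, z in z_by_symbol.items()
    ]
    return records, stats


def apply_threshold(
    records: Sequence[ScoreRecord], tau: float = DEFAULT_TAU
) -> list[ScoreRecord]:
    """Significant subset: records with z strictly greater than ``tau``."""
    return [r for r in records if r.z > tau]


def threshold_sweep(
    records: Sequence[ScoreRecord],
    taus: Sequence[float],
    known_symbols: Iterable[str] = (),
) -> pd.DataFrame:
    """Survivor counts per threshold, split into known and new markers.

    Mirrors the empirical threshold sweep used to pick the cut-off: as tau
    rises the survivor counts can only shrink.
    """
    known = set(known_symbols)
    rows = []
    for tau in taus:
        survivors = apply_threshold(records, tau)
        n_known = sum(1 for r in survivors if r.symbol in known)
        rows.append(
            {
                "tau": float(tau),
                "n_known_significant": n_known,
                "n_new_significant": len(survivors) - n_known,
            }
        )
    return pd.DataFrame(rows, columns=["tau", "n_known_significant", "n_new_significant"])


def write_score_table(
    records: Sequence[ScoreRecord],
    stream: TextIO,
    tau: float = DEFAULT_TAU,
) -> None:
    """Write the ranked score table as TSV.

    Columns: symbol, df1, df2, dft, ex, ev, f, z, significant (0/1), and the
    supporting S1 PMIDs semicolon-joined.  These z values are the ranked
    output of the method and double as informative priors for downstream
    disease modeling.
    """
    stream.write("symbol\tdf1\tdf2\tdft\tex\tev\tf\tz\tsignificant\ts1_pmids\n")
    for r in records:
        pmids = ";".join(sorted(r.s1_pmids))
        stream.write(
            f"{r.symbol}\t{r.df1}\t{r.df2}\t{r.dft}\t{r.ex:.10g}\t{r.ev}\t"
            f"{r.f:.10g}\t{r.z:.10g}\t{int(r.z > tau)}\t{pmids}\n"
        )
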