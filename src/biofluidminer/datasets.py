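"""Bundled reference data.

Two small editable tables ship with the package: a biofluid synonym list and
the curated per-biofluid marker count summaries for breast and lung cancer
from which every reported percentage is derived at run time.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .corpus import load_biofluid_synonyms

__all__ = ["load_reference_counts", "load_default_biofluid_synonyms"]


def _read_text(name: str) -> str:
    return (resources.files("biofluidminer") / "data" / name).read_text()


def load_reference_counts() -> pd.DataFrame:
    """Curated disease × biofluid integer marker counts.

    Columns: disease, biofluid, total_found, known_found, n_significant,
    known_significant.  Percentages are never stored; compute them with
    :mod:`biofluidminer.verification`.
    """
    from io import StringIO

    return pd.read_csv(
        StringIO(_read_text("reference_marker_counts.tsv")),
        sep="\t",
        comment="#",
    )


def load_default_biofluid_synonyms() -> dict[str, list[str]]:
    """The bundled biofluid synonym table (canonical name -> synonyms)."""
    return load_biofluid_synonyms(_read_text("biofluid_synonyms.tsv"))
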