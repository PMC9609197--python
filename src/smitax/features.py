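"""Explainable feature extraction.

Two feature families, both directly readable by a human: counts of the
characters making up the SMILES string (case-sensitive — lowercase
symbols carry aromaticity information) and one binary indicator per
superclass.  Together with the kingdom column they form a fixed-order
table ready for ML consumption.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import pandas as pd

from .elements import DEFAULT_TABLES, ElementTables
from .smiles import SmilesError
from .taxonomy import ALL_SUPERCLASSES, TaxonomyResult, classify

__all__ = [
    "TRACKED_CHARACTERS",
    "OTHER_KEY",
    "char_count_features",
    "superclass_flag_vector",
    "feature_table",
    "feature_columns",
]

#: The tracked character alphabet, fixed and versioned.  Two-letter
#: element symbols contribute at character level ('Cl' -> 'C' plus an
#: untracked 'l'); anything untracked is tallied under :data:`OTHER_KEY`.
TRACKED_CHARACTERS: tuple[str, ...] = tuple(
    list("BCNOPSFIH")
    + list("bcnops")
    + [str(d) for d in range(10)]
    + list("%()[]=#+-./\\@")
)
OTHER_KEY = "other"

#: CSV-safe column name for each tracked character.
_CHAR_COLUMN_NAMES = {
    "%": "percent", "(": "open_paren", ")": "close_paren",
    "[": "open_bracket", "]": "close_bracket", "=": "equals",
    "#": "hash", "+": "plus", "-": "minus", ".": "dot",
    "/": "slash", "\\": "backslash", "@": "at",
}


def _char_column(ch: str) -> str:
    return "char_" + _CHAR_COLUMN_NAMES.get(ch, ch)


def char_count_features(smiles: str) -> dict[str, int]:
    """Count tracked characters; untracked ones go under ``other``.

    The counts (including ``other``) always sum to the string length.
    """
    raw = Counter(smiles)
    counts = {ch: raw.pop(ch, 0) for ch in TRACKED_CHARACTERS}
    counts[OTHER_KEY] = sum(raw.values())
    return counts


def superclass_flag_vector(result: TaxonomyResult) -> list[int]:
    """One 0/1 indicator per superclass, in enumeration order."""
    return [int(label in result.superclasses) for label in ALL_SUPERCLASSES]


def feature_columns() -> list[str]:
    """The fixed output column order of :func:`feature_table`."""
    return (
        ["smiles", "kingdom"]
        + [_char_column(ch) for ch in TRACKED_CHARACTERS]
        + ["char_" + OTHER_KEY]
        + ["sc_" + label for label in ALL_SUPERCLASSES]
    )


def feature_table(
    smiles_list: Iterable[str],
    ids: Sequence[str] | None = None,
    tables: ElementTables = DEFAULT_TABLES,
) -> tuple[pd.DataFrame, list[dict]]:
    """Classify every molecule and assemble the feature table.

    Malformed SMILES are skipped, never emitted as NA rows; each failure
    is recorded in the returned error report as
    ``{"index", "smiles", "error"}``.  ``ids`` optionally supplies a row
    identifier (e.g. a compound name) used instead of the SMILES string.
    """
    rows = []
    errors: list[dict] = []
    index = []
    for i, smi in enumerate(smiles_list):
        try:
            result = classify(smi, tables)
        except SmilesError as exc:
            errors.append({"index": i, "smiles": smi, "error": str(exc)})
            continue
        counts = char_count_features(result.smiles)
        row = {"smiles": result.smiles, "kingdom": result.kingdom}
        for ch in TRACKED_CHARACTERS:
            row[_char_column(ch)] = counts[ch]
        row["char_" + OTHER_KEY] = counts[OTHER_KEY]
        for label, flag in zip(ALL_SUPERCLASSES, superclass_flag_vector(result)):
            row["sc_" + label] = flag
        rows.append(row)
        index.append(ids[i] if ids is not None else result.smiles)
    df = pd.DataFrame(rows, columns=feature_columns(), index=pd.Index(index, name="id"))
    numeric = df.columns[2:]
    df[numeric] = df[numeric].astype(int) if len(df) else df[numeric]
    return df, errors
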