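"""Tab-delimited table I/O for trait matrices and truth tables.

A trait matrix is one row per individual plant: ``species``, ``year``,
``individual_id``, then one numeric column per trait.  Decimal points
are required; comma decimals are rejected with a clear error rather
than silently misparsed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_trait_table", "write_trait_table", "META_COLUMNS"]

META_COLUMNS = ["species", "year", "individual_id"]


def write_trait_table(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in META_COLUMNS})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing required columns: {missing}")
    trait_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not trait_cols:
        raise ValueError("trait table has no trait columns")
    for col in trait_cols:
        if df[col].dtype == object:
            sample = df[col].astype(str)
            if sample.str.contains(",").any():
                raise ValueError(
                    f"column {col!r} contains comma decimals; "
                    "use a decimal point (e.g. 3.5, not 3,5)"
                )
            df[col] = pd.to_numeric(df[col])
    return df
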