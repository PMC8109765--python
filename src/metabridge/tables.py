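"""Concentration-table conventions and I/O.

A concentration table is a pandas DataFrame with the metadata columns

    sample_id, sex, genotype, age_point, fluid

followed by one relative-concentration column per metabolite.  ``sample_id``
identifies the pooled sample; the blood and CSF rows of one pool share the
same ``sample_id`` so cross-fluid correlations can pair them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

META_COLUMNS = ["sample_id", "sex", "genotype", "age_point", "fluid"]

SEXES = ("male", "female")
GENOTYPES = ("WT", "APP")
AGE_POINTS = ("early", "late")
FLUIDS = ("blood", "csf")


def metabolite_columns(table: pd.DataFrame) -> list[str]:
    """Metabolite (non-metadata) columns in table order."""
    return [c for c in table.columns if c not in META_COLUMNS]


def validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"concentration table missing metadata columns: {missing}")
    if not metabolite_columns(table):
        raise ValueError("concentration table has no metabolite columns")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_table(table)
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_table(table)
    return table


def select_group(
    table: pd.DataFrame,
    sex: str | None = None,
    genotype: str | None = None,
    age_point: str | None = None,
) -> pd.DataFrame:
    """Subset a table by any combination of group labels."""
    mask = pd.Series(True, index=table.index)
    for col, value in (("sex", sex), ("genotype", genotype), ("age_point", age_point)):
        if value is not None:
            mask &= table[col] == value
    return table.loc[mask].reset_index(drop=True)
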