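"""Bundled reference data.

``marker_panel.tsv`` is a panel of 74 validated polymorphic SSR markers
(primer pairs plus per-locus diversity statistics computed over 40
individuals, overall and split into tall/dwarf groups). It serves as a
fixed reference for validator tests and summary arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_NUMERIC_INT = ["repeat_count", "tm", "product_size", "na_all", "na_tall", "na_dwarf"]
_NUMERIC_FLOAT = ["maf", "he_all", "he_tall", "he_dwarf",
                  "ho_all", "ho_tall", "ho_dwarf",
                  "pic_all", "pic_tall", "pic_dwarf"]


def load_marker_panel() -> pd.DataFrame:
    """The 74-marker reference panel as a DataFrame."""
    with resources.files("ssrmine.data").joinpath("marker_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for col in _NUMERIC_INT:
        df[col] = df[col].astype(int)
    for col in _NUMERIC_FLOAT:
        df[col] = df[col].astype(float)
    return df


def marker_panel_summary(df: pd.DataFrame) -> dict[str, float]:
    """Column totals and means of the panel, means rounded to 2 decimals."""
    mean = lambda c: round(float(df[c].mean()), 2)
    return {
        "n_markers": int(len(df)),
        "total_alleles": int(df["na_all"].sum()),
        "mean_na_all": mean("na_all"),
        "mean_na_tall": mean("na_tall"),
        "mean_na_dwarf": mean("na_dwarf"),
        "mean_maf": mean("maf"),
        "mean_he_all": mean("he_all"),
        "mean_he_tall": mean("he_tall"),
        "mean_he_dwarf": mean("he_dwarf"),
        "mean_ho_all": mean("ho_all"),
        "mean_ho_tall": mean("ho_tall"),
        "mean_ho_dwarf": mean("ho_dwarf"),
        "mean_pic_all": mean("pic_all"),
        "mean_pic_tall": mean("pic_tall"),
        "mean_pic_dwarf": mean("pic_dwarf"),
    }
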