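"""Tabulated summary reports over extracted interfaces and networks."""

from __future__ import annotations

import pandas as pd

from histonet.interfaces import FOUR_CLASSES


def interactions_per_class(
    edge_table: pd.DataFrame,
    organism_of_structure: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Residue-level interaction counts per class (optionally per organism)."""
    df = edge_table[edge_table["class"].isin(FOUR_CLASSES)].copy()
    if organism_of_structure:
        df["organism"] = df["structure_id"].map(organism_of_structure).fillna("unknown")
        out = (
            df.groupby(["organism", "class"]).size().rename("n_interactions")
            .reset_index()
        )
    else:
        out = df.groupby("class").size().rename("n_interactions").reset_index()
    return out


def partners_per_functional_class(
    partner_classes: pd.DataFrame,
) -> pd.DataFrame:
    """Binding-partner counts per functional class.

    Input: table with columns ``partner_id`` and ``functional_class``
    (a NucleosomeDB/PANTHER-style annotation, supplied as data).
    """
    required = {"partner_id", "functional_class"}
    missing = required - set(partner_classes.columns)
    if missing:
        raise KeyError(f"annotation table missing columns: {sorted(missing)}")
    return (
        partner_classes.drop_duplicates(["partner_id", "functional_class"])
        .groupby("functional_class")["partner_id"].nunique()
        .rename("n_partners").reset_index()
        .sort_values("n_partners", ascending=False, ignore_index=True)
    )
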