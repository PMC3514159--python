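"""Packaged reference data: the Hoxa1 two-hybrid screen tables.

Two hit lists (one per screen orientation) mirror the published interactor
tables row for row; the two enrichment reference tables carry the printed
per-term statistics in their original decimal-comma dialect and are parsed
through :func:`y2hnet.io.parse_decimal`.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .catalog import Catalog, InteractorRecord, ProteinRef, merge_screens, read_catalog_tsv
from .io import parse_decimal

__all__ = [
    "hoxa1_ad_screen",
    "hoxa1_bait",
    "hoxa1_catalog",
    "hoxa1_db_screen",
    "hoxa1_go_reference",
    "hoxa1_pathway_reference",
]


def _data_path(name: str):
    return resources.files("y2hnet.data").joinpath(name)


def hoxa1_bait() -> ProteinRef:
    """The bait protein of the packaged screen."""
    return ProteinRef(
        symbol="HOXA1", entrez_id=3198, uniprot_acc="P49639",
        name="homeobox A1",
    )


def hoxa1_db_screen() -> list[InteractorRecord]:
    """Hits of the DB-bait orientation (40 records)."""
    with _data_path("hoxa1_db_screen.tsv").open("r", encoding="utf-8") as fh:
        return read_catalog_tsv(fh)


def hoxa1_ad_screen() -> list[InteractorRecord]:
    """Hits of the AD-bait orientation (28 records)."""
    with _data_path("hoxa1_ad_screen.tsv").open("r", encoding="utf-8") as fh:
        return read_catalog_tsv(fh)


def hoxa1_catalog() -> Catalog:
    """The merged 60-protein union catalog (bait homodimer included)."""
    return merge_screens(hoxa1_db_screen(), hoxa1_ad_screen(), hoxa1_bait())


def _read_decimal_table(name: str, numeric: dict[str, type]) -> pd.DataFrame:
    with _data_path(name).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    for col, typ in numeric.items():
        df[col] = df[col].map(
            lambda s: int(s) if typ is int else parse_decimal(s)
        )
    return df


def hoxa1_go_reference() -> pd.DataFrame:
    """Published per-term GO enrichment statistics of the direct set."""
    return _read_decimal_table(
        "hoxa1_go_enrichment.tsv",
        {"obs": int, "odds_ratio": float, "p_value": float,
         "corr_p_value": float},
    )


def hoxa1_pathway_reference() -> pd.DataFrame:
    """Published per-pathway statistics of the second-degree analysis."""
    return _read_decimal_table(
        "hoxa1_pathway_enrichment.tsv",
        {"obs": int, "odds_ratio": float, "fdr": float, "corr_fdr": float},
    )
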