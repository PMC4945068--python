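"""Packaged reference tables for the 46-genome gut / non-gut study design.

Three small TSVs ship with the package:

* ``per_genome_annotation_localization.tsv`` — the 46 genomes (23 gut,
  23 non-gut) with predicted localization counts (pse/sec/cyto/mem), total
  proteome size, and the number and percentage of proteins assigned to
  ortholog groups. Decimal commas in the published percentages were
  normalized to points when the table was packaged; the Oenococcus oeni row
  is kept exactly as published even though its compartment counts sum to
  1398 against a printed total of 1675 (fractions use the printed total).
* ``groups_overrepresented.tsv`` / ``groups_underrepresented.tsv`` — the
  44 and 67 description-level feature groups that pass the >= 12
  genome-count-difference screen in each direction, with their functional
  category, catalog-wide abundance (NA for multi-member groups) and the
  per-cohort abundance percentages.
"""

from __future__ import annotations

import re
from importlib.resources import files

import pandas as pd

from .io_formats import GenomeRecord, Habitat, LocalizationProfile

__all__ = [
    "load_genome_table",
    "load_screened_groups",
    "reference_genomes",
    "reference_localization_profiles",
]

_DATA = files("gutnog") / "data"

_CATEGORY_LETTER = re.compile(r"\[([A-Z])\]")


def load_genome_table() -> pd.DataFrame:
    """The packaged per-genome annotation/localization table (46 rows)."""
    with (_DATA / "per_genome_annotation_localization.tsv").open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle, sep="\t")


def reference_genomes() -> list[GenomeRecord]:
    df = load_genome_table()
    return [
        GenomeRecord(
            genome_id=row.genome_id,
            habitat=Habitat.from_label(row.habitat_label),
            total_proteins=int(row.total),
        )
        for row in df.itertuples()
    ]


def reference_localization_profiles() -> list[LocalizationProfile]:
    """Localization profiles for the 46 genomes.

    One published row is internally inconsistent (compartments vs printed
    total); the consistency warning this would trigger on re-reading is the
    reader's concern, not the fixture's, so none is emitted here.
    """
    df = load_genome_table()
    return [
        LocalizationProfile(
            genome_id=row.genome_id,
            pse=int(row.pse),
            sec=int(row.sec),
            cyto=int(row.cyto),
            mem=int(row.mem),
            total=int(row.total),
        )
        for row in df.itertuples()
    ]


def load_screened_groups(direction: str) -> pd.DataFrame:
    """The published screened feature groups, ``direction`` in {"over", "under"}.

    Adds parsed columns: ``nogs`` (tuple of member ortholog-group ids) and
    ``category_letters`` (tuple of single letters, empty for NA). The
    catalog-wide abundance column is NaN where the publication printed NA or
    left the cell blank (multi-member groups).
    """
    name = {
        "over": "groups_overrepresented.tsv",
        "under": "groups_underrepresented.tsv",
    }.get(direction)
    if name is None:
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    with (_DATA / name).open("r", encoding="utf-8") as handle:
        df = pd.read_csv(handle, sep="\t", na_values=["NA"])
    df["nogs"] = df["nog_ids"].map(lambda s: tuple(s.split(",")))
    df["category_letters"] = df["category"].map(
        lambda s: tuple(_CATEGORY_LETTER.findall(s)) if isinstance(s, str) else ()
    )
    return df
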