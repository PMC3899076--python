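"""Packaged reference tables from the published 2009 Southeast Asia
50-m L-band mosaic forest-mapping study.

Two small CSVs ship with the package:

* the validation confusion matrix of the four-class land-cover map against
  ground-reference ROI pixels (predicted rows × reference columns);
* the national forest-area comparison (10³ km²) among the 50-m SAR map,
  FAO FRA 2010 statistics, GlobCover 2009 and MCD12Q1 2009, for the 11
  countries of Southeast Asia. The SAR column keeps the MODIS-filled part
  of the Indonesian total (the Papua gap) in a separate column; loaders
  sum the two.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .accuracy import ConfusionMatrix
from .comparison import AreaTable

__all__ = [
    "load_validation_confusion",
    "load_national_areas",
    "MAINLAND_COUNTRIES",
    "AREA_SOURCES",
]

MAINLAND_COUNTRIES = ("Myanmar", "Thailand", "Laos", "Vietnam", "Cambodia")
AREA_SOURCES = ("palsar", "fao_fra", "globcover", "mcd12q1")


def _data_path(name: str):
    return resources.files("sarforest.data").joinpath(name)


def load_validation_confusion() -> ConfusionMatrix:
    """The published 4×4 validation confusion matrix (pixel counts)."""
    with resources.as_file(_data_path("sea2009_validation_confusion.csv")) as p:
        return ConfusionMatrix.from_csv(p)


def load_national_areas(source: str, mainland_only: bool = False) -> AreaTable:
    """National forest areas (10³ km²) for one map product.

    ``source`` is one of 'palsar', 'fao_fra', 'globcover', 'mcd12q1'. For
    the SAR product the MODIS-filled Papua complement is added to the
    Indonesian total. ``mainland_only`` restricts to the five mainland
    countries (Myanmar, Thailand, Laos, Vietnam, Cambodia).
    """
    if source not in AREA_SOURCES:
        raise KeyError(f"unknown source {source!r}; choose from {AREA_SOURCES}")
    with resources.as_file(_data_path("sea2009_national_forest_areas.csv")) as p:
        df = pd.read_csv(p)
    area = df[source].astype(float)
    if source == "palsar":
        area = area + df["palsar_modis_fill"].astype(float)
    table = pd.DataFrame(
        {"region_id": df["region_id"], "region_name": df["country"], "area_1e3km2": area}
    )
    if mainland_only:
        table = table[table["region_name"].isin(MAINLAND_COUNTRIES)].reset_index(drop=True)
    return AreaTable(table=table, source=source)
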