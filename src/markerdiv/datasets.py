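"""Loaders for the published per-population tables packaged with markerdiv.

The study system is a set of 20 shrub populations (13 individuals each,
288 ISSR loci) from five semi-arid regions.  The packaged tables carry
the published per-region climate normals, per-population soil
chemistry, per-population diversity indices, per-primer band counts,
and the gradient-pooled differentiation estimates.  Published
dispersion columns are retained only where used; soil SDs contain
printing errors and are deliberately not packaged.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_population_metadata",
    "load_climate_regions",
    "load_climate_populations",
    "load_soil_table",
    "load_diversity_table",
    "load_primer_table",
    "load_gradient_table",
    "CLIMATE_VARIABLES",
    "SOIL_VARIABLES",
    "DIVERSITY_INDICES",
]

CLIMATE_VARIABLES = ["AMT", "ART", "WI", "CI", "AP", "S"]
SOIL_VARIABLES = ["SOC", "SAN", "SOP", "SOC/SAN", "SOC/SOP", "SAN/SOP"]
DIVERSITY_INDICES = ["P", "Na", "Ne", "h", "I"]


def _read(name: str, index_col: str | None = None) -> pd.DataFrame:
    with resources.as_file(
        resources.files("markerdiv").joinpath("data", name)
    ) as path:
        df = pd.read_csv(path)
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def load_population_metadata() -> pd.DataFrame:
    """Region and dune-habitat class of each of the 20 populations."""
    return _read("table1_populations.csv", "population")


def load_climate_regions() -> pd.DataFrame:
    """Published climate-index means for the five sampling regions."""
    return _read("table2_climate.csv", "region")


def load_climate_populations() -> pd.DataFrame:
    """Region climate expanded to the 20 populations (each inherits its region)."""
    meta = load_population_metadata()
    regions = load_climate_regions()
    out = regions.loc[meta["region"]].set_axis(meta.index)
    out.index.name = "population"
    return out


def load_soil_table() -> pd.DataFrame:
    """Published soil chemistry means per population (SOC, SAN, SOP + ratios)."""
    return _read("table3_soil.csv", "population")


def load_diversity_table(values_only: bool = True) -> pd.DataFrame:
    """Published per-population diversity indices.

    With values_only (default), returns the five indices P, Na, Ne, h, I;
    otherwise includes sample sizes, polymorphic-locus counts and the
    published across-locus SD columns.
    """
    df = _read("table5_diversity.csv", "population")
    return df[DIVERSITY_INDICES] if values_only else df


def load_primer_table() -> pd.DataFrame:
    """Published per-primer band counts and polymorphism percentages."""
    return _read("table4_primers.csv", "primer")


def load_gradient_table() -> pd.DataFrame:
    """Published gradient-pooled diversity, Gst and Nm (11 gradient classes)."""
    return _read("table7_gradients.csv")
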