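"""Kira-style climate indices from monthly temperature and rainfall.

From twelve monthly mean temperatures t_i (deg C) and rainfalls r_i (mm):

- AMT: mean annual temperature, mean(t)
- ART: annual temperature range, max(t) - min(t) of the monthly MEANS
- WI (warmth index): sum over months with t_i > 5 of (t_i - 5)
- CI (coldness index): sum over months with t_i < 5 of (5 - t_i)
- AP: annual rainfall, sum(r)
- S (hydrothermal synthesis index): sum over all 12 months of
  0.18 * r_i / 1.045**t_i  (larger = moister; the exponential discounts
  rainfall in warm months)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MonthlyClimate", "ClimateIndices", "compute_climate_indices",
           "indices_for_sites"]


@dataclass
class MonthlyClimate:
    """Twelve monthly mean temperatures (deg C) and rainfalls (mm), Jan-Dec."""

    t: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.t.shape != (12,) or self.r.shape != (12,):
            raise ValueError(
                f"need exactly 12 monthly values; got t{self.t.shape}, r{self.r.shape}"
            )
        if (self.r < 0).any():
            raise ValueError("rainfall must be nonnegative")


@dataclass
class ClimateIndices:
    AMT: float
    ART: float
    WI: float
    CI: float
    AP: float
    S: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {k: getattr(self, k) for k in ("AMT", "ART", "WI", "CI", "AP", "S")}
        )


def compute_climate_indices(clim: MonthlyClimate) -> ClimateIndices:
    t, r = clim.t, clim.r
    wi = float(np.sum(np.clip(t - 5.0, 0.0, None)))
    ci = float(np.sum(np.clip(5.0 - t, 0.0, None)))
    s = float(np.sum(0.18 * r / np.power(1.045, t)))
    return ClimateIndices(
        AMT=float(t.mean()),
        ART=float(t.max() - t.min()),
        WI=wi,
        CI=ci,
        AP=float(r.sum()),
        S=s,
    )


def indices_for_sites(series: dict[str, MonthlyClimate]) -> pd.DataFrame:
    """One row of indices per site, in input order."""
    if not series:
        raise ValueError("need >=1 site")
    rows = {site: compute_climate_indices(c).as_series() for site, c in series.items()}
    out = pd.DataFrame(rows).T
    out.index.name = "site"
    return out
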