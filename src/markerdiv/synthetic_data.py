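"""Synthetic dominant-marker, environment, and climate generators.

Every downstream stage is testable against known ground truth:

- :func:`simulate_dominant_markers` draws population band-allele
  frequencies around a shared ancestral frequency from the
  Balding-Nichols beta model (a single Fst dial), samples diploid
  genotypes under Hardy-Weinberg, and collapses them to dominant band
  phenotypes (optionally with a scoring flip error).
- :func:`simulate_env_linked_diversity` builds a multivariate linear
  diversity~environment relationship with a configured population
  redundancy R^2.
- :func:`simulate_monthly_climate` produces sinusoidal seasonal
  temperature cycles with summer-peaked rainfall, in the temperate
  semi-arid range of the study system (site means a few degrees C,
  annual rainfall a few hundred mm).

All generators are deterministic given their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate_indices import MonthlyClimate
from .marker_data import MarkerMatrix

__all__ = [
    "SimulationConfig",
    "simulate_dominant_markers",
    "simulate_env_linked_diversity",
    "simulate_monthly_climate",
]


@dataclass
class SimulationConfig:
    """Study-design-shaped defaults: 20 populations x 13 diploids, 288 loci.

    fst is the Balding-Nichols differentiation parameter (the study's
    overall Phi_ST was ~0.11, hence the default); ancestral band-allele
    frequencies are uniform on [ancestral_low, ancestral_high] to avoid
    quasi-monomorphic loci dominating; flip_error is a per-band
    phenotype scoring error rate (default 0).
    """

    n_populations: int = 20
    n_individuals: int = 13
    n_loci: int = 288
    fst: float = 0.11
    ancestral_low: float = 0.1
    ancestral_high: float = 0.9
    flip_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_populations, self.n_individuals, self.n_loci) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not 0.0 <= self.ancestral_low <= self.ancestral_high <= 1.0:
            raise ValueError("ancestral frequency bounds out of order")
        if not 0.0 <= self.flip_error <= 1.0:
            raise ValueError("flip_error must be a probability")


def simulate_dominant_markers(cfg: SimulationConfig):
    """Simulate a dominant-marker matrix; returns (MarkerMatrix, truth).

    truth holds the latent ancestral frequencies 'p0' (loci,) and the
    per-population band-allele frequencies 'p' (populations x loci).
    """
    rng = np.random.default_rng(cfg.seed)
    K, N, L, F = cfg.n_populations, cfg.n_individuals, cfg.n_loci, cfg.fst
    p0 = rng.uniform(cfg.ancestral_low, cfg.ancestral_high, size=L)
    if F == 0.0:
        p = np.tile(p0, (K, 1))
    else:
        a = p0 * (1.0 - F) / F
        b = (1.0 - p0) * (1.0 - F) / F
        p = rng.beta(np.tile(a, (K, 1)), np.tile(b, (K, 1)))
    # diploid genotypes under HWE; band shown unless null homozygote
    band_prob = 1.0 - (1.0 - p) ** 2
    values = np.empty((K * N, L), dtype=np.int8)
    for k in range(K):
        values[k * N : (k + 1) * N] = (
            rng.random((N, L)) < band_prob[k]
        ).astype(np.int8)
    if cfg.flip_error > 0:
        flips = rng.random(values.shape) < cfg.flip_error
        values = np.where(flips, 1 - values, values)
    pops = [f"Pop{k + 1}" for k in range(K)]
    ids = [f"Pop{k + 1}_ind{i + 1}" for k in range(K) for i in range(N)]
    matrix = MarkerMatrix(
        individual_ids=ids,
        locus_ids=[f"L{j + 1}" for j in range(L)],
        values=values,
        population_of={
            f"Pop{k + 1}_ind{i + 1}": pops[k] for k in range(K) for i in range(N)
        },
    )
    truth = {"p0": p0, "p": p, "band_prob": band_prob, "fst": F}
    return matrix, truth


def simulate_env_linked_diversity(
    n_sites: int = 20,
    n_indices: int = 5,
    n_env: int = 6,
    effect_r2: float = 0.5,
    seed: int = 0,
):
    """Linear diversity~environment data with known redundancy R^2.

    Environment columns are iid standard normal; each response column is
    x . b + e with the coefficient and noise scales chosen so the
    population explained fraction equals effect_r2 exactly.  Returns
    (response DataFrame, environment DataFrame, truth dict).
    """
    if not 0.0 <= effect_r2 < 1.0:
        raise ValueError("effect_r2 must be in [0, 1)")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_sites, n_env))
    B = rng.standard_normal((n_env, n_indices))
    # scale each coefficient column so Var(x.b) = effect_r2, Var(e) = 1 - effect_r2
    norms = np.linalg.norm(B, axis=0)
    norms[norms == 0] = 1.0
    B = B / norms * np.sqrt(effect_r2)
    noise = rng.standard_normal((n_sites, n_indices)) * np.sqrt(1.0 - effect_r2)
    Y = X @ B + noise
    sites = [f"Site{i + 1}" for i in range(n_sites)]
    Ydf = pd.DataFrame(
        Y, index=sites, columns=[f"D{j + 1}" for j in range(n_indices)]
    )
    Xdf = pd.DataFrame(
        X, index=sites, columns=[f"E{j + 1}" for j in range(n_env)]
    )
    truth = {"B": B, "effect_r2": effect_r2}
    return Ydf, Xdf, truth


def simulate_monthly_climate(
    n_sites: int = 5,
    amt_range: tuple[float, float] = (3.0, 7.0),
    annual_rain_range: tuple[float, float] = (350.0, 500.0),
    amplitude_range: tuple[float, float] = (15.0, 19.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    amt_targets: list[float] | None = None,
) -> dict[str, MonthlyClimate]:
    """Sinusoidal seasonal cycles with a summer rainfall peak.

    Temperature: t_m = AMT - A cos(2 pi (m-1)/12) (+ optional noise),
    peaking in July.  Rainfall splits the annual total over months with
    summer-heavy weights.  amt_targets overrides the uniform draw of
    site mean temperatures.
    """
    rng = np.random.default_rng(seed)
    months = np.arange(12)
    season = -np.cos(2.0 * np.pi * months / 12.0)  # -1 in Jan, +1 in Jul
    if amt_targets is not None:
        amts = np.asarray(amt_targets, dtype=float)
        n_sites = len(amts)
    else:
        amts = rng.uniform(*amt_range, size=n_sites)
    out: dict[str, MonthlyClimate] = {}
    for i in range(n_sites):
        amp = rng.uniform(*amplitude_range)
        t = amts[i] + amp * season
        if noise_sd > 0:
            t = t + rng.normal(0.0, noise_sd, size=12)
        annual = rng.uniform(*annual_rain_range)
        weights = np.exp(1.5 * season)
        r = annual * weights / weights.sum()
        out[f"Site{i + 1}"] = MonthlyClimate(t=t, r=r)
    return out
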