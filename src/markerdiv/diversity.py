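"""Dominant-marker diversity statistics.

Implements the classical index suite for band presence/absence data
under a biallelic model with Hardy-Weinberg equilibrium: per-unit
percentage of polymorphic loci (P), observed and effective numbers of
alleles (Na, Ne), Nei's gene diversity (h), Shannon's information index
(I), and across-unit differentiation (Ht, Hs, Gst) with the equilibrium
gene-flow estimate Nm = 0.5(1 - Gst)/Gst.

The band-presence allele frequency p is inferred from the band phenotype
frequency B.  The default square-root estimator sets q = sqrt(1 - B)
(frequency of the recessive null allele) and p = 1 - q; the
Lynch-Milligan estimator applies the standard second-order bias
correction q = sqrt(x) / (1 - Var(x) / (8 x^2)) with x = 1 - B and
Var(x) = x(1 - x)/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .marker_data import MarkerMatrix

__all__ = [
    "AlleleFrequencies",
    "DiversitySummary",
    "DifferentiationSummary",
    "band_frequencies",
    "estimate_allele_frequencies",
    "locus_statistics",
    "diversity_summary",
    "differentiation",
    "gene_flow",
    "gst_from_nm",
]


@dataclass
class AlleleFrequencies:
    """Per-locus frequencies of the band-presence (p) and null (q) allele."""

    unit: str
    p: np.ndarray
    q: np.ndarray


@dataclass
class DiversitySummary:
    """POPGENE-style per-unit summary; dispersion is the across-locus SD."""

    unit: str
    sample_size: int
    n_polymorphic: int
    P: float  # percentage of polymorphic loci
    Na: float
    Na_sd: float
    Ne: float
    Ne_sd: float
    h: float
    h_sd: float
    I: float
    I_sd: float


@dataclass
class DifferentiationSummary:
    grouping: str
    Ht: float
    Hs: float
    Gst: float
    Nm: float


def band_frequencies(matrix: MarkerMatrix, unit: str = "all") -> np.ndarray:
    """Fraction of individuals in *unit* carrying the band, per locus."""
    rows = matrix.rows_in(unit)
    if rows.size == 0:
        raise ValueError(f"unit {unit!r} has no individuals")
    return matrix.values[rows].mean(axis=0)


def _sqrt_estimate(B: np.ndarray) -> np.ndarray:
    return np.sqrt(np.clip(1.0 - B, 0.0, 1.0))


def _lynch_milligan_estimate(B: np.ndarray, n: int) -> np.ndarray:
    x = np.clip(1.0 - B, 0.0, 1.0)
    q = np.sqrt(x)
    var = x * (1.0 - x) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = 1.0 - var / (8.0 * x**2)
    ok = x > 0
    q[ok] = q[ok] / corr[ok]
    return np.clip(q, 0.0, 1.0)


def estimate_allele_frequencies(
    matrix: MarkerMatrix, unit: str = "all", method: str = "sqrt"
) -> AlleleFrequencies:
    """Estimate the biallelic frequencies at every locus for one unit.

    method='sqrt' assumes Hardy-Weinberg: the band-absent phenotype is
    the null homozygote, so q = sqrt(1 - B).  method='lynch_milligan'
    adds the small-sample bias correction and requires >=2 individuals.
    """
    rows = matrix.rows_in(unit)
    B = matrix.values[rows].mean(axis=0)
    if method == "sqrt":
        q = _sqrt_estimate(B)
    elif method == "lynch_milligan":
        if rows.size < 2:
            raise ValueError("lynch_milligan requires >=2 individuals")
        q = _lynch_milligan_estimate(B, rows.size)
    else:
        raise ValueError(f"unknown estimator: {method!r}")
    p = np.clip(1.0 - q, 0.0, 1.0)
    return AlleleFrequencies(unit=unit, p=p, q=1.0 - p)


def locus_statistics(p: np.ndarray, q: np.ndarray, polymorphic: np.ndarray):
    """Per-locus Na, Ne, h and I from biallelic frequencies.

    Na is the count of observed alleles (2 where the locus is scored
    polymorphic, 1 otherwise); Ne = 1/(p^2+q^2); h = 1 - p^2 - q^2;
    I = -p ln p - q ln q with 0 ln 0 := 0.
    """
    na = np.where(polymorphic, 2.0, 1.0)
    sum_sq = p**2 + q**2
    ne = 1.0 / sum_sq
    h = 1.0 - sum_sq
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0) + np.where(
            q > 0, -q * np.log(q), 0.0
        )
    return na, ne, h, terms


def diversity_summary(
    matrix: MarkerMatrix,
    unit: str = "all",
    method: str = "sqrt",
    polymorphism_criterion: str = "any",
) -> DiversitySummary:
    """Per-unit index suite, averaged over ALL loci (monomorphic included).

    polymorphism_criterion='any' counts a locus as polymorphic when both
    phenotypes occur in the unit (0 < B < 1); 'freq95' additionally
    requires the minor allele frequency to exceed 5%.
    """
    rows = matrix.rows_in(unit)
    if rows.size == 0:
        raise ValueError(f"empty unit: {unit!r}")
    B = matrix.values[rows].mean(axis=0)
    freqs = estimate_allele_frequencies(matrix, unit, method)
    p, q = freqs.p, freqs.q
    if polymorphism_criterion == "any":
        poly = (B > 0) & (B < 1)
    elif polymorphism_criterion == "freq95":
        poly = (np.minimum(p, q) > 0.05)
    else:
        raise ValueError(f"unknown criterion: {polymorphism_criterion!r}")
    na, ne, h, inf = locus_statistics(p, q, poly)
    L = matrix.n_loci
    n_poly = int(poly.sum())

    def msd(x):
        return float(x.mean()), float(x.std(ddof=1)) if L > 1 else 0.0

    Na, Na_sd = msd(na)
    Ne, Ne_sd = msd(ne)
    H, H_sd = msd(h)
    I, I_sd = msd(inf)
    return DiversitySummary(
        unit=unit,
        sample_size=int(rows.size),
        n_polymorphic=n_poly,
        P=100.0 * n_poly / L,
        Na=Na,
        Na_sd=Na_sd,
        Ne=Ne,
        Ne_sd=Ne_sd,
        h=H,
        h_sd=H_sd,
        I=I,
        I_sd=I_sd,
    )


def differentiation(
    matrix: MarkerMatrix,
    units: list[str] | None = None,
    method: str = "sqrt",
    grouping_name: str = "populations",
) -> DifferentiationSummary:
    """Nei's gene differentiation across units (default: all populations).

    Per locus, Ht = 1 - pbar^2 - qbar^2 with pbar the unweighted mean of
    the unit allele frequencies, and Hs the unweighted mean of the unit
    gene diversities.  Ht and Hs are averaged over loci first and
    Gst = (Ht - Hs)/Ht is formed from the locus means (avoids 0/0 at
    loci monomorphic everywhere).
    """
    if units is None:
        units = matrix.populations
    if len(units) < 2:
        raise ValueError("differentiation needs >=2 units")
    P = np.stack(
        [estimate_allele_frequencies(matrix, u, method).p for u in units]
    )  # units x loci
    hs_loc = (1.0 - P**2 - (1.0 - P) ** 2).mean(axis=0)
    pbar = P.mean(axis=0)
    ht_loc = 1.0 - pbar**2 - (1.0 - pbar) ** 2
    Ht = float(ht_loc.mean())
    Hs = float(hs_loc.mean())
    if Ht == 0:
        raise ZeroDivisionError("all loci monomorphic in every unit: Gst undefined")
    Gst = max((Ht - Hs) / Ht, 0.0)  # guard float noise when units coincide
    nm = gene_flow(Gst) if Gst > 0 else float("inf")
    return DifferentiationSummary(
        grouping=grouping_name, Ht=Ht, Hs=Hs, Gst=Gst, Nm=nm
    )


def gene_flow(gst: float) -> float:
    """Equilibrium gene-flow estimate Nm = 0.5 (1 - Gst) / Gst."""
    if not 0.0 < gst <= 1.0:
        raise ValueError(f"Gst must be in (0, 1]: {gst}")
    return 0.5 * (1.0 - gst) / gst


def gst_from_nm(nm: float) -> float:
    """Inverse of :func:`gene_flow`: Gst = 1/(2 Nm + 1)."""
    if nm < 0:
        raise ValueError(f"Nm must be >= 0: {nm}")
    return 1.0 / (2.0 * nm + 1.0)
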