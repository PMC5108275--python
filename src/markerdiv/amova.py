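"""Analysis of molecular variance (AMOVA) for binary marker profiles.

Squared Euclidean distances between 0/1 band profiles (= the count of
loci at which two individuals differ) are partitioned into hierarchical
variance components following the classical sums-of-squares
decomposition: one-level designs split variation among and within
populations (Phi_ST); two-level designs add a group stratum above the
populations (Phi_CT among groups, Phi_SC among populations within
groups).  Significance is assessed by permutation: individuals among
populations for Phi_ST, whole populations among groups for Phi_CT, and
individuals among populations within their group for Phi_SC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .marker_data import GroupingScheme, MarkerMatrix

__all__ = [
    "AmovaResult",
    "ThresholdClassification",
    "squared_distance_matrix",
    "amova",
    "classify_populations",
]


@dataclass
class AmovaResult:
    """Variance decomposition table plus fixation indices and p-values."""

    rows: pd.DataFrame  # source, df, SS, variance, pct_variation
    phi: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    seed: int | None
    raw_components: dict[str, float] = field(default_factory=dict)


@dataclass
class ThresholdClassification:
    """Ordinal classes of populations along one environmental variable."""

    variable: str
    breaks: tuple[float, ...]
    class_of: dict[str, str]
    class_labels: tuple[str, ...] = ("low", "mid", "high")

    def as_grouping(self) -> GroupingScheme:
        return GroupingScheme(group_of=dict(self.class_of), name=self.variable)

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.class_of.values():
            out[c] = out.get(c, 0) + 1
        return out


def squared_distance_matrix(matrix: MarkerMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distance between 0/1 profiles.

    For binary vectors this equals the Hamming count of differing loci.
    """
    V = matrix.values.astype(np.int32)
    # (a-b)^2 summed = |a| + |b| - 2 a.b for 0/1 vectors
    sums = V.sum(axis=1)
    cross = V @ V.T
    d2 = sums[:, None] + sums[None, :] - 2 * cross
    np.fill_diagonal(d2, 0)
    return d2.astype(float)


def _ss_within_sets(d2: np.ndarray, sets: list[np.ndarray]) -> float:
    """Sum over sets of (1/n_k) * sum of pairwise d2 within the set."""
    total = 0.0
    for idx in sets:
        if idx.size < 1:
            continue
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * idx.size)
    return total


def _components_one_level(
    d2: np.ndarray, pops: list[np.ndarray]
) -> tuple[float, float, float, float, float, float]:
    N = sum(len(p) for p in pops)
    K = len(pops)
    ss_total = _ss_within_sets(d2, [np.concatenate(pops)])
    ss_within = _ss_within_sets(d2, pops)
    ss_among = ss_total - ss_within
    df_among, df_within = K - 1, N - K
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    sizes = np.array([len(p) for p in pops], dtype=float)
    n0 = (N - (sizes**2).sum() / N) / (K - 1)
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0
    return ss_among, ss_within, ss_total, sigma_among, sigma_within, n0


def _phi_st_one_level(d2: np.ndarray, pops: list[np.ndarray]) -> float:
    _, _, _, sa, sw, _ = _components_one_level(d2, pops)
    tot = sa + sw
    return sa / tot if tot > 0 else 0.0


def _components_two_level(d2: np.ndarray, groups: list[list[np.ndarray]]):
    """Excoffier two-level decomposition with unequal-size coefficients."""
    pops = [p for g in groups for p in g]
    N = sum(len(p) for p in pops)
    K = len(pops)
    G = len(groups)
    all_idx = np.concatenate(pops)
    ss_total = _ss_within_sets(d2, [all_idx])
    ss_wp = _ss_within_sets(d2, pops)
    ss_groups = _ss_within_sets(d2, [np.concatenate(g) for g in groups])
    ss_ap_wg = ss_groups - ss_wp
    ss_ag = ss_total - ss_groups
    df_ag, df_ap, df_wp = G - 1, K - G, N - K
    ms_ag = ss_ag / df_ag
    ms_ap = ss_ap_wg / df_ap if df_ap > 0 else 0.0
    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    group_sizes = np.array([sum(len(p) for p in g) for g in groups], dtype=float)
    # unequal-size coefficients (standard three-coefficient scheme)
    sum_nk2_over_Ng = sum(
        sum(len(p) ** 2 for p in g) / Ng for g, Ng in zip(groups, group_sizes)
    )
    sum_nk2_over_N = sum(len(p) ** 2 for p in pops) / N
    sum_Ng2_over_N = (group_sizes**2).sum() / N
    n_c = (N - sum_nk2_over_Ng) / (K - G) if K > G else 1.0
    n_cp = (sum_nk2_over_Ng - sum_nk2_over_N) / (G - 1)
    n_cpp = (N - sum_Ng2_over_N) / (G - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n_c if K > G else 0.0
    sigma_a = (ms_ag - sigma_c - n_cp * sigma_b) / n_cpp
    return {
        "ss_ag": ss_ag,
        "ss_ap_wg": ss_ap_wg,
        "ss_wp": ss_wp,
        "ss_total": ss_total,
        "df_ag": df_ag,
        "df_ap": df_ap,
        "df_wp": df_wp,
        "sigma_a": sigma_a,
        "sigma_b": sigma_b,
        "sigma_c": sigma_c,
    }


def _phis_two_level(comp: dict[str, float]) -> dict[str, float]:
    sa, sb, sc = comp["sigma_a"], comp["sigma_b"], comp["sigma_c"]
    tot = sa + sb + sc
    return {
        "Phi_ST": (sa + sb) / tot if tot > 0 else 0.0,
        "Phi_CT": sa / tot if tot > 0 else 0.0,
        "Phi_SC": sb / (sb + sc) if (sb + sc) > 0 else 0.0,
    }


def amova(
    matrix: MarkerMatrix,
    grouping: GroupingScheme | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Run a one-level (populations) or two-level (groups) AMOVA.

    p-values use the permutation convention p = (1 + #{perm >= obs}) /
    (n_perm + 1).  Negative variance components are truncated to zero
    for the percentage column but reported signed in raw_components.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pops_order = matrix.populations
    if len(pops_order) < 2:
        raise ValueError("AMOVA needs >=2 populations")
    d2 = squared_distance_matrix(matrix)
    pop_idx = {p: matrix.rows_in(p) for p in pops_order}
    rng = np.random.default_rng(seed)
    labels = np.array([matrix.population_of[i] for i in matrix.individual_ids])

    if grouping is None:
        pops = [pop_idx[p] for p in pops_order]
        ss_a, ss_w, ss_t, sa, sw, _ = _components_one_level(d2, pops)
        phi_obs = _phi_st_one_level(d2, pops)
        count = 0
        sizes = [len(p) for p in pops]
        order = np.arange(matrix.n_individuals)
        for _ in range(n_perm):
            perm = rng.permutation(order)
            sets, start = [], 0
            for s in sizes:
                sets.append(perm[start : start + s])
                start += s
            if _phi_st_one_level(d2, sets) >= phi_obs - 1e-12:
                count += 1
        p_st = (1 + count) / (n_perm + 1)
        sa_t, sw_t = max(sa, 0.0), max(sw, 0.0)
        tot = sa_t + sw_t
        if tot == 0:
            raise ZeroDivisionError("zero total variance: degenerate data")
        rows = pd.DataFrame(
            {
                "source": ["Among populations", "Within populations", "Total"],
                "df": [len(pops) - 1, matrix.n_individuals - len(pops),
                       matrix.n_individuals - 1],
                "SS": [ss_a, ss_w, ss_t],
                "variance": [sa_t, sw_t, tot],
                "pct_variation": [100 * sa_t / tot, 100 * sw_t / tot, 100.0],
            }
        )
        return AmovaResult(
            rows=rows,
            phi={"Phi_ST": phi_obs},
            p_values={"Phi_ST": p_st},
            n_permutations=n_perm,
            seed=seed,
            raw_components={"sigma_among": sa, "sigma_within": sw},
        )

    # ---- two-level design -------------------------------------------------
    grouping.check_covers(matrix)
    group_names = list(dict.fromkeys(grouping.group_of[p] for p in pops_order))
    if len(group_names) < 2:
        raise ValueError("two-level AMOVA needs >=2 groups")
    pops_by_group = {
        g: [p for p in pops_order if grouping.group_of[p] == g] for g in group_names
    }
    groups = [[pop_idx[p] for p in pops_by_group[g]] for g in group_names]
    comp = _components_two_level(d2, groups)
    phis = _phis_two_level(comp)

    # Phi_ST: permute individuals across everything
    all_pops_flat = [pop_idx[p] for p in pops_order]
    sizes = [len(p) for p in all_pops_flat]
    group_of_pop = [grouping.group_of[p] for p in pops_order]

    def split(perm):
        sets, start = [], 0
        for s in sizes:
            sets.append(perm[start : start + s])
            start += s
        return sets

    def regroup(sets):
        by_g: dict[str, list[np.ndarray]] = {g: [] for g in group_names}
        for g, s in zip(group_of_pop, sets):
            by_g[g].append(s)
        return [by_g[g] for g in group_names]

    order = np.arange(matrix.n_individuals)
    counts = {"Phi_ST": 0, "Phi_CT": 0, "Phi_SC": 0}
    for _ in range(n_perm):
        # Phi_ST: individuals among populations, ignoring groups
        sets = split(rng.permutation(order))
        ph = _phis_two_level(_components_two_level(d2, regroup(sets)))
        if ph["Phi_ST"] >= phis["Phi_ST"] - 1e-12:
            counts["Phi_ST"] += 1
        # Phi_CT: permute whole populations among groups
        perm_pops = rng.permutation(len(pops_order))
        by_g: dict[str, list[np.ndarray]] = {g: [] for g in group_names}
        for slot, k in enumerate(perm_pops):
            by_g[group_of_pop[slot]].append(all_pops_flat[k])
        ph = _phis_two_level(
            _components_two_level(d2, [by_g[g] for g in group_names])
        )
        if ph["Phi_CT"] >= phis["Phi_CT"] - 1e-12:
            counts["Phi_CT"] += 1
        # Phi_SC: permute individuals among populations within each group
        new_groups = []
        for g in group_names:
            g_pops = [pop_idx[p] for p in pops_by_group[g]]
            pool = rng.permutation(np.concatenate(g_pops))
            sets_g, start = [], 0
            for p in g_pops:
                sets_g.append(pool[start : start + len(p)])
                start += len(p)
            new_groups.append(sets_g)
        ph = _phis_two_level(_components_two_level(d2, new_groups))
        if ph["Phi_SC"] >= phis["Phi_SC"] - 1e-12:
            counts["Phi_SC"] += 1
    p_values = {k: (1 + c) / (n_perm + 1) for k, c in counts.items()}

    sa = max(comp["sigma_a"], 0.0)
    sb = max(comp["sigma_b"], 0.0)
    sc = max(comp["sigma_c"], 0.0)
    tot = sa + sb + sc
    if tot == 0:
        raise ZeroDivisionError("zero total variance: degenerate data")
    rows = pd.DataFrame(
        {
            "source": [
                "Among groups",
                "Among populations within groups",
                "Within populations",
                "Total",
            ],
            "df": [comp["df_ag"], comp["df_ap"], comp["df_wp"],
                   matrix.n_individuals - 1],
            "SS": [comp["ss_ag"], comp["ss_ap_wg"], comp["ss_wp"], comp["ss_total"]],
            "variance": [sa, sb, sc, tot],
            "pct_variation": [
                100 * sa / tot,
                100 * sb / tot,
                100 * sc / tot,
                100.0,
            ],
        }
    )
    return AmovaResult(
        rows=rows,
        phi=phis,
        p_values=p_values,
        n_permutations=n_perm,
        seed=seed,
        raw_components={k: comp[k] for k in ("sigma_a", "sigma_b", "sigma_c")},
    )


def classify_populations(
    env: pd.DataFrame,
    variable: str,
    breaks="tertiles",
    labels: tuple[str, ...] | None = None,
) -> ThresholdClassification:
    """Assign populations to ordinal classes along one variable.

    With explicit *breaks* (strictly increasing), a value exactly on a
    break goes to the LOWER class.  With breaks='tertiles', populations
    are split by rank into three classes of near-equal size (20 values
    give 7/7/6); ties in value are broken by input order.
    """
    if variable not in env.columns:
        raise KeyError(f"variable {variable!r} not in environment table")
    values = env[variable]
    pops = list(env.index.astype(str))
    if isinstance(breaks, str) and breaks == "tertiles":
        order = np.argsort(values.to_numpy(), kind="stable")
        n = len(pops)
        cls = np.empty(n, dtype=int)
        for rank, pos in enumerate(order):
            cls[pos] = rank * 3 // n
        labels = labels or ("low", "mid", "high")
        class_of = {p: labels[c] for p, c in zip(pops, cls)}
        return ThresholdClassification(
            variable=variable, breaks=(), class_of=class_of, class_labels=labels
        )
    breaks = tuple(float(b) for b in breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    labels = labels or (
        ("low", "mid", "high") if len(breaks) == 2
        else tuple(f"class{i}" for i in range(len(breaks) + 1))
    )
    if len(labels) != len(breaks) + 1:
        raise ValueError("need one more label than breaks")
    class_of = {}
    for p, v in zip(pops, values):
        k = int(np.sum(np.asarray(breaks) < v))  # value on a break -> lower class
        class_of[p] = labels[k]
    return ThresholdClassification(
        variable=variable, breaks=breaks, class_of=class_of, class_labels=tuple(labels)
    )
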