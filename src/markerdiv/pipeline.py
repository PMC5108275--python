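"""One-command reproduction of the full analysis surface.

Given a marker matrix (real or simulated) plus environment tables, the
pipeline writes: the per-population diversity table, gradient-pooled
differentiation (Gst/Nm), one-level and grouped AMOVAs, diversity x
environment correlation matrices, and the climate and soil redundancy
analyses with forward selection — plus a machine-readable summary and a
run log recording every resolved flag and seed.

Fixtures-only mode (no marker matrix) runs the correlation and RDA
stages directly on the packaged published tables: the published
diversity indices become the response.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datasets
from .amova import amova, classify_populations
from .diversity import differentiation, diversity_summary
from .marker_data import MarkerMatrix, read_marker_matrix
from .rda import (
    fit_rda,
    forward_selection,
    marginal_contributions,
    pearson_correlations,
    permutation_test,
    preprocess,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "PipelineError", "run_full_analysis"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Paths and flags for a full run.

    With marker_path=None the pipeline runs in fixtures-only mode on the
    packaged published tables.  climate_path/soil_path default to the
    packaged tables when None.
    """

    marker_path: str | None = None
    climate_path: str | None = None
    soil_path: str | None = None
    grouping: dict[str, str] | None = None  # population -> gradient class
    estimator: str = "sqrt"
    polymorphism_criterion: str = "any"
    standardize: bool = True
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 1
    out_dir: str = "results/pipeline"
    decimals: int = 4
    extra: dict = field(default_factory=dict)


def _diversity_table(matrix: MarkerMatrix, cfg: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for pop in matrix.populations:
        s = diversity_summary(
            matrix, pop, method=cfg.estimator,
            polymorphism_criterion=cfg.polymorphism_criterion,
        )
        rows.append(
            {
                "population": pop, "sample_size": s.sample_size,
                "n": s.n_polymorphic, "P": s.P, "Na": s.Na, "Na_sd": s.Na_sd,
                "Ne": s.Ne, "Ne_sd": s.Ne_sd, "h": s.h, "h_sd": s.h_sd,
                "I": s.I, "I_sd": s.I_sd,
            }
        )
    sp = diversity_summary(
        matrix, "all", method=cfg.estimator,
        polymorphism_criterion=cfg.polymorphism_criterion,
    )
    rows.append(
        {
            "population": "Species level", "sample_size": sp.sample_size,
            "n": sp.n_polymorphic, "P": sp.P, "Na": sp.Na, "Na_sd": sp.Na_sd,
            "Ne": sp.Ne, "Ne_sd": sp.Ne_sd, "h": sp.h, "h_sd": sp.h_sd,
            "I": sp.I, "I_sd": sp.I_sd,
        }
    )
    return pd.DataFrame(rows).set_index("population")


def _gradient_table(matrix: MarkerMatrix, grouping: dict[str, str],
                    cfg: AnalysisConfig) -> pd.DataFrame:
    classes: dict[str, list[str]] = {}
    for pop, cls in grouping.items():
        classes.setdefault(cls, []).append(pop)
    rows = []
    for cls, pops in classes.items():
        if len(pops) < 2:
            logger.warning("gradient class %r has <2 populations; skipped", cls)
            continue
        d = differentiation(matrix, units=pops, method=cfg.estimator,
                            grouping_name=cls)
        rows.append(
            {"class": cls, "n_populations": len(pops), "Ht": d.Ht, "Hs": d.Hs,
             "Gst": d.Gst, "Nm": d.Nm}
        )
    return pd.DataFrame(rows).set_index("class")


def _rda_bundle(Y: pd.DataFrame, X: pd.DataFrame, label: str,
                cfg: AnalysisConfig, seed: int) -> tuple[dict, dict[str, pd.DataFrame]]:
    Yt = preprocess(Y, standardize=cfg.standardize)
    Xt = preprocess(X, standardize=cfg.standardize)
    res = fit_rda(Yt, Xt)
    f_all, p_all = permutation_test(
        Yt, Xt, term="all", n_perm=cfg.n_permutations, seed=seed
    )
    trace = forward_selection(
        Yt, Xt, alpha=cfg.alpha, n_perm=cfg.n_permutations, seed=seed + 1
    )
    marg = marginal_contributions(Yt, Xt)
    r, p = pearson_correlations(Y, X)
    eig = pd.DataFrame(
        {
            "eigenvalue": res.constrained_eigenvalues,
            "fraction_of_total": res.axis_fractions,
        },
        index=[f"RDA{i+1}" for i in range(len(res.constrained_eigenvalues))],
    )
    partition = pd.DataFrame(
        {"marginal_fraction": marg, "marginal_pct": 100 * marg}
    )
    summary = {
        f"{label}_explained_pct": 100 * res.explained_fraction,
        f"{label}_axis1_pct": (
            100 * res.axis_fractions[0] if len(res.axis_fractions) else 0.0
        ),
        f"{label}_axis2_pct": (
            100 * res.axis_fractions[1] if len(res.axis_fractions) > 1 else 0.0
        ),
        f"{label}_overall_pseudo_F": f_all,
        f"{label}_overall_p": p_all,
        f"{label}_selected": trace.selected,
    }
    tables = {
        f"rda_{label}_eigenvalues": eig,
        f"rda_{label}_variance_partition": partition,
        f"rda_{label}_forward_selection": trace.as_frame(),
        f"correlations_{label}_r": r,
        f"correlations_{label}_p": p,
    }
    return summary, tables


def run_full_analysis(cfg: AnalysisConfig) -> dict:
    """Run every applicable stage; returns the summary dict.

    All tables are computed before anything is written, so a failing
    stage leaves no partial output.  Tables are written rounded to
    cfg.decimals with full-precision companions (suffix _full).
    """
    log_lines = [f"seed={cfg.seed}", f"estimator={cfg.estimator}",
                 f"polymorphism_criterion={cfg.polymorphism_criterion}",
                 f"standardize={cfg.standardize}",
                 f"n_permutations={cfg.n_permutations}", f"alpha={cfg.alpha}"]
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {}

    matrix = None
    if cfg.marker_path is not None:
        try:
            matrix = read_marker_matrix(cfg.marker_path)
        except Exception as exc:
            raise PipelineError("read_markers", exc) from exc

    try:
        climate = (
            pd.read_csv(cfg.climate_path, index_col=0)
            if cfg.climate_path
            else datasets.load_climate_populations()
        )
        soil = (
            pd.read_csv(cfg.soil_path, index_col=0)
            if cfg.soil_path
            else datasets.load_soil_table()
        )
    except Exception as exc:
        raise PipelineError("read_environment", exc) from exc

    if matrix is not None:
        try:
            div = _diversity_table(matrix, cfg)
            tables["diversity_populations"] = div
            summary["species_h"] = float(div.loc["Species level", "h"])
            summary["species_I"] = float(div.loc["Species level", "I"])
            d_all = differentiation(matrix, method=cfg.estimator)
            summary.update(
                {"Ht": d_all.Ht, "Hs": d_all.Hs, "Gst": d_all.Gst, "Nm": d_all.Nm}
            )
        except Exception as exc:
            raise PipelineError("diversity", exc) from exc
        if cfg.grouping:
            try:
                tables["gradients_differentiation"] = _gradient_table(
                    matrix, cfg.grouping, cfg
                )
            except Exception as exc:
                raise PipelineError("gradients", exc) from exc
        try:
            res1 = amova(matrix, n_perm=cfg.n_permutations, seed=cfg.seed)
            tables["amova_populations"] = res1.rows.set_index("source")
            summary["Phi_ST"] = res1.phi["Phi_ST"]
            summary["Phi_ST_p"] = res1.p_values["Phi_ST"]
            for var, env_df in (("WI", climate), ("SOP", soil)):
                if var not in env_df.columns:
                    continue
                common = [p for p in matrix.populations if p in env_df.index]
                if len(common) != len(matrix.populations):
                    log_lines.append(
                        f"amova_{var}: environment table does not cover all "
                        "populations; grouped AMOVA skipped"
                    )
                    continue
                cls = classify_populations(env_df.loc[common], var, "tertiles")
                res2 = amova(
                    matrix, cls.as_grouping(), n_perm=cfg.n_permutations,
                    seed=cfg.seed,
                )
                tables[f"amova_{var}_groups"] = res2.rows.set_index("source")
                for key, val in res2.phi.items():
                    summary[f"{var}_{key}"] = val
                    summary[f"{var}_{key}_p"] = res2.p_values[key]
        except Exception as exc:
            raise PipelineError("amova", exc) from exc
        response = tables["diversity_populations"].loc[
            matrix.populations, datasets.DIVERSITY_INDICES
        ]
    else:
        response = datasets.load_diversity_table()
        log_lines.append("fixtures-only mode: published diversity table as response")

    for label, env_df in (("climate", climate), ("soil", soil)):
        try:
            common = response.index.intersection(env_df.index)
            if len(common) < 4:
                log_lines.append(f"rda_{label}: <4 shared populations; skipped")
                continue
            s, t = _rda_bundle(
                response.loc[common], env_df.loc[common], label, cfg, cfg.seed
            )
            summary.update(s)
            tables.update(t)
        except Exception as exc:
            raise PipelineError(f"rda_{label}", exc) from exc

    out = Path(cfg.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.round(cfg.decimals).to_csv(out / f"{name}.csv")
            df.to_csv(out / f"{name}_full.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        with open(out / "run_log.txt", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    except Exception as exc:
        for f in out.glob("*"):
            f.unlink(missing_ok=True)
        raise PipelineError("write_outputs", exc) from exc
    return summary
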