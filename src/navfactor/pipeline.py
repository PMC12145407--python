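"""End-to-end pipeline: simulate -> score -> model -> associate.

Mirrors the analysis order of the study design: descriptives, partial
correlations within and across paradigms (controlling age and IQ), the
six confirmatory factor models with fit indices and a power column,
factor scores from the best-fitting proper model, and regressions of
those scores on the paradigm-independent measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import (
    PARADIGM_INDICATORS,
    composite_scores,
    descriptives,
    partial_correlation_matrix,
    regress_factor_scores,
    required_n_rmsea,
)
from .cfa import build_indicator_table, candidate_model_specs, compare_models, factor_scores, fit_cfa
from .io import write_json, write_raw_trials, write_scored_table
from .latent import INDICATORS, LatentSpec, default_latent_spec
from .simulate import draw_participants, generate_raw_trials, score_participants

ALL_MODELS = (
    "unifactorial",
    "bifactorial_layout",
    "bifactorial_modality",
    "trifactorial_task",
    "trifactorial_paradigm",
    "trifactorial_paradigm_covariates",
)


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    seed: int = 0
    n: int = 94
    models: tuple[str, ...] = ALL_MODELS
    out_dir: str = "navfactor_run"
    verbosity: int = 1
    latent_spec: LatentSpec | None = None

    def to_yaml(self, path) -> None:
        payload = {
            "seed": self.seed,
            "n": self.n,
            "models": list(self.models),
            "out_dir": str(self.out_dir),
            "verbosity": self.verbosity,
        }
        if self.latent_spec is not None:
            payload["latent_spec"] = {
                "factor_names": list(self.latent_spec.factor_names),
                "loadings": {k: [f, float(l)] for k, (f, l) in self.latent_spec.loadings.items()},
                "phi": self.latent_spec.phi.tolist(),
                "covariate_effects": {
                    c: dict(v) for c, v in self.latent_spec.covariate_effects.items()
                },
            }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        spec = None
        if "latent_spec" in payload:
            raw = payload["latent_spec"]
            spec = LatentSpec(
                factor_names=tuple(raw["factor_names"]),
                loadings={k: (v[0], float(v[1])) for k, v in raw["loadings"].items()},
                phi=np.asarray(raw["phi"], dtype=float),
                covariate_effects={
                    c: {f: float(x) for f, x in v.items()}
                    for c, v in raw.get("covariate_effects", {}).items()
                },
            )
        return cls(
            seed=int(payload.get("seed", 0)),
            n=int(payload.get("n", 94)),
            models=tuple(payload.get("models", ALL_MODELS)),
            out_dir=str(payload.get("out_dir", "navfactor_run")),
            verbosity=int(payload.get("verbosity", 1)),
            latent_spec=spec,
        )


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise PipelineError(f"[stage: {name}] {err}") from err

        return wrapper

    return deco


def fit_models(
    table: pd.DataFrame, model_names=ALL_MODELS, seed: int = 0
) -> tuple[list, pd.DataFrame]:
    """Fit the requested hypothesized models and build the comparison table.

    The comparison table carries, per model, the a-priori sample size
    required for 80% power at RMSEA effect size 0.15 and alpha 0.05 given
    the model's degrees of freedom.
    """
    specs = {s.name: s for s in candidate_model_specs()}
    unknown = [m for m in model_names if m not in specs]
    if unknown:
        raise PipelineError(f"[stage: fit] unknown models {unknown}")
    fits = [fit_cfa(specs[m], table, seed=seed) for m in model_names]
    comparison = compare_models(fits)
    comparison["power_required_n"] = [
        required_n_rmsea(0.15, 0.05, 0.80, int(df)) for df in comparison["df"]
    ]
    return fits, comparison


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write all artifacts under ``config.out_dir``.

    Returns a dict of the in-memory results (scored table, comparison
    table, fits, regressions, manifest).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.latent_spec or default_latent_spec()
    warnings: list[str] = []
    if config.n < 50:
        warnings.append(
            f"n={config.n} is small for covariance-structure modelling; "
            "fit indices and loadings will be unstable"
        )

    # -- simulate ----------------------------------------------------------
    latents = _stage("simulate")(draw_participants)(spec, config.n, config.seed)
    raw = _stage("simulate")(generate_raw_trials)(latents, spec, config.seed + 1)
    write_raw_trials(raw, out / "raw")

    # -- score -------------------------------------------------------------
    scored = _stage("score")(score_participants)(raw)
    write_scored_table(scored, out / "scored.csv")

    # -- descriptives ------------------------------------------------------
    desc = _stage("descriptives")(descriptives)(
        scored, list(INDICATORS) + ["sbsod", "nsq", "mrt", "ptta", "kbit_iq"]
    )
    desc.to_csv(out / "descriptives.csv")

    # -- correlations ------------------------------------------------------
    table = _stage("standardize")(build_indicator_table)(scored)
    within_r, within_p = _stage("correlations")(partial_correlation_matrix)(
        table, list(INDICATORS)
    )
    within_r.to_csv(out / "within_paradigm_partial_r.csv")
    within_p.to_csv(out / "within_paradigm_partial_p.csv")
    comp = composite_scores(table)
    comp_table = pd.concat([comp, table[["age", "kbit_iq"]]], axis=1)
    cross_r, cross_p = partial_correlation_matrix(comp_table, list(PARADIGM_INDICATORS))
    cross_r.to_csv(out / "cross_paradigm_partial_r.csv")
    cross_p.to_csv(out / "cross_paradigm_partial_p.csv")

    # -- factor models -----------------------------------------------------
    fits, comparison = _stage("fit")(fit_models)(table, config.models, seed=config.seed)
    comparison.to_csv(out / "model_comparison.csv")
    write_json(
        {
            f.spec.name: {
                "chi2": f.chi2,
                "df": f.df,
                "p_value": f.p_value,
                "cfi": f.cfi,
                "rmsea": f.rmsea,
                "converged": f.converged,
                "proper_solution": f.proper_solution,
                "loadings_std": f.loadings_std.to_dict(),
                "phi_std": f.phi_std.to_numpy().tolist(),
                "gamma_std": None if f.gamma_std is None else f.gamma_std.to_dict(),
            }
            for f in fits
        },
        out / "model_fits.json",
    )

    # -- factor scores and regressions ------------------------------------
    results: dict = {
        "scored": scored,
        "comparison": comparison,
        "fits": fits,
        "regressions": {},
    }
    by_name = {f.spec.name: f for f in fits}
    best_name = comparison.iloc[0]["model"]
    score_fit = by_name.get("trifactorial_paradigm", by_name.get(best_name))
    if score_fit is not None and score_fit.proper_solution:
        scores = _stage("factor_scores")(factor_scores)(score_fit, table)
        scores.to_csv(out / "factor_scores.csv", index=False)
        predictors = table[["ptta", "mrt", "nsq", "sbsod", "age", "kbit_iq"]].copy()
        predictors["gender"] = table["gender"].to_numpy()
        reg_rows = []
        for fac in scores.columns:
            y = (scores[fac] - scores[fac].mean()) / scores[fac].std(ddof=1)
            rr = _stage("regression")(regress_factor_scores)(y, predictors, outcome_name=fac)
            results["regressions"][fac] = rr
            if (rr.vif >= 2).any():
                warnings.append(f"VIF >= 2 among predictors of {fac}")
            for name in rr.beta.index:
                reg_rows.append(
                    {
                        "outcome": fac,
                        "predictor": name,
                        "beta": rr.beta[name],
                        "se": rr.se[name],
                        "ci_low": rr.ci_low[name],
                        "ci_high": rr.ci_high[name],
                        "p_value": rr.p_values[name],
                        "f_partial": rr.f_partial.get(name, np.nan),
                        "vif": rr.vif.get(name, np.nan),
                        "adj_r2": rr.adj_r2,
                    }
                )
        pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)
    else:
        warnings.append("no proper factor-model fit; factor scores and regressions skipped")

    manifest = {
        "package": "navfactor",
        "version": __version__,
        "seed": config.seed,
        "n": config.n,
        "models": list(config.models),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "warnings": warnings,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    write_json(manifest, out / "run_manifest.json")
    results["manifest"] = manifest
    if config.verbosity:
        print(f"pipeline complete: {len(raw)} participants, artifacts in {out}")
        for w in warnings:
            print(f"  warning: {w}")
    return results
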