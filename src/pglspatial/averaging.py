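"""All-subsets AICc model averaging with relative variable importance.

Every subset of the candidate predictor terms is fit by PGLS-spatial (the
dependence parameters are re-optimized within each candidate model), models
are weighted by exp(-dAICc/2) normalized to sum to one, and each predictor's
relative variable importance (RVI) is the summed weight of the models that
contain it. Coefficients are model-averaged either conditionally (weights
renormalized over the models containing the term) or in "full" mode (absent
terms contribute zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pglspatial.covariance import CovarianceSet
from pglspatial.gls import (
    GLSFit,
    VarianceCache,
    dependence_tests,
    fit_pgls_spatial,
    gls_r_squared,
    sweep_profile_grid,
)

__all__ = [
    "CandidateModel",
    "ModelAveragingResult",
    "enumerate_models",
    "akaike_weights",
    "relative_variable_importance",
    "model_averaged_coefficients",
    "run_model_averaging",
]

MAX_PREDICTORS = 20


@dataclass
class CandidateModel:
    """One candidate model: the included terms, its fit, and its Akaike weight."""

    included: tuple[str, ...]
    fit: GLSFit
    weight: float | None = None


@dataclass
class ModelAveragingResult:
    """Per-predictor RVI, averaged coefficients and dependence-component summary."""

    rvi: dict[str, float]
    beta_avg: dict[str, float]
    ci: dict[str, tuple[float, float]]
    dependence: dict[str, float]
    models: list[CandidateModel]
    predictors: list[str]
    r2_best: float | None = None
    n: int = 0

    def table(self) -> pd.DataFrame:
        """Predictor table sorted by RVI descending (the shape of the study's result tables)."""
        rows = []
        for term in self.predictors:
            lo, hi = self.ci.get(term, (np.nan, np.nan))
            rows.append(
                {"predictor": term, "rvi": self.rvi[term],
                 "beta": self.beta_avg.get(term, np.nan), "ci_lo": lo, "ci_hi": hi}
            )
        return pd.DataFrame(rows).sort_values("rvi", ascending=False, kind="mergesort").reset_index(drop=True)

    def to_flat_dict(self) -> dict[str, float]:
        """Flat scalar summary used for aggregation across replicates."""
        out: dict[str, float] = {}
        for term in self.predictors:
            out[f"rvi.{term}"] = self.rvi[term]
            out[f"beta.{term}"] = self.beta_avg.get(term, np.nan)
            lo, hi = self.ci.get(term, (np.nan, np.nan))
            out[f"ci_lo.{term}"] = lo
            out[f"ci_hi.{term}"] = hi
        out.update({f"dependence.{k}": v for k, v in self.dependence.items()})
        if self.r2_best is not None:
            out["r2_best"] = self.r2_best
        out["n"] = float(self.n)
        return out


def enumerate_models(predictors) -> list[tuple[str, ...]]:
    """All 2^k subsets of the predictor terms, in binary-counting order.

    The empty (intercept-only) model is included. With 10 candidate predictors
    this yields 1024 models. Factor terms mapped to several dummy columns enter
    and leave as a block (the term, not the column, is the unit here).
    """
    predictors = list(predictors)
    k = len(predictors)
    if k == 0:
        return [()]
    if k > MAX_PREDICTORS:
        raise ValueError(
            f"{k} predictors would enumerate {2**k} models; restrict the candidate set explicitly"
        )
    return [tuple(p for i, p in enumerate(predictors) if (m >> i) & 1) for m in range(2**k)]


def akaike_weights(aiccs) -> np.ndarray:
    """Akaike weights w_i = exp(-dAICc_i/2) / sum_j exp(-dAICc_j/2)."""
    aiccs = np.asarray(aiccs, dtype=float)
    bad = np.where(~np.isfinite(aiccs))[0]
    if bad.size:
        raise ValueError(f"non-finite AICc for models {bad.tolist()}")
    delta = aiccs - aiccs.min()
    raw = np.exp(-delta / 2.0)
    return raw / raw.sum()


def relative_variable_importance(models: list[CandidateModel]) -> dict[str, float]:
    """RVI per term: the sum of Akaike weights of all models including it."""
    terms = sorted({t for m in models for t in m.included})
    return {t: float(sum(m.weight for m in models if t in m.included)) for t in terms}


def model_averaged_coefficients(models: list[CandidateModel], mode: str = "conditional"):
    """Akaike-weighted coefficients and 95% CIs per design column.

    conditional: weights are renormalized over models containing the term;
    the interval uses the unconditional variance
    sum w~_i [se_i^2 + (beta_i - beta_bar)^2]. full: absent models contribute
    beta = 0 with se = 0 and weights are not renormalized.
    """
    if mode not in ("conditional", "full"):
        raise ValueError(f"mode must be 'conditional' or 'full', got {mode!r}")
    cols = []
    for m in models:
        for t in m.fit.terms:
            if t != "intercept" and t not in cols:
                cols.append(t)
    beta_avg: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    for col in cols:
        betas, ses, ws = [], [], []
        for m in models:
            if col in m.fit.terms:
                j = m.fit.terms.index(col)
                betas.append(m.fit.beta[j])
                ses.append(m.fit.se[j])
                ws.append(m.weight)
            elif mode == "full":
                betas.append(0.0)
                ses.append(0.0)
                ws.append(m.weight)
        betas, ses, ws = np.asarray(betas), np.asarray(ses), np.asarray(ws)
        if ws.sum() <= 0:
            continue
        if mode == "conditional":
            ws = ws / ws.sum()
        bbar = float(ws @ betas)
        var_u = float(ws @ (ses**2 + (betas - bbar) ** 2))
        half = 1.96 * np.sqrt(var_u)
        beta_avg[col] = bbar
        ci[col] = (bbar - half, bbar + half)
    return beta_avg, ci


def run_model_averaging(
    X: pd.DataFrame,
    y,
    cov: CovarianceSet,
    term_map: dict[str, list[str]] | None = None,
    forced_in: list[str] | None = None,
    gls_mode: str = "both",
    averaging_mode: str = "conditional",
) -> ModelAveragingResult:
    """Enumerate, fit and average all candidate models on one dataset.

    ``X`` holds the design columns (no intercept); ``term_map`` groups columns
    into predictor terms that enter/leave together (default: every column is
    its own term). ``forced_in`` terms appear in every model (RVI 1 by
    construction). The dependence summary (lambda', phi, gamma and their LRT
    p-values) is computed on the full design with every candidate included.
    """
    y = np.asarray(y, dtype=float).ravel()
    if term_map is None:
        term_map = {c: [c] for c in X.columns}
    forced_in = list(forced_in or [])
    candidates = [t for t in term_map if t not in forced_in]
    subsets = enumerate_models(candidates)
    cache = VarianceCache(cov)

    Xfull = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in X.columns])
    col_index = {c: i + 1 for i, c in enumerate(X.columns)}

    terms_per_subset = [forced_in + list(s) for s in subsets]
    cols_per_subset = [[c for t in terms for c in term_map[t]] for terms in terms_per_subset]
    idx_per_subset = [[0] + [col_index[c] for c in cols] for cols in cols_per_subset]
    _, seed_vals = sweep_profile_grid(cache, Xfull, y, idx_per_subset, gls_mode)

    models: list[CandidateModel] = []
    for m, subset in enumerate(subsets):
        fit = fit_pgls_spatial(
            Xfull, y, cov, mode=gls_mode, cache=cache, cols=idx_per_subset[m],
            terms=["intercept"] + cols_per_subset[m],
            seed_nll=None if seed_vals is None else seed_vals[m],
        )
        models.append(CandidateModel(included=tuple(terms_per_subset[m]), fit=fit))

    weights = akaike_weights([m.fit.aicc for m in models])
    for m, w in zip(models, weights):
        m.weight = float(w)

    rvi = {t: 0.0 for t in term_map}
    rvi.update(relative_variable_importance(models))
    beta_cols, ci_cols = model_averaged_coefficients(models, mode=averaging_mode)
    # report per-term by its design columns; single-column terms read naturally
    beta_avg = dict(beta_cols)
    ci = dict(ci_cols)
    for t, cols in term_map.items():
        if len(cols) == 1 and cols[0] != t and cols[0] in beta_cols:
            beta_avg[t] = beta_cols[cols[0]]
            ci[t] = ci_cols[cols[0]]

    full_tests = dependence_tests(Xfull, y, cov, cache=cache)
    p_full = full_tests.fits["both"].params
    dependence = {
        "lambda_prime": p_full.lam_prime,
        "phi": p_full.phi,
        "gamma": p_full.gamma,
        "p_lambda": full_tests.p_lambda,
        "p_phi": full_tests.p_phi,
    }

    best = int(np.argmin([m.fit.aicc for m in models]))
    best_model = models[best]
    best_cols = [c for t in best_model.included for c in term_map[t]]
    Xbest = Xfull[:, [0] + [col_index[c] for c in best_cols]]
    try:
        r2_best = gls_r_squared(best_model.fit, Xbest, y, cov)
    except ValueError:
        r2_best = None

    report_terms = []
    for t, cols in term_map.items():
        report_terms.extend(cols if len(cols) > 1 else [t])
        for c in cols:
            if len(cols) > 1:
                rvi.setdefault(c, rvi[t])
    return ModelAveragingResult(
        rvi=rvi,
        beta_avg=beta_avg,
        ci=ci,
        dependence=dependence,
        models=models,
        predictors=report_terms,
        r2_best=r2_best,
        n=len(y),
    )
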