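"""Variable transformation, OLS fitting, exhaustive AICc model selection, and
95%-confidence-set model averaging.

Conventions follow the small-sample information-theoretic workflow standard in
macroecology: candidate models are all subsets of the standardized predictors
(any spatial filter held fixed in every model), ranked by
AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1) with k counting the intercept, the
slopes, the filter columns and the error variance.  Akaike weights
w_m = exp(-Delta_m/2)/sum exp(-Delta/2) define the smallest 95% confidence
set, within which coefficients are model-averaged with zero substitution and
Burnham-Anderson unconditional standard errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransformSpec",
    "ModelFit",
    "ModelSet",
    "AveragedModel",
    "transform",
    "fit_ols",
    "aicc",
    "all_subsets",
    "confidence_set",
    "model_average",
]


@dataclass(frozen=True)
class TransformSpec:
    """Which columns get log / sqrt transforms before standardization."""

    log_vars: tuple[str, ...] = ("richness", "t_velocity", "p_velocity", "beta_eff")
    sqrt_vars: tuple[str, ...] = ("p_ann",)
    standardize: bool = True


def transform(table: pd.DataFrame, spec: TransformSpec = TransformSpec()) -> pd.DataFrame:
    """Natural-log / square-root transforms then optional z-standardization.

    Standardization (mean 0, sd 1 with the n-1 denominator) is applied to
    every numeric column, response included, so that estimates are
    comparable across predictors.
    """
    out = table.copy()
    for col in spec.log_vars:
        if col not in out.columns:
            raise KeyError(f"log variable {col!r} not in table")
        vals = out[col].astype(float)
        if (vals <= 0).any():
            bad = out.index[vals <= 0][0]
            raise ValueError(f"non-positive value of {col!r} at site {bad}: cannot log-transform")
        out[col] = np.log(vals)
    for col in spec.sqrt_vars:
        if col not in out.columns:
            raise KeyError(f"sqrt variable {col!r} not in table")
        vals = out[col].astype(float)
        if (vals < 0).any():
            bad = out.index[vals < 0][0]
            raise ValueError(f"negative value of {col!r} at site {bad}: cannot sqrt-transform")
        out[col] = np.sqrt(vals)
    if spec.standardize:
        num = out.select_dtypes(include=[np.number]).columns
        for col in num:
            sd = out[col].std(ddof=1)
            if sd == 0:
                raise ValueError(f"constant column {col!r} cannot be standardized")
            out[col] = (out[col] - out[col].mean()) / sd
    return out


@dataclass(frozen=True)
class ModelFit:
    """One fitted OLS candidate model (intercept and fixed terms always included)."""

    terms: tuple[str, ...]
    coefficients: Mapping[str, float]
    std_errors: Mapping[str, float]
    t_values: Mapping[str, float]
    p_values: Mapping[str, float]
    r_squared: float
    log_likelihood: float
    n: int
    k: int  # intercept + slopes + filter columns + error variance
    aicc: float
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)


def _aicc_value(log_lik: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        raise ValueError(f"model too large for AICc (n={n}, k={k})")
    return -2.0 * log_lik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def aicc(fit: ModelFit) -> float:
    """Sample-size-corrected Akaike information criterion of a fitted model."""
    return _aicc_value(fit.log_likelihood, fit.n, fit.k)


def fit_ols(
    y: Sequence[float] | np.ndarray,
    X: pd.DataFrame | None,
    filter_basis: np.ndarray | None = None,
) -> ModelFit:
    """OLS of y on [1, X, filter] with Gaussian log-likelihood and AICc.

    X may be None/empty for the intercept-only model.  Filter columns (e.g. a
    fixed SEVM basis) are appended after the named terms and reported as
    ``_sevm{i}``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    names = ["(Intercept)"]
    cols = [np.ones(n)]
    if X is not None and len(getattr(X, "columns", [])) > 0:
        for c in X.columns:
            names.append(str(c))
            cols.append(np.asarray(X[c], dtype=float))
    nq = 0
    if filter_basis is not None and filter_basis.size:
        nq = filter_basis.shape[1]
        for i in range(nq):
            names.append(f"_sevm{i + 1}")
            cols.append(filter_basis[:, i])
    D = np.column_stack(cols)
    p = D.shape[1]
    if np.linalg.matrix_rank(D) < p:
        raise ValueError(f"rank-deficient design; collinear terms among {names}")
    if n <= p + 1:
        raise ValueError("too few observations")
    beta, rss, fitted, resid, se = _ols_core(D, y)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    # Gaussian log-likelihood at the MLE variance rss/n
    ll = -0.5 * n * (np.log(2.0 * np.pi) + np.log(max(rss, 1e-300) / n) + 1.0)
    k = p + 1  # + error variance
    return ModelFit(
        terms=tuple(names[1 : p - nq]),
        coefficients=dict(zip(names, beta)),
        std_errors=dict(zip(names, se)),
        t_values=dict(zip(names, tvals)),
        p_values=dict(zip(names, pvals)),
        r_squared=float(r2),
        log_likelihood=float(ll),
        n=n,
        k=k,
        aicc=_aicc_value(float(ll), n, k),
        residuals=resid,
        fitted=fitted,
    )


def _ols_core(D: np.ndarray, y: np.ndarray):
    """Least squares with coefficient covariance via the Gram inverse."""
    G = D.T @ D
    Ginv = np.linalg.inv(G)
    beta = Ginv @ (D.T @ y)
    fitted = D @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    n, p = D.shape
    sigma2 = rss / (n - p)
    se = np.sqrt(np.maximum(np.diag(Ginv) * sigma2, 0.0))
    return beta, rss, fitted, resid, se


@dataclass(frozen=True)
class ModelSet:
    """AICc-ranked candidate models with Akaike weights (ascending AICc)."""

    fits: tuple[ModelFit, ...]
    delta_aicc: tuple[float, ...]
    akaike_weights: tuple[float, ...]

    @property
    def best(self) -> ModelFit:
        return self.fits[0]


def _rank_models(fits: list[ModelFit]) -> ModelSet:
    # sort by AICc; ties by fewer terms, then lexicographic term names
    fits = sorted(fits, key=lambda f: (f.aicc, len(f.terms), f.terms))
    a = np.array([f.aicc for f in fits])
    delta = a - a[0]
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    return ModelSet(tuple(fits), tuple(float(d) for d in delta), tuple(float(x) for x in w))


def all_subsets(
    y: Sequence[float] | np.ndarray,
    candidates: pd.DataFrame,
    filter_basis: np.ndarray | None = None,
    max_terms: int = 16,
) -> ModelSet:
    """Fit every subset of the candidate terms (2^p models).

    Each model includes the intercept and all filter columns (the fixed
    spatial filter).  Rank-deficient subsets are skipped with a warning.
    """
    term_names = [str(c) for c in candidates.columns]
    if len(term_names) > max_terms:
        raise ValueError(f"too many candidate terms ({len(term_names)} > {max_terms})")
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xfull = candidates.to_numpy(dtype=float)
    nq = filter_basis.shape[1] if filter_basis is not None and filter_basis.size else 0
    fixed = filter_basis if nq else np.empty((n, 0))
    # precompute the Gram matrix of [1 | candidates | fixed] once
    D_all = np.column_stack([np.ones(n), Xfull, fixed])
    G_all = D_all.T @ D_all
    g_all = D_all.T @ y
    yty = float(y @ y)
    tss = float(np.sum((y - y.mean()) ** 2))
    p_cand = len(term_names)
    fixed_idx = [0] + list(range(1 + p_cand, 1 + p_cand + nq))
    fits: list[ModelFit] = []
    skipped = 0
    for mask in itertools.product([0, 1], repeat=p_cand):
        subset = [i for i, b in enumerate(mask) if b]
        idx = fixed_idx[:1] + [1 + i for i in subset] + fixed_idx[1:]
        G = G_all[np.ix_(idx, idx)]
        g = g_all[idx]
        p = len(idx)
        if n <= p + 1:
            skipped += 1
            continue
        try:
            Ginv = np.linalg.inv(G)
        except np.linalg.LinAlgError:
            skipped += 1
            continue
        if np.linalg.cond(G) > 1e12:
            skipped += 1
            continue
        beta = Ginv @ g
        rss = max(float(yty - 2 * beta @ g + beta @ G @ beta), 0.0)
        sigma2 = rss / (n - p)
        se = np.sqrt(np.maximum(np.diag(Ginv) * sigma2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
        ll = -0.5 * n * (np.log(2.0 * np.pi) + np.log(max(rss, 1e-300) / n) + 1.0)
        k = p + 1
        names = (
            ["(Intercept)"]
            + [term_names[i] for i in subset]
            + [f"_sevm{i + 1}" for i in range(nq)]
        )
        fits.append(
            ModelFit(
                terms=tuple(term_names[i] for i in subset),
                coefficients=dict(zip(names, beta)),
                std_errors=dict(zip(names, se)),
                t_values=dict(zip(names, tvals)),
                p_values=dict(zip(names, pvals)),
                r_squared=float(1.0 - rss / tss) if tss > 0 else 1.0,
                log_likelihood=float(ll),
                n=n,
                k=k,
                aicc=_aicc_value(float(ll), n, k),
            )
        )
    if skipped:
        import warnings

        warnings.warn(f"skipped {skipped} rank-deficient/oversized subsets")
    if not fits:
        raise ValueError("no fittable subsets")
    return _rank_models(fits)


def confidence_set(model_set: ModelSet, level: float = 0.95) -> ModelSet:
    """Smallest AICc-ordered prefix with cumulative Akaike weight >= level.

    Weights are renormalized within the retained subset.
    """
    cum = np.cumsum(model_set.akaike_weights)
    n_keep = int(np.searchsorted(cum, level - 1e-12) + 1)
    n_keep = min(n_keep, len(model_set.fits))
    fits = model_set.fits[:n_keep]
    delta = model_set.delta_aicc[:n_keep]
    w = np.array(model_set.akaike_weights[:n_keep])
    w = w / w.sum()
    return ModelSet(fits, delta, tuple(float(x) for x in w))


@dataclass(frozen=True)
class AveragedModel:
    """Full (zero-substitution) model-averaged coefficients over a model set."""

    terms: tuple[str, ...]
    coefficients: Mapping[str, float]
    unconditional_se: Mapping[str, float]
    z_values: Mapping[str, float]
    p_values: Mapping[str, float]
    relative_importance: Mapping[str, float]


def model_average(model_set: ModelSet) -> AveragedModel:
    """Average coefficients across models with zero substitution.

    beta_bar_j = sum_m w_m beta_jm (beta_jm = 0 where term j is absent);
    unconditional SE_j = sum_m w_m sqrt(var_jm + (beta_jm - beta_bar_j)^2);
    two-sided p from a normal z on the unconditional SE.
    """
    w = np.array(model_set.akaike_weights)
    terms = sorted({t for f in model_set.fits for t in f.terms})
    names = ["(Intercept)"] + terms
    coefs, ses, zs, ps, imp = {}, {}, {}, {}, {}
    for name in names:
        b = np.array([f.coefficients.get(name, 0.0) for f in model_set.fits])
        v = np.array([f.std_errors.get(name, 0.0) ** 2 for f in model_set.fits])
        bbar = float(w @ b)
        se = float(w @ np.sqrt(v + (b - bbar) ** 2))
        coefs[name] = bbar
        ses[name] = se
        z = bbar / se if se > 0 else np.inf * np.sign(bbar) if bbar else 0.0
        zs[name] = float(z)
        ps[name] = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
        if name != "(Intercept)":
            present = np.array([name in f.terms for f in model_set.fits])
            imp[name] = float(w[present].sum())
    return AveragedModel(tuple(terms), coefs, ses, zs, ps, imp)
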