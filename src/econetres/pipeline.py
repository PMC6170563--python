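"""End-to-end study: networks -> beta_eff -> site table -> transformed
regression -> Moran diagnostics -> (if needed) SEVM -> AICc selection,
averaging, and report tables.

The regression step mirrors the standard macroecological protocol: a full OLS
model of (log, standardized) network resilience on the nine candidate terms
(richness, elevation, T_mean, T_seasonality, P_ann, P_seasonality, human
footprint, T_velocity, P_velocity); an exact Moran test on the residuals; and,
when residual spatial autocorrelation is significant (p < 0.05), a spatial
eigenvector (SEVM) re-analysis in which the Moran-eigenvector filter selected
on the full model is held fixed through model selection and averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bipartite_io import IncidenceMatrix
from .model_selection import (
    AveragedModel,
    ModelFit,
    ModelSet,
    TransformSpec,
    all_subsets,
    confidence_set,
    fit_ols,
    model_average,
    transform,
)
from .resilience import beta_eff, network_summary, project
from .spatial import (
    EigenvectorFilter,
    MoranTestResult,
    SpatialWeights,
    build_weights,
    moran_residual_test,
    select_spatial_filter,
)

__all__ = ["StudyConfig", "ApproachReport", "StudyReport", "run_study",
           "render_report", "residual_partials", "CANDIDATE_TERMS"]

logger = logging.getLogger("econetres")

#: the nine candidate explanatory terms of the full model
CANDIDATE_TERMS = (
    "richness",
    "elevation",
    "t_mean",
    "t_seasonality",
    "p_ann",
    "p_seasonality",
    "hf",
    "t_velocity",
    "p_velocity",
)


@dataclass(frozen=True)
class StudyConfig:
    response: str = "beta_eff_plant"
    alpha: float = 0.05
    knn_k: int = 4
    confidence_level: float = 0.95
    sevm_trigger: str = "full"  # test full-model residuals ("full", "best", "either")
    transform_spec: TransformSpec | None = None
    seed: int = 0


@dataclass(frozen=True)
class ApproachReport:
    """Full/best/averaged results for one modelling approach (OLS or SEVM)."""

    approach: str  # "OLS" | "SEVM"
    full: ModelFit
    model_set: ModelSet = field(repr=False, default=None)
    best: ModelFit = None
    averaged: AveragedModel = None
    moran_full: MoranTestResult = None
    moran_best: MoranTestResult = None
    filter: EigenvectorFilter | None = None


@dataclass(frozen=True)
class StudyReport:
    response: str
    table: pd.DataFrame = field(repr=False)
    ols: ApproachReport
    sevm: ApproachReport | None
    weights: SpatialWeights = field(repr=False, default=None)
    provenance: Mapping[str, object] = field(default_factory=dict)

    @property
    def sevm_triggered(self) -> bool:
        return self.sevm is not None


def _design(table: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    return table.loc[:, list(terms)]


def _moran_design(full: ModelFit, table: pd.DataFrame, terms: Sequence[str],
                  filter_basis: np.ndarray | None) -> np.ndarray:
    n = len(table)
    cols = [np.ones(n)] + [table[t].to_numpy(dtype=float) for t in terms]
    if filter_basis is not None and filter_basis.size:
        cols.append(filter_basis)
    return np.column_stack(cols)


def _fit_approach(
    approach: str,
    y: np.ndarray,
    table: pd.DataFrame,
    weights: SpatialWeights,
    cfg: StudyConfig,
    filter_basis: np.ndarray | None,
    filt: EigenvectorFilter | None,
) -> ApproachReport:
    X_full = _design(table, CANDIDATE_TERMS)
    full = fit_ols(y, X_full, filter_basis)
    model_set = all_subsets(y, X_full, filter_basis)
    best = model_set.best
    cset = confidence_set(model_set, cfg.confidence_level)
    averaged = model_average(cset)
    moran_full = moran_residual_test(
        _moran_design(full, table, CANDIDATE_TERMS, filter_basis), y, weights, method="exact"
    )
    moran_best = moran_residual_test(
        _moran_design(best, table, best.terms, filter_basis), y, weights, method="exact"
    )
    logger.info(
        "%s: n=%d best terms=%s AICc=%.2f Moran p(full)=%.3f filter q=%d",
        approach, full.n, best.terms, best.aicc, moran_full.p_value,
        0 if filt is None else filt.q,
    )
    return ApproachReport(approach, full, model_set, best, averaged,
                         moran_full, moran_best, filt)


def run_study(
    networks: Mapping[str, IncidenceMatrix] | None,
    site_table: pd.DataFrame,
    response: str = "beta_eff_plant",
    config: StudyConfig | None = None,
) -> StudyReport:
    """Run the full analysis for one response (plant- or animal-side resilience).

    ``networks`` maps site_id -> pruned binary incidence matrix; if the site
    table already carries the response and richness columns, ``networks`` may
    be None.  The table must hold raw-scale covariates; transformation and
    standardization happen here.
    """
    cfg = config or StudyConfig(response=response)
    table = site_table.copy()
    if networks is not None:
        side = "plant" if "plant" in response else "animal"
        missing = [sid for sid in table.index if sid not in networks]
        if missing:
            raise ValueError(f"stage join: no network for sites {missing}")
        table[response] = [
            beta_eff(project(networks[sid], side)).beta_eff for sid in table.index
        ]
        table["richness"] = [network_summary(networks[sid])["richness"] for sid in table.index]
    if response not in table.columns:
        raise ValueError(f"stage join: response column {response!r} missing")

    spec = cfg.transform_spec or TransformSpec(
        log_vars=("richness", "t_velocity", "p_velocity", response),
        sqrt_vars=("p_ann",),
        standardize=True,
    )
    cols = ["latitude", "longitude", *CANDIDATE_TERMS, response]
    try:
        ztab = transform(table.loc[:, [c for c in cols if c != "latitude" and c != "longitude"]], spec)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"stage transform: {exc}") from exc
    y = ztab[response].to_numpy(dtype=float)
    coords = table.loc[:, ["latitude", "longitude"]].to_numpy(dtype=float)
    weights = build_weights(coords, k=cfg.knn_k)

    ols = _fit_approach("OLS", y, ztab, weights, cfg, None, None)

    trigger_p = {
        "full": ols.moran_full.p_value,
        "best": ols.moran_best.p_value,
        "either": min(ols.moran_full.p_value, ols.moran_best.p_value),
    }[cfg.sevm_trigger]
    sevm = None
    if trigger_p < cfg.alpha:
        X_full = _moran_design(ols.full, ztab, CANDIDATE_TERMS, None)
        filt = select_spatial_filter(X_full, y, weights, alpha=cfg.alpha)
        basis = filt.basis if filt.q else None
        # the filter is FIXED: every SEVM candidate model carries it
        sevm = _fit_approach("SEVM", y, ztab, weights, cfg, basis, filt)

    report = StudyReport(
        response=response,
        table=ztab.assign(latitude=coords[:, 0], longitude=coords[:, 1]),
        ols=ols,
        sevm=sevm,
        weights=weights,
        provenance={
            "response": response,
            "alpha": cfg.alpha,
            "knn_k": cfg.knn_k,
            "confidence_level": cfg.confidence_level,
            "sevm_trigger": cfg.sevm_trigger,
            "seed": cfg.seed,
            "n_sites": len(table),
            "transform": {
                "log": list(spec.log_vars), "sqrt": list(spec.sqrt_vars),
                "standardize": spec.standardize,
            },
        },
    )
    return report


def _fmt(x: float | None, p: float | None) -> str:
    if x is None:
        return ""
    if p is None:
        return f"{x:.3f}"
    ptxt = "<0.01" if p < 0.01 else f"{p:.2f}"
    return f"{x:.3f} ({ptxt})"


def report_table(report: StudyReport) -> pd.DataFrame:
    """Coefficient table mirroring the study's published layout: one row per
    term, columns estimate(full/best/average) per approach, plus Moran's I
    and R-squared rows (p-values in brackets)."""
    approaches = [report.ols] + ([report.sevm] if report.sevm else [])
    rows = {}
    for term in CANDIDATE_TERMS:
        row = {}
        for ap in approaches:
            row[f"{ap.approach} full"] = _fmt(
                ap.full.coefficients.get(term), ap.full.p_values.get(term)
            )
            row[f"{ap.approach} best"] = (
                _fmt(ap.best.coefficients.get(term), ap.best.p_values.get(term))
                if term in ap.best.terms else ""
            )
            row[f"{ap.approach} average"] = (
                _fmt(ap.averaged.coefficients.get(term), ap.averaged.p_values.get(term))
                if term in ap.averaged.terms else ""
            )
        rows[term] = row
    for ap in approaches:
        rows.setdefault("Moran's I", {})[f"{ap.approach} full"] = _fmt(
            ap.moran_full.I, ap.moran_full.p_value
        )
        rows["Moran's I"][f"{ap.approach} best"] = _fmt(ap.moran_best.I, ap.moran_best.p_value)
        rows["Moran's I"][f"{ap.approach} average"] = ""
        rows.setdefault("R2", {})[f"{ap.approach} full"] = _fmt(ap.full.r_squared, None)
        rows["R2"][f"{ap.approach} best"] = _fmt(ap.best.r_squared, None)
        rows["R2"][f"{ap.approach} average"] = ""
    df = pd.DataFrame(rows).T
    df.index.name = "variable"
    return df


def render_report(report: StudyReport, out_dir: str | Path, fmt: str = "csv") -> list[Path]:
    """Write the coefficient table (CSV and/or markdown) plus a provenance block."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = report_table(report)
    written = []
    if fmt in ("csv", "both"):
        p = out_dir / f"{report.response}_models.csv"
        df.to_csv(p)
        written.append(p)
    if fmt in ("markdown", "both"):
        p = out_dir / f"{report.response}_models.md"
        lines = [f"# Model results: {report.response}", ""]
        if report.sevm is None:
            lines.append("SEVM: not triggered (full-model residual Moran p >= alpha)")
            lines.append("")
        lines.append(df.to_markdown())
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    prov = out_dir / f"{report.response}_provenance.txt"
    with open(prov, "w") as fh:
        for k in sorted(report.provenance):
            fh.write(f"{k}: {report.provenance[k]}\n")
    written.append(prov)
    return written


def residual_partials(
    report: StudyReport, term: str, approach: str = "auto"
) -> tuple[np.ndarray, np.ndarray]:
    """Added-variable (partial-residual) pairs for one best-model term.

    Returns (x_resid, y_resid): the focal term and the response, each
    residualized on the other best-model terms (plus the spatial filter for
    the SEVM approach).  The OLS slope of y_resid on x_resid equals the
    term's best-model coefficient (Frisch-Waugh-Lovell).
    """
    if approach == "auto":
        ap = report.sevm if report.sevm is not None else report.ols
    elif approach.upper() == "SEVM":
        if report.sevm is None:
            raise ValueError("SEVM approach was not triggered for this study")
        ap = report.sevm
    else:
        ap = report.ols
    best = ap.best
    if term not in best.terms:
        raise ValueError(f"term {term!r} not in the {ap.approach} best model {best.terms}")
    tab = report.table
    others = [t for t in best.terms if t != term]
    n = len(tab)
    cols = [np.ones(n)] + [tab[t].to_numpy(dtype=float) for t in others]
    if ap.filter is not None and ap.filter.q:
        cols.append(ap.filter.basis)
    Z = np.column_stack(cols)
    Q, _ = np.linalg.qr(Z)

    def resid(v: np.ndarray) -> np.ndarray:
        return v - Q @ (Q.T @ v)

    x = tab[term].to_numpy(dtype=float)
    y = tab[report.response].to_numpy(dtype=float)
    return resid(x), resid(y)
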