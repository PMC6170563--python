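"""Synthetic study generator: random site networks, spatially autocorrelated
covariates, and responses with known ground truth.

The generator emulates the statistical shape of a global mutualistic-network
compilation: a few dozen sites scattered over a large extent, spatially
autocorrelated environmental covariates (Gaussian random fields with
exponential covariance over great-circle distance), binary bipartite webs of
varying richness and connectance, and a response that is a linear combination
of standardized covariates plus spatially structured and iid noise.

Two modes:

* ``regression-recovery`` — the response (a log-resilience surrogate) is
  drawn directly from the linear model, so the regression machinery can be
  checked against known coefficients;
* ``end-to-end`` — bipartite networks are generated with the animal richness
  monotonically linked to a chosen covariate, and beta_eff computed from the
  networks carries the signal through the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bipartite_io import IncidenceMatrix
from .resilience import beta_eff, network_summary, project
from .spatial import great_circle_matrix

__all__ = [
    "SimulationConfig",
    "POLLINATION_PRESET",
    "SEED_DISPERSAL_PRESET",
    "generate_sites",
    "generate_spatial_field",
    "generate_bipartite",
    "generate_study",
]

#: covariates the study regression uses (richness enters via the networks)
ENV_COVARIATES = (
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
class SimulationConfig:
    """Study-level knobs; defaults mirror the pollination-scale compilation
    (62 sites) over a continental extent."""

    n_sites: int = 62
    lat_range: tuple[float, float] = (-30.0, 30.0)
    lon_range: tuple[float, float] = (-60.0, 60.0)
    #: true standardized coefficients of the response on each covariate
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"richness": 0.4, "hf": 0.25, "t_velocity": 0.2}
    )
    #: exponential-covariance field for covariates and the structured error
    field_range_km: float = 1500.0
    field_sill: float = 1.0
    field_nugget: float = 0.05
    spatial_error_sill: float = 0.5
    iid_noise_sd: float = 0.4
    n_plants_range: tuple[int, int] = (8, 30)
    n_animals_range: tuple[int, int] = (10, 45)
    connectance_range: tuple[float, float] = (0.15, 0.45)
    seed: int = 0


POLLINATION_PRESET = SimulationConfig(n_sites=62)
SEED_DISPERSAL_PRESET = SimulationConfig(
    n_sites=30, n_plants_range=(6, 25), n_animals_range=(6, 30)
)


def generate_sites(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform random (lat, lon) coordinates within the configured extent."""
    if cfg.n_sites < 3:
        raise ValueError("need at least 3 sites")
    if cfg.lat_range[0] >= cfg.lat_range[1] or cfg.lon_range[0] >= cfg.lon_range[1]:
        raise ValueError("degenerate extent")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lat = rng.uniform(*cfg.lat_range, cfg.n_sites)
    lon = rng.uniform(*cfg.lon_range, cfg.n_sites)
    return np.column_stack([lat, lon])


def generate_spatial_field(
    coords: np.ndarray,
    range_km: float,
    sill: float = 1.0,
    nugget: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Zero-mean Gaussian random field with covariance sill*exp(-d/range) + nugget*I.

    Drawn by Cholesky factorization of the covariance over the great-circle
    distance matrix (jittered once if needed).
    """
    if range_km <= 0:
        raise ValueError("range must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    D = great_circle_matrix(coords)
    C = sill * np.exp(-D / range_km) + nugget * np.eye(len(coords))
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        try:
            L = np.linalg.cholesky(C + 1e-10 * np.trace(C) / len(coords) * np.eye(len(coords)))
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance not positive definite after jitter") from exc
    return L @ rng.standard_normal(len(coords))


def generate_bipartite(
    n: int,
    m: int,
    connectance: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    max_redraws: int = 50,
) -> IncidenceMatrix:
    """Random binary bipartite web: each cell 1 with probability = connectance,
    redrawn until no plant or animal is isolated."""
    if not 0 < connectance <= 1:
        raise ValueError("connectance must be in (0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    for _ in range(max_redraws):
        M = (rng.random((n, m)) < connectance).astype(float)
        if M.sum(axis=1).min() > 0 and M.sum(axis=0).min() > 0:
            plants = tuple(f"P{i + 1}" for i in range(n))
            animals = tuple(f"A{j + 1}" for j in range(m))
            return IncidenceMatrix(plants, animals, M)
    raise ValueError(f"connectance {connectance} too low for a {n}x{m} web without isolates")


def generate_study(
    cfg: SimulationConfig,
    mode: str = "regression-recovery",
    link_covariate: str = "t_velocity",
    link_strength: float = 1.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Generate a complete synthetic study.

    Returns a dict with ``sites`` (DataFrame indexed by site_id, raw scale),
    ``networks`` (site_id -> IncidenceMatrix), ``response`` (the surrogate
    log-beta_eff in regression-recovery mode; None in end-to-end mode where
    beta_eff comes from the networks), and ``truth`` (the generating model).
    """
    if mode not in {"regression-recovery", "end-to-end"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    coords = generate_sites(cfg, rng)
    n = cfg.n_sites

    # independent spatially autocorrelated covariates, standardized
    cov: dict[str, np.ndarray] = {}
    for name in ENV_COVARIATES:
        f = generate_spatial_field(
            coords, cfg.field_range_km, cfg.field_sill, cfg.field_nugget, rng=rng
        )
        cov[name] = (f - f.mean()) / f.std(ddof=1)

    # networks: richness and connectance per site
    nets: dict[str, IncidenceMatrix] = {}
    site_ids = [f"S{i + 1:03d}" for i in range(n)]
    if mode == "end-to-end":
        # animal richness follows the link covariate (monotone link)
        u = cov[link_covariate]
        rank = (pd.Series(u).rank().to_numpy() - 0.5) / n
        lo, hi = cfg.n_animals_range
        m_sizes = np.round(lo + (hi - lo) * np.clip(rank * link_strength + (1 - link_strength) * rng.random(n), 0, 1)).astype(int)
    else:
        m_sizes = rng.integers(cfg.n_animals_range[0], cfg.n_animals_range[1] + 1, n)
    n_sizes = rng.integers(cfg.n_plants_range[0], cfg.n_plants_range[1] + 1, n)
    conns = rng.uniform(*cfg.connectance_range, n)
    for sid, np_, m_, c_ in zip(site_ids, n_sizes, m_sizes, conns):
        c_eff = max(c_, 3.0 / min(np_, m_))  # keep isolate-free draws feasible
        nets[sid] = generate_bipartite(int(np_), int(m_), min(c_eff, 1.0), rng=rng)

    # raw-scale covariates whose standard transforms (log velocities, sqrt
    # precipitation, z-standardization) recover the Gaussian fields exactly
    raw = {
        "elevation": 1200.0 + 600.0 * cov["elevation"],
        "t_mean": 150.0 + 80.0 * cov["t_mean"],
        "t_seasonality": 40.0 + 15.0 * cov["t_seasonality"],
        "p_ann": (35.0 + 6.0 * np.clip(cov["p_ann"], -5, 5)) ** 2,
        "p_seasonality": 50.0 + 20.0 * cov["p_seasonality"],
        "hf": 30.0 + 15.0 * cov["hf"],
        "t_velocity": np.exp(cov["t_velocity"]),
        "p_velocity": np.exp(cov["p_velocity"]),
    }
    rows = []
    for i, (sid, (lat, lon)) in enumerate(zip(site_ids, coords)):
        summ = network_summary(nets[sid])
        rows.append({"site_id": sid, "latitude": lat, "longitude": lon,
                     **{k: raw[k][i] for k in ENV_COVARIATES},
                     "richness": summ["richness"], "connectance": summ["connectance"]})
    sites = pd.DataFrame(rows).set_index("site_id")

    response = None
    truth = {
        "mode": mode,
        "coefficients": dict(cfg.coefficients),
        "spatial_error_sill": cfg.spatial_error_sill,
        "iid_noise_sd": cfg.iid_noise_sd,
        "field_range_km": cfg.field_range_km,
    }
    if mode == "regression-recovery":
        logS = np.log(sites["richness"].to_numpy(dtype=float))
        zS = (logS - logS.mean()) / logS.std(ddof=1)
        lin = np.zeros(n)
        for name, b in cfg.coefficients.items():
            lin += b * (zS if name == "richness" else cov[name])
        eps_sp = (
            generate_spatial_field(coords, cfg.field_range_km, cfg.spatial_error_sill, 0.0, rng=rng)
            if cfg.spatial_error_sill > 0
            else np.zeros(n)
        )
        eps = rng.standard_normal(n) * cfg.iid_noise_sd
        response = lin + eps_sp + eps
        truth["linear_predictor"] = lin
    else:
        truth["link_covariate"] = link_covariate
        truth["link_strength"] = link_strength
        for side in ("plant", "animal"):
            sites[f"beta_eff_{side}"] = [
                beta_eff(project(nets[sid], side)).beta_eff for sid in site_ids
            ]
    return {"sites": sites, "networks": nets, "response": response,
            "coords": coords, "truth": truth}
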