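"""One-mode projection of bipartite networks and the macroscopic resilience
parameter beta_eff.

The bipartite plant-animal network (incidence matrix M, n plants x m animals)
is projected onto one side with inverse-degree weights:

    plant side:   A_ij = sum_k M_ik M_jk / sum_s M_sk      (k over animals)
    animal side:  A_ij = sum_k M_ki M_kj / sum_s M_ks      (k over plants)

i.e. A_ij is the sum of the inverse degrees of the partners plants (animals)
i and j share: sharing more partners strengthens the effective mutualistic
coupling, while a generalist shared partner contributes less to each pair.

The effective one-dimensional dynamics of such a network has a single
macroscopic resilience parameter

    beta_eff = sum_ij A_ij A_ji / sum_ij A_ij

(for the symmetric A produced here this is sum A_ij^2 / sum A_ij); larger
beta_eff means the community state is further from the collapse threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .bipartite_io import IncidenceMatrix

__all__ = ["ProjectedNetwork", "ResilienceResult", "project", "beta_eff", "network_summary"]

Side = Literal["plant", "animal"]
DiagonalPolicy = Literal["include", "exclude"]
Variant = Literal["ratio", "gao"]


@dataclass(frozen=True)
class ProjectedNetwork:
    """Symmetric weighted one-mode network for one side of a bipartite web."""

    side: Side
    labels: tuple[str, ...]
    A: np.ndarray
    diagonal_policy: DiagonalPolicy = "include"

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("projected matrix must be square")
        if A.shape[0] != len(self.labels):
            raise ValueError("labels do not match matrix dimension")
        if not np.array_equal(A, A.T):
            raise ValueError("projected matrix must be exactly symmetric")
        if np.any(A < 0):
            raise ValueError("negative projection weights")


@dataclass(frozen=True)
class ResilienceResult:
    beta_eff: float
    side: Side
    variant: Variant
    diagonal_policy: DiagonalPolicy


def project(
    net: IncidenceMatrix,
    side: Side,
    diagonal_policy: DiagonalPolicy = "include",
) -> ProjectedNetwork:
    """Inverse-degree one-mode projection of a binary, pruned bipartite network.

    Weighted inputs are rejected (binarize first); zero rows/columns are
    rejected (prune first) because they zero the degree denominators.
    """
    if not net.is_binary:
        raise ValueError("projection requires a binary incidence matrix; binarize first")
    M = net.M
    if np.any(M.sum(axis=1) == 0) or np.any(M.sum(axis=0) == 0):
        raise ValueError("zero row/column in incidence matrix; prune isolates first")
    if side == "plant":
        # A_ij = sum_k M_ik M_jk / d_k with d_k = animal k's plant degree
        d = M.sum(axis=0)
        A = (M / d) @ M.T
        labels = net.plant_labels
    elif side == "animal":
        d = M.sum(axis=1)
        A = (M / d[:, None]).T @ M
        labels = net.animal_labels
    else:
        raise ValueError(f"unknown side {side!r}")
    A = (A + A.T) / 2.0  # symmetric up to rounding; make it exact
    if diagonal_policy == "exclude":
        if A.shape[0] == 1:
            raise ValueError("1x1 projection has no off-diagonal weights under exclude")
        np.fill_diagonal(A, 0.0)
    elif diagonal_policy != "include":
        raise ValueError(f"unknown diagonal_policy {diagonal_policy!r}")
    return ProjectedNetwork(side, labels, A, diagonal_policy)


def beta_eff(proj: ProjectedNetwork, variant: Variant = "ratio") -> ResilienceResult:
    """Macroscopic resilience parameter of a projected network.

    variant="ratio": sum_ij A_ij A_ji / sum_ij A_ij (the overlap-ratio form).
    variant="gao":   weighted-degree form <s_out s_in>/<s> = (1'A A 1)/(1'A 1),
    the estimator of the originating resilience-reduction theory; the two
    coincide only for special A, so both are exposed.
    """
    A = proj.A
    total = A.sum()
    if total <= 0:
        raise ValueError("undefined resilience: all-zero projected matrix")
    if variant == "ratio":
        value = float((A * A.T).sum() / total)
    elif variant == "gao":
        s = A.sum(axis=1)
        value = float(s @ s / total)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return ResilienceResult(value, proj.side, variant, proj.diagonal_policy)


def network_summary(net: IncidenceMatrix) -> dict[str, float]:
    """Richness and connectance of a pruned bipartite network.

    S = n + m (species richness); connectance = realized links / (n * m).
    """
    links = int(np.count_nonzero(net.M))
    return {
        "n_plants": net.n,
        "n_animals": net.m,
        "richness": net.n + net.m,
        "links": links,
        "connectance": links / (net.n * net.m),
    }
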