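"""Neighbor identification and neighbor genotypic-identity covariates.

For a focal individual i and marker k, the neighbor covariate is the mean of
products x_i[k] * x_j[k] over the L neighbors j within the reference spatial
scale s: +1 when every neighbor carries the focal allele, -1 when every
neighbor carries the other allele, 0 when identical and different alleles
balance. An optional exponential distance decay w(t, alpha) = exp(-alpha*(t-1))
down-weights shells t > 1; the decayed form is what the phenotype simulator
uses, while model fitting uses the unweighted covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import GenotypeTable, SpatialMap

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborScale",
    "NeighborIndex",
    "CovariateMatrices",
    "lattice_thresholds",
    "build_neighbor_index",
    "decay_weight",
    "neighbor_covariate",
    "collinearity_diagnostics",
]

#: relative inflation applied to lattice distance thresholds so that shell
#: boundaries are float-safe
_LATTICE_EPS = 1e-6


@dataclass(frozen=True)
class NeighborScale:
    """One nested spatial shell: scale index s, distance threshold delta."""

    s: int
    delta: float


@dataclass
class NeighborIndex:
    """Per-individual neighbor shells at nested spatial scales.

    ``shells[t-1][i]`` holds the indices j whose distance from i satisfies
    delta_{t-1} < d(i, j) <= delta_t (delta_0 = 0), so the sets are disjoint
    across shells and their union up to s is the cumulative neighborhood.
    ``L[s]`` maps scale -> per-individual cumulative neighbor counts.
    """

    scales: list[NeighborScale]
    shells: list[list[np.ndarray]]  # [shell][individual] -> neighbor indices
    n: int

    def cumulative_count(self, s: int) -> np.ndarray:
        """L_i: number of neighbors of each individual within delta_s."""
        self._check_scale(s)
        L = np.zeros(self.n, dtype=np.int64)
        for t in range(s):
            L += np.array([len(a) for a in self.shells[t]])
        return L

    def neighbor_set(self, i: int, s: int) -> np.ndarray:
        """Cumulative neighbor indices of individual i within scale s."""
        self._check_scale(s)
        parts = [self.shells[t][i] for t in range(s)]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    def _check_scale(self, s: int) -> None:
        if not (1 <= s <= len(self.scales)):
            raise ValueError(f"scale {s} outside available 1..{len(self.scales)}")


@dataclass
class CovariateMatrices:
    """Self (X1), neighbor (X2), and asymmetric (X12 = X1 ⊙ X2) covariates."""

    X1: np.ndarray
    X2: np.ndarray
    X12: np.ndarray
    L: np.ndarray  # per-individual cumulative neighbor counts


def lattice_thresholds(smap: SpatialMap, s_max: int) -> list[float]:
    """Distance thresholds delta_s = s*sqrt(2)*(1+eps) for a checkered lattice.

    On a unit-spaced checkered grid these give interior individuals L = 4
    cumulative neighbors at s = 1 (the four diagonal nearest neighbors) and
    L = 12 at s = 2 (up to the second nearest neighbors).
    """
    meta = smap.lattice_meta
    if not meta or not meta.get("checkered"):
        raise ValueError(
            "lattice thresholds require a checkered-lattice map; supply "
            "explicit deltas for irregular maps"
        )
    spacing = float(meta.get("spacing", 1.0))
    return [s * np.sqrt(2.0) * spacing * (1.0 + _LATTICE_EPS)
            for s in range(1, s_max + 1)]


def build_neighbor_index(smap: SpatialMap,
                         deltas: list[float] | np.ndarray) -> NeighborIndex:
    """Assign every ordered pair to a distance shell.

    j belongs to shell t of i iff delta_{t-1} < d(i, j) <= delta_t with
    delta_0 = 0 (Euclidean distance); symmetry holds exactly.
    """
    deltas = [float(d) for d in deltas]
    if any(b <= a for a, b in zip(deltas, deltas[1:])):
        raise ValueError("deltas must be strictly increasing")
    n = smap.n
    D = squareform(pdist(smap.coords))
    shells: list[list[np.ndarray]] = []
    lo = 0.0
    for d in deltas:
        shell = [np.flatnonzero((D[i] > lo) & (D[i] <= d) &
                                (np.arange(n) != i)) for i in range(n)]
        shells.append(shell)
        lo = d
    scales = [NeighborScale(s=t + 1, delta=d) for t, d in enumerate(deltas)]
    idx = NeighborIndex(scales=scales, shells=shells, n=n)
    if idx.cumulative_count(1).max() == 0:
        raise ValueError(
            f"no individual has a neighbor within delta_1 = {deltas[0]}; "
            "increase the first threshold"
        )
    return idx


def decay_weight(s: int, alpha: float) -> float:
    """Exponential distance decay w(s, alpha) = exp(-alpha * (s - 1))."""
    if s < 1:
        raise ValueError("shell index s must be >= 1")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return float(np.exp(-alpha * (s - 1)))


def neighbor_covariate(G: GenotypeTable | np.ndarray, idx: NeighborIndex,
                       s: int, weighted: bool = False,
                       alpha: float = 0.0) -> CovariateMatrices:
    """Build X1, X2, X12 at reference scale s.

    X2[i, k] = (1/L_i) * sum over shells t <= s, sum over j in shell t of
    w * x_i[k] * x_j[k], with w = 1 unweighted or w = decay_weight(t, alpha).
    Unweighted, L_i is the cumulative neighbor count; weighted, it is the
    decay-weighted count sum_t w(t, alpha) * |shell_t(i)|, so the covariate
    is always a weighted mean of products: it reduces to the unweighted form
    at alpha = 0 and converges to the unweighted s = 1 covariate as
    alpha -> inf. Isolated individuals (L_i = 0) get zero rows rather than
    being dropped, with a logged warning.

    Accepts a GenotypeTable (±1 entries) or a plain matrix, e.g. column-
    standardized genotypes as used by the phenotype simulator.
    """
    X1 = np.asarray(G.values if isinstance(G, GenotypeTable) else G, dtype=float)
    if X1.shape[0] != idx.n:
        raise ValueError("genotype rows do not match neighbor index size")
    L = idx.cumulative_count(s)
    if (L == 0).any():
        logger.warning("%d individual(s) have no neighbors at s=%d; "
                       "their neighbor covariates are set to 0",
                       int((L == 0).sum()), s)
    # weighted sum over shells of neighbor genotypes, and the matching
    # (possibly decay-weighted) neighbor count
    S = np.zeros_like(X1)
    Lw = np.zeros(X1.shape[0])
    for t in range(1, s + 1):
        w = decay_weight(t, alpha) if weighted else 1.0
        for i, nbrs in enumerate(idx.shells[t - 1]):
            if nbrs.size:
                S[i] += w * X1[nbrs].sum(axis=0)
                Lw[i] += w * nbrs.size
    Lsafe = np.where(Lw == 0, 1.0, Lw)
    X2 = X1 * S / Lsafe[:, None]
    X2[L == 0] = 0.0
    X12 = X1 * X2
    return CovariateMatrices(X1=X1, X2=X2, X12=X12, L=L)


def collinearity_diagnostics(C: CovariateMatrices) -> dict:
    """Per-marker Pearson correlation between the self and neighbor covariates.

    Low-MAF markers and broad scales drive |r| toward 1, in which case the
    self and neighbor fixed effects are not separable in a single model.
    Returns per-marker r (NaN where either column has zero variance) and
    summary quantiles of |r|.
    """
    X1, X2 = C.X1, C.X2
    if X1.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    x1c = X1 - X1.mean(axis=0)
    x2c = X2 - X2.mean(axis=0)
    s1 = np.sqrt((x1c ** 2).sum(axis=0))
    s2 = np.sqrt((x2c ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x1c * x2c).sum(axis=0) / (s1 * s2)
    r[(s1 == 0) | (s2 == 0)] = np.nan
    ok = np.abs(r[~np.isnan(r)])
    qs = (np.percentile(ok, [0, 25, 50, 75, 100]) if ok.size
          else np.full(5, np.nan))
    return {
        "r": r,
        "abs_r_quantiles": dict(zip(["min", "q25", "median", "q75", "max"], qs)),
        "n_undefined": int(np.isnan(r).sum()),
    }
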