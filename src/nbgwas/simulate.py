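"""Synthetic genotypes, field layouts, and the generative phenotype model.

The phenotype generator is deliberately richer than the fitted model: per
individual i,

    y_i = b0 + b1*x_i + (b2/L) sum_j w(s,a) x_i x_j
        + b12*(x_i/L) sum_j w(s,a) x_i x_j + u_i + e_i,

with an exponential distance decay w(s, a) = exp(-a*(s-1)) over neighbor
shells, an asymmetric interaction term b12, and a polygenic background
u ~ Norm(0, s1^2 K1 + s2^2 K2 + s12^2 K12). Fitting it with the decay-free
two-component model is the intended mis-specification stress test.

Causal markers split into four classes (fractions of the causal set):
15% carry self+neighbor+asymmetric effects, 15% self+neighbor, 35% self
only, 35% neighbor only; non-zero coefficients are independent ±1 signs.

The ratio PVE_self:PVE_nei:PVE_sxn fixes the relative contribution of the
three effect classes to the phenotype: within the fixed part and within the
polygenic background alike, each class sub-block is normalized to unit
realized variance and weighted by the square root of its ratio share, so a
1:0:0 ratio removes neighbor effects entirely and 1:8:1 makes them dominate.
Variance fractions are then calibrated so the realized fixed-effect share of
var(y) equals PVE_beta and the fixed+random share equals PVE_beta + PVE_u.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .io import GenotypeTable, SpatialMap
from .mixed_model import make_kinship
from .neighbors import NeighborIndex, build_neighbor_index, lattice_thresholds, \
    neighbor_covariate

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "CausalSet", "SimPhenotype", "generate_genotypes",
           "place_on_grid", "assign_causal", "simulate_phenotype"]

#: causal-class proportions, in a fixed class order
CLASS_NAMES = ("self+nei+asym", "self+nei", "self-only", "nei-only")
CLASS_PROPS = (0.15, 0.15, 0.35, 0.35)


@dataclass
class SimConfig:
    """Generative-model settings.

    alpha: distance-decay coefficient (0.01 broad / 1 moderate / 3 narrow
    are the study grid); pve_beta: variance fraction of the major-effect
    fixed part; pve_total: fixed + polygenic fraction (residual takes the
    rest); ratio: relative weights of the self, neighbor, and asymmetric
    variance components of the polygenic background; s_max: deepest
    neighbor shell entering the generative covariates.
    """

    alpha: float = 1.0
    pve_beta: float = 0.3
    pve_total: float = 0.8
    ratio: tuple[float, float, float] = (8.0, 1.0, 1.0)
    n_causal: int = 50
    s_max: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pve_beta <= self.pve_total < 1):
            raise ValueError("need 0 < pve_beta <= pve_total < 1")
        if any(r < 0 for r in self.ratio) or not any(self.ratio):
            raise ValueError("ratio components must be >= 0 and not all 0")


@dataclass
class CausalSet:
    """Ground truth: causal marker indices, classes, and ±1 signs.

    beta1/beta2/beta12 are length-q sign vectors (0 for non-causal loci).
    """

    indices: np.ndarray
    classes: np.ndarray  # class label per causal marker
    beta1: np.ndarray
    beta2: np.ndarray
    beta12: np.ndarray

    @property
    def self_loci(self) -> np.ndarray:
        return np.flatnonzero(self.beta1 != 0)

    @property
    def nei_loci(self) -> np.ndarray:
        return np.flatnonzero(self.beta2 != 0)


@dataclass
class SimPhenotype:
    """Standardized phenotype plus everything needed to score a method."""

    y: np.ndarray
    truth: CausalSet
    true_pve: dict[str, float]
    u_components: np.ndarray
    sd_raw: float  # std of the pre-standardization phenotype
    #: realized scalar coefficient magnitude per effect class, on the raw-y
    #: scale: the effective per-locus coefficient is coef_* times the ±1 sign
    coef_self: float = 0.0
    coef_nei: float = 0.0
    coef_asym: float = 0.0


def generate_genotypes(n: int, q: int, n_subpop: int = 3, fst: float = 0.1,
                       maf_min: float = 0.1, seed: int = 0,
                       return_freqs: bool = False):
    """Balding–Nichols-style inbred genotypes with optional structure.

    Each marker draws an ancestral frequency uniform on
    (maf_min, 1 - maf_min); subpopulation frequencies are Beta-perturbed
    around it with variance governed by ``fst``; individuals are fully
    inbred, so alleles are single ±1 draws. Markers whose realized maf falls
    below ``maf_min`` are redrawn.
    """
    if n < 2 or q < 2:
        raise ValueError("need n, q >= 2")
    if not (0 <= fst < 1):
        raise ValueError("fst must be in [0, 1)")
    if maf_min >= 0.5:
        raise ValueError("maf_min >= 0.5 is infeasible")
    rng = np.random.default_rng(seed)
    pops = np.repeat(np.arange(n_subpop), -(-n // n_subpop))[:n]
    X = np.empty((n, q), dtype=np.int8)
    anc = np.empty(q)
    for k in range(q):
        while True:
            p = rng.uniform(maf_min, 1.0 - maf_min)
            if fst > 0:
                a = p * (1.0 - fst) / fst
                b = (1.0 - p) * (1.0 - fst) / fst
                p_sub = rng.beta(a, b, size=n_subpop)
            else:
                p_sub = np.full(n_subpop, p)
            col = np.where(rng.random(n) < p_sub[pops], 1, -1).astype(np.int8)
            f = np.mean(col == 1)
            if min(f, 1 - f) >= maf_min:
                X[:, k] = col
                anc[k] = p
                break
    ids = np.array([f"1:{k + 1}" for k in range(q)], dtype=object)
    G = GenotypeTable(values=X, marker_ids=ids,
                      chrom=np.full(q, "1", dtype=object),
                      pos=np.arange(1, q + 1),
                      individual_ids=np.array([f"i{j}" for j in range(n)],
                                              dtype=object))
    if return_freqs:
        return G, anc, pops
    return G


def place_on_grid(n: int, rows: int, cols: int, checkered: bool = True,
                  seed: int = 0) -> SpatialMap:
    """Randomly assign n individuals to the occupied cells of a grid.

    A checkered grid occupies exactly the cells with even row+column sum
    (nearest occupied neighbors are then the four diagonals); a full grid
    occupies every cell. Assignment is a permutation without replacement.
    """
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if checkered:
        mask = (rr + cc) % 2 == 0
    else:
        mask = np.ones_like(rr, dtype=bool)
    cells = np.column_stack([cc[mask], rr[mask]]).astype(float)  # (x, y)
    if len(cells) < n:
        raise ValueError(f"grid has {len(cells)} occupied cells < n={n}")
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(len(cells))[:n]
    return SpatialMap(coords=cells[chosen],
                      lattice_meta={"rows": rows, "cols": cols,
                                    "checkered": checkered, "spacing": 1.0})


def _largest_remainder(n_causal: int) -> list[int]:
    quota = [p * n_causal for p in CLASS_PROPS]
    sizes = [int(np.floor(x)) for x in quota]
    short = n_causal - sum(sizes)
    # ties in the remainders go to the earlier-listed class
    order = sorted(range(len(quota)),
                   key=lambda i: (-(quota[i] - sizes[i]), i))
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def assign_causal(q: int, n_causal: int, seed: int = 0) -> CausalSet:
    """Sample causal markers and split them into the four effect classes."""
    if n_causal > q:
        raise ValueError("n_causal exceeds the number of markers")
    rng = np.random.default_rng(seed)
    idx = rng.choice(q, size=n_causal, replace=False)
    sizes = _largest_remainder(n_causal)
    classes = np.repeat(np.array(CLASS_NAMES, dtype=object), sizes)
    beta1 = np.zeros(q)
    beta2 = np.zeros(q)
    beta12 = np.zeros(q)
    sign = lambda size: rng.choice([-1.0, 1.0], size=size)
    for j, (k, cls) in enumerate(zip(idx, classes)):
        if cls in ("self+nei+asym", "self+nei", "self-only"):
            beta1[k] = sign(None)
        if cls in ("self+nei+asym", "self+nei", "nei-only"):
            beta2[k] = sign(None)
        if cls == "self+nei+asym":
            beta12[k] = sign(None)
    return CausalSet(indices=idx, classes=classes, beta1=beta1, beta2=beta2,
                     beta12=beta12)


def _calibrate(fixed, u, e, pve_beta, pve_total, max_rounds=200):
    """Find scalars (a, b) so the realized variance fractions hit the targets.

    Solves var(a*f)/var(y) = pve_beta and var(b*u)/var(y) = pve_total -
    pve_beta for y = a*f + b*u + e, by alternating two 1-D root solves
    (deterministic given the draws). Cross-covariances among the realized
    draws make the problem non-separable, hence the fixed-point iteration.
    """
    pu = pve_total - pve_beta
    var = lambda v: float(np.var(v))
    if var(fixed) == 0:
        raise ValueError("fixed part has zero variance; no causal effects?")

    def frac_f(a, b):
        y = a * fixed + b * u + e
        return var(a * fixed) / var(y)

    def frac_u(a, b):
        y = a * fixed + b * u + e
        return var(b * u) / var(y)

    a, b = 1.0, 1.0 if (pu > 0 and var(u) > 0) else 0.0
    if pu == 0 or var(u) == 0:
        if pu > 1e-12 and var(u) == 0:
            raise ValueError("random part has zero variance but pve_u > 0")
        b = 0.0
    for _ in range(max_rounds):
        a_new = _solve_scale(lambda s: frac_f(s, b) - pve_beta, a)
        b_new = b
        if b != 0.0:
            b_new = _solve_scale(lambda s: frac_u(a_new, s) - pu, max(b, 1e-6))
        if abs(a_new - a) < 1e-12 and abs(b_new - b) < 1e-12:
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    achieved = (frac_f(a, b), frac_u(a, b))
    if abs(achieved[0] - pve_beta) > 0.02 or (b != 0 and abs(achieved[1] - pu) > 0.02):
        raise ValueError(
            f"PVE calibration failed: achieved fixed={achieved[0]:.3f}, "
            f"random={achieved[1]:.3f} for targets {pve_beta}, {pu}"
        )
    return a, b


def _solve_scale(g, x0):
    """1-D root of a monotone variance-fraction equation by bracketing."""
    lo, hi = 1e-9, max(10.0 * x0, 1.0)
    glo, ghi = g(lo), g(hi)
    for _ in range(200):
        if ghi > 0:
            break
        hi *= 2.0
        ghi = g(hi)
    else:
        raise ValueError("could not bracket the PVE scaling factor; the "
                         "requested fraction is unattainable")
    if glo > 0:
        return lo
    return float(optimize.brentq(g, lo, hi, xtol=1e-14))


def simulate_phenotype(G: GenotypeTable, smap: SpatialMap, causal: CausalSet,
                       cfg: SimConfig,
                       idx: NeighborIndex | None = None) -> SimPhenotype:
    """Draw one standardized phenotype from the generative model.

    Genotype columns are standardized to mean 0, variance 1 before effect
    construction; the decay-weighted neighbor covariates at ``cfg.s_max``
    enter both the fixed part and the background kinships K2/K12. The self,
    neighbor, and asymmetric sub-blocks of the fixed part and of the
    background are each normalized to unit realized variance and combined
    with weights sqrt(ratio share). Two scalar calibrations then set the
    realized fixed and random variance fractions to PVE_beta and
    PVE_u = pve_total - pve_beta, and y is standardized.
    """
    rng = np.random.default_rng(cfg.seed)
    if idx is None:
        idx = build_neighbor_index(smap, lattice_thresholds(smap, cfg.s_max))
    X = G.values.astype(float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("monomorphic markers cannot be standardized")
    Xs = (X - X.mean(axis=0)) / sd

    C = neighbor_covariate(Xs, idx, s=cfg.s_max, weighted=True,
                           alpha=cfg.alpha)
    w = np.asarray(cfg.ratio, float)
    w = w / w.sum()
    n = G.n

    # fixed part: per-class sub-blocks, normalized then ratio-weighted
    blocks = [Xs @ causal.beta1, C.X2 @ causal.beta2, C.X12 @ causal.beta12]
    fixed = np.zeros(n)
    coef = [0.0, 0.0, 0.0]
    for m, blk in enumerate(blocks):
        s_blk = float(blk.std())
        if w[m] > 0 and s_blk > 0:
            coef[m] = np.sqrt(w[m]) / s_blk
            fixed += coef[m] * blk
        elif w[m] > 0:
            logger.warning("effect class %d has ratio weight %.2f but no "
                           "causal variance; skipped", m, w[m])

    # polygenic background: independent draws per class, same weighting
    pve_u = cfg.pve_total - cfg.pve_beta
    u = np.zeros(n)
    if pve_u > 0:
        mats = [make_kinship(G.values, kind="self").values if w[0] > 0 else None,
                make_kinship(C.X2, kind="neighbor").values if w[1] > 0 else None,
                make_kinship(C.X12, kind="asym").values if w[2] > 0 else None]
        for m, K in enumerate(mats):
            if K is None:
                continue
            lam, U = linalg.eigh(K)
            u_m = U @ (np.sqrt(np.maximum(lam, 0.0)) * rng.standard_normal(n))
            s_u = float(u_m.std())
            if s_u > 0:
                u += np.sqrt(w[m]) * u_m / s_u
    e = rng.standard_normal(n)

    a, b = _calibrate(fixed, u, e, cfg.pve_beta, cfg.pve_total)
    y_raw = a * fixed + b * u + e
    sd_raw = float(y_raw.std())
    y = (y_raw - y_raw.mean()) / sd_raw

    var_y = float(np.var(y_raw))
    true_pve = {
        "pve_beta": float(np.var(a * fixed)) / var_y,
        "pve_u": float(np.var(b * u)) / var_y,
        "pve_total": (float(np.var(a * fixed)) + float(np.var(b * u))) / var_y,
        "scale_fixed": a,
        "scale_random": b,
    }
    return SimPhenotype(y=y, truth=causal, true_pve=true_pve,
                        u_components=b * u, sd_raw=sd_raw,
                        coef_self=a * coef[0], coef_nei=a * coef[1],
                        coef_asym=a * coef[2])
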