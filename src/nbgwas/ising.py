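"""Forward Ising machinery: population phenotype sums and annealing search.

With per-individual phenotype y_i = b1*x_i + b2*sum_{j in N(i)} x_i x_j,
the population sum over a lattice is

    sum_i y_i = b1 * sum_i x_i + 2*b2 * sum_{pairs <i,j>} x_i x_j,

each unordered neighbor pair being counted from both of its members.
Substituting E = -b2 and H = -b1 gives the interaction energy of the 2-D
ferromagnetic Ising model, so a positive neighbor coefficient favors mixed
(checkerboard-like) allele arrangements at the minimum of the sum and a
negative one favors clusters, while b1 biases the lattice toward one
allele. Simulated annealing over single-spin flips searches for the
arrangement minimizing (or maximizing) the sum — e.g. the planting layout
minimizing total herbivory once b1, b2 are estimated from a scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IsingConfig", "LatticeState", "grid_pairs", "population_sum",
           "anneal"]


@dataclass
class IsingConfig:
    """Annealing problem: coefficients, lattice, schedule."""

    beta1: float
    beta2: float
    rows: int
    cols: int
    checkered: bool = False
    n_iter: int = 1000  # sweeps; one sweep proposes a flip per site
    t_init: float = 10.0
    t_final: float = 0.01
    direction: str = "minimize"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not (self.t_init > 0 and self.t_final > 0
                and self.t_final < self.t_init):
            raise ValueError("temperatures must be positive and decreasing")
        if self.direction not in ("minimize", "maximize"):
            raise ValueError("direction must be minimize or maximize")


@dataclass
class LatticeState:
    """Spins on the occupied cells plus the current population sum."""

    spins: np.ndarray  # (n_sites,) values in {-1, +1}
    coords: np.ndarray  # (n_sites, 2) integer (row, col)
    pairs: np.ndarray  # (n_pairs, 2) site-index pairs
    energy: float = field(default=np.nan)


def grid_pairs(rows: int, cols: int, checkered: bool = False):
    """Occupied-cell coordinates and first-shell neighbor pairs of a grid.

    Full grids pair orthogonally adjacent cells; checkered grids (occupied
    cells = even row+column sum) pair the four diagonal nearest neighbors.
    """
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if checkered:
        mask = (rr + cc) % 2 == 0
        offsets = [(1, 1), (1, -1)]
    else:
        mask = np.ones_like(rr, dtype=bool)
        offsets = [(0, 1), (1, 0)]
    coords = np.column_stack([rr[mask], cc[mask]])
    index = -np.ones((rows, cols), dtype=int)
    index[coords[:, 0], coords[:, 1]] = np.arange(len(coords))
    pairs = []
    for r, c in coords:
        for dr, dc in offsets:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and index[r2, c2] >= 0:
                pairs.append((index[r, c], index[r2, c2]))
    return coords, (np.asarray(pairs, dtype=int) if pairs
                    else np.empty((0, 2), dtype=int))


def population_sum(state: LatticeState, cfg: IsingConfig) -> float:
    """sum_i y_i = b1*sum x_i + 2*b2*sum_pairs x_i x_j."""
    s = state.spins
    pair_term = float(np.sum(s[state.pairs[:, 0]] * s[state.pairs[:, 1]])) \
        if len(state.pairs) else 0.0
    return cfg.beta1 * float(s.sum()) + 2.0 * cfg.beta2 * pair_term


def anneal(cfg: IsingConfig) -> LatticeState:
    """Metropolis single-spin-flip annealing from a uniform random start.

    Geometric cooling from ``t_init`` to ``t_final`` over ``n_iter`` sweeps;
    returns the best state visited, so the reported optimum is monotone in
    the iteration count.
    """
    rng = np.random.default_rng(cfg.seed)
    coords, pairs = grid_pairs(cfg.rows, cfg.cols, cfg.checkered)
    n = len(coords)
    spins = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)

    # adjacency as flat neighbor lists for O(1) local energy deltas
    nbr_idx = [[] for _ in range(n)]
    for i, j in pairs:
        nbr_idx[i].append(j)
        nbr_idx[j].append(i)
    nbr_flat = np.concatenate([np.asarray(a, dtype=int) for a in nbr_idx]) \
        if pairs.size else np.empty(0, dtype=int)
    nbr_start = np.zeros(n + 1, dtype=int)
    nbr_start[1:] = np.cumsum([len(a) for a in nbr_idx])

    sign = 1.0 if cfg.direction == "minimize" else -1.0
    temps = np.geomspace(cfg.t_init, cfg.t_final, cfg.n_iter)

    state = LatticeState(spins=spins, coords=coords, pairs=pairs)
    energy = population_sum(state, cfg)
    best_spins, best_energy = spins.copy(), energy
    for T in temps:
        for i in rng.permutation(n):
            si = spins[i]
            nb = nbr_flat[nbr_start[i]:nbr_start[i + 1]]
            local = float(spins[nb].sum()) if nb.size else 0.0
            # flipping s_i changes b1 term by -2*b1*s_i and each incident
            # pair contribution 2*b2*s_i*s_j by -4*b2*s_i*s_j
            dE = -2.0 * cfg.beta1 * si - 4.0 * cfg.beta2 * si * local
            if sign * dE <= 0 or rng.random() < np.exp(-sign * dE / T):
                spins[i] = -si
                energy += dE
                if sign * energy < sign * best_energy:
                    best_energy = energy
                    best_spins = spins.copy()
    out = LatticeState(spins=best_spins, coords=coords, pairs=pairs)
    out.energy = population_sum(out, cfg)
    return out
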