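"""One-stop simulation replicates for power and calibration studies.

Each replicate generates structured genotypes, a checkered field, a
simulated phenotype, runs the forward-selection scan, and scores it against
the simulator truth. A single integer seed drives all stochastic stages via
SeedSequence spawning, so replicates are reproducible and independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import neglog10, roc_auc, sensitivity_at_fpr
from .scan import assoc_scan, records_to_frame
from .simulate import SimConfig, assign_causal, generate_genotypes, \
    place_on_grid, simulate_phenotype
from .pipeline import prepare_inputs

__all__ = ["ReplicateResult", "power_replicate", "null_auc_replicate"]


@dataclass
class ReplicateResult:
    auc_self: float
    auc_nei: float
    sens_self: float
    sens_nei: float
    frame: object  # per-marker results DataFrame
    sim: object  # SimPhenotype
    causal: object  # CausalSet
    genotypes: object = None  # GenotypeTable


def _spawn(seed: int, k: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(k)]


def power_replicate(seed: int, n: int = 400, q: int = 1000, rows: int = 20,
                    cols: int = 40, n_causal: int = 10, alpha: float = 1.0,
                    pve_beta: float = 0.6, pve_total: float = 0.8,
                    ratio: tuple = (8, 1, 1), s: int = 1,
                    s_max: int = 3) -> ReplicateResult:
    """Simulate one phenotype under the generative model and scan it.

    The scan runs at scale ``s`` with an intercept-only fixed design; truth
    labels for the self (neighbor) ROC are the markers with non-zero beta1
    (beta2).
    """
    s_geno, s_map, s_causal, s_pheno = _spawn(seed, 4)
    G = generate_genotypes(n=n, q=q, seed=s_geno)
    smap = place_on_grid(n, rows=rows, cols=cols, checkered=True, seed=s_map)
    causal = assign_causal(q, n_causal, seed=s_causal)
    cfg = SimConfig(alpha=alpha, pve_beta=pve_beta, pve_total=pve_total,
                    ratio=ratio, n_causal=n_causal, s_max=s_max, seed=s_pheno)
    sim = simulate_phenotype(G, smap, causal, cfg)
    inputs = prepare_inputs(G, smap, s)
    W = np.ones((n, 1))
    recs = assoc_scan(sim.y, W, G, inputs.X2_by_scale[s], inputs.K1,
                      inputs.K2_by_scale[s])
    df = records_to_frame(recs)
    score_self = neglog10(df["p_self"].to_numpy())
    score_nei = neglog10(df["p_nei"].to_numpy())
    t_self = causal.beta1 != 0
    t_nei = causal.beta2 != 0
    return ReplicateResult(
        auc_self=roc_auc(score_self, t_self),
        auc_nei=roc_auc(score_nei, t_nei),
        sens_self=sensitivity_at_fpr(score_self, t_self),
        sens_nei=sensitivity_at_fpr(score_nei, t_nei),
        frame=df, sim=sim, causal=causal, genotypes=G)


def null_auc_replicate(seed: int, n: int = 400, q: int = 1000,
                       rows: int = 20, cols: int = 40, s: int = 1,
                       n_labels: int = 50) -> tuple[float, float]:
    """Scan a pure-noise phenotype and score it against random labels.

    Returns (auc_self, auc_nei) against ``n_labels`` randomly designated
    "causal" markers; both should sit near 0.5 since the phenotype carries
    no marker signal at all.
    """
    s_geno, s_map, s_pheno, s_lab = _spawn(seed, 4)
    G = generate_genotypes(n=n, q=q, seed=s_geno)
    smap = place_on_grid(n, rows=rows, cols=cols, checkered=True, seed=s_map)
    rng = np.random.default_rng(s_pheno)
    y = rng.standard_normal(n)
    y = (y - y.mean()) / y.std()
    inputs = prepare_inputs(G, smap, s)
    W = np.ones((n, 1))
    recs = assoc_scan(y, W, G, inputs.X2_by_scale[s], inputs.K1,
                      inputs.K2_by_scale[s])
    df = records_to_frame(recs)
    labels = np.zeros(q, dtype=bool)
    labels[np.random.default_rng(s_lab).choice(q, n_labels, replace=False)] = True
    return (roc_auc(neglog10(df["p_self"].to_numpy()), labels),
            roc_auc(neglog10(df["p_nei"].to_numpy()), labels))
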