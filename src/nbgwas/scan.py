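"""User-facing analyses: PVE partitioning and the per-marker association scan.

Because self and neighbor covariates are collinear for low-MAF markers and
broad scales, both analyses are deliberately conservative: variance
components and marker effects involving the neighbors are always tested
against the corresponding self-only (standard GWAS) model, never against
the fixed-effects-only null.

PVE vocabulary (variance fractions from REML estimates):

- single PVE_self = s1/(s1+se), from the one-random-effect model with K1;
- single PVE_nei(s) = s2/(s2+se), from the one-random-effect model with K2;
- partial PVE_self/nei(s) = s1/(s1+s2+se) and s2/(s1+s2+se), jointly fitted;
- net PVE_nei(s) = (partial self + partial nei) - single self, the gain of
  the two-component model over standard GWAS;
- dPVE_nei(s) = partial PVE_nei(s) - partial PVE_nei(s-1), with the s = 0
  value defined as 0 (no neighbor model exists at s = 0); its argmax
  estimates the effective spatial scale of the neighbor effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeTable
from .mixed_model import (KinshipMatrix, PluginRotation, VarianceComponents,
                          fixed_effect_test, lrt_pvalue, reml_fit)

logger = logging.getLogger(__name__)

__all__ = ["PVEResult", "AssocRecord", "pve_partition", "effective_scale",
           "assoc_scan", "records_to_frame"]


@dataclass
class PVEResult:
    """Variance partitions across spatial scales with their LRTs."""

    scales: list[int]
    single_pve_self: float
    single_pve_nei: dict[int, float]
    partial_pve_self: dict[int, float]
    partial_pve_nei: dict[int, float]
    net_pve_nei: dict[int, float]
    delta_pve_nei: dict[int, float]
    lrt_single_self: tuple[float, float]  # (statistic, p)
    lrt_single_nei: dict[int, tuple[float, float]]
    lrt_partial_self: dict[int, tuple[float, float]]  # two-K vs K2-only
    lrt_partial_nei: dict[int, tuple[float, float]]   # two-K vs K1-only
    s_hat: int = 0
    reliable: bool = True
    vc_by_scale: dict[int, VarianceComponents] = field(default_factory=dict)
    vc_self: VarianceComponents | None = None


@dataclass
class AssocRecord:
    """Per-marker association result from the forward-selection scan."""

    marker_id: str
    chrom: str
    pos: int
    maf: float
    beta1_hat: float
    p_self: float
    beta2_hat: float
    p_nei: float
    beta12_hat: float | None = None
    p_asym: float | None = None
    flagged: bool = False


def _pve(num: float, *rest: float) -> float:
    tot = num + sum(rest)
    return num / tot if tot > 0 else 0.0


def pve_partition(y: np.ndarray, W: np.ndarray, K1: KinshipMatrix,
                  K2_by_scale: dict[int, KinshipMatrix]) -> PVEResult:
    """Partition phenotypic variance into self and neighbor components.

    Fits, with the same fixed design W: (a) the fixed-effects-only null,
    (b) the K1-only model, (c) the K2-only model per scale, and (d) the
    K1+K2 model per scale. Single PVE_self is tested by the LRT of (b)
    against (a); partial PVE_nei at scale s by (d) against (b) — the
    conservative comparison against standard GWAS.
    """
    y = np.asarray(y, float)
    scales = sorted(K2_by_scale)
    fit_null = reml_fit(y, W, [])
    fit_self = reml_fit(y, W, [K1])
    reliable = fit_self.converged

    single_self = _pve(fit_self.sigma1_sq, fit_self.sigma_e_sq)
    stat_ss = 2.0 * (fit_self.loglik_reml - fit_null.loglik_reml)
    lrt_single_self = (stat_ss, lrt_pvalue(fit_self.loglik_reml,
                                           fit_null.loglik_reml))

    single_nei, partial_self, partial_nei = {}, {}, {}
    lrt_sn, lrt_ps, lrt_pn = {}, {}, {}
    vc_by_scale = {}
    for s in scales:
        K2 = K2_by_scale[s]
        fit_nei = reml_fit(y, W, [K2])
        fit_both = reml_fit(y, W, [K1, K2])
        reliable &= fit_nei.converged and fit_both.converged
        single_nei[s] = _pve(fit_nei.sigma1_sq, fit_nei.sigma_e_sq)
        partial_self[s] = _pve(fit_both.sigma1_sq, fit_both.sigma2_sq,
                               fit_both.sigma_e_sq)
        partial_nei[s] = _pve(fit_both.sigma2_sq, fit_both.sigma1_sq,
                              fit_both.sigma_e_sq)
        lrt_sn[s] = (2.0 * (fit_nei.loglik_reml - fit_null.loglik_reml),
                     lrt_pvalue(fit_nei.loglik_reml, fit_null.loglik_reml))
        lrt_ps[s] = (2.0 * (fit_both.loglik_reml - fit_nei.loglik_reml),
                     lrt_pvalue(fit_both.loglik_reml, fit_nei.loglik_reml))
        lrt_pn[s] = (2.0 * (fit_both.loglik_reml - fit_self.loglik_reml),
                     lrt_pvalue(fit_both.loglik_reml, fit_self.loglik_reml))
        vc_by_scale[s] = fit_both

    net = {s: (partial_self[s] + partial_nei[s]) - single_self for s in scales}
    delta = {}
    prev = 0.0
    for s in scales:
        delta[s] = partial_nei[s] - prev
        prev = partial_nei[s]
    if not reliable:
        logger.warning("REML non-convergence in at least one PVE model; "
                       "metrics marked unreliable")
    res = PVEResult(scales=scales, single_pve_self=single_self,
                    single_pve_nei=single_nei, partial_pve_self=partial_self,
                    partial_pve_nei=partial_nei, net_pve_nei=net,
                    delta_pve_nei=delta, lrt_single_self=lrt_single_self,
                    lrt_single_nei=lrt_sn, lrt_partial_self=lrt_ps,
                    lrt_partial_nei=lrt_pn, reliable=reliable,
                    vc_by_scale=vc_by_scale, vc_self=fit_self)
    res.s_hat = effective_scale(res)
    return res


def effective_scale(P: PVEResult) -> int:
    """Estimate the effective neighbor range as argmax_s dPVE_nei(s).

    dPVE_nei at the first scale is partial PVE_nei(1) - 0 because no
    neighbor component exists at s = 0. Ties break toward the smallest s.
    With a single scale only, s = 1 is returned with a warning.
    """
    scales = P.scales
    if len(scales) < 2:
        logger.warning("effective scale requested with a single scale; "
                       "returning s=%d", scales[0] if scales else 1)
        return scales[0] if scales else 1
    best_s, best = scales[0], -np.inf
    for s in scales:
        d = P.delta_pve_nei[s]
        if d > best + 1e-12:
            best, best_s = d, s
    return best_s


def assoc_scan(y: np.ndarray, W: np.ndarray, G: GenotypeTable,
               X2: np.ndarray, K1: KinshipMatrix, K2: KinshipMatrix,
               test_asym: bool = False, X12: np.ndarray | None = None,
               reestimate_per_marker: bool = False) -> list[AssocRecord]:
    """Forward-selection association scan for self and neighbor effects.

    Per marker k:

    1. the null likelihood is computed under the K1-only covariance
       (sigma2^2 = 0), i.e. the standard GWAS model;
    2. p_self is the LRT of adding the self genotype x_k to that null;
    3. the self-likelihood is computed under the two-component covariance
       with x_k included;
    4. p_nei is the LRT of adding the neighbor covariate X2[:, k] on top —
       conservative by construction, since any purely self-genotypic signal
       is already absorbed in step 3;
    5. optionally p_asym adds the asymmetric covariate X12[:, k] as a third
       forward-selection step (df = 1).

    Variance components are estimated once on the no-marker model and held
    fixed across the genome (the plug-in scheme); ``reestimate_per_marker``
    re-runs REML for every marker and exists for validation only.
    """
    y = np.asarray(y, float)
    W = np.atleast_2d(np.asarray(W, float))
    if X2.shape != G.values.shape:
        raise ValueError("X2 must align with the genotype matrix")
    if test_asym and X12 is None:
        raise ValueError("test_asym=True requires X12")

    vc1 = reml_fit(y, W, [K1])
    vc2 = reml_fit(y, W, [K1, K2])
    rot1 = PluginRotation([K1], vc1)
    rot2 = PluginRotation([K1, K2], vc2)

    records = []
    for k in range(G.q):
        rec = _scan_marker(y, W, G, X2, X12, k, rot1, rot2, test_asym,
                           (vc1, vc2) if reestimate_per_marker else None,
                           (K1, K2))
        records.append(rec)
    return records


def _scan_marker(y, W, G, X2, X12, k, rot1, rot2, test_asym, reest, Kpair):
    x = G.values[:, k].astype(float)
    mid, ch, po, maf = (str(G.marker_ids[k]), str(G.chrom[k]),
                        int(G.pos[k]), float(G.maf[k]))
    if np.ptp(x) == 0:
        return AssocRecord(mid, ch, po, maf, 0.0, 1.0, 0.0, 1.0,
                           beta12_hat=0.0 if test_asym else None,
                           p_asym=1.0 if test_asym else None, flagged=True)
    if reest is not None:
        K1, K2 = Kpair
        rot1 = PluginRotation([K1], reml_fit(y, np.column_stack([W, x]), [K1]))
        rot2 = PluginRotation([K1, K2],
                              reml_fit(y, np.column_stack([W, x]), [K1, K2]))

    fit_self, _, p_self = fixed_effect_test(y, W, x, rot1)
    beta1 = float(fit_self.beta_hat[-1]) if not fit_self.flagged else np.nan

    x2 = X2[:, k]
    W_self = np.column_stack([W, x])
    flagged = fit_self.flagged
    if np.ptp(x2) == 0:
        beta2, p_nei = 0.0, 1.0
        flagged = True
        W_nei = W_self
    else:
        fit_nei, _, p_nei = fixed_effect_test(y, W_self, x2, rot2)
        beta2 = float(fit_nei.beta_hat[-1]) if not fit_nei.flagged else np.nan
        flagged |= fit_nei.flagged
        W_nei = np.column_stack([W_self, x2])

    beta12 = p_asym = None
    if test_asym:
        x12 = X12[:, k]
        if np.ptp(x12) == 0:
            beta12, p_asym = 0.0, 1.0
            flagged = True
        else:
            fit_a, _, p_asym = fixed_effect_test(y, W_nei, x12, rot2)
            beta12 = float(fit_a.beta_hat[-1]) if not fit_a.flagged else np.nan
            flagged |= fit_a.flagged
    return AssocRecord(mid, ch, po, maf, beta1, p_self, beta2, p_nei,
                       beta12, p_asym, flagged)


def records_to_frame(records: list[AssocRecord]) -> pd.DataFrame:
    """Long-format results table (one row per marker), ready for TSV export."""
    rows = []
    for r in records:
        row = {"marker_id": r.marker_id, "chrom": r.chrom, "pos": r.pos,
               "maf": r.maf, "beta1_hat": r.beta1_hat, "p_self": r.p_self,
               "beta2_hat": r.beta2_hat, "p_nei": r.p_nei}
        if r.beta12_hat is not None:
            row["beta12_hat"] = r.beta12_hat
            row["p_asym"] = r.p_asym
        row["flagged"] = r.flagged
        rows.append(row)
    return pd.DataFrame(rows)
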