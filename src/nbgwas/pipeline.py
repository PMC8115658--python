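"""Convenience wiring from raw inputs to scan-ready matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeTable, SpatialMap
from .mixed_model import KinshipMatrix, make_kinship
from .neighbors import (NeighborIndex, build_neighbor_index,
                        lattice_thresholds, neighbor_covariate)

__all__ = ["ScanInputs", "prepare_inputs"]


@dataclass
class ScanInputs:
    """Neighbor index, covariates, and kinships for a set of scales."""

    idx: NeighborIndex
    K1: KinshipMatrix
    X2_by_scale: dict[int, np.ndarray]
    X12_by_scale: dict[int, np.ndarray]
    K2_by_scale: dict[int, KinshipMatrix]


def prepare_inputs(G: GenotypeTable, smap: SpatialMap, s_max: int,
                   deltas: list[float] | None = None) -> ScanInputs:
    """Build everything the PVE partition and scan need, once per dataset.

    ``deltas`` defaults to the checkered-lattice thresholds when the map
    carries lattice metadata; irregular maps must supply them explicitly.
    """
    if deltas is None:
        deltas = lattice_thresholds(smap, s_max)
    idx = build_neighbor_index(smap, deltas)
    K1 = make_kinship(G.values, kind="self")
    X2_by_scale, X12_by_scale, K2_by_scale = {}, {}, {}
    for s in range(1, s_max + 1):
        C = neighbor_covariate(G, idx, s=s)
        X2_by_scale[s] = C.X2
        X12_by_scale[s] = C.X12
        K2_by_scale[s] = make_kinship(C.X2, kind="neighbor")
    return ScanInputs(idx=idx, K1=K1, X2_by_scale=X2_by_scale,
                      X12_by_scale=X12_by_scale, K2_by_scale=K2_by_scale)
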