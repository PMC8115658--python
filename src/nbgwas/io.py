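"""Input handling for genotypes, phenotypes, and spatial maps.

Genotypes are biallelic markers coded to {-1, +1} per individual: the
reference allele maps to -1 and the alternate allele to +1. The coding is
arbitrary but fixed; every downstream statistic is orientation-symmetric
except the sign of estimated marker effects, which are reported relative to
the +1 allele. Heterozygous or missing calls are rejected unless a fill
policy is supplied, because the model is defined for inbred (homozygous)
individuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeTable",
    "PhenotypeTable",
    "SpatialMap",
    "load_genotypes",
    "write_vcf",
    "filter_markers",
    "load_table",
]


@dataclass
class GenotypeTable:
    """n individuals x q biallelic markers coded {-1, +1}.

    ``maf[k]`` is ``min(f, 1 - f)`` with ``f`` the fraction of +1 alleles at
    marker ``k``; monomorphic markers have maf 0 and trigger a warning at
    load time.
    """

    values: np.ndarray  # (n, q) entries in {-1, +1}
    marker_ids: np.ndarray  # (q,) unique labels
    chrom: np.ndarray  # (q,) chromosome labels
    pos: np.ndarray  # (q,) 1-based coordinates, non-decreasing within chrom
    individual_ids: np.ndarray  # (n,) labels
    maf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        bad = (self.values != 1) & (self.values != -1)
        if bad.any():
            i, k = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype entries must be -1 or +1; individual "
                f"{self.individual_ids[i]!r}, marker {self.marker_ids[k]!r} "
                f"has {self.values[i, k]}"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids are not unique")
        f = np.mean(self.values == 1, axis=0)
        self.maf = np.minimum(f, 1.0 - f)
        n_mono = int((self.maf == 0).sum())
        if n_mono:
            warnings.warn(f"{n_mono} monomorphic marker(s) (maf = 0)", stacklevel=2)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def take_markers(self, index: np.ndarray) -> "GenotypeTable":
        """Return a new table restricted to the given marker indices."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return GenotypeTable(
                values=self.values[:, index],
                marker_ids=self.marker_ids[index],
                chrom=self.chrom[index],
                pos=self.pos[index],
                individual_ids=self.individual_ids,
            )


@dataclass
class PhenotypeTable:
    """Phenotype vector plus optional fixed covariates, in genotype order."""

    y: np.ndarray  # (n,)
    covariates: pd.DataFrame  # (n, c), may be empty
    standardized: bool = False

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.standardized:
            if abs(self.y.mean()) > 1e-8 or abs(self.y.var() - 1.0) > 1e-8:
                raise ValueError("standardized flag set but y is not standardized")


@dataclass
class SpatialMap:
    """Planar (x, y) positions of the n individuals.

    ``lattice_meta`` carries (rows, cols, checkered, spacing) when positions
    come from a regular grid; it enables lattice-specific distance
    thresholds. Positions on a checkered grid occupy the cells whose
    row+column sum is even, so the nearest neighbors sit on the diagonals.
    """

    coords: np.ndarray  # (n, 2)
    lattice_meta: dict | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def check_unique(self) -> None:
        _, counts = np.unique(self.coords, axis=0, return_counts=True)
        if (counts > 1).any():
            raise ValueError("duplicate coordinates in spatial map")


def _code_gt(g: tuple, marker_id: str, fill: float | None) -> int | float:
    # cyvcf2 genotype tuple: (allele1, allele2, phased)
    a, b = g[0], g[1]
    if a < 0 or b < 0:
        if fill is None:
            raise ValueError(
                f"missing genotype at marker {marker_id!r} and no fill policy"
            )
        return fill
    if a != b:
        raise ValueError(
            f"heterozygous call at marker {marker_id!r}: the ±1 coding is "
            "defined for homozygous (inbred) individuals only"
        )
    return -1 if a == 0 else 1


def load_genotypes(path: str | Path, format: str | None = None,
                   fill_missing: bool = False) -> GenotypeTable:
    """Load a genotype table from a VCF or a delimited ±1 matrix.

    Parameters
    ----------
    path
        File path. Format inferred from the extension when not given
        (``.vcf`` -> vcf, else matrix).
    format
        ``"vcf"`` or ``"matrix"``.
    fill_missing
        If True, missing calls are mean-filled per marker and rounded to ±1.
        Defaults off: the intended inputs are externally imputed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "matrix"
    if format == "vcf":
        return _load_vcf(path, fill_missing)
    if format == "matrix":
        return _load_matrix(path, fill_missing)
    raise ValueError(f"unknown genotype format {format!r}")


def _load_vcf(path: Path, fill_missing: bool) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    cols, ids, chroms, poss = [], [], [], []
    fill = np.nan if fill_missing else None
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"marker {var.ID or f'{var.CHROM}:{var.POS}'} is not biallelic "
                f"(ALT={var.ALT})"
            )
        mid = var.ID if var.ID not in (None, ".", "") else f"{var.CHROM}:{var.POS}"
        col = np.array([_code_gt(g, mid, fill) for g in var.genotypes], dtype=float)
        if np.isnan(col).any():
            m = np.nanmean(col)
            col = np.where(np.isnan(col), 1.0 if m >= 0 else -1.0, col)
        cols.append(col)
        ids.append(mid)
        chroms.append(var.CHROM)
        poss.append(var.POS)
    vcf.close()
    if not cols:
        raise ValueError(f"no variants in {path}")
    return GenotypeTable(
        values=np.column_stack(cols),
        marker_ids=np.asarray(ids, dtype=object),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss),
        individual_ids=samples,
    )


def _load_matrix(path: Path, fill_missing: bool) -> GenotypeTable:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        if not fill_missing:
            raise ValueError(f"missing genotypes in {path} and no fill policy")
        m = np.nanmean(vals, axis=0)
        fill = np.where(m >= 0, 1.0, -1.0)
        idx = np.where(np.isnan(vals))
        vals[idx] = fill[idx[1]]
    chroms, poss = _parse_marker_ids(df.columns)
    return GenotypeTable(
        values=vals,
        marker_ids=np.asarray(df.columns, dtype=object),
        chrom=chroms,
        pos=poss,
        individual_ids=np.asarray(df.index, dtype=object),
    )


def _parse_marker_ids(ids) -> tuple[np.ndarray, np.ndarray]:
    """Parse "chrom:pos" marker labels; fall back to ordinal positions."""
    chroms, poss = [], []
    for k, mid in enumerate(ids):
        parts = str(mid).split(":")
        if len(parts) == 2 and parts[1].isdigit():
            chroms.append(parts[0])
            poss.append(int(parts[1]))
        else:
            chroms.append("1")
            poss.append(k + 1)
    return np.asarray(chroms, dtype=object), np.asarray(poss)


def write_vcf(G: GenotypeTable, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with -1 -> 0/0 and +1 -> 1/1 homozygous calls."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(G.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT"] + [str(s) for s in G.individual_ids]
        fh.write("\t".join(header) + "\n")
        for k in range(G.q):
            gts = ["0/0" if v == -1 else "1/1" for v in G.values[:, k]]
            row = [str(G.chrom[k]), str(G.pos[k]), str(G.marker_ids[k]),
                   "A", "T", ".", "PASS", ".", "GT"] + gts
            fh.write("\t".join(row) + "\n")


def filter_markers(G: GenotypeTable, maf_min: float = 0.05,
                   ld_r2_max: float = 0.8) -> GenotypeTable:
    """MAF and adjacent-LD pruning.

    Drops markers with maf <= ``maf_min``; then scans surviving markers in
    genomic-position order within each chromosome and drops the latter of
    any adjacent pair whose squared Pearson correlation is >= ``ld_r2_max``.
    Idempotent for fixed thresholds.
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if not (0 < ld_r2_max <= 1):
        raise ValueError("ld_r2_max must be in (0, 1]")
    keep = np.flatnonzero(G.maf > maf_min)
    if keep.size == 0:
        raise ValueError(f"no markers survive maf > {maf_min}")
    kept: list[int] = []
    X = G.values.astype(float)
    for c in pd.unique(G.chrom[keep]):
        idx = keep[G.chrom[keep] == c]
        idx = idx[np.argsort(G.pos[idx], kind="stable")]
        last = None
        for k in idx:
            if last is not None:
                r = np.corrcoef(X[:, last], X[:, k])[0, 1]
                if r * r >= ld_r2_max:
                    continue
            kept.append(k)
            last = k
    if not kept:
        raise ValueError(
            f"no markers survive maf > {maf_min} and adjacent r^2 < {ld_r2_max}"
        )
    return G.take_markers(np.asarray(sorted(kept)))


def load_table(path: str | Path, role: str, G: GenotypeTable | None = None,
               id_col: str = "id", phenotype_col: str | None = None,
               allow_duplicates: bool = False) -> PhenotypeTable | SpatialMap:
    """Load a delimited phenotype/covariate table or a spatial map.

    Rows are reordered to the individual order of ``G`` when given;
    individuals present in the genotypes but absent from the table raise an
    error listing the missing ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if id_col not in df.columns:
        raise ValueError(f"table {path} lacks an {id_col!r} column")
    df[id_col] = df[id_col].astype(str)
    df = df.set_index(id_col)
    if G is not None:
        want = [str(s) for s in G.individual_ids]
        missing = [s for s in want if s not in df.index]
        if missing:
            raise ValueError(f"individuals missing from {path}: {missing}")
        df = df.loc[want]
    if role == "phenotype":
        pcol = phenotype_col or df.columns[0]
        y = df[pcol].to_numpy(dtype=float)
        cov = df.drop(columns=[pcol])
        return PhenotypeTable(y=y, covariates=cov)
    if role == "map":
        if not {"x", "y"}.issubset(df.columns):
            raise ValueError(f"map table {path} must have columns x, y")
        smap = SpatialMap(coords=df[["x", "y"]].to_numpy(dtype=float))
        if not allow_duplicates:
            smap.check_unique()
        return smap
    raise ValueError(f"unknown table role {role!r}")
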