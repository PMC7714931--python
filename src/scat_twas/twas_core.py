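"""Single-tissue summary-level TWAS (the FUSION-style test).

Given marginal GWAS z-scores ``z`` for the cis-SNPs of a gene, a vector of
expression weights ``w`` estimated in one reference tissue, and an LD
correlation matrix ``R`` from a reference panel, the gene-trait association
statistic is

    Z_t = (z w') / sqrt(w R w')

Under the null of no SNP-trait association, z ~ MVN(0, R), hence Z_t is
asymptotically standard normal and a two-sided normal p-value applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Variance below which the ridge fallback kicks in (w R w' considered degenerate).
VARIANCE_FLOOR = 1e-10
#: Ridge added to the LD diagonal by the automatic fallback.
FALLBACK_RIDGE = 1e-6


class SnpAlignmentError(ValueError):
    """Raised when GWAS, weight and LD inputs share no SNPs."""


class DegenerateVarianceError(ValueError):
    """Raised when w (R + ridge I) w' is not positive even after the ridge fallback."""


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class GwasZVector:
    """Marginal GWAS z-scores for the cis-SNPs of one gene."""

    snp_ids: tuple[str, ...]
    z: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "snp_ids", tuple(str(s) for s in self.snp_ids))
        z = _as_1d_float(self.z, "z")
        if len(self.snp_ids) == 0:
            raise ValueError("GwasZVector needs at least one SNP")
        if z.shape[0] != len(self.snp_ids):
            raise ValueError("z and snp_ids lengths differ")
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite z-score")
        object.__setattr__(self, "z", z)

    def subset(self, ids: list[str]) -> "GwasZVector":
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        idx = [pos[s] for s in ids]
        return GwasZVector(tuple(ids), self.z[idx])


@dataclass(frozen=True)
class WeightVector:
    """Estimated joint cis-SNP effect sizes on expression for one gene in one tissue."""

    gene: str
    tissue: str
    snp_ids: tuple[str, ...]
    w: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "snp_ids", tuple(str(s) for s in self.snp_ids))
        w = _as_1d_float(self.w, "w")
        if w.shape[0] != len(self.snp_ids):
            raise ValueError("w and snp_ids lengths differ")
        if not np.any(w != 0):
            raise ValueError(
                f"gene {self.gene} ({self.tissue}): all-zero weight vector is untestable"
            )
        object.__setattr__(self, "w", w)

    def subset(self, ids: list[str]) -> "WeightVector":
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        idx = [pos[s] for s in ids]
        return WeightVector(self.gene, self.tissue, tuple(ids), self.w[idx])


@dataclass(frozen=True)
class LDMatrix:
    """SNP-SNP correlation matrix estimated from a reference panel."""

    snp_ids: tuple[str, ...]
    R: np.ndarray

    #: tolerances for the validity checks
    sym_tol: float = field(default=1e-8, repr=False)
    diag_tol: float = field(default=1e-6, repr=False)
    eig_tol: float = field(default=-1e-8, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "snp_ids", tuple(str(s) for s in self.snp_ids))
        R = np.asarray(self.R, dtype=float)
        m = len(self.snp_ids)
        if R.shape != (m, m):
            raise ValueError(f"LD matrix shape {R.shape} does not match {m} SNP ids")
        if not np.allclose(R, R.T, atol=self.sym_tol):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=self.diag_tol):
            raise ValueError("LD matrix diagonal is not 1")
        if np.linalg.eigvalsh(R).min() < self.eig_tol:
            raise ValueError("LD matrix has a substantially negative eigenvalue")
        object.__setattr__(self, "R", R)

    def subset(self, ids: list[str]) -> "LDMatrix":
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        idx = np.array([pos[s] for s in ids])
        return LDMatrix(tuple(ids), self.R[np.ix_(idx, idx)])


@dataclass(frozen=True)
class TissueAssociation:
    """TWAS result for one gene in one tissue: statistic ``z_t`` and its p-value."""

    gene: str
    tissue: str
    z_t: float
    p_t: float
    n_snps: int = 0


def two_sided_p(z) -> np.ndarray | float:
    """Two-sided standard-normal p-value of a z statistic."""
    return 2.0 * stats.norm.sf(np.abs(z))


def align_snps(
    z: GwasZVector, w: WeightVector, ld: LDMatrix
) -> tuple[GwasZVector, WeightVector, LDMatrix]:
    """Restrict the three inputs to their common SNPs, in the weight file's order.

    Missing weights are treated as absent SNPs (intersection), not as zeros.
    Raises :class:`SnpAlignmentError` when the intersection is empty.
    """
    common = set(z.snp_ids) & set(w.snp_ids) & set(ld.snp_ids)
    if not common:
        raise SnpAlignmentError(f"no overlapping SNPs for gene {w.gene} ({w.tissue})")
    order = [s for s in w.snp_ids if s in common]
    for name, obj in (("GWAS", z), ("weights", w), ("LD", ld)):
        dropped = len(obj.snp_ids) - len(order)
        if dropped:
            logger.info("align_snps: dropped %d %s SNPs for gene %s", dropped, name, w.gene)
    if order == list(z.snp_ids) == list(w.snp_ids) == list(ld.snp_ids):
        return z, w, ld
    return z.subset(order), w.subset(order), ld.subset(order)


def twas_z(
    z: GwasZVector, w: WeightVector, ld: LDMatrix, ridge: float = 0.0
) -> TissueAssociation:
    """Compute the single-tissue TWAS statistic Z_t = z w' / sqrt(w R w').

    ``ridge`` is added to the LD diagonal before forming the variance; when the
    variance is still at or below the degeneracy floor with the requested ridge,
    a fallback ridge of ``FALLBACK_RIDGE`` is applied once and logged.  The
    statistic is invariant to rescaling of ``w``.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if not (tuple(z.snp_ids) == tuple(w.snp_ids) == tuple(ld.snp_ids)):
        z, w, ld = align_snps(z, w, ld)
    wv = w.w
    num = float(z.z @ wv)
    var = float(wv @ ld.R @ wv) + ridge * float(wv @ wv)
    if var <= VARIANCE_FLOOR:
        var = float(wv @ ld.R @ wv) + FALLBACK_RIDGE * float(wv @ wv)
        logger.warning(
            "twas_z: w R w' <= %g for gene %s (%s); applying ridge %g",
            VARIANCE_FLOOR, w.gene, w.tissue, FALLBACK_RIDGE,
        )
        if var <= 0:
            raise DegenerateVarianceError(
                f"degenerate weight/LD combination for gene {w.gene} ({w.tissue})"
            )
    z_t = num / np.sqrt(var)
    return TissueAssociation(
        gene=w.gene, tissue=w.tissue, z_t=float(z_t),
        p_t=float(two_sided_p(z_t)), n_snps=len(w.snp_ids),
    )
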