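"""Combine per-tissue TWAS p-values for a gene into a single gene-level p-value.

Three combiners are provided:

* :func:`scat_combine` — the Cauchy aggregation test.  The statistic

      T = sum_t  varpi_t * tan((1/2 - p_t) * pi)

  is, under the null, a weighted sum of standard Cauchy variables; T divided
  by the weight total is again approximately standard Cauchy *whatever* the
  dependence among the p-values (exactly so under independence), so

      P = 1/2 - arctan(T / sum_t varpi_t) / pi

  is a valid combined p-value without knowledge of the correlation structure.
* :func:`fisher_combine` — Fisher's -2 sum log p against chi-square(2k); valid
  only for independent tests, included as the classical comparator.
* :func:`oracle_combine` — the chi-square test Q = Z C^-1 Z' available only
  when the inter-tissue correlation C of the z-scores is known.

Missing tissues (NaN p-values) are dropped and the weight normaliser is
recomputed over the observed tissues.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: clipping bounds for incoming p-values (double precision safety)
P_MIN = 1e-300
P_MAX = 1.0 - 1e-16
#: below this, tan((1/2-p)pi) is evaluated through its asymptote 1/(p*pi)
TAN_ASYMPTOTE_P = 1e-15
#: above this (statistic / weight total), the combined p uses the Cauchy tail 1/(pi*x)
CAUCHY_TAIL_X = 1e15


class NoCombinableTissuesError(ValueError):
    """Raised when every tissue of a gene is missing."""


@dataclass(frozen=True)
class TissuePValueSet:
    """Per-gene collection of per-tissue p-values with combination weights.

    Missing tissues are encoded as NaN in ``p``.  ``varpi`` are the
    non-negative combination weights; equal weights when omitted.
    """

    gene: str
    tissues: tuple[str, ...]
    p: np.ndarray
    varpi: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "tissues", tuple(str(t) for t in self.tissues))
        p = np.asarray(self.p, dtype=float)
        if p.shape != (len(self.tissues),):
            raise ValueError("p and tissues lengths differ")
        object.__setattr__(self, "p", p)
        if self.varpi is None:
            varpi = np.full(p.shape, 1.0 / len(self.tissues))
        else:
            varpi = np.asarray(self.varpi, dtype=float)
            if varpi.shape != p.shape:
                raise ValueError("varpi and p lengths differ")
            if np.any(varpi < 0):
                raise ValueError("combination weights must be non-negative")
        object.__setattr__(self, "varpi", varpi)
        obs = ~np.isnan(p)
        if not obs.any():
            raise NoCombinableTissuesError(f"gene {self.gene}: no combinable tissues")
        if not np.any(varpi[obs] > 0):
            raise ValueError(f"gene {self.gene}: no positive weight on an observed tissue")


@dataclass(frozen=True)
class ZScoreVector:
    """Per-tissue TWAS z-scores for one gene (complete, no missing entries)."""

    gene: str
    tissues: tuple[str, ...]
    Z: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "tissues", tuple(str(t) for t in self.tissues))
        Z = np.asarray(self.Z, dtype=float)
        if Z.shape != (len(self.tissues),):
            raise ValueError("Z and tissues lengths differ")
        if not np.all(np.isfinite(Z)):
            raise ValueError("non-finite z-score")
        object.__setattr__(self, "Z", Z)


@dataclass(frozen=True)
class ExpressionCorrelation:
    """Known correlation matrix of the per-tissue TWAS z-scores."""

    tissues: tuple[str, ...]
    C: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "tissues", tuple(str(t) for t in self.tissues))
        C = np.asarray(self.C, dtype=float)
        T = len(self.tissues)
        if C.shape != (T, T):
            raise ValueError("correlation matrix shape does not match tissues")
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-6):
            raise ValueError("correlation matrix diagonal is not 1")
        object.__setattr__(self, "C", C)


@dataclass(frozen=True)
class CombinedResult:
    gene: str
    method: str  # SCAT | FISHER | ORACLE | MINP
    statistic: float
    p: float
    n_tissues_used: int


def _clip_p(p: np.ndarray, gene: str) -> np.ndarray:
    out = p.copy()
    bad = (~np.isnan(out)) & ((out <= 0) | (out >= 1))
    if bad.any():
        warnings.warn(
            f"gene {gene}: {int(bad.sum())} p-value(s) outside (0,1) clipped to "
            f"[{P_MIN:g}, {P_MAX!r}]",
            stacklevel=3,
        )
    return np.clip(out, P_MIN, P_MAX)


def cauchy_tan(p: np.ndarray) -> np.ndarray:
    """tan((1/2 - p) * pi), evaluated accurately over the whole of (0, 1).

    The direct formula loses precision for small p (the argument rounds near
    pi/2, where tan amplifies the rounding error by 1/p), so the identity
    tan((1/2 - p) pi) = cot(p pi) = -cot((1-p) pi) is used on the half nearer
    to each endpoint, with the asymptote 1/(p pi) below ``TAN_ASYMPTOTE_P``.
    """
    p = np.asarray(p, dtype=float)
    tiny = p < TAN_ASYMPTOTE_P
    lower = p <= 0.5
    safe = np.where(tiny, 0.25, p)  # placeholder keeps tan() off its pole
    with np.errstate(divide="ignore"):
        out = np.where(lower,
                       1.0 / np.tan(safe * np.pi),
                       -1.0 / np.tan((1.0 - p) * np.pi))
        out = np.where(tiny, 1.0 / (np.where(tiny, p, 1.0) * np.pi), out)
    return out


def cauchy_sf_standard(x: float) -> float:
    """Upper tail of the standard Cauchy, stable for huge |x|."""
    if x > CAUCHY_TAIL_X:
        return 1.0 / (np.pi * x)
    if x < -CAUCHY_TAIL_X:
        return 1.0 - 1.0 / (np.pi * (-x))
    return 0.5 - np.arctan(x) / np.pi


def scat_combine(ps: TissuePValueSet) -> CombinedResult:
    """Cauchy aggregation of one gene's per-tissue p-values.

    Missing tissues are dropped; the observed weights enter both the statistic
    and the normaliser, so the combined p-value is invariant to rescaling all
    weights.  A single p-value is returned unchanged.
    """
    obs = ~np.isnan(ps.p)
    p = _clip_p(ps.p[obs], ps.gene)
    w = ps.varpi[obs]
    stat = float(w @ cauchy_tan(p))
    scale = float(w.sum())
    combined = cauchy_sf_standard(stat / scale)
    # guard the open-interval contract
    combined = min(max(combined, np.nextafter(0.0, 1.0)), 1.0)
    return CombinedResult(ps.gene, "SCAT", stat, float(combined), int(obs.sum()))


def fisher_combine(ps: TissuePValueSet) -> CombinedResult:
    """Fisher's method: -2 sum log p ~ chi-square(2k) under independence."""
    obs = ~np.isnan(ps.p)
    p = _clip_p(ps.p[obs], ps.gene)
    k = int(obs.sum())
    stat = float(-2.0 * np.log(p).sum())
    combined = float(stats.chi2.sf(stat, 2 * k))
    return CombinedResult(ps.gene, "FISHER", stat, combined, k)


def oracle_combine(
    zs: ZScoreVector, c: ExpressionCorrelation, ridge: float = 0.0
) -> CombinedResult:
    """Q = Z C^-1 Z' against chi-square(T), for a known correlation C.

    C is inverted implicitly via a linear solve; ``ridge`` is added to the
    diagonal first when given.
    """
    if zs.tissues != c.tissues:
        raise ValueError("tissue ids of z-scores and correlation matrix differ")
    C = c.C + ridge * np.eye(len(c.tissues))
    try:
        sol = np.linalg.solve(C, zs.Z)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"correlation matrix not invertible for gene {zs.gene}") from e
    T = len(zs.tissues)
    q = float(zs.Z @ sol)
    return CombinedResult(zs.gene, "ORACLE", q, float(stats.chi2.sf(q, T)), T)


def _minp_bonferroni(ps: TissuePValueSet) -> CombinedResult:
    # benchmark helper only: min-p with Bonferroni calibration, not exported
    obs = ~np.isnan(ps.p)
    p = _clip_p(ps.p[obs], ps.gene)
    k = int(obs.sum())
    stat = float(p.min())
    return CombinedResult(ps.gene, "MINP", stat, float(min(1.0, k * stat)), k)


_METHODS = {"scat": scat_combine, "fisher": fisher_combine, "minp": _minp_bonferroni}


def combine_table(
    results: pd.DataFrame,
    method: str = "scat",
    weights: pd.DataFrame | None = None,
    correlation: ExpressionCorrelation | None = None,
) -> pd.DataFrame:
    """Combine a per-tissue result table (columns GENE, TISSUE, TWAS_P and,
    for the oracle, TWAS_Z) into one row per gene.

    ``weights`` optionally carries columns GENE, TISSUE, VARPI overriding the
    default equal weights.  The oracle requires ``correlation`` (the z-score
    correlation is unknown in practice, which is exactly why SCAT exists) and
    genes observed in every tissue of that matrix.
    """
    method = method.lower()
    if method not in (*_METHODS, "oracle"):
        raise ValueError(f"unknown combination method: {method}")
    required = {"GENE", "TISSUE", "TWAS_P"} if method != "oracle" else {"GENE", "TISSUE", "TWAS_Z"}
    missing_cols = required - set(results.columns)
    if missing_cols:
        raise ValueError(f"result table lacks columns: {sorted(missing_cols)}")
    if method == "oracle" and correlation is None:
        raise ValueError(
            "oracle combination requires a tissue correlation matrix, "
            "which is often unknown for summary-level data"
        )
    wmap: dict[tuple[str, str], float] = {}
    if weights is not None:
        wmap = {
            (str(r.GENE), str(r.TISSUE)): float(r.VARPI)
            for r in weights.itertuples(index=False)
        }

    rows = []
    for gene, grp in results.groupby("GENE", sort=True):
        grp = grp.sort_values("TISSUE")
        tissues = tuple(grp["TISSUE"].astype(str))
        if method == "oracle":
            order = {t: i for i, t in enumerate(correlation.tissues)}
            if set(tissues) != set(correlation.tissues):
                raise ValueError(
                    f"gene {gene}: oracle needs z-scores for every tissue of C"
                )
            grp = grp.iloc[np.argsort([order[t] for t in tissues])]
            zs = ZScoreVector(str(gene), correlation.tissues,
                              grp["TWAS_Z"].to_numpy(dtype=float))
            res = oracle_combine(zs, correlation)
        else:
            varpi = None
            if wmap:
                varpi = np.array([wmap.get((str(gene), t), 0.0) for t in tissues])
            ps = TissuePValueSet(str(gene), tissues,
                                 grp["TWAS_P"].to_numpy(dtype=float), varpi)
            res = _METHODS[method](ps)
        rows.append((res.gene, res.method, res.n_tissues_used, res.statistic, res.p))
    return pd.DataFrame(rows, columns=["GENE", "METHOD", "N_TISSUES", "STAT", "P"])
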