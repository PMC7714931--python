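"""Benjamini-Hochberg FDR adjustment and significance calling."""

from __future__ import annotations

import numpy as np
import pandas as pd


def bh_adjust(p) -> np.ndarray:
    """Classical BH step-up adjusted values: q_(i) = min_{j>=i} m p_(j) / j, capped at 1.

    NaN entries propagate and are excluded from the effective number of tests m
    (an untestable gene is not a hypothesis).  Adjusted values follow their
    p-values under any reordering of the input; ties share a value.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    obs = ~np.isnan(p)
    if np.any((p[obs] < 0) | (p[obs] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    m = int(obs.sum())
    if m == 0:
        return q
    po = p[obs]
    order = np.argsort(po, kind="stable")
    ranked = po[order] * m / np.arange(1, m + 1)
    qo = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = qo
    q[obs] = out
    return q


def call_significant(
    results: pd.DataFrame, threshold: float = 0.05, pcol: str = "P"
) -> pd.DataFrame:
    """Append BH q-values and a strict-inequality significance flag (q < threshold)."""
    if pcol not in results.columns:
        raise ValueError(f"no column {pcol!r} in results table")
    out = results.copy()
    out["Q"] = bh_adjust(out[pcol].to_numpy(dtype=float))
    out["SIGNIFICANT"] = out["Q"] < threshold
    out.loc[out["Q"].isna(), "SIGNIFICANT"] = False
    return out
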