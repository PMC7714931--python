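"""Monte-Carlo engine for the type-I-error and power experiments.

Replicates are per-tissue z-score vectors drawn as z = mu + MVN(0, C).  Under
the null mu = 0; under the alternative each per-tissue mean is drawn iid
N(0, variance) (default variance 2.5), by default resampled in every
replicate.  Each z is converted to two-sided standard-normal p-values,
optionally a random subset of 5-11 tissues is set missing (matching the fact
that most genes are not cis-heritable in every reference tissue), and the
remaining p-values are combined per method.  Empirical size/power is the
rejection fraction at the nominal level.

All methods are evaluated on the same replicate draws (variance reduction for
method comparisons), and every run is reproducible from its seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .combination import cauchy_tan, cauchy_sf_standard

KNOWN_METHODS = ("scat", "fisher", "single_tissue", "oracle", "minp")

#: default number of tissues (the 13 GTEx brain reference panels)
DEFAULT_T = 13

#: replicate rows generated per chunk (keeps peak memory modest at 10^6 reps)
_CHUNK = 100_000

#: maximum points written to a QQ table
_QQ_POINTS = 1_000


@dataclass(frozen=True)
class CorrelationSpec:
    """Correlation structure of the per-tissue z-scores (the C matrix)."""

    kind: str = "independent"  # independent | exchangeable | ar1 | matrix
    rho: float = 0.0
    T: int = DEFAULT_T
    matrix: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("independent", "exchangeable", "ar1", "matrix"):
            raise ValueError(f"unknown correlation kind: {self.kind}")
        if self.kind in ("exchangeable", "ar1") and not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.kind == "matrix":
            if self.matrix is None:
                raise ValueError("kind 'matrix' requires an explicit matrix")
            M = np.asarray(self.matrix, dtype=float)
            if M.shape[0] != M.shape[1]:
                raise ValueError("correlation matrix must be square")
            object.__setattr__(self, "matrix", M)
            object.__setattr__(self, "T", M.shape[0])
        if self.T < 1:
            raise ValueError("T must be >= 1")

    def build(self) -> np.ndarray:
        if self.kind == "matrix":
            return self.matrix.copy()
        if self.kind == "independent":
            return np.eye(self.T)
        if self.kind == "exchangeable":
            C = np.full((self.T, self.T), self.rho)
            np.fill_diagonal(C, 1.0)
            return C
        idx = np.arange(self.T)
        return self.rho ** np.abs(np.subtract.outer(idx, idx))

    def cholesky(self) -> np.ndarray:
        C = self.build()
        try:
            return np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            lam = np.linalg.eigvalsh(C).min()
            raise ValueError(
                f"correlation matrix is not positive definite (min eigenvalue {lam:.3g})"
            )


@dataclass(frozen=True)
class MeanModel:
    """Mean vector of the z-scores: zero under the null, iid Gaussian under power runs."""

    kind: str = "null"  # null | gaussian
    variance: float = 2.5
    resample_per_replicate: bool = True

    def __post_init__(self):
        if self.kind not in ("null", "gaussian"):
            raise ValueError(f"unknown mean kind: {self.kind}")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


@dataclass(frozen=True)
class MissingnessSpec:
    """Per replicate, a uniform number k in [min_missing, max_missing] of
    uniformly chosen tissues is set missing (power runs only)."""

    enabled: bool = False
    min_missing: int = 5
    max_missing: int = 11

    def __post_init__(self):
        if self.enabled and not (0 <= self.min_missing <= self.max_missing):
            raise ValueError("need 0 <= min_missing <= max_missing")


@dataclass(frozen=True)
class SimulationResult:
    method: str
    n_reps: int
    alpha: float
    rejections: int
    seed: int
    rate: float = field(init=False)
    mc_se: float = field(init=False)

    def __post_init__(self):
        rate = self.rejections / self.n_reps
        object.__setattr__(self, "rate", rate)
        object.__setattr__(self, "mc_se", float(np.sqrt(rate * (1 - rate) / self.n_reps)))


def simulate_z(
    corr: CorrelationSpec,
    mean: MeanModel = MeanModel(),
    n_reps: int = 1,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw an (n_reps, T) matrix of z-score replicates z = mu + MVN(0, C)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    L = corr.cholesky()
    T = corr.T
    z = rng.standard_normal((n_reps, T)) @ L.T
    if mean.kind == "gaussian" and mean.variance > 0:
        sd = np.sqrt(mean.variance)
        if mean.resample_per_replicate:
            z += rng.normal(0.0, sd, size=(n_reps, T))
        else:
            z += rng.normal(0.0, sd, size=(1, T))
    return z


def z_to_pvalues(z: np.ndarray) -> np.ndarray:
    """Two-sided standard-normal p-values, elementwise."""
    return 2.0 * stats.norm.sf(np.abs(z))


def _apply_missingness(p: np.ndarray, miss: MissingnessSpec, rng: np.random.Generator) -> np.ndarray:
    if not miss.enabled:
        return p
    n, T = p.shape
    if miss.max_missing >= T:
        raise ValueError("max_missing must be smaller than the number of tissues")
    out = p.copy()
    k = rng.integers(miss.min_missing, miss.max_missing + 1, size=n)
    # rank a uniform draw per cell: the k smallest ranks are the missing set
    u = rng.random((n, T))
    order = np.argsort(u, axis=1)
    mask = np.arange(T)[None, :] < k[:, None]
    rows = np.repeat(np.arange(n), T).reshape(n, T)
    out[rows[mask], order[mask]] = np.nan
    return out


def _scat_p_rows(p: np.ndarray) -> np.ndarray:
    """Equal-weight Cauchy combination of each row (NaN entries dropped)."""
    t = cauchy_tan(np.clip(p, 1e-300, 1 - 1e-16))
    t = np.where(np.isnan(p), np.nan, t)
    with np.errstate(invalid="ignore"):
        x = np.nanmean(t, axis=1)
    return np.array([cauchy_sf_standard(v) for v in x])


def _fisher_p_rows(p: np.ndarray) -> np.ndarray:
    q = np.clip(p, 1e-300, 1 - 1e-16)
    stat = -2.0 * np.nansum(np.where(np.isnan(p), np.nan, np.log(q)), axis=1)
    k = (~np.isnan(p)).sum(axis=1)
    return stats.chi2.sf(stat, 2 * k)


def _minp_p_rows(p: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        m = np.nanmin(p, axis=1)
    k = (~np.isnan(p)).sum(axis=1)
    return np.minimum(1.0, k * m)


def _oracle_p_rows(z: np.ndarray, C: np.ndarray) -> np.ndarray:
    sol = np.linalg.solve(C, z.T).T
    q = np.einsum("ij,ij->i", z, sol)
    return stats.chi2.sf(q, z.shape[1])


def combined_pvalues(
    method: str,
    p: np.ndarray,
    z: np.ndarray | None = None,
    C: np.ndarray | None = None,
) -> np.ndarray:
    """Per-replicate combined p-values for one method on a (n, T) p matrix.

    ``single_tissue`` returns the first tissue's p-values (each tissue is
    marginally identical by exchangeability of the designs used here); use
    :func:`per_tissue_rejection_rates` for all tissues.
    """
    if method == "scat":
        return _scat_p_rows(p)
    if method == "fisher":
        return _fisher_p_rows(p)
    if method == "minp":
        return _minp_p_rows(p)
    if method == "single_tissue":
        return p[:, 0]
    if method == "oracle":
        if z is None or C is None:
            raise ValueError("oracle needs the z matrix and the true correlation C")
        return _oracle_p_rows(z, C)
    raise ValueError(f"unknown method: {method}")


def per_tissue_rejection_rates(p: np.ndarray, alpha: float) -> np.ndarray:
    """Rejection rate of each single-tissue test (missing = no rejection)."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(p < alpha, axis=0)


def _run(
    corr: CorrelationSpec,
    mean: MeanModel,
    miss: MissingnessSpec,
    methods: list[str],
    n_reps: int,
    alphas: list[float],
    seed: int,
    collect_qq: bool,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    for m in methods:
        if m not in KNOWN_METHODS:
            raise ValueError(f"unknown method: {m}")
    rng = np.random.default_rng(seed)
    C = corr.build()
    counts = {(m, a): 0 for m in methods for a in alphas}
    pools: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    done = 0
    while done < n_reps:
        n = min(_CHUNK, n_reps - done)
        z = simulate_z(corr, mean, n, rng=rng)
        p = _apply_missingness(z_to_pvalues(z), miss, rng)
        for m in methods:
            cp = combined_pvalues(m, p, z=z, C=C)
            for a in alphas:
                counts[(m, a)] += int(np.sum(cp < a))
            if collect_qq:
                pools[m].append(cp)
        done += n
    rows = [
        SimulationResult(method=m, n_reps=n_reps, alpha=a,
                         rejections=counts[(m, a)], seed=seed)
        for m in methods for a in alphas
    ]
    res = pd.DataFrame(
        [(r.method, r.alpha, r.n_reps, r.rate, r.mc_se, r.seed) for r in rows],
        columns=["METHOD", "ALPHA", "N_REPS", "RATE", "MC_SE", "SEED"],
    )
    qq_rows = []
    if collect_qq:
        for m in methods:
            cp = np.sort(np.concatenate(pools[m]))
            n = len(cp)
            take = np.unique(np.linspace(0, n - 1, min(_QQ_POINTS, n)).astype(int))
            exp = -np.log10((take + 0.5) / n)
            obs = -np.log10(np.clip(cp[take], 1e-300, 1.0))
            qq_rows.extend(zip(exp, obs, [m] * len(take)))
    qq = pd.DataFrame(qq_rows, columns=["EXPECTED_NEGLOG10P", "OBSERVED_NEGLOG10P", "METHOD"])
    return res, qq


def estimate_size(
    corr: CorrelationSpec,
    methods: list[str] = ["scat"],
    n_reps: int = 1_000_000,
    alpha_grid: list[float] = [0.01, 0.05],
    seed: int = 0,
    collect_qq: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Empirical type-I error of each method at each nominal level.

    Size runs use complete vectors (no missingness) and mu = 0.
    """
    return _run(corr, MeanModel(kind="null"), MissingnessSpec(enabled=False),
                list(methods), n_reps, list(alpha_grid), seed, collect_qq)


def estimate_power(
    corr: CorrelationSpec,
    mean: MeanModel = MeanModel(kind="gaussian", variance=2.5),
    missing: MissingnessSpec = MissingnessSpec(enabled=True),
    methods: list[str] = ["scat"],
    n_reps: int = 1_000,
    alpha: float = 0.05,
    seed: int = 0,
    collect_qq: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Empirical power: rejection fraction of combined p < alpha over replicates."""
    if missing.enabled and corr.T <= missing.max_missing:
        raise ValueError("missingness would remove every tissue")
    return _run(corr, mean, missing, list(methods), n_reps, [alpha], seed, collect_qq)


def empirical_style_correlation() -> tuple[tuple[str, ...], np.ndarray]:
    """A synthetic 13-tissue correlation matrix standing in for an empirical
    inter-tissue z-score correlation: three anatomical blocks with strong
    within-block (0.6-0.9) and moderate between-block (0.3-0.45) correlation.

    Deterministic, positive definite, unit diagonal.  It is NOT the matrix any
    real expression panel produced; supply your own via ``kind='matrix'`` when
    you have one.
    """
    tissues = tuple(f"BRAIN_{i:02d}" for i in range(1, 14))
    blocks = [(0, 5, 0.80), (5, 9, 0.70), (9, 13, 0.60)]
    C = np.full((13, 13), 0.30)
    for i0, i1, r in blocks:
        C[i0:i1, i0:i1] = r
    C[0:5, 5:9] = C[5:9, 0:5] = 0.45
    C[5:9, 9:13] = C[9:13, 5:9] = 0.40
    np.fill_diagonal(C, 1.0)
    assert np.linalg.eigvalsh(C).min() > 0
    return tissues, C


# ---------------------------------------------------------------------------
# scenario files

_SCHEMA_DOC = """scenario JSON keys:
  correlation: {kind: independent|exchangeable|ar1|matrix, rho?, T?, matrix_file?}
  mean: {kind: null|gaussian, variance?, resample_per_replicate?}
  missingness: {enabled, min, max}
  methods: [scat|fisher|single_tissue|oracle|minp, ...]
  n_reps: int; alpha: number or [numbers]; seed: int; out_prefix: str
"""


class ScenarioError(ValueError):
    """Scenario config does not validate; message carries the field path."""


def _req(cfg: dict, key: str, typ, path: str):
    if key not in cfg:
        raise ScenarioError(f"{path}.{key}: missing required field")
    v = cfg[key]
    if typ is float:
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ScenarioError(f"{path}.{key}: expected a number, got {type(v).__name__}")
        return float(v)
    if not isinstance(v, typ):
        raise ScenarioError(f"{path}.{key}: expected {typ.__name__}, got {type(v).__name__}")
    return v


def parse_scenario(cfg: dict, base_dir: Path | str = ".") -> dict:
    """Validate a scenario config dict; returns typed pieces ready to run."""
    if not isinstance(cfg, dict):
        raise ScenarioError("$: scenario must be a JSON object")
    c = _req(cfg, "correlation", dict, "$")
    kind = _req(c, "kind", str, "$.correlation")
    if kind == "matrix":
        mf = _req(c, "matrix_file", str, "$.correlation")
        from .io import read_square_matrix
        _, M = read_square_matrix(Path(base_dir) / mf)
        corr = CorrelationSpec(kind="matrix", matrix=M)
    else:
        try:
            corr = CorrelationSpec(kind=kind, rho=float(c.get("rho", 0.0)),
                                   T=int(c.get("T", DEFAULT_T)))
        except ValueError as e:
            raise ScenarioError(f"$.correlation: {e}") from e
    m = _req(cfg, "mean", dict, "$")
    try:
        mean = MeanModel(kind=_req(m, "kind", str, "$.mean"),
                         variance=float(m.get("variance", 2.5)),
                         resample_per_replicate=bool(m.get("resample_per_replicate", True)))
    except ValueError as e:
        raise ScenarioError(f"$.mean: {e}") from e
    mi = cfg.get("missingness", {"enabled": False})
    if not isinstance(mi, dict):
        raise ScenarioError("$.missingness: expected an object")
    try:
        miss = MissingnessSpec(enabled=bool(mi.get("enabled", False)),
                               min_missing=int(mi.get("min", 5)),
                               max_missing=int(mi.get("max", 11)))
    except ValueError as e:
        raise ScenarioError(f"$.missingness: {e}") from e
    methods = _req(cfg, "methods", list, "$")
    for i, mm in enumerate(methods):
        if mm not in KNOWN_METHODS:
            raise ScenarioError(f"$.methods[{i}]: unknown method {mm!r}")
    n_reps = _req(cfg, "n_reps", int, "$")
    alpha = cfg.get("alpha", 0.05)
    alphas = [float(a) for a in alpha] if isinstance(alpha, list) else [float(alpha)]
    for a in alphas:
        if not (0 < a <= 1):
            raise ScenarioError("$.alpha: levels must lie in (0, 1]")
    seed = int(cfg.get("seed", 0))
    out_prefix = _req(cfg, "out_prefix", str, "$")
    return dict(corr=corr, mean=mean, miss=miss, methods=list(methods),
                n_reps=int(n_reps), alphas=alphas, seed=seed, out_prefix=out_prefix)


def run_scenario(
    config: dict | str | Path,
    out_dir: str | Path = ".",
    seed: int | None = None,
    n_reps: int | None = None,
) -> tuple[Path, Path]:
    """Run a scenario config and write <out_prefix>_results.tsv and <out_prefix>_qq.tsv.

    Output headers embed the seed, a hash of the resolved config, and the
    package version, so identical (config, seed) runs are byte-identical.
    """
    from . import __version__

    base_dir = Path(".")
    if not isinstance(config, dict):
        path = Path(config)
        base_dir = path.parent
        with open(path) as fh:
            config = json.load(fh)
    sc = parse_scenario(config, base_dir=base_dir)
    if seed is not None:
        sc["seed"] = int(seed)
    if n_reps is not None:
        sc["n_reps"] = int(n_reps)
    res, qq = _run(sc["corr"], sc["mean"], sc["miss"], sc["methods"],
                   sc["n_reps"], sc["alphas"], sc["seed"], collect_qq=True)
    cfg_for_hash = dict(config, seed=sc["seed"], n_reps=sc["n_reps"])
    digest = hashlib.sha256(
        json.dumps(cfg_for_hash, sort_keys=True).encode()
    ).hexdigest()[:16]
    header = (f"# scat-twas {__version__}\n# seed={sc['seed']}\n"
              f"# config_hash={digest}\n")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res_path = out_dir / f"{sc['out_prefix']}_results.tsv"
    qq_path = out_dir / f"{sc['out_prefix']}_qq.tsv"
    for path, df, fmt in ((res_path, res, "%.6g"), (qq_path, qq, "%.6g")):
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format=fmt)
    return res_path, qq_path
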