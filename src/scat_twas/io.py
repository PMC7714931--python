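"""Readers and writers for the toolkit's text dialects, plus fixture generation.

All tables are tab-separated with mandatory headers and ``NA`` as the sole
missing-value token.  The square-matrix dialect is a whitespace-delimited
matrix preceded by one header line of ids (the PLINK ``--r square`` layout
with an added header).  SNP/tissue/gene ids are opaque strings; the methods
never use genomic positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .twas_core import GwasZVector, LDMatrix, WeightVector, two_sided_p

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class FileFormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _require_columns(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise FileFormatError(f"{path}: missing required column(s) {sorted(missing)}")


# ---------------------------------------------------------------------------
# GWAS summary statistics: SNP, A1, A2, Z

def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, {"SNP", "A1", "A2", "Z"}, path)
    try:
        df["Z"] = df["Z"].astype(float)
    except ValueError as e:
        raise FileFormatError(f"{path}: non-numeric Z value ({e})") from e
    return df


def write_gwas(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# expression weights: GENE, TISSUE, SNP, A1, A2, WEIGHT

def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, {"GENE", "TISSUE", "SNP", "A1", "A2", "WEIGHT"}, path)
    numeric = pd.to_numeric(df["WEIGHT"], errors="coerce")
    na = numeric.isna()
    explicit_na = df["WEIGHT"].isin(["NA", "nan", ""]) | df["WEIGHT"].isna()
    if (na & ~explicit_na).any():
        row = int(np.flatnonzero(na & ~explicit_na)[0]) + 2  # header is line 1
        raise FileFormatError(f"{path}: non-numeric WEIGHT at line {row}")
    if na.any():
        logger.warning("%s: skipped %d rows with missing WEIGHT", path, int(na.sum()))
    out = df.loc[~na].copy()
    out["WEIGHT"] = numeric[~na]
    return out


def write_weights(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# square matrix with id header (LD or tissue correlation)

def read_square_matrix(path) -> tuple[tuple[str, ...], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise FileFormatError(f"{path}: empty header line")
        m = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            vals = line.split()
            if len(vals) != m:
                raise FileFormatError(
                    f"{path}: ragged matrix row at line {lineno} "
                    f"(expected {m} values, got {len(vals)})"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as e:
                raise FileFormatError(f"{path}: non-numeric cell at line {lineno}") from e
    if len(rows) != m:
        raise FileFormatError(
            f"{path}: ragged matrix: {m} header ids but {len(rows)} rows "
            f"(file ends at line {len(rows) + 1})"
        )
    return tuple(header), np.array(rows)


def write_square_matrix(ids, M: np.ndarray, path) -> None:
    M = np.asarray(M, dtype=float)
    with open(path, "w") as fh:
        fh.write(" ".join(ids) + "\n")
        for row in M:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_ld_matrix(path) -> LDMatrix:
    ids, M = read_square_matrix(path)
    return LDMatrix(ids, M)


# ---------------------------------------------------------------------------
# per-tissue results: GENE, TISSUE, NSNPS?, TWAS_Z, TWAS_P

def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    _require_columns(df, {"GENE", "TISSUE", "TWAS_P"}, path)
    return df


def write_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


# ---------------------------------------------------------------------------
# scenario JSON

def read_scenario(path) -> dict:
    with open(path) as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as e:
            raise FileFormatError(f"{path}: invalid JSON at line {e.lineno}") from e


# ---------------------------------------------------------------------------
# allele harmonisation

def harmonise_alleles(
    gwas: pd.DataFrame, weights: pd.DataFrame, drop_ambiguous: bool = False
) -> pd.DataFrame:
    """Align GWAS z-scores to the weight file's effect alleles.

    Returns the GWAS table restricted to SNPs present in the weight table,
    with Z sign-flipped where A1/A2 are swapped relative to the weights.
    SNPs whose alleles cannot be reconciled are dropped with a warning;
    strand-ambiguous (A/T, C/G) SNPs are dropped only when ``drop_ambiguous``.
    """
    wa = weights[["SNP", "A1", "A2"]].drop_duplicates("SNP").set_index("SNP")
    rows = []
    n_flip = n_drop = n_amb = 0
    for rec in gwas.itertuples(index=False):
        if rec.SNP not in wa.index:
            continue
        a1, a2 = str(rec.A1).upper(), str(rec.A2).upper()
        if drop_ambiguous and (a1, a2) in AMBIGUOUS_PAIRS:
            n_amb += 1
            continue
        w1, w2 = str(wa.at[rec.SNP, "A1"]).upper(), str(wa.at[rec.SNP, "A2"]).upper()
        if (a1, a2) == (w1, w2):
            rows.append((rec.SNP, a1, a2, rec.Z))
        elif (a1, a2) == (w2, w1):
            rows.append((rec.SNP, w1, w2, -rec.Z))
            n_flip += 1
        else:
            n_drop += 1
    if n_flip:
        logger.info("harmonise_alleles: flipped z sign for %d swapped-allele SNPs", n_flip)
    if n_drop:
        logger.warning("harmonise_alleles: dropped %d SNPs with irreconcilable alleles", n_drop)
    if n_amb:
        logger.info("harmonise_alleles: dropped %d strand-ambiguous SNPs", n_amb)
    return pd.DataFrame(rows, columns=["SNP", "A1", "A2", "Z"])


def gwas_z_vector(gwas: pd.DataFrame) -> GwasZVector:
    return GwasZVector(tuple(gwas["SNP"]), gwas["Z"].to_numpy(dtype=float))


def weight_vectors(weights: pd.DataFrame):
    """Yield a WeightVector per (gene, tissue) group of a weights table."""
    for (gene, tissue), grp in weights.groupby(["GENE", "TISSUE"], sort=True):
        yield WeightVector(str(gene), str(tissue), tuple(grp["SNP"]),
                           grp["WEIGHT"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# fixtures

@dataclass(frozen=True)
class FixtureBundle:
    gwas: Path
    weights: Path
    ld: Path
    results: Path
    table2_like: Path
    scenarios: tuple[Path, ...]


#: Published per-tissue p-values of a gene detected in 9 of 13 brain tissues,
#: reused as a realistic combination-stage input (C9orf72-like profile).
C9ORF72_LIKE_P = (2.71e-8, 3.93e-10, 4.97e-4, 6.41e-3, 3.84e-16,
                  1.12e-4, 3.32e-24, 6.04e-7, 1.26e-7)

_TISSUES = tuple(f"BRAIN_{i:02d}" for i in range(1, 14))


def _random_ld(rng: np.random.Generator, m: int) -> np.ndarray:
    # AR(1)-flavoured block: always PD with unit diagonal
    rho = rng.uniform(0.2, 0.7)
    idx = np.arange(m)
    return rho ** np.abs(np.subtract.outer(idx, idx))


def make_fixtures(seed: int = 1, out_dir: str | Path = "fixtures") -> FixtureBundle:
    """Write a deterministic, self-consistent fixture bundle.

    Planted structure: GENE_MULTI carries a strong signal visible in many
    tissues, GENE_SINGLE is testable in exactly one tissue, GENE_NULL is pure
    noise, so end-to-end runs have a known expected ordering of combined
    p-values (multi < null).
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = {
        "GENE_MULTI": dict(m=6, tissues=_TISSUES[:10], lam=7.0),
        "GENE_SINGLE": dict(m=4, tissues=_TISSUES[:1], lam=5.0),
        "GENE_NULL": dict(m=5, tissues=_TISSUES[:9], lam=0.0),
    }
    snp_ids: list[str] = []
    ld_blocks: list[np.ndarray] = []
    gwas_rows, weight_rows = [], []
    alleles = ("A", "G")
    for gname, spec in genes.items():
        m = spec["m"]
        ids = [f"rs_{gname}_{j}" for j in range(m)]
        R = _random_ld(rng, m)
        snp_ids.extend(ids)
        ld_blocks.append(R)
        base_w = rng.normal(0.0, 1.0, m)
        # z centred on lam * R w / sqrt(w R w): the TWAS statistic then has
        # mean lam in tissues whose weights align with base_w
        mu_z = spec["lam"] * (R @ base_w) / np.sqrt(base_w @ R @ base_w)
        z = mu_z + np.linalg.cholesky(R) @ rng.standard_normal(m)
        for sid, zval in zip(ids, z):
            gwas_rows.append((sid, *alleles, zval))
        for tissue in spec["tissues"]:
            w = base_w + rng.normal(0.0, 0.25, m)
            for sid, wval in zip(ids, w):
                weight_rows.append((gname, tissue, sid, *alleles, wval))

    gwas = pd.DataFrame(gwas_rows, columns=["SNP", "A1", "A2", "Z"])
    weights = pd.DataFrame(weight_rows,
                           columns=["GENE", "TISSUE", "SNP", "A1", "A2", "WEIGHT"])
    n = len(snp_ids)
    LD = np.eye(n)
    pos = 0
    for blk in ld_blocks:
        k = blk.shape[0]
        LD[pos:pos + k, pos:pos + k] = blk
        pos += k

    gwas_path, weights_path, ld_path = out / "gwas.tsv", out / "weights.tsv", out / "ld.mat"
    write_gwas(gwas.round(8), gwas_path)
    write_weights(weights.round(8), weights_path)
    write_square_matrix(snp_ids, LD, ld_path)

    # per-tissue association table, computed through the single-tissue test
    from .twas_core import align_snps, twas_z
    zvec_all = gwas_z_vector(gwas)
    ld_all = LDMatrix(tuple(snp_ids), LD)
    res_rows = []
    for wv in weight_vectors(weights):
        zv, wv2, ldv = align_snps(zvec_all, wv, ld_all)
        assoc = twas_z(zv, wv2, ldv)
        res_rows.append((assoc.gene, assoc.tissue, assoc.n_snps, assoc.z_t, assoc.p_t))
    results = pd.DataFrame(res_rows, columns=["GENE", "TISSUE", "NSNPS", "TWAS_Z", "TWAS_P"])
    results_path = out / "per_tissue_results.tsv"
    write_results(results, results_path)

    # gene x tissue p-value matrix shaped like a published multi-tissue table,
    # with one row observed in 9 tissues (the C9orf72-like profile)
    t2 = pd.DataFrame(np.nan, index=list(_TISSUES), columns=["GENE_C9LIKE"])
    obs_rows = [2, 3, 4, 5, 6, 7, 9, 10, 11]
    for r, p in zip(obs_rows, C9ORF72_LIKE_P):
        t2.iloc[r, 0] = p
    for g in genes:
        col = results[results["GENE"] == g].set_index("TISSUE")["TWAS_P"]
        t2[g] = col.reindex(t2.index)
    t2_path = out / "table2_like.tsv"
    t2.rename_axis("TISSUE").reset_index().to_csv(
        t2_path, sep="\t", index=False, na_rep="NA", float_format="%.6g")

    scen_dir = out / "scenarios"
    scen_dir.mkdir(exist_ok=True)
    scen_paths = []
    for name, cfg in _default_scenarios(seed).items():
        p = scen_dir / f"{name}.json"
        with open(p, "w") as fh:
            json.dump(cfg, fh, indent=1, sort_keys=True)
            fh.write("\n")
        scen_paths.append(p)

    return FixtureBundle(gwas_path, weights_path, ld_path, results_path,
                         t2_path, tuple(scen_paths))


def _default_scenarios(seed: int) -> dict[str, dict]:
    base_mean = {"kind": "gaussian", "variance": 2.5}
    miss = {"enabled": True, "min": 5, "max": 11}
    scens = {
        "fig2_typeI_independent": {
            "correlation": {"kind": "independent", "T": 13},
            "mean": {"kind": "null"},
            "missingness": {"enabled": False},
            "methods": ["scat", "fisher"],
            "n_reps": 100_000,
            "alpha": [0.01, 0.05],
            "seed": seed,
            "out_prefix": "typeI_independent",
        },
    }
    for rho in (0.0, 0.3, 0.6, 0.9):
        scens[f"power_exchangeable_rho{rho:g}"] = {
            "correlation": {"kind": "exchangeable", "rho": rho, "T": 13},
            "mean": base_mean,
            "missingness": miss,
            "methods": ["scat"],
            "n_reps": 1_000,
            "alpha": 0.05,
            "seed": seed,
            "out_prefix": f"power_exch_rho{rho:g}",
        }
    return scens
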