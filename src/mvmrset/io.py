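"""Readers, writers and fixture generation.

All tabular files are TSV (tab separated, header row, UTF-8, '.' decimal);
missing values are encoded as ``NA`` and rejected in required numeric
fields.  Summary covariances are serialized as three TSV blocks sharing
SNP/gene headers (``<prefix>.EX.tsv``, ``<prefix>.EY.tsv``,
``<prefix>.EE.tsv``) plus a small JSON sidecar with sample sizes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators as est
from . import simulate
from .locus import EQTL_COLUMNS, GWAS_COLUMNS

__all__ = [
    "TableValidationError",
    "read_eqtl",
    "read_gwas",
    "read_ld",
    "write_table",
    "write_ld",
    "write_summary_covariances",
    "read_summary_covariances",
    "write_estimates",
    "generate_fixture",
]

NA = "NA"


class TableValidationError(ValueError):
    """Raised for malformed tabular input."""


_EQTL_NUMERIC = ["pos", "beta", "se", "fdr", "maf"]
_GWAS_NUMERIC = ["pos", "beta", "se", "p", "n"]


def _read_tsv(path, required, numeric, column_map=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        bad = df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise TableValidationError(f"{path}: NA in required column {col!r} (line {row})")
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            conv = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(conv.isna())[0]) + 2
            raise TableValidationError(
                f"{path}: non-numeric value in column {col!r} (line {row})"
            ) from None
    return df


def read_eqtl(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an eQTL summary-statistics TSV into the canonical schema."""
    df = _read_tsv(path, EQTL_COLUMNS, _EQTL_NUMERIC, column_map)
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] <= 0).any():
        raise TableValidationError(f"{path}: positions must be positive (1-based)")
    if ((df["maf"] <= 0) | (df["maf"] >= 0.5)).any():
        raise TableValidationError(f"{path}: MAF must lie in (0, 0.5)")
    dup = df.duplicated(["snp_id", "gene_id", "tissue"])
    if dup.any():
        rows = df.loc[dup, ["snp_id", "gene_id", "tissue"]].iloc[0].tolist()
        raise TableValidationError(f"{path}: duplicate (snp, gene, tissue) row {rows}")
    return df


def read_gwas(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV into the canonical schema."""
    df = _read_tsv(path, GWAS_COLUMNS, _GWAS_NUMERIC, column_map)
    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(int)
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise TableValidationError(f"{path}: GWAS p-values must lie in (0, 1]")
    if (df["n"] <= 0).any():
        raise TableValidationError(f"{path}: sample sizes must be positive")
    if df.duplicated("snp_id").any():
        snp = df.loc[df.duplicated("snp_id"), "snp_id"].iloc[0]
        raise TableValidationError(f"{path}: duplicate GWAS row for SNP {snp!r}")
    return df


def read_ld(path, atol: float = 1e-8) -> pd.DataFrame:
    """Read a square LD (correlation) matrix TSV with a SNP-id header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise TableValidationError(f"{path}: LD row and column SNP ids differ")
    m = df.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=atol):
        raise TableValidationError(f"{path}: LD matrix asymmetric beyond {atol}")
    if not np.allclose(np.diag(m), 1.0, atol=1e-6):
        raise TableValidationError(f"{path}: LD matrix diagonal must be 1")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA)
    return path


def write_ld(ld: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ld.to_csv(path, sep="\t", index=True, na_rep=NA)
    return path


def write_summary_covariances(s: est.SummaryCovariances, prefix) -> list[Path]:
    """Serialize summary covariances as three TSV blocks plus JSON metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ex = pd.DataFrame(s.sigma_EX, index=s.instrument_ids, columns=s.exposure_ids)
    ey = pd.DataFrame({"cov_EY": s.sigma_EY}, index=s.instrument_ids)
    ee = pd.DataFrame(s.sigma_EE, index=s.instrument_ids, columns=s.instrument_ids)
    paths = []
    for tag, frame in (("EX", ex), ("EY", ey), ("EE", ee)):
        p = prefix.with_name(prefix.name + f".{tag}.tsv")
        frame.to_csv(p, sep="\t", index_label="snp_id")
        paths.append(p)
    meta = {"n_exposure": s.n_exposure, "n_outcome": s.n_outcome}
    if s.sigma_XX is not None:
        meta["sigma_XX"] = np.asarray(s.sigma_XX).tolist()
    mp = prefix.with_name(prefix.name + ".meta.json")
    mp.write_text(json.dumps(meta, indent=1))
    paths.append(mp)
    return paths


def read_summary_covariances(prefix) -> est.SummaryCovariances:
    prefix = Path(prefix)
    ex = pd.read_csv(prefix.with_name(prefix.name + ".EX.tsv"), sep="\t", index_col=0)
    ey = pd.read_csv(prefix.with_name(prefix.name + ".EY.tsv"), sep="\t", index_col=0)
    ee = pd.read_csv(prefix.with_name(prefix.name + ".EE.tsv"), sep="\t", index_col=0)
    if list(ex.index) != list(ey.index) or list(ex.index) != list(ee.index):
        raise TableValidationError(f"{prefix}: SNP ids differ across blocks")
    m = ee.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-8):
        raise TableValidationError(f"{prefix}: LD block asymmetric beyond 1e-8")
    meta_path = prefix.with_name(prefix.name + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    sigma_XX = meta.get("sigma_XX")
    return est.SummaryCovariances(
        sigma_EX=ex.to_numpy(dtype=float),
        sigma_EY=ey["cov_EY"].to_numpy(dtype=float),
        sigma_EE=m,
        n_exposure=meta.get("n_exposure"),
        n_outcome=meta.get("n_outcome"),
        instrument_ids=list(ex.index),
        exposure_ids=list(ex.columns),
        sigma_XX=None if sigma_XX is None else np.asarray(sigma_XX, dtype=float),
    )


def write_estimates(res: est.CausalEffectEstimate, path) -> Path:
    """Per-exposure TSV of effects, SEs, p-values and diagnostics."""
    rows = []
    diag = {
        k: v for k, v in res.diagnostics.items()
        if np.isscalar(v) or isinstance(v, (int, float))
    }
    for k, gene in enumerate(res.exposure_ids):
        rows.append(
            {
                "exposure": gene,
                "estimator": res.estimator,
                "effect": res.effects[k],
                "se": None if res.se is None else res.se[k],
                "p": None if res.p is None else res.p[k],
                **diag,
            }
        )
    return write_table(pd.DataFrame(rows), path)


# ---------------------------------------------------------------------------
# fixture generation


DEFAULT_FIXTURE_SPEC = {
    "n_loci": 1,
    "genes_per_locus": 3,
    "instruments_per_locus": 7,
    "tissues": ["LIV"],
    # large enough that a typical causal variant (corr ~ 0.06 with the
    # outcome) clears genome-wide significance at 5e-8; the locus/gene/SNP
    # counts, not the cohort size, are what keep the fixture toy-scale
    "n": 20_000,
    # sign-consistent defaults: with positive instrument effects, opposing
    # gene effects can cancel in the variant-outcome covariance and leave a
    # toy-scale locus without genome-wide-significant SNPs
    "true_effects": [0.3, 0.0, 0.25],
    "eqtl_p_max": 1e-3,
    "chrom": "1",
    "locus_spacing_bp": 10_000_000,
    "snp_spacing_bp": 5_000,
    # "per_gene": each gene has its own causal variant (distinct instrument
    # signatures, robustly identifiable); "shared": all causal variants act
    # on every gene (regulatory pleiotropy at its most collinear)
    "causal_assignment": "per_gene",
}


def _univariate_betas(gz: np.ndarray, trait: np.ndarray):
    """Per-SNP regression slopes of a trait on raw genotype, with SE and p."""
    import scipy.stats

    n, L = gz.shape
    gc = gz - gz.mean(axis=0)
    tc = trait - trait.mean()
    var_g = (gc**2).mean(axis=0)
    beta = gc.T @ tc / (n * var_g)
    resid_var = (tc**2).mean() - beta**2 * var_g
    se = np.sqrt(np.clip(resid_var, 1e-12, None) / ((n - 2) * var_g))
    z = beta / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def generate_fixture(spec: dict | None = None, seed: int = 0, out_dir=".") -> dict:
    """Write a toy eQTL/GWAS/LD fixture with embedded ground truth.

    Each locus is simulated from the structural model (genotypes with
    Markov LD, exposures per tissue, a shared outcome accumulating all
    causal effects), then summarized into eQTL and GWAS tables by
    univariate regressions.  A ``truth.json`` sidecar records the true
    causal effects so pipeline runs can be scored against them.
    """
    cfg = dict(DEFAULT_FIXTURE_SPEC)
    cfg.update(spec or {})
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n = int(cfg["n"])
    K = int(cfg["genes_per_locus"])
    L = int(cfg["instruments_per_locus"])
    tissues = list(cfg["tissues"])
    effects = np.asarray(cfg["true_effects"], dtype=float)
    if effects.shape != (K,):
        raise ValueError("true_effects must have one entry per gene")

    eqtl_rows, gwas_rows = [], []
    ld_blocks, snp_ids = [], []
    outcome = rng.normal(0.0, 1.0, size=n)
    truth = {"seed": seed, "n": n, "loci": []}
    genotypes_all = []
    for locus_i in range(int(cfg["n_loci"])):
        center = (locus_i + 1) * int(cfg["locus_spacing_bp"])
        maf = rng.uniform(0.1, 0.4, size=L)
        succ = np.array(
            [
                rng.uniform(0.3, max(0.3, min(
                    0.7, 0.95 * simulate.feasible_r_bound(maf[i], maf[i + 1]))))
                for i in range(L - 1)
            ]
        )
        g = simulate.markov_genotypes(maf, succ, n, rng)
        gz = (g - g.mean(axis=0)) / g.std(axis=0)
        causal = np.sort(rng.choice(L, size=min(K, L), replace=False))
        A_full = np.zeros((L, K))
        if cfg["causal_assignment"] == "per_gene":
            for k in range(K):
                A_full[causal[k % len(causal)], k] = rng.uniform(0.1, 0.3)
        elif cfg["causal_assignment"] == "shared":
            # determinant floor only where the entry range makes it attainable
            A_full[causal] = simulate.random_instrument_matrix(
                min(K, L), K, (0.1, 0.3),
                det_min=0.05 if K <= 2 else None, seed=rng,
            )
        else:
            raise ValueError("causal_assignment must be 'per_gene' or 'shared'")
        x_tissue = {
            t: gz @ A_full + rng.normal(0.0, 1.0, size=(n, K)) for t in tissues
        }
        outcome = outcome + x_tissue[tissues[0]] @ effects

        ids = [f"rs{locus_i + 1}{j:03d}" for j in range(L)]
        pos = [center + j * int(cfg["snp_spacing_bp"]) for j in range(L)]
        genes = [f"GENE{locus_i + 1}_{k + 1}" for k in range(K)]
        snp_ids.extend(ids)
        genotypes_all.append(g)
        emp_maf = g.mean(axis=0) / 2.0
        emp_maf = np.clip(np.minimum(emp_maf, 1 - emp_maf), 1e-3, 0.499)
        for t in tissues:
            for k, gene in enumerate(genes):
                beta, se, p = _univariate_betas(g.astype(float), x_tissue[t][:, k])
                for j in range(L):
                    if p[j] > float(cfg["eqtl_p_max"]):
                        continue
                    eqtl_rows.append(
                        {
                            "snp_id": ids[j], "chrom": str(cfg["chrom"]),
                            "pos": pos[j], "gene_id": gene, "tissue": t,
                            "beta": beta[j], "se": se[j], "fdr": p[j],
                            "maf": emp_maf[j],
                            "effect_allele": "A", "other_allele": "G",
                        }
                    )
        truth["loci"].append(
            {
                "center": center,
                "snps": ids,
                "genes": genes,
                "true_effects": effects.tolist(),
                "causal_snps": [ids[j] for j in causal],
                "tissue_of_effect": tissues[0],
            }
        )

    for block, ids0 in zip(genotypes_all, truth["loci"]):
        beta, se, p = _univariate_betas(block.astype(float), outcome)
        emp_maf = block.mean(axis=0) / 2.0
        for j, sid in enumerate(ids0["snps"]):
            gwas_rows.append(
                {
                    "snp_id": sid, "chrom": str(cfg["chrom"]),
                    "pos": ids0["center"] + j * int(cfg["snp_spacing_bp"]),
                    "beta": beta[j], "se": se[j], "p": p[j], "n": n,
                    "effect_allele": "A", "other_allele": "G",
                }
            )

    all_g = np.concatenate(genotypes_all, axis=1).astype(float)
    ld = pd.DataFrame(np.corrcoef(all_g, rowvar=False), index=snp_ids, columns=snp_ids)

    paths = {
        "eqtl": write_table(pd.DataFrame(eqtl_rows), out_dir / "eqtl.tsv"),
        "gwas": write_table(pd.DataFrame(gwas_rows), out_dir / "gwas.tsv"),
        "ld": write_ld(ld, out_dir / "ld.tsv"),
    }
    tp = out_dir / "truth.json"
    tp.write_text(json.dumps(truth, indent=1))
    paths["truth"] = tp
    return paths
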