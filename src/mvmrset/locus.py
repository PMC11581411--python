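"""Locus construction and causal-gene prediction from summary statistics.

Builds closed causal diagrams at GWAS loci with regulatory pleiotropy: a
lead SNP is chosen greedily by GWAS p-value among eQTL variants, all eQTLs
within a window and in LD with it join the locus, nearly identical variants
are pruned, and the exposure set is closed under shared cis-eQTL
associations.  Each locus then yields one MVMR model per tissue (or one
model over gene-tissue pairs), estimated from summary covariances, and
genes are called causal by a combined absolute-effect and Bonferroni
p-value rule.

Tabular inputs are pandas DataFrames with canonical columns (see
``EQTL_COLUMNS`` / ``GWAS_COLUMNS``); readers in :mod:`mvmrset.io` produce
them from TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from . import inference

__all__ = [
    "EQTL_COLUMNS",
    "GWAS_COLUMNS",
    "LocusModel",
    "GenePrediction",
    "build_loci",
    "prune_instruments",
    "close_exposure_set",
    "run_locus_mvmr",
    "classify_causal",
    "harmonize_alleles",
]

EQTL_COLUMNS = ["snp_id", "chrom", "pos", "gene_id", "tissue", "beta", "se", "fdr", "maf"]
GWAS_COLUMNS = [
    "snp_id", "chrom", "pos", "beta", "se", "p", "n", "effect_allele", "other_allele",
]

_AMBIGUOUS = {frozenset("AT"), frozenset("CG")}

DEFAULT_GWAS_P = 5e-8
DEFAULT_RADIUS_BP = 500_000
DEFAULT_LD_FLOOR = 0.01
DEFAULT_R2_PRUNE = 0.95


class MissingLdError(ValueError):
    """Raised when required SNP pairs are absent from the LD matrix."""


@dataclass
class LocusModel:
    """A closed causal diagram at one GWAS locus."""

    locus_id: str
    lead_snp: str
    snps: list[str]
    ld: pd.DataFrame
    eqtl: pd.DataFrame
    gwas: pd.DataFrame
    window_bp: int
    notes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return sorted(self.eqtl["gene_id"].unique())

    @property
    def tissues(self) -> list[str]:
        return sorted(self.eqtl["tissue"].unique())


@dataclass
class GenePrediction:
    """Per-exposure causal-effect prediction at a locus."""

    gene: str
    tissue: str
    effect: float
    se: float | None
    p: float | None
    causal_call: bool
    locus_id: str
    estimator: str = "LS"
    diagnostics: dict = field(default_factory=dict)


def _check_frames(gwas: pd.DataFrame, eqtl: pd.DataFrame) -> None:
    missing = [c for c in GWAS_COLUMNS if c not in gwas.columns]
    if missing:
        raise ValueError(f"GWAS table lacks columns: {missing}")
    missing = [c for c in EQTL_COLUMNS if c not in eqtl.columns]
    if missing:
        raise ValueError(f"eQTL table lacks columns: {missing}")


def build_loci(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    ld: pd.DataFrame,
    gwas_p_thresh: float = DEFAULT_GWAS_P,
    radius_bp: int = DEFAULT_RADIUS_BP,
    ld_floor: float = DEFAULT_LD_FLOOR,
) -> list[LocusModel]:
    """Greedy locus construction from genome-wide significant eQTL variants.

    eQTL variants are filtered by GWAS p-value, sorted, and consumed
    greedily: each lead SNP collects every remaining eQTL variant on the
    same chromosome within ``radius_bp`` whose LD with the lead exceeds
    ``ld_floor`` in absolute value.  The resulting loci are disjoint in
    SNPs.
    """
    _check_frames(gwas, eqtl)
    eqtl_snps = set(eqtl["snp_id"])
    g = gwas.drop_duplicates("snp_id").set_index("snp_id")
    shared = [s for s in eqtl_snps if s in g.index]
    missing_ld = sorted(s for s in shared if s not in ld.index)
    if missing_ld:
        raise MissingLdError(f"SNPs absent from the LD matrix: {missing_ld}")

    sig = [s for s in shared if g.loc[s, "p"] < gwas_p_thresh]
    sig.sort(key=lambda s: (g.loc[s, "p"], g.loc[s, "pos"], s))
    pool = set(shared)
    loci: list[LocusModel] = []
    while sig:
        lead = sig[0]
        lead_chrom, lead_pos = g.loc[lead, "chrom"], g.loc[lead, "pos"]
        members = {lead}
        for s in pool:
            if s == lead or g.loc[s, "chrom"] != lead_chrom:
                continue
            if abs(int(g.loc[s, "pos"]) - int(lead_pos)) > radius_bp:
                continue
            if abs(float(ld.loc[lead, s])) >= ld_floor:
                members.add(s)
        snps = sorted(members, key=lambda s: int(g.loc[s, "pos"]))
        locus = LocusModel(
            locus_id=f"{lead_chrom}:{int(lead_pos)}",
            lead_snp=lead,
            snps=snps,
            ld=ld.loc[snps, snps].copy(),
            eqtl=eqtl[eqtl["snp_id"].isin(members)].copy(),
            gwas=gwas[gwas["snp_id"].isin(members)].copy(),
            window_bp=radius_bp,
        )
        loci.append(locus)
        pool -= members
        sig = [s for s in sig if s not in members]
    return loci


def prune_instruments(locus: LocusModel, r2_max: float = DEFAULT_R2_PRUNE) -> LocusModel:
    """Remove one SNP from every pair with LD ``r^2 >= r2_max``.

    From each clashing pair the SNP with the larger GWAS p-value is dropped
    (ties broken by larger position), so the lead SNP is always retained.
    Returns a new locus; the original is unmodified.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must lie in (0, 1]")
    g = locus.gwas.drop_duplicates("snp_id").set_index("snp_id")

    def priority(s):  # smaller is better
        return (float(g.loc[s, "p"]) if s in g.index else np.inf,
                int(g.loc[s, "pos"]) if s in g.index else np.inf, s)

    keep = sorted(locus.snps, key=priority)
    retained: list[str] = []
    for s in keep:
        if all(float(locus.ld.loc[s, t]) ** 2 < r2_max for t in retained):
            retained.append(s)
    snps = [s for s in locus.snps if s in set(retained)]
    out = LocusModel(
        locus_id=locus.locus_id,
        lead_snp=locus.lead_snp,
        snps=snps,
        ld=locus.ld.loc[snps, snps].copy(),
        eqtl=locus.eqtl[locus.eqtl["snp_id"].isin(snps)].copy(),
        gwas=locus.gwas[locus.gwas["snp_id"].isin(snps)].copy(),
        window_bp=locus.window_bp,
        notes=list(locus.notes),
    )
    n_genes = len(out.genes)
    if len(snps) < n_genes:
        out.notes.append(
            f"pruning left {len(snps)} instruments for {n_genes} genes; "
            "the locus is under-determined"
        )
    return out


def close_exposure_set(
    locus: LocusModel,
    eqtl: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    gwas: pd.DataFrame | None = None,
) -> LocusModel:
    """Fixed-point closure of the locus gene and instrument sets.

    Alternately adds genes with a cis-eQTL association to any instrument in
    the locus, and instruments (within the window, with LD information)
    associated with any included gene, until nothing changes.  Closure is
    idempotent.
    """
    g_all = (gwas if gwas is not None else locus.gwas).drop_duplicates(
        "snp_id").set_index("snp_id")
    lead_pos = int(g_all.loc[locus.lead_snp, "pos"])
    lead_chrom = g_all.loc[locus.lead_snp, "chrom"]
    ld_full = ld if ld is not None else locus.ld

    in_window = eqtl[
        (eqtl["chrom"] == lead_chrom)
        & ((eqtl["pos"] - lead_pos).abs() <= locus.window_bp)
        & eqtl["snp_id"].isin(ld_full.index)
    ]
    snps = set(locus.snps)
    genes = set(in_window[in_window["snp_id"].isin(snps)]["gene_id"])
    while True:
        new_snps = set(in_window[in_window["gene_id"].isin(genes)]["snp_id"])
        new_genes = set(in_window[in_window["snp_id"].isin(snps | new_snps)]["gene_id"])
        if new_snps <= snps and new_genes <= genes:
            break
        snps |= new_snps
        genes |= new_genes

    usable = [s for s in snps if s in g_all.index]
    dropped = sorted(snps - set(usable))
    snp_order = sorted(usable, key=lambda s: int(g_all.loc[s, "pos"]))
    out = LocusModel(
        locus_id=locus.locus_id,
        lead_snp=locus.lead_snp,
        snps=snp_order,
        ld=ld_full.loc[snp_order, snp_order].copy(),
        eqtl=in_window[
            in_window["snp_id"].isin(snp_order) & in_window["gene_id"].isin(genes)
        ].copy(),
        gwas=(gwas if gwas is not None else locus.gwas),
        window_bp=locus.window_bp,
        notes=list(locus.notes),
    )
    out.gwas = out.gwas[out.gwas["snp_id"].isin(snp_order)].copy()
    if dropped:
        out.notes.append(f"instruments without GWAS records dropped: {dropped}")
    return out


def harmonize_alleles(eqtl: pd.DataFrame, gwas: pd.DataFrame):
    """Align GWAS effect alleles to the eQTL orientation.

    Returns ``(gwas_aligned, dropped_snps)``.  When both tables carry allele
    columns, a swapped effect/other pair flips the GWAS beta sign;
    strand-ambiguous pairs (A/T, C/G) and irreconcilable pairs are dropped.
    Without eQTL allele columns, records are assumed aligned.
    """
    if "effect_allele" not in eqtl.columns:
        return gwas.copy(), []
    e = eqtl.drop_duplicates("snp_id").set_index("snp_id")
    out = gwas.copy()
    drop: list[str] = []
    flip: list[str] = []
    for snp, row in out.drop_duplicates("snp_id").set_index("snp_id").iterrows():
        if snp not in e.index:
            continue
        ea_e, oa_e = e.loc[snp, "effect_allele"], e.loc[snp, "other_allele"]
        ea_g, oa_g = row["effect_allele"], row["other_allele"]
        if frozenset((ea_g, oa_g)) in _AMBIGUOUS:
            drop.append(snp)
        elif (ea_e, oa_e) == (ea_g, oa_g):
            continue
        elif (ea_e, oa_e) == (oa_g, ea_g):
            flip.append(snp)
        else:
            drop.append(snp)
    if flip:
        m = out["snp_id"].isin(flip)
        out.loc[m, "beta"] = -out.loc[m, "beta"]
        out.loc[m, ["effect_allele", "other_allele"]] = out.loc[
            m, ["other_allele", "effect_allele"]
        ].values
    if drop:
        out = out[~out["snp_id"].isin(drop)]
    return out, sorted(drop)


def _exposure_labels(locus: LocusModel, mode: str):
    """(label, gene, tissue) exposure triples for the requested mode."""
    if mode == "per_tissue":
        return {
            t: [(gene, gene, t) for gene in sorted(
                locus.eqtl[locus.eqtl["tissue"] == t]["gene_id"].unique())]
            for t in locus.tissues
        }
    if mode == "gene_tissue_pairs":
        pairs = sorted(
            {(r.gene_id, r.tissue) for r in locus.eqtl.itertuples()}
        )
        return {"all": [(f"{g}@{t}", g, t) for g, t in pairs]}
    raise ValueError("mode must be 'per_tissue' or 'gene_tissue_pairs'")


def _locus_summary(locus, gwas_aligned, triples, snps):
    """Assemble SummaryCovariances for one tissue model at a locus."""
    eqtl = locus.eqtl
    g = gwas_aligned.drop_duplicates("snp_id").set_index("snp_id")
    snps = [s for s in snps if s in g.index]
    L, K = len(snps), len(triples)
    maf = {}
    for r in eqtl.itertuples():
        maf.setdefault(r.snp_id, float(r.maf))
    snp_sd = np.array([np.sqrt(2 * maf[s] * (1 - maf[s])) for s in snps])
    B = np.zeros((L, K))
    for k, (_, gene, tissue) in enumerate(triples):
        sub = eqtl[(eqtl["gene_id"] == gene) & (eqtl["tissue"] == tissue)]
        betas = dict(zip(sub["snp_id"], sub["beta"]))
        for l, s in enumerate(snps):
            # absent association = zero effect after the FDR filter
            B[l, k] = betas.get(s, 0.0) * snp_sd[l]
    ey = np.array([float(g.loc[s, "beta"]) for s in snps]) * snp_sd
    n_out = int(np.median([int(g.loc[s, "n"]) for s in snps]))
    return est.SummaryCovariances(
        sigma_EX=B,
        sigma_EY=ey,
        sigma_EE=locus.ld.loc[snps, snps].to_numpy(),
        n_outcome=n_out,
        instrument_ids=snps,
        exposure_ids=[t[0] for t in triples],
    ), n_out


def run_locus_mvmr(
    locus: LocusModel,
    mode: str = "per_tissue",
    estimator: str = "LS",
) -> list[GenePrediction]:
    """Estimate direct causal effects for every exposure model at a locus.

    One model per tissue (``per_tissue``) or a single model over gene-tissue
    pairs.  For a single exposure the estimate coincides with the classical
    instrumental-variable ratio.  Models with fewer instruments than
    exposures are flagged in ``locus.notes`` and produce no estimates.
    """
    if estimator not in ("LS", "GMM"):
        raise ValueError("estimator must be 'LS' or 'GMM'")
    gwas_aligned, dropped = harmonize_alleles(locus.eqtl, locus.gwas)
    if dropped:
        locus.notes.append(f"allele harmonization dropped SNPs: {dropped}")
    preds: list[GenePrediction] = []
    for model_tag, triples in _exposure_labels(locus, mode).items():
        if not triples:
            continue
        snps = [
            s for s in locus.snps
            if s in set(gwas_aligned["snp_id"])
        ]
        if len(snps) < len(triples):
            locus.notes.append(
                f"model {model_tag!r}: {len(snps)} instruments < "
                f"{len(triples)} exposures; effects not identifiable"
            )
            continue
        s, n_out = _locus_summary(locus, gwas_aligned, triples, snps)
        diag = inference.determinacy_check(s, n=n_out)
        if "under_determined" in diag.flags:
            locus.notes.append(
                f"model {model_tag!r}: instrument-exposure covariance is rank "
                "deficient; effects not identifiable"
            )
            continue
        fn = est.ls_estimate if estimator == "LS" else est.gmm_estimate
        try:
            res = fn(s)
        except Exception as exc:  # rank/conditioning failures become notes
            locus.notes.append(f"model {model_tag!r}: estimation failed ({exc})")
            continue
        for k, (_, gene, tissue) in enumerate(triples):
            preds.append(
                GenePrediction(
                    gene=gene,
                    tissue=tissue,
                    effect=float(res.effects[k]),
                    se=None if res.se is None else float(res.se[k]),
                    p=None if res.p is None else float(res.p[k]),
                    causal_call=False,
                    locus_id=locus.locus_id,
                    estimator=estimator,
                    diagnostics=diag.to_dict(),
                )
            )
    return preds


def classify_causal(
    preds: list[GenePrediction],
    effect_thresh: float = 0.1,
    alpha: float = 0.05,
    m_tests: int | None = None,
) -> list[GenePrediction]:
    """Set ``causal_call`` on each prediction.

    A gene-tissue combination is called causal when its absolute effect
    reaches ``effect_thresh`` and (when a p-value is available) its p-value
    passes the Bonferroni threshold ``alpha / m_tests``; ``m_tests``
    defaults to the number of predictions in this run.
    """
    if effect_thresh <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    m = m_tests if m_tests is not None else max(len(preds), 1)
    cut = inference.bonferroni_threshold(alpha, m)
    for pr in preds:
        ok_effect = abs(pr.effect) >= effect_thresh
        ok_p = True if pr.p is None else pr.p < cut
        pr.causal_call = bool(ok_effect and ok_p)
    return preds


def predictions_frame(preds: list[GenePrediction]) -> pd.DataFrame:
    """Predictions as a tidy DataFrame (one row per gene-tissue model)."""
    return pd.DataFrame(
        [
            {
                "locus_id": p.locus_id,
                "gene": p.gene,
                "tissue": p.tissue,
                "estimator": p.estimator,
                "effect": p.effect,
                "se": p.se,
                "p": p.p,
                "causal_call": p.causal_call,
            }
            for p in preds
        ]
    )
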