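"""Locus construction, pruning, closure, MVMR models, causal calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mvmrset import estimators as est, io, locus as loc, simulate as sim


def _gwas_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "beta", "se", "p", "n",
                 "effect_allele", "other_allele"],
    )


def _eqtl_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "gene_id", "tissue", "beta", "se",
                 "fdr", "maf"],
    )


def _ld_frame(snps, mat):
    return pd.DataFrame(np.asarray(mat, dtype=float), index=snps, columns=snps)


def _toy_inputs(link_second=False):
    """Six SNPs; two pass genome-wide significance."""
    snps = [f"rs{i}" for i in range(6)]
    pos = [100_000, 150_000, 200_000, 2_000_000, 2_050_000, 9_000_000]
    p = [1e-10, 1e-3, 0.5, 1e-9, 0.02, 0.8]
    gwas = _gwas_frame(
        [(s, "1", pp, 0.1, 0.02, pv, 50_000, "A", "G")
         for s, pp, pv in zip(snps, pos, p)]
    )
    m = np.eye(6)
    pairs = {(0, 1): 0.8, (1, 2): 0.5, (0, 2): 0.4, (3, 4): 0.7}
    if link_second:
        # second significant SNP sits in LD with (and near) the lead
        gwas.loc[3, "pos"] = 250_000
        gwas.loc[4, "pos"] = 300_000
        pairs[(0, 3)] = 0.6
        pairs[(3, 4)] = 0.7
    for (i, j), v in pairs.items():
        m[i, j] = m[j, i] = v
    ld = _ld_frame(snps, m)
    eqtl = _eqtl_frame(
        [(s, "1", pp, f"G{i // 2}", "LIV", 0.3, 0.05, 1e-4, 0.25)
         for i, (s, pp) in enumerate(zip(snps, gwas["pos"]))]
    )
    return gwas, eqtl, ld


class TestBuildLoci:
    def test_two_separated_leads_make_two_loci(self):
        gwas, eqtl, ld = _toy_inputs()
        loci = loc.build_loci(gwas, eqtl, ld)
        assert len(loci) == 2
        assert loci[0].lead_snp == "rs0"
        assert set(loci[0].snps) == {"rs0", "rs1", "rs2"}
        assert loci[1].lead_snp == "rs3"
        assert set(loci[1].snps) == {"rs3", "rs4"}

    def test_linked_second_hit_joins_the_lead_locus(self):
        gwas, eqtl, ld = _toy_inputs(link_second=True)
        loci = loc.build_loci(gwas, eqtl, ld)
        # rs3 is absorbed by the lead's locus; rs4 (linked only to rs3, not
        # to the lead) is never collected and forms no locus of its own
        assert len(loci) == 1
        assert set(loci[0].snps) == {"rs0", "rs1", "rs2", "rs3"}

    def test_loci_partition_the_snp_set(self):
        gwas, eqtl, ld = _toy_inputs()
        loci = loc.build_loci(gwas, eqtl, ld)
        seen = list(itertools.chain.from_iterable(l.snps for l in loci))
        assert len(seen) == len(set(seen))

    def test_no_significant_snp_gives_empty_list(self):
        gwas, eqtl, ld = _toy_inputs()
        gwas["p"] = 0.5
        assert loc.build_loci(gwas, eqtl, ld) == []

    def test_missing_ld_entries_reported(self):
        gwas, eqtl, ld = _toy_inputs()
        with pytest.raises(loc.MissingLdError, match="rs5"):
            loc.build_loci(gwas, eqtl, ld.drop(index="rs5", columns="rs5"))


class TestPruneInstruments:
    def _locus(self, snps, mat, pvals):
        gwas = _gwas_frame(
            [(s, "1", 100 + i, 0.1, 0.02, pv, 1000, "A", "G")
             for i, (s, pv) in enumerate(zip(snps, pvals))]
        )
        eqtl = _eqtl_frame(
            [(s, "1", 100 + i, "G1", "LIV", 0.3, 0.05, 1e-4, 0.25)
             for i, s in enumerate(snps)]
        )
        return loc.LocusModel(
            locus_id="1:100", lead_snp=snps[int(np.argmin(pvals))], snps=snps,
            ld=_ld_frame(snps, mat), eqtl=eqtl, gwas=gwas, window_bp=500_000,
        )

    def test_perfect_ld_pair_keeps_the_smaller_p(self):
        locus = self._locus(["a", "b"], [[1, 1], [1, 1]], [1e-8, 1e-4])
        out = loc.prune_instruments(locus, 0.95)
        assert out.snps == ["a"]

    def test_below_threshold_is_a_no_op(self):
        locus = self._locus(["a", "b"], [[1, 0.5], [0.5, 1]], [1e-8, 1e-4])
        assert loc.prune_instruments(locus, 0.95).snps == ["a", "b"]

    @pytest.mark.parametrize("seed", range(8))
    def test_chained_duplicates_match_exhaustive_max_retention(self, seed):
        """Greedy pruning retains a maximum-size admissible subset."""
        rng = np.random.default_rng(seed)
        L = 7
        base = rng.uniform(-1, 1, size=(L, 3))
        m = np.corrcoef(base @ base.T + np.eye(L) * 0.05)
        # inject chained near-duplicates
        for i in (1, 2):
            m[i] = m[0] * 0.999 + rng.normal(0, 0.0005, L)
            m[:, i] = m[i]
            m[i, i] = 1.0
        m = (m + m.T) / 2
        snps = [f"s{i}" for i in range(L)]
        pvals = rng.uniform(1e-9, 1e-3, L)
        locus = self._locus(snps, m, pvals)
        got = loc.prune_instruments(locus, 0.95)

        def admissible(subset):
            return all(
                m[i, j] ** 2 < 0.95
                for i, j in itertools.combinations(subset, 2)
            )

        best = max(
            (s for r in range(L + 1) for s in
             itertools.combinations(range(L), r) if admissible(s)),
            key=len,
        )
        assert len(got.snps) == len(best)

    def test_pruning_below_gene_count_warns_in_notes(self):
        locus = self._locus(["a", "b"], [[1, 1], [1, 1]], [1e-8, 1e-4])
        locus.eqtl = _eqtl_frame(
            [("a", "1", 100, g, "LIV", 0.3, 0.05, 1e-4, 0.25)
             for g in ("G1", "G2")]
        )
        out = loc.prune_instruments(locus, 0.95)
        assert any("under-determined" in n for n in out.notes)


class TestCloseExposureSet:
    def _inputs(self):
        snps = ["s1", "s2", "s3"]
        gwas = _gwas_frame(
            [(s, "1", 100_000 + i * 1000, 0.1, 0.02, 1e-9, 1000, "A", "G")
             for i, s in enumerate(snps)]
        )
        # A-s1, B-s1, B-s2, C-s2 plus an unrelated gene D-s3 far away
        eqtl = _eqtl_frame(
            [
                ("s1", "1", 100_000, "A", "LIV", 0.3, 0.05, 1e-4, 0.25),
                ("s1", "1", 100_000, "B", "LIV", 0.2, 0.05, 1e-4, 0.25),
                ("s2", "1", 101_000, "B", "LIV", 0.25, 0.05, 1e-4, 0.3),
                ("s2", "1", 101_000, "C", "LIV", 0.15, 0.05, 1e-4, 0.3),
            ]
        )
        ld = _ld_frame(snps, np.eye(3) * 0.5 + 0.5)
        locus = loc.LocusModel(
            locus_id="1:100000", lead_snp="s1", snps=["s1"],
            ld=ld.loc[["s1"], ["s1"]], eqtl=eqtl[eqtl.snp_id == "s1"],
            gwas=gwas, window_bp=500_000,
        )
        return locus, eqtl, ld, gwas

    def test_transitive_closure_collects_shared_genes(self):
        locus, eqtl, ld, gwas = self._inputs()
        out = loc.close_exposure_set(locus, eqtl, ld=ld, gwas=gwas)
        assert set(out.genes) == {"A", "B", "C"}
        assert set(out.snps) == {"s1", "s2"}

    def test_closure_is_idempotent(self):
        locus, eqtl, ld, gwas = self._inputs()
        once = loc.close_exposure_set(locus, eqtl, ld=ld, gwas=gwas)
        twice = loc.close_exposure_set(once, eqtl, ld=ld, gwas=gwas)
        assert once.snps == twice.snps
        assert once.genes == twice.genes

    def test_isolated_gene_snp_pair_unchanged(self):
        locus, eqtl, ld, gwas = self._inputs()
        solo = eqtl[eqtl.gene_id == "A"]
        out = loc.close_exposure_set(locus, solo, ld=ld, gwas=gwas)
        assert out.snps == ["s1"] and out.genes == ["A"]


class TestHarmonization:
    def test_swapped_alleles_flip_beta(self):
        eqtl = _eqtl_frame(
            [("s1", "1", 1, "A", "LIV", 0.3, 0.05, 1e-4, 0.25)]
        ).assign(effect_allele="A", other_allele="G")
        gwas = _gwas_frame([("s1", "1", 1, 0.1, 0.02, 1e-9, 1000, "G", "A")])
        out, dropped = loc.harmonize_alleles(eqtl, gwas)
        assert dropped == []
        assert out["beta"].iloc[0] == pytest.approx(-0.1)

    def test_ambiguous_and_mismatched_dropped(self):
        eqtl = _eqtl_frame(
            [("s1", "1", 1, "A", "LIV", 0.3, 0.05, 1e-4, 0.25),
             ("s2", "1", 2, "A", "LIV", 0.3, 0.05, 1e-4, 0.25)]
        ).assign(effect_allele=["A", "A"], other_allele=["T", "G"])
        gwas = _gwas_frame(
            [("s1", "1", 1, 0.1, 0.02, 1e-9, 1000, "A", "T"),
             ("s2", "1", 2, 0.1, 0.02, 1e-9, 1000, "A", "C")]
        )
        out, dropped = loc.harmonize_alleles(eqtl, gwas)
        assert dropped == ["s1", "s2"]
        assert out.empty


class TestRunLocusMvmr:
    def _synthetic_locus(self, seed=0, n=20_000, effects=(0.3, 0.0, 0.25)):
        paths = io.generate_fixture(
            {"n": n, "true_effects": list(effects),
             "genes_per_locus": len(effects)}, seed=seed,
            out_dir=f"scratch/locus_fixture_{seed}",
        )
        eqtl = io.read_eqtl(paths["eqtl"])
        gwas = io.read_gwas(paths["gwas"])
        ld = io.read_ld(paths["ld"])
        loci = loc.build_loci(gwas, eqtl, ld)
        assert len(loci) == 1
        closed = loc.close_exposure_set(loci[0], eqtl, ld=ld, gwas=gwas)
        return loc.prune_instruments(closed), effects

    def test_single_exposure_model_reduces_to_ratio(self):
        locus, _ = self._synthetic_locus(seed=1, effects=(0.25,),)
        preds = loc.run_locus_mvmr(locus, estimator="LS")
        gene_preds = {p.gene: p for p in preds}
        assert len(gene_preds) == 1
        (p,) = gene_preds.values()
        s, _ = loc._locus_summary(
            locus, locus.gwas, [(p.gene, p.gene, p.tissue)], locus.snps
        )
        if s.n_instruments == 1:
            expected = est.univariate_ratio(s.sigma_EY[0], s.sigma_EX[0, 0])
            assert p.effect == pytest.approx(expected)
        assert abs(p.effect - 0.25) < 0.1

    def test_recovers_embedded_truth(self):
        locus, effects = self._synthetic_locus(seed=2)
        preds = loc.run_locus_mvmr(locus, estimator="GMM")
        got = {p.gene: p.effect for p in preds}
        for gene, true in zip(sorted(got), effects):
            assert got[gene] == pytest.approx(true, abs=0.08)

    def test_causal_calls_separate_null_and_causal_genes(self):
        locus, effects = self._synthetic_locus(seed=3)
        preds = loc.run_locus_mvmr(locus, estimator="LS")
        loc.classify_causal(preds, effect_thresh=0.1)
        calls = {p.gene: p.causal_call for p in preds}
        genes = sorted(calls)
        assert calls[genes[0]] is True      # true effect 0.3
        assert calls[genes[1]] is False     # true effect 0
        assert calls[genes[2]] is True      # true effect 0.25

    def test_underdetermined_locus_yields_no_estimates(self):
        locus, _ = self._synthetic_locus(seed=4)
        # collapse to a single instrument while keeping three genes
        locus.snps = locus.snps[:1]
        locus.ld = locus.ld.iloc[:1, :1]
        preds = loc.run_locus_mvmr(locus)
        assert preds == []
        assert any("not identifiable" in n for n in locus.notes)


class TestClassifyCausal:
    def _pred(self, effect, p=1e-9):
        return loc.GenePrediction(
            gene="G", tissue="LIV", effect=effect, se=0.01, p=p,
            causal_call=False, locus_id="1:1",
        )

    def test_effect_just_below_threshold_not_called(self):
        (p,) = loc.classify_causal([self._pred(0.099)], effect_thresh=0.1,
                                   m_tests=150)
        assert p.causal_call is False

    def test_negative_effect_called_by_absolute_value(self):
        (p,) = loc.classify_causal([self._pred(-0.27)], effect_thresh=0.1,
                                   m_tests=150)
        assert p.causal_call is True

    def test_unit_pvalues_block_all_calls(self):
        preds = [self._pred(0.5, p=1.0), self._pred(-0.9, p=1.0)]
        assert not any(p.causal_call for p in loc.classify_causal(preds))
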