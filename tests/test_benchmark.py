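import numpy as np
import pandas as pd
import pytest

import cgiscreen as cg
from cgiscreen.benchmark import (
    EssentialStandardConfig,
    define_essential_standard,
    essential_guide_support,
    gold_standard_hits,
    hit_overlap_test,
    library_hit_rate,
    random_subset_null,
    select_top_guides,
    snr_report,
    subset_rescore,
)
from cgiscreen.io import LibraryDefinition, ValidationError
from cgiscreen.scoring import bh_adjust

from _oracles import bh_bruteforce


class TestSNR:
    def test_formula_on_constructed_vector(self):
        # hand-constructed screen: expected sigma computed by independent
        # percentile slicing in the test, mu = mean |CGI| over gold genes
        rng = np.random.default_rng(0)
        values = np.round(rng.normal(0, 0.3, 100), 6)
        genes = [f"G{i}" for i in range(100)]
        cgi = pd.Series(values, index=genes)
        gold = {genes[int(np.argmax(values))], genes[int(np.argmin(values))]}
        row = snr_report(cgi, gold)
        q10, q90 = np.percentile(values, [10, 90])
        background = values[(values >= q10) & (values <= q90)]
        expected_sigma = background.std(ddof=1)
        expected_mu = np.mean([abs(values.max()), abs(values.min())])
        assert row.sigma == pytest.approx(expected_sigma, rel=1e-12)
        assert row.mu == pytest.approx(expected_mu, rel=1e-12)
        assert row.snr == pytest.approx(expected_mu / expected_sigma, rel=1e-12)

    def test_gold_magnitudes_one_and_two_with_background_half(self):
        # mu = mean(|1|, |2|) = 1.5; snr = 1.5 / sigma
        rng = np.random.default_rng(1)
        values = rng.normal(0, 0.2, 200)
        genes = [f"G{i}" for i in range(200)] + ["GOLD_NEG", "GOLD_POS"]
        cgi = pd.Series(np.concatenate([values, [-1.0, 2.0]]), index=genes)
        row = snr_report(cgi, {"GOLD_NEG", "GOLD_POS"})
        assert row.mu == pytest.approx(1.5)
        assert row.snr == pytest.approx(1.5 / row.sigma)

    def test_scale_covariance(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(150)]
        cgi = pd.Series(rng.normal(0, 1, 150), index=genes)
        gold = set(genes[:5])
        a = snr_report(cgi, gold)
        b = snr_report(cgi * 3.0, gold)
        assert a.snr == pytest.approx(b.snr, rel=1e-9)

    def test_background_band_for_1011_genes(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(1011)]
        cgi = pd.Series(rng.normal(size=1011), index=genes)
        row = snr_report(cgi, {genes[0]})
        assert row.background_size in (809, 810)

    def test_empty_gold_rejected(self):
        cgi = pd.Series(np.arange(30.0), index=[f"G{i}" for i in range(30)])
        with pytest.raises(ValidationError, match="gold"):
            snr_report(cgi, {"ABSENT"})


class TestGoldStandard:
    def _table(self, hits, timepoints=None):
        rows = []
        for gene, sign in hits.items():
            rows.append({"gene": gene, "hit": sign,
                         **({"timepoint": timepoints[gene]} if timepoints else {})})
        rows.append({"gene": "NULLGENE", "hit": 0,
                     **({"timepoint": 6} if timepoints else {})})
        return pd.DataFrame(rows)

    def test_identical_tables(self):
        hits = {"A": -1, "B": 1, "C": -1}
        gold = gold_standard_hits(self._table(hits), self._table(hits))
        assert gold == set(hits)

    def test_opposite_signs_excluded(self):
        a = self._table({"A": -1, "B": 1})
        b = self._table({"A": 1, "B": -1})
        with pytest.warns(UserWarning, match="empty"):
            assert gold_standard_hits(a, b) == set()

    def test_disjoint_hits_empty(self):
        with pytest.warns(UserWarning):
            assert gold_standard_hits(self._table({"A": -1}), self._table({"B": -1})) == set()

    def test_union_across_timepoints(self):
        scal = pd.DataFrame(
            {"gene": ["A", "A", "B"], "hit": [0, -1, 1], "timepoint": [6, 12, 6]}
        )
        gw = pd.DataFrame({"gene": ["A", "B"], "hit": [-1, 1]})
        assert gold_standard_hits(scal, gw) == {"A", "B"}


class TestHitRate:
    def _table(self, n_hits, n_genes=1011, timepoint=12):
        genes = [f"G{i}" for i in range(n_genes)]
        hit = [-1] * n_hits + [0] * (n_genes - n_hits)
        return pd.DataFrame(
            {"gene": genes, "hit": hit, "compound": "HU", "timepoint": timepoint}
        )

    def test_average_hit_rate_value(self):
        table = self._table(143)
        out = library_hit_rate(table, 1011)
        rate = out.loc[out["timepoint"] == 12, "hit_rate"].iloc[0]
        assert rate == pytest.approx(143 / 1011)
        assert rate == pytest.approx(0.141, abs=5e-4)

    def test_zero_hits(self):
        out = library_hit_rate(self._table(0), 1011)
        assert (out["hit_rate"] == 0).all()

    def test_union_counts_gene_once(self):
        t1 = self._table(5, n_genes=20, timepoint=6)
        t2 = self._table(5, n_genes=20, timepoint=12)
        out = library_hit_rate(pd.concat([t1, t2]), 20)
        union = out[out["timepoint"] == "union"]
        assert union["n_hits"].iloc[0] == 5  # same genes hit at both timepoints


class TestSubsetRescore:
    def _table(self, p_values, cgi=None):
        genes = [f"G{i}" for i in range(len(p_values))]
        return pd.DataFrame(
            {
                "gene": genes,
                "cgi": cgi if cgi is not None else [-1.0] * len(p_values),
                "p": p_values,
            }
        )

    def test_full_subset_equals_full_bh(self):
        rng = np.random.default_rng(4)
        table = self._table(rng.uniform(0, 1, 50))
        out = subset_rescore(table, set(table["gene"]))
        assert np.allclose(out["fdr"], bh_adjust(table["p"].to_numpy()))

    def test_hand_computed_ten_gene_toy(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        table = self._table(p)
        out = subset_rescore(table, set(table["gene"]))
        assert np.allclose(out["fdr"], bh_bruteforce(np.array(p)), atol=1e-12)

    def test_restriction_gives_milder_correction(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.uniform(0, 0.01, 10), rng.uniform(0.2, 1, 90)])
        table = self._table(p)
        full = subset_rescore(table, set(table["gene"]))
        strong = set(table["gene"][:10])
        sub = subset_rescore(table, strong)
        full_hits = (full[full["gene"].isin(strong)]["hit"] != 0).sum()
        assert (sub["hit"] != 0).sum() >= full_hits

    def test_missing_subset_gene_rejected(self):
        table = self._table([0.1, 0.2])
        with pytest.raises(ValidationError, match="GHOST"):
            subset_rescore(table, {"GHOST"})


class TestRandomSubsetNull:
    def _gw(self, n=3000, n_sig=100, seed=6):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(n)]
        p = rng.uniform(0, 1, n)
        cgi = rng.normal(0, 0.3, n)
        sig = rng.choice(n, n_sig, replace=False)
        p[sig] = rng.uniform(0, 1e-6, n_sig)
        cgi[sig] = rng.choice([-1.5, 1.5], n_sig)
        return pd.DataFrame({"gene": genes, "p": p, "cgi": cgi})

    def test_seed_reproducibility(self):
        gw = self._gw()
        a = random_subset_null(gw, observed_hits=50, n_genes=500, n_iter=50, seed=1)
        b = random_subset_null(gw, observed_hits=50, n_genes=500, n_iter=50, seed=1)
        assert np.array_equal(a.counts, b.counts)
        assert a.empirical_p == b.empirical_p

    def test_null_mean_matches_expectation(self):
        gw = self._gw()
        null = random_subset_null(gw, observed_hits=999, n_genes=1000, n_iter=100, seed=2)
        # hits spread uniformly: expect ~ total_sig * n_genes / N
        assert null.counts.mean() == pytest.approx(100 * 1000 / 3000, rel=0.25)

    def test_extreme_observation_floor_p(self):
        gw = self._gw()
        null = random_subset_null(gw, observed_hits=10_000, n_genes=500, n_iter=100, seed=3)
        assert null.empirical_p == pytest.approx(1.0 / 101.0)

    def test_empirical_p_bounds(self):
        gw = self._gw()
        null = random_subset_null(gw, observed_hits=0, n_genes=500, n_iter=20, seed=4)
        assert 1.0 / 21.0 <= null.empirical_p <= 1.0

    def test_oversized_subset_rejected(self):
        gw = self._gw(n=100)
        with pytest.raises(ValidationError):
            random_subset_null(gw, observed_hits=1, n_genes=200, n_iter=5, seed=5)


class TestHitOverlap:
    def _table(self, signs):
        return pd.DataFrame({"gene": list(signs), "hit": list(signs.values())})

    def test_identical_sets_extreme_significance(self):
        signs = {f"G{i}": (-1 if i % 2 else 1) for i in range(50)}
        result = hit_overlap_test(self._table(signs), self._table(signs), 1011)
        assert result.overlap == 50
        assert result.p < 1e-30

    def test_sign_flip_zeroes_overlap(self):
        signs = {f"G{i}": -1 for i in range(20)}
        flipped = {g: 1 for g in signs}
        result = hit_overlap_test(self._table(signs), self._table(flipped), 1011)
        assert result.overlap == 0

    def test_calibration_under_independence(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(400)]
        p_values = []
        for _ in range(200):
            a = {g: -1 for g in rng.choice(genes, 40, replace=False)}
            b = {g: -1 for g in rng.choice(genes, 40, replace=False)}
            p_values.append(hit_overlap_test(self._table(a), self._table(b), 400).p)
        # under the null the p-value is stochastically ~U(0,1)
        assert 0.35 < np.mean(p_values) < 0.65

    def test_small_universe_rejected(self):
        signs = {f"G{i}": 1 for i in range(30)}
        with pytest.raises(ValidationError):
            hit_overlap_test(self._table(signs), self._table(signs), 10)


class TestEssentialStandard:
    def test_threshold_rule(self):
        ceres = pd.DataFrame(
            {f"cl{i}": [-1.2 if i < 7 else 0.0, -1.2 if i < 6 else 0.0, 0.0]
             for i in range(10)},
            index=["ess70", "borderline60", "never"],
        )
        std = define_essential_standard(ceres)
        assert "ess70" in std            # < -1 in 70% of lines
        assert "borderline60" not in std  # exactly 60%: strict inequality
        assert "never" not in std

    def test_all_zero_matrix_empty(self):
        ceres = pd.DataFrame(np.zeros((5, 10)), index=[f"G{i}" for i in range(5)])
        assert define_essential_standard(ceres) == set()

    def test_missing_values_leave_denominator(self):
        row = [-1.5, -1.5, np.nan, np.nan]  # 2/2 observed below threshold
        ceres = pd.DataFrame([row], index=["G1"])
        assert define_essential_standard(ceres) == {"G1"}

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            EssentialStandardConfig(fraction_threshold=1.5)


def _guide_fitness(gene_lfc: dict) -> cg.GuideFitness:
    """Build a GuideFitness from {guide: {(cond, tp): lfc}} (one replicate)."""
    frames = {}
    for guide, values in gene_lfc.items():
        for (cond, tp), v in values.items():
            frames.setdefault((cond, tp, "A"), {})[guide] = v
    lfc = pd.DataFrame(frames)
    lfc.columns = pd.MultiIndex.from_tuples(
        lfc.columns, names=["condition", "timepoint", "replicate"]
    )
    return cg.GuideFitness(lfc, 1.0)


class TestEssentialGuideSupport:
    def _lib(self):
        return LibraryDefinition(
            pd.DataFrame(
                {"guide_id": ["E_g1", "E_g2", "E_g3"], "gene": ["E"] * 3}
            )
        )

    def _fitness(self, diffs_by_guide):
        """Control LFC has small guide scatter; compound adds per-guide diffs."""
        base = {"E_g1": 0.1, "E_g2": -0.1, "E_g3": 0.05}
        data = {}
        for guide in base:
            entry = {}
            for i, tp in enumerate((6, 12, 15)):
                dmso = -0.5 * (i + 1) + base[guide]
                entry[("DMSO", tp)] = dmso
                entry[("CPT", tp)] = dmso + diffs_by_guide.get(guide, (0, 0, 0))[i]
            data[guide] = entry
        return _guide_fitness(data)

    def test_single_guide_outlier(self):
        gf = self._fitness({"E_g1": (-3.0, -3.0, 0.0)})
        calls = essential_guide_support(gf, self._lib(), [("E", "CPT")])
        assert calls[0].support_class == "single_guide"
        assert calls[0].flagged_guides == ("E_g1",)

    def test_two_guides_multi_support(self):
        gf = self._fitness({"E_g1": (-3.0, -3.0, 0.0), "E_g2": (-2.0, 0.0, -2.0)})
        calls = essential_guide_support(gf, self._lib(), [("E", "CPT")])
        assert calls[0].support_class == "multi_guide"

    def test_one_timepoint_only_not_flagged(self):
        gf = self._fitness({"E_g1": (-3.0, 0.0, 0.0)})
        calls = essential_guide_support(gf, self._lib(), [("E", "CPT")])
        assert calls[0].support_class == "unsupported"

    def test_relabeling_invariance(self):
        gf = self._fitness({"E_g1": (-3.0, -3.0, 0.0)})
        renamed = cg.GuideFitness(
            gf.lfc.rename(index={"E_g1": "E_gX", "E_g2": "E_g1", "E_g3": "E_g2"}),
            1.0,
        )
        lib = LibraryDefinition(
            pd.DataFrame({"guide_id": ["E_gX", "E_g1", "E_g2"], "gene": ["E"] * 3})
        )
        calls = essential_guide_support(renamed, lib, [("E", "CPT")])
        assert calls[0].support_class == "single_guide"
        assert calls[0].flagged_guides == ("E_gX",)

    def test_requires_two_timepoints(self):
        data = {
            g: {("DMSO", 6): 0.0, ("CPT", 6): -1.0}
            for g in ("E_g1", "E_g2", "E_g3")
        }
        gf = _guide_fitness(data)
        with pytest.raises(ValidationError, match="timepoints"):
            essential_guide_support(gf, self._lib(), [("E", "CPT")])


class TestSelectTopGuides:
    def _lib(self, guides_by_gene):
        rows = [
            {"guide_id": g, "gene": gene}
            for gene, guides in guides_by_gene.items()
            for g in guides
        ]
        return LibraryDefinition(pd.DataFrame(rows))

    def test_correlated_trio_selected(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 30)
        profiles = pd.DataFrame(
            {
                "G_g1": base + rng.normal(0, 0.2, 30),
                "G_g2": base + rng.normal(0, 0.2, 30),
                "G_g3": base + rng.normal(0, 0.2, 30),
                "G_g4": rng.normal(0, 1, 30),
            }
        ).T
        lib = self._lib({"G": ["G_g1", "G_g2", "G_g3", "G_g4"]})
        selected = select_top_guides(profiles, lib, k=3)
        assert sorted(selected.guide_ids) == ["G_g1", "G_g2", "G_g3"]

    def test_exactly_k_guides_all_kept(self):
        rng = np.random.default_rng(9)
        profiles = pd.DataFrame(rng.normal(size=(3, 10)),
                                index=["G_g1", "G_g2", "G_g3"])
        lib = self._lib({"G": ["G_g1", "G_g2", "G_g3"]})
        assert sorted(select_top_guides(profiles, lib, k=3).guide_ids) == [
            "G_g1", "G_g2", "G_g3",
        ]

    def test_tie_broken_lexicographically(self):
        # two identical pairs with orthogonal profiles: every score ties
        v = np.array([1.0, -1.0, 1.0, -1.0, 0.0, 0.0])
        w = np.array([0.0, 0.0, 0.0, 0.0, 1.0, -1.0]) * np.sqrt(2)
        w = w - w.mean()  # uncorrelated with v by construction
        profiles = pd.DataFrame(
            [v, v.copy(), w, w.copy()],
            index=["G_gb", "G_ga", "G_gd", "G_gc"],
        )
        corr = np.corrcoef(v, w)[0, 1]
        assert abs(corr) < 1e-12
        lib = self._lib({"G": ["G_ga", "G_gb", "G_gc", "G_gd"]})
        selected = select_top_guides(profiles, lib, k=3)
        assert sorted(selected.guide_ids) == ["G_ga", "G_gb", "G_gc"]

    def test_constant_profile_warns(self):
        rng = np.random.default_rng(10)
        profiles = pd.DataFrame(
            [np.ones(10), rng.normal(size=10), rng.normal(size=10),
             rng.normal(size=10)],
            index=["G_g1", "G_g2", "G_g3", "G_g4"],
        )
        lib = self._lib({"G": ["G_g1", "G_g2", "G_g3", "G_g4"]})
        with pytest.warns(UserWarning, match="constant"):
            select_top_guides(profiles, lib, k=3)
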