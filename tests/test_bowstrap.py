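"""Bootstrap expression calling: resampling, RPKM, significance, diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mycometab.bowstrap import (
    BowstrapConfig,
    alignment_accounting,
    assign_iteration,
    cnd_pvalue,
    intersect_replicates,
    overlap_significance,
    rpkm,
    run_bowstrap,
)
from mycometab.types import (
    CandidateLocation,
    GeneCatalog,
    GeneModel,
    MultiAlignmentSet,
    Organism,
)


def make_catalog(lengths):
    return GeneCatalog(
        GeneModel(g, Organism.A, n) for g, n in lengths.items()
    )


def aln(reads, total=None):
    reads = {
        rid: [CandidateLocation(g, s, "+") for g, s in locs] for rid, locs in reads.items()
    }
    return MultiAlignmentSet(reads, total if total is not None else len(reads))


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,denom,expected",
        [
            (10, 1000, 10**6, 10.0),
            (0, 1000, 10**6, 0.0),
            (7, 2500, 2 * 10**6, 1.4),
        ],
    )
    def test_values(self, count, length, denom, expected):
        assert rpkm(count, length, denom) == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 1000, 0)


class TestCndPvalue:
    def test_no_signal_gives_one(self):
        assert cnd_pvalue(0.0, 5.0) == 1.0

    def test_constant_signal_gives_zero(self):
        assert cnd_pvalue(3.0, 0.0) == 0.0

    def test_zero_mu_takes_precedence_over_zero_sigma(self):
        assert cnd_pvalue(0.0, 0.0) == 1.0

    @pytest.mark.parametrize("s", [0.1, 1.0, 42.0])
    def test_mu_equal_sigma_is_phi_minus_one(self, s):
        assert cnd_pvalue(s, s) == pytest.approx(0.15865525393145707, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cnd_pvalue(-1.0, 1.0)

    @given(
        ratios=st.lists(
            st.floats(min_value=0.01, max_value=30.0), min_size=2, max_size=10, unique=True
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing_in_signal_to_noise(self, ratios):
        ratios = sorted(ratios)
        ps = [cnd_pvalue(r, 1.0) for r in ratios]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestAssignIteration:
    def test_unique_read_always_credits_its_gene(self):
        cat = make_catalog({"g1": 1000, "g2": 1000})
        a = aln({"r1": [("g1", 0)]})
        rng = np.random.default_rng(0)
        for _ in range(5):
            counts = assign_iteration(a, cat, rng)
            assert counts.tolist() == [1, 0]

    def test_two_locations_one_gene_is_effectively_unique(self):
        cat = make_catalog({"g1": 1000, "g2": 1000})
        a = aln({"r1": [("g1", 0), ("g1", 50)]})
        counts = assign_iteration(a, cat, np.random.default_rng(0))
        assert counts.tolist() == [1, 0]

    def test_multiread_splits_half_half_in_the_mean(self):
        cat = make_catalog({"g1": 1000, "g2": 1000})
        a = aln({"r": [("g1", 0), ("g2", 0)]})
        rng = np.random.default_rng(1)
        b = 4000
        mean = np.mean([assign_iteration(a, cat, rng)[0] for _ in range(b)])
        assert mean == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(b))

    def test_ten_multireads_have_binomial_spread(self):
        cat = make_catalog({"g1": 1000, "g2": 1000})
        a = aln({f"r{i}": [("g1", 0), ("g2", 0)] for i in range(10)})
        rng = np.random.default_rng(2)
        draws = np.array([assign_iteration(a, cat, rng)[0] for _ in range(4000)])
        # count(g1) ~ Binomial(10, 0.5): SD -> sqrt(2.5)
        assert draws.std() == pytest.approx(math.sqrt(2.5), rel=0.1)

    def test_conservation(self, small_experiment):
        a = small_experiment.libraries[0].alignments
        cat = small_experiment.catalog
        counts = assign_iteration(a, cat, np.random.default_rng(3))
        assert counts.sum() == a.n_mapped

    def test_empty_alignments_give_zero_counts(self):
        cat = make_catalog({"g1": 1000})
        counts = assign_iteration(aln({}, total=0), cat, np.random.default_rng(0))
        assert counts.tolist() == [0]


class TestRunBowstrap:
    def test_unique_only_library(self):
        cat = make_catalog({"g1": 1000, "g2": 1000, "g3": 500})
        a = aln({"r1": [("g1", 0)], "r2": [("g1", 10)], "r3": [("g2", 0)]})
        table = run_bowstrap(a, cat, BowstrapConfig(iterations=50, seed=1))
        assert table["g1"].sigma == 0.0 and table["g1"].pvalue == 0.0
        assert table["g2"].sigma == 0.0 and table["g2"].pvalue == 0.0
        assert table["g3"].mu == 0.0 and table["g3"].pvalue == 1.0
        assert not table["g3"].expressed

    def test_covers_every_catalog_gene(self, small_experiment):
        cat = small_experiment.catalog
        a = small_experiment.libraries[0].alignments
        table = run_bowstrap(a, cat, BowstrapConfig(iterations=20, seed=2))
        assert set(table.estimates) == set(cat.gene_ids)

    def test_deterministic_given_seed(self, small_experiment):
        cat = small_experiment.catalog
        a = small_experiment.libraries[0].alignments
        cfg = BowstrapConfig(iterations=30, seed=7)
        t1 = run_bowstrap(a, cat, cfg)
        t2 = run_bowstrap(a, cat, cfg)
        assert t1.estimates == t2.estimates

    def test_mu_recovers_planted_rpkm(self, small_experiment):
        cat = small_experiment.catalog
        lib = small_experiment.libraries[0]
        table = run_bowstrap(lib.alignments, cat, BowstrapConfig(iterations=100, seed=3))
        truth = lib.gene_truth.set_index("gene_id")
        ok = total = 0
        for g in cat.gene_ids:
            if truth.loc[g, "true_count"] == 0:
                continue
            total += 1
            est = table[g]
            tol = 3 * max(est.sigma, truth.loc[g, "se_rpkm"])
            ok += abs(est.mu - truth.loc[g, "true_rpkm"]) <= tol
        assert ok / total >= 0.9

    def test_rpkm_mass_conserved_per_iteration(self):
        # with the mapped-reads denominator, sum(RPKM * kb) is exactly 1e6
        cat = make_catalog({"g1": 1000, "g2": 4000})
        a = aln({"r1": [("g1", 0), ("g2", 0)], "r2": [("g2", 5)]})
        table = run_bowstrap(a, cat, BowstrapConfig(iterations=200, seed=4))
        mean_mass = sum(
            table[g].mu * cat[g].length_bp / 1e3 for g in cat.gene_ids
        )
        assert mean_mass == pytest.approx(1e6, rel=1e-9)


class TestReplicates:
    def _table(self, pvals):
        cat = make_catalog({g: 1000 for g in pvals})
        a = aln({f"r_{g}": [(g, 0)] for g, p in pvals.items() if p < 1})
        t = run_bowstrap(a, cat, BowstrapConfig(iterations=5, seed=0))
        return t

    def test_gene_significant_in_one_replicate_excluded(self):
        t1 = self._table({"g1": 0.0, "g2": 0.0})
        t2 = self._table({"g1": 0.0, "g2": 1.0})
        assert intersect_replicates([t1, t2]) == {"g1"}

    def test_mismatched_catalogs_rejected(self):
        t1 = self._table({"g1": 0.0})
        t2 = self._table({"g2": 0.0})
        with pytest.raises(ValueError):
            intersect_replicates([t1, t2])

    def test_replicate_overlap_on_shared_truth(self, small_experiment):
        cat = small_experiment.catalog
        tables = [
            run_bowstrap(lib.alignments, cat, BowstrapConfig(iterations=60, seed=9))
            for lib in small_experiment.libraries
        ]
        inter = intersect_replicates(tables)
        union = tables[0].expressed_genes() | tables[1].expressed_genes()
        # replicates share the planted expression levels, so the expressed
        # sets must agree almost completely
        assert len(inter) / len(union) >= 0.9


class TestOverlapSignificance:
    def test_forced_overlap_is_certain(self):
        u = {f"g{i}" for i in range(20)}
        assert overlap_significance(u, u, 20) == pytest.approx(1.0)

    def test_two_of_two_in_four(self):
        a = {"g1", "g2"}
        assert overlap_significance(a, a, 4) == pytest.approx(1 / 6, rel=1e-12)

    def test_disjoint_sets_not_significant(self):
        a = {f"a{i}" for i in range(50)}
        b = {f"b{i}" for i in range(50)}
        assert overlap_significance(a, b, 10_000) > 0.5

    def test_sets_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_significance({"a", "b"}, {"a"}, 1)


class TestAlignmentAccounting:
    def test_all_reads_in_both(self):
        gm = aln({"r1": [("g1", 0)], "r2": [("g1", 5)]})
        gn = aln({"r1": [("g1", 0)], "r2": [("g1", 5)]})
        frac = alignment_accounting(gm, gn)
        assert frac["both"] == 1.0
        assert frac["gene_model_only"] == frac["genome_only"] == frac["neither"] == 0.0

    def test_planted_categories(self):
        gm = aln({"r1": [("g1", 0)], "r2": [("g1", 1)], "r3": [("g1", 2), ("g2", 0)]},
                 total=5)
        gn = aln({"r1": [("s1", 0)], "r4": [("s1", 5)]}, total=5)
        frac = alignment_accounting(gm, gn)
        assert frac["both"] == pytest.approx(0.2)            # r1
        assert frac["gene_model_only"] == pytest.approx(0.4)  # r2, r3
        assert frac["genome_only"] == pytest.approx(0.2)      # r4
        assert frac["neither"] == pytest.approx(0.2)          # r5
        assert frac["multi_location"] == pytest.approx(0.2)   # r3
        total = sum(frac[k] for k in ("both", "gene_model_only", "genome_only", "neither"))
        assert total == pytest.approx(1.0)

    def test_missing_genome_reports_undefined_not_zero(self):
        gm = aln({"r1": [("g1", 0)]})
        frac = alignment_accounting(gm, None)
        assert frac["both"] is None and frac["neither"] is None
        assert frac["gene_model"] == 1.0
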