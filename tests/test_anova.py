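import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from voigex import (
    AnalysisConfig,
    DegenerateDesignError,
    TissueSample,
    ValidationError,
    VoiAssignment,
)
from voigex.anova import (
    DesignTable,
    anova_f,
    build_design,
    permutation_pvalues,
    permute_labels,
    run_analysis,
)

from conftest import make_one_way_table, one_way_f_oracle, run_quiet


def relabelings(n, n_a):
    """All distinct two-group label vectors with group sizes (n_a, n - n_a)."""
    out = []
    for pos in itertools.combinations(range(n), n_a):
        lab = np.array(["B"] * n, dtype=object)
        lab[list(pos)] = "A"
        out.append(lab)
    return out


class TestAnovaF:
    def test_textbook_one_way_f(self):
        dt = make_one_way_table([1, 2, 3, 4, 5, 6], ["A"] * 3 + ["B"] * 3)
        f, df_e, df_err = anova_f(dt)
        assert f == pytest.approx(13.5, rel=1e-9)
        assert (df_e, df_err) == (1, 4)

    def test_identical_groups_give_zero_f(self):
        dt = make_one_way_table([1, 2, 3, 1, 2, 3], ["A"] * 3 + ["B"] * 3)
        f, _, _ = anova_f(dt)
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_donor_identical_to_tsl_is_confounded(self):
        n = 6
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dt = DesignTable(
                unit_id="u",
                gene_symbol="u",
                sample_ids=[f"s{i}" for i in range(n)],
                response=np.arange(n, dtype=float),
                tsl=np.array(["A"] * 3 + ["B"] * 3, dtype=object),
                donor=np.array(["dA"] * 3 + ["dB"] * 3, dtype=object),
                age=np.full(n, 40.0),
                sex=np.array(["M"] * n, dtype=object),
                ethnicity=np.array(["c"] * n, dtype=object),
            )
            with pytest.raises(DegenerateDesignError, match="confound"):
                anova_f(dt)

    def test_matches_one_way_oracle_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            y = rng.normal(size=n_a + n_b)
            labels = ["A"] * n_a + ["B"] * n_b
            dt = make_one_way_table(y, labels)
            f, _, _ = anova_f(dt)
            assert f == pytest.approx(one_way_f_oracle(y, labels), rel=1e-9)

    def test_matches_statsmodels_model_comparison(self):
        """Full-vs-reduced F equals statsmodels anova_lm on a covariate design."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(1)
        n = 40
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "tsl": rng.permutation(["A"] * 18 + ["B"] * 22),
                "donor": rng.choice(["d1", "d2", "d3"], size=n),
                "age": rng.uniform(24, 57, size=n),
                "sex": rng.choice(["M", "F"], size=n),
                "eth": rng.choice(["c", "a"], size=n),
            }
        )
        dt = DesignTable(
            unit_id="u",
            gene_symbol="u",
            sample_ids=[f"s{i}" for i in range(n)],
            response=df["y"].to_numpy(),
            tsl=df["tsl"].to_numpy(dtype=object),
            donor=df["donor"].to_numpy(dtype=object),
            age=df["age"].to_numpy(),
            sex=df["sex"].to_numpy(dtype=object),
            ethnicity=df["eth"].to_numpy(dtype=object),
        )
        f, df_e, df_err = anova_f(dt)
        full = smf.ols("y ~ C(tsl) + C(donor) + age + C(sex) + C(eth)", df).fit()
        red = smf.ols("y ~ C(donor) + age + C(sex) + C(eth)", df).fit()
        tab = anova_lm(red, full)
        assert f == pytest.approx(float(tab["F"].iloc[1]), rel=1e-8)
        assert df_e == int(tab["df_diff"].iloc[1])
        assert df_err == int(full.df_resid)

    def test_aliased_covariates_dropped_matches_donor_only_model(self):
        """Donor-determined age/sex/ethnicity are pruned; F equals the donor-only fit."""
        rng = np.random.default_rng(2)
        n = 30
        donor = np.repeat([f"d{i}" for i in range(6)], 5)
        meta = {f"d{i}": (30 + i, "M" if i else "F", "c" if i < 3 else "a") for i in range(6)}
        y = rng.normal(size=n)
        tsl = rng.permutation(["A"] * 12 + ["B"] * 18)
        with pytest.warns(UserWarning, match="dropped"):
            dt = DesignTable(
                unit_id="u",
                gene_symbol="u",
                sample_ids=[f"s{i}" for i in range(n)],
                response=y,
                tsl=tsl.astype(object),
                donor=donor.astype(object),
                age=np.array([meta[d][0] for d in donor], dtype=float),
                sex=np.array([meta[d][1] for d in donor], dtype=object),
                ethnicity=np.array([meta[d][2] for d in donor], dtype=object),
            )
            f_full, _, df_err = anova_f(dt)

        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = pd.DataFrame({"y": y, "tsl": tsl, "donor": donor})
        full = smf.ols("y ~ C(tsl) + C(donor)", df).fit()
        red = smf.ols("y ~ C(donor)", df).fit()
        tab = anova_lm(red, full)
        assert f_full == pytest.approx(float(tab["F"].iloc[1]), rel=1e-8)
        assert df_err == int(full.df_resid)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(-50, 50).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-100, 100),
        seed=st.integers(0, 10**6),
    )
    def test_f_invariant_under_affine_response_transform(self, a, b, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=10)
        labels = ["A"] * 5 + ["B"] * 5
        f1, _, _ = anova_f(make_one_way_table(y, labels))
        f2, _, _ = anova_f(make_one_way_table(a * y + b, labels))
        assert f2 == pytest.approx(f1, rel=1e-6, abs=1e-9)


class TestPermuteLabels:
    def test_every_arrangement_reachable(self):
        labels = np.array(["A", "A", "B", "B"], dtype=object)
        rng = np.random.default_rng(0)
        seen = {tuple(permute_labels(labels, rng)) for _ in range(500)}
        assert len(seen) == 6  # 4!/(2!2!) distinct arrangements

    def test_multiset_preserved_and_seed_reproducible(self):
        labels = np.array(["A"] * 5 + ["B"] * 7, dtype=object)
        p1 = [tuple(permute_labels(labels, np.random.default_rng(3))) for _ in range(5)]
        p2 = [tuple(permute_labels(labels, np.random.default_rng(3))) for _ in range(5)]
        assert p1 == p2
        assert sorted(p1[0]) == sorted(labels)


class TestPermutationPvalues:
    def test_single_unit_fwe_equals_nominal_exactly(self):
        dt = make_one_way_table([1.0, 2.0, 3.0, 4.0, 2.5, 0.5], ["A"] * 3 + ["B"] * 3)
        (res,) = permutation_pvalues([dt], n_permutations=300, rng_seed=1)
        assert res.p_fwe == res.p_nominal

    def test_worked_example_against_exhaustive_enumeration(self):
        """Data [1,2,3,4] / labels AABB: oracle F over all 6 relabelings is
        {8, 8, 0.5, 0.5, 0, 0}; exact p of the observed grouping is 2/6."""
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fs = sorted(
            one_way_f_oracle(y, lab) for lab in relabelings(4, 2)
        )
        assert fs == pytest.approx([0.0, 0.0, 0.5, 0.5, 8.0, 8.0])
        f_obs = one_way_f_oracle(y, ["A", "A", "B", "B"])
        exact_p = sum(f >= f_obs for f in fs) / len(fs)
        assert exact_p == pytest.approx(2 / 6)

        dt = make_one_way_table(y, ["A", "A", "B", "B"])
        (res,) = permutation_pvalues([dt], n_permutations=4000, rng_seed=7)
        se = np.sqrt(exact_p * (1 - exact_p) / 4000)
        assert abs(res.p_nominal - exact_p) < 3 * se + 1 / 4000

    def test_fwe_dominates_nominal_across_units(self, spiked_dataset, fast_cfg):
        results = run_quiet(spiked_dataset.expression, spiked_dataset.assignment, fast_cfg)
        assert all(r.p_fwe >= r.p_nominal for r in results)

    def test_identical_seed_gives_bit_identical_pvalues(self, spiked_dataset, fast_cfg):
        r1 = run_quiet(spiked_dataset.expression, spiked_dataset.assignment, fast_cfg)
        r2 = run_quiet(spiked_dataset.expression, spiked_dataset.assignment, fast_cfg)
        assert [(r.p_nominal, r.p_fwe, r.f_observed) for r in r1] == [
            (r.p_nominal, r.p_fwe, r.f_observed) for r in r2
        ]

    def test_mismatched_designs_rejected(self):
        a = make_one_way_table([1, 2, 3, 4], ["A", "A", "B", "B"], unit_id="a")
        b = make_one_way_table([1, 2, 3, 4], ["A", "B", "A", "B"], unit_id="b")
        with pytest.raises(ValidationError, match="share"):
            permutation_pvalues([a, b], 10, 0)


class TestBuildDesign:
    def _samples(self, n=6):
        return [
            TissueSample(
                f"s{i}", f"d{i % 2}", (0.0, 0.0, 0.0), {"age": 30 + i, "sex": "M", "ethnicity": "c"}
            )
            for i in range(n)
        ]

    def _matrix(self, units, sample_ids):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            rng.normal(size=(len(units), len(sample_ids))), index=units, columns=sample_ids
        )

    def test_response_length_matches_labeled_samples(self):
        samples = self._samples(6)
        ids = [s.sample_id for s in samples]
        assignment = VoiAssignment({ids[i]: ("VOI1" if i < 3 else "VOI2") for i in range(6)})
        tables = build_design(self._matrix(["g1", "g2"], ids), samples, assignment)
        assert len(tables) == 2 and all(t.n == 6 for t in tables)

    def test_single_sample_voi_rejected(self):
        samples = self._samples(4)
        ids = [s.sample_id for s in samples]
        assignment = VoiAssignment({ids[0]: "VOI1", ids[1]: "VOI2", ids[2]: "VOI2", ids[3]: "VOI2"})
        with pytest.raises(DegenerateDesignError, match=">= 2"):
            build_design(self._matrix(["g"], ids), samples, assignment)

    def test_missing_covariate_rejected(self):
        samples = self._samples(6)
        del samples[2].covariates["age"]
        ids = [s.sample_id for s in samples]
        assignment = VoiAssignment({ids[i]: ("VOI1" if i < 3 else "VOI2") for i in range(6)})
        with pytest.raises(ValidationError, match="age"):
            build_design(self._matrix(["g"], ids), samples, assignment)


class TestRunAnalysis:
    def test_all_probes_units_are_genes(self, spiked_dataset, fast_cfg):
        results = run_quiet(spiked_dataset.expression, spiked_dataset.assignment, fast_cfg)
        assert len(results) == len(spiked_dataset.gene_probe_counts)

    def test_single_probe_units_are_probes(self, spiked_dataset, fast_cfg):
        cfg = AnalysisConfig(
            mode="single_probe", n_permutations=fast_cfg.n_permutations, rng_seed=1
        )
        results = run_quiet(spiked_dataset.expression, spiked_dataset.assignment, cfg)
        assert len(results) == spiked_dataset.expression.n_probes
        by_gene = {}
        for r in results:
            by_gene[r.gene_symbol] = by_gene.get(r.gene_symbol, 0) + 1
        assert by_gene == spiked_dataset.gene_probe_counts

    def test_results_sorted_by_fwe_then_f(self, spiked_dataset, fast_cfg):
        results = run_quiet(spiked_dataset.expression, spiked_dataset.assignment, fast_cfg)
        keys = [(r.p_fwe, -r.f_observed, r.unit_id) for r in results]
        assert keys == sorted(keys)

    def test_spiked_gene_ranks_first(self, spiked_dataset, fast_cfg):
        results = run_quiet(spiked_dataset.expression, spiked_dataset.assignment, fast_cfg)
        assert results[0].unit_id == "GENE001"
        assert results[0].p_fwe < 0.05
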