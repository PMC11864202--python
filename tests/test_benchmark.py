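"""Constrained subsampling, deviation bookkeeping, bimodality screening,
and the bimodal-vs-unimodal group comparison."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ssdbench.benchmark import (
    records_to_frame,
    APPROACHES,
    BIMODALITY_THRESHOLD,
    BimodalityResult,
    DeviationRecord,
    DeviationSummary,
    SubsampleSpec,
    aggregate_across_chemicals,
    bimodality_coefficient,
    compare_groups,
    run_benchmark,
    subsample,
    summarize_deviations,
)
from ssdbench.exceptions import (
    ConfigError,
    DomainError,
    InsufficientDataError,
    NumericError,
)
from ssdbench.ingest import TaxonGroup

from conftest import make_dataset


class TestSubsample:
    def test_full_set_when_size_equals_n(self, rng):
        ds = make_dataset(np.linspace(1, 15, 15))
        spec = SubsampleSpec(size=15, iterations=1, seed=0)
        sub = subsample(ds, spec, rng)
        assert sub.species_values == ds.species_values

    def test_constraint_forces_rare_groups(self):
        """13 fish + 1 algae + 1 invertebrate, size 3: every accepted draw
        must contain both rare species (the only 3-group subsets).
        Cross-checked against exhaustive enumeration of C(15,3)."""
        groups = [TaxonGroup.FISH] * 13 + [TaxonGroup.ALGAE, TaxonGroup.INVERTEBRATE]
        ds = make_dataset(np.linspace(1, 15, 15), groups=groups)
        valid = [
            c
            for c in itertools.combinations(range(15), 3)
            if len({groups[i] for i in c}) >= 3
        ]
        assert all(13 in c and 14 in c for c in valid)  # enumeration oracle
        spec = SubsampleSpec(size=3, iterations=1, seed=0)
        for seed in range(30):
            sub = subsample(ds, spec, np.random.default_rng(seed))
            names = {s for s, _, _ in sub.species_values}
            assert {"sp_0013", "sp_0014"} <= names

    def test_deterministic_given_generator_state(self):
        ds = make_dataset(np.linspace(1, 40, 40))
        spec = SubsampleSpec(size=10, iterations=1, seed=5)
        s1 = subsample(ds, spec, np.random.default_rng(11))
        s2 = subsample(ds, spec, np.random.default_rng(11))
        assert s1.species_values == s2.species_values

    def test_unsatisfiable_constraint_is_config_error(self, rng):
        groups = [TaxonGroup.FISH, TaxonGroup.ALGAE] * 10
        ds = make_dataset(np.linspace(1, 20, 20), groups=groups)
        with pytest.raises(ConfigError):
            subsample(ds, SubsampleSpec(size=5, iterations=1), rng)

    def test_too_few_species(self, rng):
        ds = make_dataset(np.linspace(1, 5, 5))
        with pytest.raises(InsufficientDataError):
            subsample(ds, SubsampleSpec(size=10, iterations=1), rng)

    def test_marginal_uniformity_when_constraint_nonbinding(self):
        """All four groups well represented: inclusion frequency of each
        species stays within 5 SE of size/n over many draws."""
        n, size, draws = 20, 15, 20000
        ds = make_dataset(np.linspace(1, n, n))
        spec = SubsampleSpec(size=size, iterations=1, seed=0)
        counts = np.zeros(n)
        rng = np.random.default_rng(123)
        for _ in range(draws):
            sub = subsample(ds, spec, rng)
            for s, _, _ in sub.species_values:
                counts[int(s[3:])] += 1
        p = size / n
        se = math.sqrt(p * (1 - p) / draws)
        np.testing.assert_array_less(np.abs(counts / draws - p), 5 * se)

    def test_spec_validation(self):
        with pytest.raises(ConfigError):
            SubsampleSpec(size=2, min_groups=3)
        with pytest.raises(ConfigError):
            SubsampleSpec(iterations=0)


class TestRunBenchmark:
    def test_record_count_and_exclusion_accounting(self, lognormal_dataset):
        spec = SubsampleSpec(size=15, iterations=30, seed=3)
        records = run_benchmark(lognormal_dataset, spec)
        assert len(records) == 30 * 6
        assert {r.approach for r in records} == set(APPROACHES)
        summaries = summarize_deviations(records)
        for s in summaries:
            excluded = sum(
                1
                for r in records
                if r.approach == s.approach and r.excluded
            )
            assert s.n_used + excluded == spec.iterations

    def test_deterministic_across_calls(self, lognormal_dataset):
        spec = SubsampleSpec(size=10, iterations=10, seed=9)
        r1 = run_benchmark(lognormal_dataset, spec)
        r2 = run_benchmark(lognormal_dataset, spec)
        pd.testing.assert_frame_equal(records_to_frame(r1), records_to_frame(r2))

    def test_deviation_zero_when_estimate_equals_reference(self):
        rec = DeviationRecord("c", 0, "lnorm", 0.05, 0.0, False)
        assert rec.deviation == 0.0  # log10(HC_est) - log10(HC_ref) at equality


class TestSummarize:
    def test_all_zero_deviations(self):
        records = [
            DeviationRecord("c", i, "lnorm", 0.05, 0.0, False) for i in range(100)
        ]
        (s,) = summarize_deviations(records)
        assert (s.q025, s.q50, s.q975) == (0.0, 0.0, 0.0)
        assert s.n_used == 100

    def test_median_of_three(self):
        records = [
            DeviationRecord("c", i, "ma", 0.05, d, False)
            for i, d in enumerate([-1.0, 0.0, 1.0])
        ]
        (s,) = summarize_deviations(records)
        assert s.q50 == 0.0

    def test_percentiles_match_linear_interpolation_oracle(self):
        devs = np.arange(1.0, 1001.0) / 100.0
        records = [
            DeviationRecord("c", i, "x", 0.05, float(d), False)
            for i, d in enumerate(devs)
        ]
        (s,) = summarize_deviations(records)
        assert s.q025 == pytest.approx(np.quantile(devs, 0.025, method="linear"))
        assert s.q975 == pytest.approx(np.quantile(devs, 0.975, method="linear"))

    def test_all_excluded_flagged_with_zero_n(self):
        records = [
            DeviationRecord("c", i, "burr3", 0.05, float("nan"), True)
            for i in range(5)
        ]
        (s,) = summarize_deviations(records)
        assert s.n_used == 0 and math.isnan(s.q50)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            summarize_deviations([])


class TestAggregate:
    def test_single_chemical_degenerate_range(self):
        s = DeviationSummary("c1", "lnorm", -0.1, 0.0, 0.2, 100)
        df = aggregate_across_chemicals([s])
        row = df.iloc[0]
        assert row["q50_mean"] == row["q50_min"] == row["q50_max"] == 0.0

    def test_mean_and_range_of_two(self):
        rows = [
            DeviationSummary("c1", "lnorm", -0.2, -0.1, 0.3, 100),
            DeviationSummary("c2", "lnorm", -0.4, 0.1, 0.5, 100),
        ]
        df = aggregate_across_chemicals(rows)
        row = df.iloc[0]
        assert row["q50_mean"] == pytest.approx(0.0)
        assert (row["q50_min"], row["q50_max"]) == (-0.1, 0.1)
        # permutation invariance
        df2 = aggregate_across_chemicals(rows[::-1])
        assert df.drop(columns="approach").equals(df2.drop(columns="approach"))


class TestBimodalityCoefficient:
    def test_normal_sample_approaches_one_third(self):
        rng = np.random.default_rng(0)
        values = 10.0 ** rng.normal(1.0, 0.5, size=10**6)
        res = bimodality_coefficient(values)
        assert abs(res.bc - 1.0 / 3.0) < 0.01
        assert not res.bimodal

    def test_uniform_sample_approaches_threshold(self):
        rng = np.random.default_rng(1)
        values = 10.0 ** rng.uniform(0.0, 3.0, size=10**6)
        res = bimodality_coefficient(values)
        assert abs(res.bc - 1.0 / 1.8) < 0.01

    def test_threshold_is_strict(self):
        r = BimodalityResult("c", 100, 0.0, 0.0, BIMODALITY_THRESHOLD, False)
        assert r.bc == 0.555 and not r.bimodal
        # the classifier itself: exactly at the threshold is NOT bimodal
        assert (BIMODALITY_THRESHOLD > BIMODALITY_THRESHOLD) is False

    def test_well_separated_mixture_flags_bimodal(self):
        rng = np.random.default_rng(2)
        values = 10.0 ** np.concatenate(
            [rng.normal(0.0, 0.3, 500), rng.normal(3.0, 0.3, 500)]
        )
        assert bimodality_coefficient(values).bimodal

    def test_guards(self):
        with pytest.raises(InsufficientDataError):
            bimodality_coefficient([1.0, 2.0, 3.0])
        with pytest.raises(NumericError):
            bimodality_coefficient([5.0, 5.0, 5.0, 5.0])
        with pytest.raises(DomainError):
            bimodality_coefficient([-1.0, 1.0, 2.0, 3.0])


def _summaries(values_by_chem, approach="lnorm", percentile_value=lambda v: v):
    return [
        DeviationSummary(c, approach, v - 1, v, v + 1, 100)
        for c, v in values_by_chem.items()
    ]


class TestCompareGroups:
    def _flags(self, bimodal_ids, all_ids):
        return [
            BimodalityResult(c, 60, 0.0, 0.0, 0.7 if c in bimodal_ids else 0.3, c in bimodal_ids)
            for c in all_ids
        ]

    def test_identical_groups_give_t_zero_p_one(self):
        vals = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 1.0, "e": 2.0, "f": 3.0}
        summaries = _summaries(vals)
        flags = self._flags({"a", "b", "c"}, vals)
        df = compare_groups(summaries, flags, "q50")
        assert df["t_statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert df["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_holm_stepdown_hand_example(self):
        """Holm on raw p = {0.01, 0.04} with m=2 gives {0.02, 0.04}."""
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests([0.01, 0.04], method="holm")[1]
        np.testing.assert_allclose(adjusted, [0.02, 0.04])

    def test_separated_groups_give_tiny_p(self):
        rng = np.random.default_rng(3)
        vals = {f"u{i}": 0.0 + 1e-6 * rng.standard_normal() for i in range(4)}
        vals.update({f"b{i}": 1.0 + 1e-6 * rng.standard_normal() for i in range(4)})
        summaries = _summaries(vals)
        flags = self._flags({k for k in vals if k.startswith("b")}, vals)
        df = compare_groups(summaries, flags, "q975")
        assert df["p_holm"].iloc[0] < 1e-6

    def test_small_group_rejected(self):
        vals = {"a": 1.0, "b": 2.0, "c": 3.0}
        summaries = _summaries(vals)
        flags = self._flags({"a"}, vals)
        with pytest.raises(InsufficientDataError):
            compare_groups(summaries, flags, "q975")

    def test_bad_percentile_name(self):
        with pytest.raises(DomainError):
            compare_groups([], [], "q99")
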