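"""Residual statistic and the two-stage bounded estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grkin.errors import FitError, ValidationError
from grkin.estimation import (
    TimeCourseDataset,
    fit_stage1_gr,
    fit_stage2,
    fit_two_stage,
    identifiable_quantities,
    recovered_relative_errors,
    residual_epsilon,
    stage1_parameter_names,
    stage2_parameter_names,
)
from grkin.models import PARAM_BOUNDS, build_model
from grkin.synthetic import SyntheticConfig, generate_dataset

from conftest import make_dataset, make_params


class TestResidualEpsilon:
    def test_hand_computed_values(self):
        assert residual_epsilon([2.0, 3.0], [1.0, 2.0]) == pytest.approx(0.625, rel=1e-12)
        assert residual_epsilon([1.0], [2.0]) == pytest.approx(0.25, rel=1e-12)
        v = np.array([0.3, 1.7, 4.2])
        assert residual_epsilon(v, v) == 0.0

    def test_denominator_is_simulated_value(self):
        # asymmetric by design: swapping y and Y changes the residual
        assert residual_epsilon([2.0], [1.0]) != residual_epsilon([1.0], [2.0])

    def test_near_zero_simulation_rejected(self):
        with pytest.raises(ValidationError, match="near-zero"):
            residual_epsilon([1.0, 1.0], [1.0, 1e-12])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            residual_epsilon([1.0, 2.0], [1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.05, 50.0), st.floats(0.05, 50.0)),
                    min_size=1, max_size=12))
    def test_matches_bruteforce_loop(self, pairs):
        y = [a for a, _ in pairs]
        Y = [b for _, b in pairs]
        brute = sum(((yi - Yi) / Yi) ** 2 for yi, Yi in zip(y, Y)) / len(pairs)
        assert residual_epsilon(y, Y) == pytest.approx(brute, abs=1e-12, rel=1e-12)


class TestDatasetValidation:
    def _frame(self, **overrides):
        rows = dict(gene=["GR", "GR"], level=["protein", "protein"],
                    time_h=[0.0, 2.0], replicate=[1, 1], value_fold=[1.0, 1.8])
        rows.update(overrides)
        return pd.DataFrame(rows)

    def test_valid_roundtrip(self):
        ds = TimeCourseDataset(self._frame())
        assert ds.observables() == [("GR", "protein")]
        t, m = ds.means("GR", "protein")
        assert list(t) == [0.0, 2.0] and list(m) == [1.0, 1.8]

    def test_t0_must_be_unity(self):
        with pytest.raises(ValidationError, match="t=0"):
            TimeCourseDataset(self._frame(value_fold=[1.2, 1.8]))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValidationError, match="non-positive"):
            TimeCourseDataset(self._frame(value_fold=[1.0, -0.5]))

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            TimeCourseDataset(self._frame(time_h=[0.0, 0.0], value_fold=[1.0, 1.0]))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError, match="no data"):
            TimeCourseDataset(pd.DataFrame(columns=["gene", "level", "time_h",
                                                    "replicate", "value_fold"]))


class TestStageOne:
    def test_recovers_gr_rates_from_noiseless_data(self):
        # model 1's GR subsystem is self-contained, so stage 1 at zero
        # noise should land within 5% of the generating rates
        data, truth = make_dataset(1, seed=11, times=(0.0, 2.0, 10.0, 24.0))
        s1 = fit_stage1_gr(build_model(1), data, seed=4, n_starts=4)
        for name in stage1_parameter_names(build_model(1)):
            assert s1.params[name] == pytest.approx(
                truth["true_rates"][name], rel=0.05), name

    def test_requires_gr_observables(self):
        data, _ = make_dataset(1, seed=1)
        downstream = TimeCourseDataset(data.frame[data.frame.gene != "GR"])
        with pytest.raises(FitError, match="GR"):
            fit_stage1_gr(build_model(1), downstream, seed=0, n_starts=2)

    def test_flat_data_flagged_non_identifiable(self):
        t = [0.0, 2.0, 10.0]
        frame = pd.DataFrame({
            "gene": ["GR"] * 6, "level": ["protein"] * 3 + ["mrna"] * 3,
            "time_h": t * 2, "replicate": [1] * 6, "value_fold": [1.0] * 6})
        s1 = fit_stage1_gr(build_model(1), TimeCourseDataset(frame),
                           seed=0, n_starts=2, stimulus_on=False)
        assert "GR.protein" in s1.non_identifiable
        # without stimulus any balanced rate vector reproduces flat data exactly
        assert s1.cost == pytest.approx(0.0, abs=1e-12)


class TestStageTwo:
    def test_noiseless_self_fit_beats_rival(self):
        data, _ = make_dataset(2, seed=21, times=(0.0, 2.0, 10.0))
        fit2 = fit_two_stage(build_model(2), data, seed=1, n_starts=3)
        fit1 = fit_two_stage(build_model(1), data, seed=1, n_starts=3)
        assert fit2.total_epsilon < 1e-3
        assert fit1.total_epsilon > fit2.total_epsilon

    def test_underdetermined_single_point_interpolated(self):
        # one observable, one non-baseline time point: always fittable to ~0
        data, _ = make_dataset(5, seed=8, times=(0.0, 2.0))
        sub = data.frame[(data.frame.gene == "GR") & (data.frame.level == "protein")]
        fit = fit_two_stage(build_model(5), TimeCourseDataset(sub), seed=0, n_starts=4)
        assert fit.total_epsilon < 1e-6

    def test_unknown_observable_raises_fit_error(self):
        data, _ = make_dataset(5, seed=8)   # GR + Erg observables
        s1 = fit_stage1_gr(build_model(1), data, seed=0, n_starts=2)
        with pytest.raises(FitError, match="no observable"):
            fit_stage2(build_model(1), s1, data, seed=0, n_starts=2)

    @pytest.mark.parametrize("mid,seed,cv", [(1, 0, 0.2), (5, 1, 0.1), (2, 2, 0.0),
                                             (3, 3, 0.3), (6, 4, 0.15), (4, 5, 0.1)])
    def test_estimates_respect_bounds(self, mid, seed, cv):
        data, _ = make_dataset(mid, seed=seed, noise_cv=cv)
        fit = fit_two_stage(build_model(mid), data, seed=seed, n_starts=2)
        lo, hi = PARAM_BOUNDS
        for name, v in fit.all_params.items():
            assert lo - 1e-9 <= v <= hi + 1e-9, name


class TestIdentifiability:
    def test_latent_chain_collapses_to_product(self):
        q = identifiable_quantities(build_model(6))
        assert "a_GR_X*a_X_Erg" in q
        assert "a_GR_X" not in q and "a_X_Erg" not in q
        # no autoregulation: GR mRNA is flat, its degradation unidentifiable
        assert "dm_GR" not in q and "dp_GR" in q

    def test_unregulated_gene_excluded(self):
        q = identifiable_quantities(build_model(3))
        assert "dm_Erg" not in q and "dp_Erg" not in q
        assert {"dm_GR", "dp_GR", "k_act", "a_auto"} <= set(q)

    def test_relative_errors_cover_all_quantities(self):
        spec = build_model(2)
        data, truth = make_dataset(2, seed=33, times=(0.0, 2.0, 10.0, 24.0))
        fit = fit_two_stage(spec, data, seed=3, n_starts=3)
        errs = recovered_relative_errors(spec, truth["true_rates"], fit.all_params)
        assert set(errs) == set(identifiable_quantities(spec))
        assert max(errs.values()) <= 0.10


def test_noise_degrades_recovery_monotonically():
    """Median worst-case parameter error grows with the noise level."""
    spec = build_model(1)
    med = {}
    for cv in (0.0, 0.05, 0.2):
        errs = []
        for trial in range(6):
            data, truth = make_dataset(1, seed=500 + trial, noise_cv=cv,
                                       times=(0.0, 2.0, 10.0, 24.0))
            fit = fit_two_stage(spec, data, seed=trial, n_starts=2)
            e = recovered_relative_errors(spec, truth["true_rates"], fit.all_params)
            errs.append(max(e.values()))
        med[cv] = float(np.median(errs))
    assert med[0.0] <= med[0.05] <= med[0.2]


def test_stage_parameter_name_layout():
    assert stage1_parameter_names(build_model(1)) == ["dm_GR", "dp_GR", "k_act", "a_auto"]
    assert stage1_parameter_names(build_model(5)) == ["dm_GR", "dp_GR", "k_act"]
    assert set(stage2_parameter_names(build_model(4))) == {
        "dm_Erg", "dp_Erg", "a_Erg_GR", "a_GR_Erg"}
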