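"""Simulator behaviour: steady states, closed forms, monotonicity, export."""

import numpy as np
import pytest

from grkin.errors import ValidationError
from grkin.experiments import closed_form_max_rel_err
from grkin.models import build_model
from grkin.simulate import SimulationResult, fold_change_at, simulate

from conftest import make_params


@pytest.mark.parametrize("mid", range(1, 7))
def test_unstimulated_system_stays_flat(mid):
    spec = build_model(mid)
    params = make_params(mid, seed=mid)
    sim = simulate(spec, params, times=np.linspace(0, 48, 25), stimulus_on=False)
    for y in sim.fold.values():
        assert np.max(np.abs(y - 1.0)) < 1e-9


def test_single_gene_matches_closed_form():
    # mrna(t) = s/dm + (1 - s/dm) e^(-dm t), relative error < 1e-6 on [0, 48]
    assert closed_form_max_rel_err(s=0.05, dm=0.2) < 1e-6
    assert closed_form_max_rel_err(s=0.3, dm=0.08) < 1e-6


@pytest.mark.parametrize("mid", range(1, 7))
def test_trajectories_never_negative(mid):
    spec = build_model(mid)
    params = make_params(mid, seed=100 + mid)
    sim = simulate(spec, params, times=np.linspace(0, 24, 121))
    assert sim.raw.min() >= 0.0
    assert all(y.min() >= 0.0 for y in sim.fold.values())


def test_observables_start_at_one_and_exclude_latent():
    sim = simulate(build_model(2), make_params(2, seed=5))
    for (gene, level), y in sim.fold.items():
        assert gene != "X"
        assert y[0] == pytest.approx(1.0, abs=1e-12)


def test_grid_refinement_stability():
    spec = build_model(1)
    params = make_params(1, seed=9)
    coarse = simulate(spec, params, times=np.arange(0, 24.01, 0.2))
    fine = simulate(spec, params, times=np.arange(0, 24.01, 0.1))
    # query at shared grid points: refinement must not perturb the solution
    for sp in coarse.fold:
        for t in (3.6, 11.4, 21.2):
            a = fold_change_at(coarse, sp, t)
            b = fold_change_at(fine, sp, t)
            assert a == pytest.approx(b, rel=1e-6)


def test_saturating_activation_is_monotone():
    # Model 5 with every activation rate at the upper bound: both GR and
    # Erg rise monotonically over the horizon
    spec = build_model(5)
    params = make_params(5, seed=3)
    params.stimulus_activation = 1.0
    params.edge_rates[("GR", "Erg")] = 1.0
    sim = simulate(spec, params, times=np.linspace(0, 24, 241))
    for y in sim.fold.values():
        assert np.all(np.diff(y) >= -1e-9)


@pytest.mark.parametrize("mid", [1, 2, 5, 6])
def test_stronger_stimulus_never_decreases_cascade_output(mid):
    # pure activation cascades: trajectories are pointwise non-decreasing
    # in the stimulus-activation rate
    spec = build_model(mid)
    params = make_params(mid, seed=40 + mid)
    times = np.linspace(0, 24, 49)
    prev = None
    for k_act in (0.1, 0.4, 0.9):
        params.stimulus_activation = k_act
        sim = simulate(spec, params, times=times)
        if prev is not None:
            for sp in sim.fold:
                assert np.all(sim.fold[sp] >= prev[sp] - 1e-7)
        prev = {sp: y.copy() for sp, y in sim.fold.items()}


class TestFoldChangeAt:
    def test_normalization_anchor_and_flat(self):
        sim = simulate(build_model(3), make_params(3, seed=2), stimulus_on=False)
        assert fold_change_at(sim, ("GR", "mrna"), 0.0) == 1.0
        assert fold_change_at(sim, ("Erg", "protein"), 12.0) == pytest.approx(1.0, abs=1e-9)

    def test_linear_interpolation_midpoint(self):
        spec = build_model(3)
        params = make_params(3, seed=2)
        res = SimulationResult(
            times=np.array([0.0, 10.0, 14.0]),
            fold={("GR", "protein"): np.array([1.0, 2.0, 4.0])},
            raw=np.zeros((5, 3)), spec=spec, params=params, stimulus_on=True)
        assert fold_change_at(res, ("GR", "protein"), 12.0) == pytest.approx(3.0)

    def test_errors(self):
        sim = simulate(build_model(1), make_params(1, seed=2))
        with pytest.raises(ValidationError, match="unknown observable"):
            fold_change_at(sim, ("X", "protein"), 2.0)
        with pytest.raises(ValidationError, match="outside"):
            fold_change_at(sim, ("GR", "protein"), 99.0)


def test_tidy_export_schema():
    sim = simulate(build_model(1), make_params(1, seed=2), times=np.array([0.0, 2.0, 10.0]))
    df = sim.to_frame()
    assert list(df.columns) == ["time_h", "species", "level_fold"]
    assert set(df["species"]) == {
        "GR_mrna", "GR_protein", "cJun_mrna", "cJun_protein", "Bim_mrna", "Bim_protein"}
    assert len(df) == 6 * 3


def test_bad_time_grids_rejected():
    spec = build_model(1)
    params = make_params(1, seed=2)
    with pytest.raises(ValidationError):
        simulate(spec, params, times=[2.0, 10.0])  # must start at 0
    with pytest.raises(ValidationError):
        simulate(spec, params, times=[0.0, 5.0, 5.0])  # strictly increasing
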