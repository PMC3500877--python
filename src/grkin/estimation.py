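"""Two-stage bounded least-squares estimation and the residual statistic.

Fitting follows the study's procedure: the GR subsystem (basal synthesis,
mRNA/protein degradation, stimulus activation and — where present —
autoregulation) is estimated first against the GR observables alone;
the remaining rates are then estimated with the stage-1 values frozen.
All estimated rates are bounded to [0.01, 1] h^-1 and fits are scored by
the least-square residual

    epsilon = (1/n) * sum_i ((y_i - Y_i) / Y_i)**2

with y_i the experimental values, Y_i the simulated values and n the
number of experimental data points — note the denominator is the
*simulated* value.  Optimisation minimises the same normalized
deviations (sum over observables), via a seeded Latin-hypercube
multi-start of scipy's bounded trust-region-reflective least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import FitError, SimulationError, ValidationError
from .models import (
    ACTIVATION,
    LATENT_TURNOVER,
    PARAM_BOUNDS,
    ModelSpec,
    RateParameters,
    build_model,
    gr_submodel,
)
from .simulate import simulate

__all__ = [
    "TimeCourseDataset",
    "Stage1Fit",
    "FitResult",
    "residual_epsilon",
    "stage1_parameter_names",
    "stage2_parameter_names",
    "assemble_params",
    "named_to_params",
    "identifiable_quantities",
    "recovered_relative_errors",
    "fit_stage1_gr",
    "fit_stage2",
    "fit_two_stage",
    "DEFAULT_N_STARTS",
]

#: Default number of seeded Latin-hypercube starts per stage.
DEFAULT_N_STARTS = 24

REQUIRED_COLUMNS = ("gene", "level", "time_h", "replicate", "value_fold")
_LEVELS = ("protein", "mrna")
_FLAT_TOL = 1e-12
_PENALTY = 1e3


class TimeCourseDataset:
    """Replicate fold-change measurements per (gene, level) observable.

    Wraps a tidy DataFrame with columns gene, level {protein|mrna},
    time_h, replicate, value_fold.  Values are folds of the untreated
    t=0 control, so every observable is exactly 1 at t=0.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"dataset missing columns {missing}")
        if len(df) == 0:
            raise ValidationError("no data: dataset is empty")
        if df["value_fold"].le(0).any():
            bad = df.index[df["value_fold"].le(0)][0]
            raise ValidationError(f"non-positive value_fold at row {bad}")
        if not df["level"].isin(_LEVELS).all():
            bad = sorted(set(df["level"]) - set(_LEVELS))
            raise ValidationError(f"unknown levels {bad}; expected {list(_LEVELS)}")
        dup = df.duplicated(subset=["gene", "level", "time_h", "replicate"])
        if dup.any():
            raise ValidationError(f"duplicate (gene, level, time, replicate) at row {df.index[dup][0]}")
        at0 = df[df["time_h"] == 0.0]
        if len(at0) and not np.allclose(at0["value_fold"], 1.0, atol=1e-9):
            raise ValidationError("t=0 values must equal 1 (fold-of-control normalization)")

    # -- accessors ---------------------------------------------------------
    def observables(self) -> List[Tuple[str, str]]:
        seen = self.frame[["gene", "level"]].drop_duplicates()
        return [tuple(r) for r in seen.itertuples(index=False)]

    def times(self) -> np.ndarray:
        return np.sort(self.frame["time_h"].unique())

    def means(self, gene: str, level: str) -> Tuple[np.ndarray, np.ndarray]:
        sub = self.frame[(self.frame["gene"] == gene) & (self.frame["level"] == level)]
        g = sub.groupby("time_h")["value_fold"].mean().sort_index()
        return g.index.to_numpy(dtype=float), g.to_numpy(dtype=float)

    def sds(self, gene: str, level: str) -> Tuple[np.ndarray, np.ndarray]:
        sub = self.frame[(self.frame["gene"] == gene) & (self.frame["level"] == level)]
        g = sub.groupby("time_h")["value_fold"].std(ddof=1).sort_index()
        return g.index.to_numpy(dtype=float), g.to_numpy(dtype=float)

    def n_points(self, gene: str, level: str) -> int:
        t, _ = self.means(gene, level)
        return len(t)

    def restrict(self, genes: Iterable[str]) -> "TimeCourseDataset":
        genes = set(genes)
        sub = self.frame[self.frame["gene"].isin(genes)]
        if len(sub) == 0:
            raise ValidationError(f"no observables for genes {sorted(genes)}")
        return TimeCourseDataset(sub)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeCourseDataset):
            return NotImplemented
        a = self.frame.sort_values(list(REQUIRED_COLUMNS)).reset_index(drop=True)
        b = other.frame.sort_values(list(REQUIRED_COLUMNS)).reset_index(drop=True)
        return a[list(REQUIRED_COLUMNS)].equals(b[list(REQUIRED_COLUMNS)])


def residual_epsilon(y: Sequence[float], Y: Sequence[float]) -> float:
    """Least-square residual epsilon = (1/n) sum ((y_i - Y_i)/Y_i)^2.

    ``y`` are experimental values, ``Y`` the simulated values at the same
    times; the denominator is the simulated value.  Undefined when any
    simulated value is (near) zero.
    """
    y = np.asarray(y, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if y.shape != Y.shape or y.ndim != 1 or y.size < 1:
        raise ValidationError("y and Y must be equal-length 1-D vectors, n >= 1")
    if np.any(np.abs(Y) < 1e-9):
        raise ValidationError("residual undefined at near-zero simulated value")
    r = (y - Y) / Y
    return float(np.mean(r * r))


# --------------------------------------------------------------------------
# Free-parameter layout
# --------------------------------------------------------------------------

def stage1_parameter_names(spec: ModelSpec) -> List[str]:
    names = ["dm_GR", "dp_GR", "k_act"]
    if spec.gr_autoregulation:
        names.append("a_auto")
    return names

def stage2_parameter_names(spec: ModelSpec) -> List[str]:
    names: List[str] = []
    for g in spec.observable_genes:
        if g == "GR":
            continue
        names += [f"dm_{g}", f"dp_{g}"]
    for e in spec.edges:
        names.append(f"a_{e.source}_{e.target}")
    return names


def assemble_params(
    spec: ModelSpec,
    named: Dict[str, float],
    latent_turnover: float = LATENT_TURNOVER,
) -> Tuple[RateParameters, float]:
    """Build RateParameters from named rates (dm_*, dp_*, a_*_*, k_act, a_auto).

    Returns ``(params, penalty)`` where penalty > 0 measures how far a
    derived basal synthesis fell below zero (basally active inflow
    exceeding degradation); in that case the synthesis is clipped to 0
    and the optimiser is charged the penalty.
    """
    dm = {}
    dp = {}
    for g in spec.observable_genes:
        try:
            dm[g] = named[f"dm_{g}"]
            dp[g] = named[f"dp_{g}"]
        except KeyError as exc:
            raise ValidationError(f"missing rate {exc.args[0]!r} for model {spec.model_id}")
    edge_rates = {}
    for e in spec.edges:
        key = f"a_{e.source}_{e.target}"
        if key not in named:
            raise ValidationError(f"missing rate {key!r}")
        edge_rates[(e.source, e.target)] = named[key]
    auto = named.get("a_auto", 0.0)
    if spec.gr_autoregulation and "a_auto" not in named:
        raise ValidationError("missing rate 'a_auto' for autoregulating model")
    if "k_act" not in named:
        raise ValidationError("missing rate 'k_act'")
    params = RateParameters.balanced(
        spec, dm, dp, edge_rates,
        stimulus_activation=named["k_act"],
        autoregulation_rate=auto,
        latent_turnover=latent_turnover,
        strict=False,
    )
    penalty = 0.0
    for g in spec.observable_genes:
        inflow = sum(
            edge_rates[(e.source, e.target)]
            for e in spec.edges_into(g)
            if e.sign == ACTIVATION and e.source != "GR" and e.source not in spec.latent_species
        )
        removal = sum(
            edge_rates[(e.source, e.target)]
            for e in spec.edges_into(g)
            if e.sign != ACTIVATION and e.source != "GR" and e.source not in spec.latent_species
        )
        deficit = inflow - removal - dm[g]
        if deficit > 0:
            penalty += deficit
    return params, penalty


def named_to_params(spec: ModelSpec, named: Dict[str, float]) -> RateParameters:
    """Strict variant of :func:`assemble_params` for user-supplied parameter files."""
    params, penalty = assemble_params(spec, named)
    if penalty > 0:
        raise ValidationError(
            "basally active regulation exceeds target degradation; "
            "derived basal synthesis would be negative")
    return params


# --------------------------------------------------------------------------
# Identifiability bookkeeping
# --------------------------------------------------------------------------

def identifiable_quantities(spec: ModelSpec) -> List[str]:
    """Names of rates (or rate products) structurally identifiable from data.

    A gene's degradation rates are identifiable only if its observable
    responds to the stimulus (GR mRNA is flat without autoregulation;
    an unregulated downstream gene is flat entirely).  The two rates of
    a chain through the unobserved intermediate X trade off against the
    arbitrary scale of X, so only their product is identifiable; it is
    reported as ``"a_GR_X*a_X_<target>"``.
    """
    out: List[str] = ["dp_GR", "k_act"]
    if spec.gr_autoregulation:
        out += ["dm_GR", "a_auto"]
    dynamic = {g: bool(spec.edges_into(g)) for g in spec.genes}
    if spec.gr_autoregulation:
        dynamic["GR"] = True
    for g in spec.observable_genes:
        if g == "GR":
            continue
        if dynamic[g]:
            out += [f"dm_{g}", f"dp_{g}"]
    x_chain: Dict[str, str] = {}
    for e in spec.edges:
        if e.target in spec.latent_species:
            continue
        if e.source in spec.latent_species:
            x_chain[e.source] = e.target
            continue
        out.append(f"a_{e.source}_{e.target}")
    for x, tgt in x_chain.items():
        out.append(f"a_GR_{x}*a_{x}_{tgt}")
    return out


def recovered_relative_errors(
    spec: ModelSpec, truth: Dict[str, float], fitted: Dict[str, float]
) -> Dict[str, float]:
    """|fitted - true| / true for every identifiable quantity."""
    def value(named: Dict[str, float], q: str) -> float:
        if "*" in q:
            a, b = q.split("*")
            return named[a] * named[b]
        return named[q]

    errs = {}
    for q in identifiable_quantities(spec):
        tv = value(truth, q)
        errs[q] = abs(value(fitted, q) - tv) / abs(tv)
    return errs


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

@dataclass
class Stage1Fit:
    """GR-submodel rates from stage 1, with optimiser diagnostics."""

    params: Dict[str, float]
    cost: float
    converged: bool
    non_identifiable: Tuple[str, ...]
    n_starts: int
    seed: int


@dataclass
class FitResult:
    """Outcome of the full two-stage fit of one topology to one dataset."""

    model_id: int
    stage1_params: Dict[str, float]
    stage2_params: Dict[str, float]
    params: RateParameters
    epsilon_by_observable: Dict[Tuple[str, str], float]
    total_epsilon: float
    n_starts: int
    converged: bool
    seed: int
    non_identifiable: Tuple[str, ...] = ()

    @property
    def all_params(self) -> Dict[str, float]:
        out = dict(self.stage1_params)
        out.update(self.stage2_params)
        return out


def _flat_observables(data: TimeCourseDataset) -> List[str]:
    flags = []
    for gene, level in data.observables():
        t, m = data.means(gene, level)
        if len(t) < 2 or np.ptp(m) <= _FLAT_TOL:
            flags.append(f"{gene}.{level}")
    return flags


def _residual_vector(
    spec: ModelSpec,
    named: Dict[str, float],
    data: TimeCourseDataset,
    observables: List[Tuple[str, str]],
    times: np.ndarray,
    stimulus_on: bool,
) -> np.ndarray:
    params, penalty = assemble_params(spec, named)
    try:
        sim = simulate(spec, params, times=times, stimulus_on=stimulus_on, rtol=1e-8)
    except SimulationError:
        return np.full(sum(data.n_points(*o) for o in observables) + 1, 1e6)
    parts = []
    for gene, level in observables:
        t, y = data.means(gene, level)
        Y = np.interp(t, sim.times, sim.fold[(gene, level)])
        Y = np.where(np.abs(Y) < 1e-9, 1e-9, Y)
        parts.append((y - Y) / Y)
    parts.append(np.array([_PENALTY * penalty]))
    return np.concatenate(parts)


def _multi_start(
    residual_fn,
    names: List[str],
    seed: int,
    n_starts: int,
    bounds=PARAM_BOUNDS,
):
    """Seeded Latin-hypercube multi-start; ties broken by lower L2 norm."""
    lo, hi = bounds
    d = len(names)
    sampler = qmc.LatinHypercube(d=d, seed=int(seed) % (2**31))
    # keep starts strictly interior
    starts = lo + (hi - lo) * (0.02 + 0.96 * sampler.random(n_starts))
    best = None
    n_ok = 0
    for x0 in starts:
        try:
            sol = least_squares(residual_fn, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10,
                                max_nfev=200)
        except Exception:
            continue
        n_ok += 1
        cost = float(sol.cost)
        norm = float(np.linalg.norm(sol.x))
        if best is None or cost < best[0] - 1e-15 or (
            abs(cost - best[0]) <= 1e-15 and norm < best[1]
        ):
            best = (cost, norm, sol)
    if best is None:
        raise FitError(f"all {n_starts} optimisation starts failed for {names}")
    return best[2], n_ok


def fit_stage1_gr(
    spec: ModelSpec,
    data: TimeCourseDataset,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
    stimulus_on: bool = True,
) -> Stage1Fit:
    """Stage 1: estimate the GR subsystem against GR observables only.

    Fits dm_GR, dp_GR, k_act (and the autoregulation rate where the
    topology has the loop) on the GR-only submodel, bounded to [0.01, 1],
    from seeded Latin-hypercube starts.
    """
    gr_obs = [(g, l) for g, l in data.observables() if g == "GR"]
    if not gr_obs:
        raise FitError("no GR observables in dataset; stage 1 needs GR protein and/or mRNA")
    sub = gr_submodel(spec)
    gr_data = data.restrict(["GR"])
    names = stage1_parameter_names(spec)
    times = gr_data.times()
    flat = _flat_observables(gr_data)

    def residual(x):
        named = dict(zip(names, x))
        return _residual_vector(sub, named, gr_data, gr_obs, times, stimulus_on)

    sol, _ = _multi_start(residual, names, seed, n_starts)
    return Stage1Fit(
        params=dict(zip(names, map(float, sol.x))),
        cost=float(sol.cost),
        converged=bool(sol.status > 0),
        non_identifiable=tuple(flat),
        n_starts=n_starts,
        seed=seed,
    )


def fit_stage2(
    spec: ModelSpec,
    stage1: Stage1Fit,
    data: TimeCourseDataset,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
    stimulus_on: bool = True,
) -> FitResult:
    """Stage 2: estimate all remaining rates with stage-1 values frozen.

    The objective covers every observable in the dataset (GR included:
    in the crosstalk topology the Erg->GR edge feeds back on GR).
    Reports per-observable epsilon at the data's sample times and their
    arithmetic mean as ``total_epsilon``.
    """
    names = stage2_parameter_names(spec)
    observables = data.observables()
    known = {(g, l) for g in spec.observable_genes for l in _LEVELS}
    unknown = [o for o in observables if o not in known]
    if unknown:
        raise FitError(
            f"model {spec.model_id} has no observable(s) {unknown}; cannot score fit")
    times = data.times()
    fixed = dict(stage1.params)
    flat = _flat_observables(data)

    if names:
        def residual(x):
            named = dict(fixed)
            named.update(zip(names, x))
            return _residual_vector(spec, named, data, observables, times, stimulus_on)

        sol, _ = _multi_start(residual, names, seed + 1, n_starts)
        stage2 = dict(zip(names, map(float, sol.x)))
        converged = bool(sol.status > 0)
    else:
        stage2 = {}
        converged = True

    named = dict(fixed)
    named.update(stage2)
    params, _ = assemble_params(spec, named)
    sim = simulate(spec, params, times=times, stimulus_on=stimulus_on)
    eps: Dict[Tuple[str, str], float] = {}
    for gene, level in observables:
        t, y = data.means(gene, level)
        Y = np.interp(t, sim.times, sim.fold[(gene, level)])
        eps[(gene, level)] = residual_epsilon(y, Y)
    total = float(np.mean(list(eps.values())))
    return FitResult(
        model_id=spec.model_id,
        stage1_params=dict(stage1.params),
        stage2_params=stage2,
        params=params,
        epsilon_by_observable=eps,
        total_epsilon=total,
        n_starts=n_starts,
        converged=converged and stage1.converged,
        seed=seed,
        non_identifiable=tuple(flat),
    )


def fit_two_stage(
    spec: ModelSpec,
    data: TimeCourseDataset,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
) -> FitResult:
    """Convenience wrapper: stage 1 on GR, then stage 2 with GR frozen."""
    s1 = fit_stage1_gr(spec, data, seed=seed, n_starts=n_starts)
    return fit_stage2(spec, s1, data, seed=seed, n_starts=n_starts)
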