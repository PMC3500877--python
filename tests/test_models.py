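"""Topology catalogue, rate conversion and raw ODE behaviour."""

import math

import numpy as np
import pytest

from grkin.errors import SimulationError, ValidationError
from grkin.models import (
    MODEL_NAMES,
    ModelSpec,
    RateParameters,
    RegulatoryEdge,
    baseline_state,
    build_model,
    half_life_to_rate,
    odes,
    state_labels,
)

from conftest import make_params


class TestCatalogue:
    @pytest.mark.parametrize("mid", range(1, 7))
    def test_topology_invariants(self, mid):
        spec = build_model(mid)
        assert spec.model_id == mid
        # sensitive C7 models carry the autoregulation loop, resistant C1 do not
        if mid <= 4:
            assert spec.cell_line == "C7_sensitive" and spec.gr_autoregulation
        else:
            assert spec.cell_line == "C1_resistant" and not spec.gr_autoregulation
        # indirect topologies have exactly one latent intermediate
        assert spec.latent_species == (("X",) if mid in (2, 6) else ())
        genes = set(spec.genes)
        for e in spec.edges:
            assert e.source in genes and e.target in genes

    def test_exactly_six_models_addressable_by_name(self):
        assert len(MODEL_NAMES) == 6
        for mid, name in MODEL_NAMES.items():
            assert build_model(name).model_id == mid

    def test_model1_and_model2_wiring(self):
        m1 = build_model(1)
        assert {(e.source, e.target) for e in m1.edges} == {("GR", "cJun"), ("cJun", "Bim")}
        assert m1.gr_autoregulation and m1.latent_species == ()
        m2 = build_model(2)
        assert {(e.source, e.target) for e in m2.edges} == {
            ("GR", "X"), ("X", "cJun"), ("cJun", "Bim")}
        assert m2.latent_species == ("X",)
        # indirect variant adds exactly one extra mRNA/protein pair
        assert len(m2.genes) == len(m1.genes) + 1

    def test_model4_crosstalk_signs_configurable(self):
        default = build_model(4)
        signs = {(e.source, e.target): e.sign for e in default.edges}
        assert signs == {("Erg", "GR"): "activation", ("GR", "Erg"): "repression"}
        flipped = build_model(4, erg_to_gr="repression", gr_to_erg="activation")
        signs = {(e.source, e.target): e.sign for e in flipped.edges}
        assert signs == {("Erg", "GR"): "repression", ("GR", "Erg"): "activation"}

    @pytest.mark.parametrize("bad", [0, 7, -1, "nope"])
    def test_unknown_model_rejected(self, bad):
        with pytest.raises(ValidationError, match="unknown model"):
            build_model(bad)

    def test_edge_outside_gene_list_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(0, "C7_sensitive", ("GR",), (RegulatoryEdge("GR", "Bim"),),
                      gr_autoregulation=False)


class TestHalfLifeConversion:
    def test_reported_receptor_range(self):
        # the 27-42 h receptor half-life maps to 0.0257-0.0165 h^-1
        assert half_life_to_rate(42.0) == pytest.approx(0.0165, abs=5e-5)
        assert half_life_to_rate(27.0) == pytest.approx(0.0257, abs=5e-5)

    def test_identity_and_roundtrip(self):
        assert half_life_to_rate(math.log(2.0)) == pytest.approx(1.0, rel=1e-12)
        p = make_params(1, seed=3)
        g = "GR"
        assert half_life_to_rate(p.protein_half_life(g)) == pytest.approx(
            p.protein_deg[g], rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_nonpositive_half_life_rejected(self, bad):
        with pytest.raises(ValidationError):
            half_life_to_rate(bad)


def _single_gene(s, dm):
    spec = ModelSpec(0, "C7_sensitive", ("G",), (), gr_autoregulation=False)
    # note: deliberately allows s != dm so the mRNA moves
    params = RateParameters(
        mrna_deg={"G": dm}, protein_deg={"G": dm}, translation={"G": dm},
        basal_synthesis={"G": s}, edge_rates={}, stimulus_activation=0.0)
    return spec, params


class TestOdes:
    def test_single_gene_hand_values(self):
        spec, params = _single_gene(s=0.1, dm=0.1)
        d = odes(spec, params, [1.0, 1.0, 0.0], stimulus=0.0)
        assert d[0] == pytest.approx(0.0, abs=1e-15)   # balanced: s - dm*1 = 0
        d = odes(spec, params, [2.0, 1.0, 0.0], stimulus=0.0)
        assert d[0] == pytest.approx(-0.1, rel=1e-12)  # s - dm*2

    @pytest.mark.parametrize("mid", range(1, 7))
    def test_baseline_is_exact_steady_state(self, mid):
        spec = build_model(mid)
        params = make_params(mid, seed=mid)
        d = odes(spec, params, baseline_state(spec, params), stimulus=0.0)
        assert np.max(np.abs(d)) == 0.0

    def test_stimulated_activation_sign(self):
        # with hormone on and active receptor present, c-Jun transcription
        # outpaces degradation at baseline
        spec = build_model(1)
        params = make_params(1, seed=1)
        y = baseline_state(spec, params)
        y[-1] = 0.5  # some active GR
        d = odes(spec, params, y, stimulus=1.0)
        i_cjun_mrna = state_labels(spec).index("mrna_cJun")
        assert d[i_cjun_mrna] > 0

    def test_negative_state_rejected(self):
        spec = build_model(1)
        params = make_params(1, seed=1)
        y = baseline_state(spec, params)
        y[0] = -0.5
        with pytest.raises(SimulationError):
            odes(spec, params, y)


class TestRateParameters:
    def test_balanced_rejects_excess_basal_inflow(self):
        spec = build_model(1)
        with pytest.raises(ValidationError):
            # c-Jun protein is basally at 1, so an edge rate above Bim's
            # mRNA degradation leaves no room for positive basal synthesis
            RateParameters.balanced(
                spec,
                mrna_deg={"GR": 0.2, "cJun": 0.2, "Bim": 0.1},
                protein_deg={"GR": 0.05, "cJun": 0.1, "Bim": 0.1},
                edge_rates={("GR", "cJun"): 0.3, ("cJun", "Bim"): 0.5},
                autoregulation_rate=0.05)

    def test_bounds_validation(self):
        spec = build_model(5)
        params = make_params(5, seed=2)
        params.edge_rates[("GR", "Erg")] = 1.5
        with pytest.raises(ValidationError, match="bounds"):
            params.validate_bounds(spec)
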