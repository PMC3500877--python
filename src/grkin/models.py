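"""Catalogue of the six GR-signalling network topologies and their mass-action ODEs.

The models describe dexamethasone-driven glucocorticoid receptor (GR)
signalling in acute lymphoblastic leukemia cell lines:

* Models 1-2 (GC-sensitive C7 cells): GR drives Bim through c-Jun, either
  directly (Model 1) or through de novo synthesis of a latent intermediate
  protein X (Model 2). Both include positive GR autoregulation.
* Models 3-4 (C7 cells): GR autoregulation alone (Model 3) or mutual
  GR/Erg crosstalk (Model 4: Erg protein activates GR transcription while
  active GR represses Erg transcription).
* Models 5-6 (GC-resistant C1 cells, no GR autoregulation): Erg as a
  direct GR target (Model 5) or an indirect one via protein X (Model 6).

Every gene is a two-tier species pair (mRNA, protein) with first-order
mass-action synthesis, translation and degradation.  The hormone stimulus
is a step input D(t) that converts GR protein into an active form "GRa"
at rate k_act*D; GRa is the transcriptionally competent species, so every
regulatory edge leaving GR uses GRa as its source.  Measured GR protein is
the total of inactive and active forms.  All concentrations are fold
changes over the untreated t=0 baseline, so every observable species sits
at exactly 1 before the stimulus; basal synthesis rates are derived to
balance degradation (and any basally active regulation) at that baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import SimulationError, ValidationError

__all__ = [
    "ACTIVATION",
    "REPRESSION",
    "PARAM_BOUNDS",
    "MODEL_NAMES",
    "RegulatoryEdge",
    "ModelSpec",
    "RateParameters",
    "build_model",
    "gr_submodel",
    "half_life_to_rate",
    "baseline_state",
    "make_rhs",
    "odes",
    "state_labels",
]

ACTIVATION = "activation"
REPRESSION = "repression"

#: Bounds imposed on every estimated rate constant, in h^-1.
PARAM_BOUNDS = (0.01, 1.0)

#: Default turnover (mRNA/protein degradation and translation) of the
#: latent intermediate X, fixed rather than estimated because X is never
#: observed; mid-range of the estimation bounds.
LATENT_TURNOVER = 0.1

MODEL_NAMES = {
    1: "c7_jun_direct",
    2: "c7_jun_indirect",
    3: "c7_erg_auto",
    4: "c7_erg_crosstalk",
    5: "c1_erg_direct",
    6: "c1_erg_indirect",
}
_NAME_TO_ID = {v: k for k, v in MODEL_NAMES.items()}

C7 = "C7_sensitive"
C1 = "C1_resistant"


def half_life_to_rate(t_half: float) -> float:
    """First-order rate constant k = ln(2) / half-life.

    Parameters
    ----------
    t_half : float
        Half-life in hours; must be positive.

    Returns
    -------
    float
        Rate in h^-1.  E.g. the 27-42 h GR protein half-life maps to
        0.0257-0.0165 h^-1.
    """
    if not np.isfinite(t_half) or t_half <= 0:
        raise ValidationError(f"half-life must be positive and finite, got {t_half!r}")
    return math.log(2.0) / float(t_half)


@dataclass(frozen=True)
class RegulatoryEdge:
    """A directed transcriptional edge: *source* protein acting on *target* mRNA.

    Activation adds a synthesis term a_e * [source protein]; repression
    adds a second-order removal term a_e * [source protein] * [target mRNA].
    Edges whose source is GR act through the active receptor GRa.
    """

    source: str
    target: str
    sign: str = ACTIVATION

    def __post_init__(self):
        if self.sign not in (ACTIVATION, REPRESSION):
            raise ValidationError(f"edge sign must be activation|repression, got {self.sign!r}")


@dataclass(frozen=True)
class ModelSpec:
    """One network topology: genes, regulatory edges, autoregulation flag.

    ``model_id`` 1-6 addresses the published catalogue; 0 marks ad-hoc
    specs (submodels, test fixtures).  ``latent_species`` lists genes that
    are never compared to data (the de novo protein X).
    """

    model_id: int
    cell_line: str
    genes: Tuple[str, ...]
    edges: Tuple[RegulatoryEdge, ...]
    gr_autoregulation: bool
    latent_species: Tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "edges", tuple(self.edges))
        object.__setattr__(self, "latent_species", tuple(self.latent_species))
        if self.model_id not in (0, 1, 2, 3, 4, 5, 6):
            raise ValidationError(f"unknown model id {self.model_id!r}")
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ValidationError("duplicate gene names")
        for e in self.edges:
            if e.source not in gene_set or e.target not in gene_set:
                raise ValidationError(
                    f"edge {e.source}->{e.target} references a gene outside {sorted(gene_set)}"
                )
        for x in self.latent_species:
            if x not in gene_set:
                raise ValidationError(f"latent species {x!r} not in gene list")

    @property
    def observable_genes(self) -> Tuple[str, ...]:
        return tuple(g for g in self.genes if g not in self.latent_species)

    def edges_into(self, gene: str) -> Tuple[RegulatoryEdge, ...]:
        return tuple(e for e in self.edges if e.target == gene)


def build_model(
    model_id,
    erg_to_gr: str = ACTIVATION,
    gr_to_erg: str = REPRESSION,
) -> ModelSpec:
    """Return one of the six catalogued topologies by id (1-6) or name.

    ``erg_to_gr`` / ``gr_to_erg`` configure the signs of Model 4's two
    crosstalk edges (the default wiring — Erg activates GR transcription,
    active GR represses Erg transcription — is the simplest first-order
    scheme reproducing attenuated GR induction together with a
    below-baseline Erg dip).
    """
    if isinstance(model_id, str):
        if model_id not in _NAME_TO_ID:
            raise ValidationError(f"unknown model {model_id!r}")
        model_id = _NAME_TO_ID[model_id]
    if model_id not in MODEL_NAMES:
        raise ValidationError(f"unknown model {model_id!r} (valid ids: 1-6)")

    if model_id == 1:
        spec = ModelSpec(1, C7, ("GR", "cJun", "Bim"),
                         (RegulatoryEdge("GR", "cJun"), RegulatoryEdge("cJun", "Bim")),
                         gr_autoregulation=True)
    elif model_id == 2:
        spec = ModelSpec(2, C7, ("GR", "X", "cJun", "Bim"),
                         (RegulatoryEdge("GR", "X"), RegulatoryEdge("X", "cJun"),
                          RegulatoryEdge("cJun", "Bim")),
                         gr_autoregulation=True, latent_species=("X",))
    elif model_id == 3:
        # Erg is carried as a basally expressed, unregulated species.
        spec = ModelSpec(3, C7, ("GR", "Erg"), (), gr_autoregulation=True)
    elif model_id == 4:
        spec = ModelSpec(4, C7, ("GR", "Erg"),
                         (RegulatoryEdge("Erg", "GR", erg_to_gr),
                          RegulatoryEdge("GR", "Erg", gr_to_erg)),
                         gr_autoregulation=True)
    elif model_id == 5:
        spec = ModelSpec(5, C1, ("GR", "Erg"), (RegulatoryEdge("GR", "Erg"),),
                         gr_autoregulation=False)
    else:
        spec = ModelSpec(6, C1, ("GR", "X", "Erg"),
                         (RegulatoryEdge("GR", "X"), RegulatoryEdge("X", "Erg")),
                         gr_autoregulation=False, latent_species=("X",))
    return replace(spec, name=MODEL_NAMES[model_id])


def gr_submodel(spec: ModelSpec) -> ModelSpec:
    """The GR-only subsystem used for stage-1 estimation.

    Keeps GR, the stimulus activation step and (if present) the
    autoregulation loop; drops every other gene and edge.
    """
    return ModelSpec(0, spec.cell_line, ("GR",), (),
                     gr_autoregulation=spec.gr_autoregulation,
                     name=f"{spec.name or spec.model_id}_gr_submodel")


@dataclass
class RateParameters:
    """Kinetic constants for one topology, all in h^-1 (concentrations are folds).

    Per gene: basal mRNA synthesis ``s_g``, mRNA degradation ``dm_g``,
    translation ``tl_g``, protein degradation ``dp_g``.  Per regulatory
    edge: an activation/repression rate.  Global: the stimulus-activation
    rate ``k_act`` (GR protein -> active GRa under hormone) and, for
    autoregulating topologies, the GR->GR mRNA rate.

    ``balanced`` derives ``s_g`` and ``tl_g`` so that the pre-stimulus
    state (observables at 1, latent species and GRa at 0) is an exact
    steady state — the fold-change normalisation convention removes these
    degrees of freedom.
    """

    mrna_deg: Dict[str, float]
    protein_deg: Dict[str, float]
    translation: Dict[str, float]
    basal_synthesis: Dict[str, float]
    edge_rates: Dict[Tuple[str, str], float]
    stimulus_activation: float
    autoregulation_rate: float = 0.0

    @classmethod
    def balanced(
        cls,
        spec: ModelSpec,
        mrna_deg: Dict[str, float],
        protein_deg: Dict[str, float],
        edge_rates: Optional[Dict[Tuple[str, str], float]] = None,
        stimulus_activation: float = 0.1,
        autoregulation_rate: float = 0.0,
        latent_turnover: float = LATENT_TURNOVER,
        strict: bool = True,
    ) -> "RateParameters":
        """Build parameters with basal rates balancing the unit baseline.

        For each observable gene ``s_g = dm_g - (basally active inflow) +
        (basally active removal)`` and ``tl_g = dp_g``; latent genes get
        ``s = 0`` and the fixed ``latent_turnover`` for all turnover rates.
        With ``strict`` a negative derived ``s_g`` raises; otherwise it is
        clipped to 0 (the fit penalises such combinations instead).
        """
        edge_rates = dict(edge_rates or {})
        dm = dict(mrna_deg)
        dp = dict(protein_deg)
        tl: Dict[str, float] = {}
        s: Dict[str, float] = {}
        for g in spec.genes:
            if g in spec.latent_species:
                dm[g] = dp[g] = tl[g] = latent_turnover
                s[g] = 0.0
                continue
            if g not in dm or g not in dp:
                raise ValidationError(f"missing degradation rates for gene {g!r}")
            tl[g] = dp[g]
            inflow = 0.0
            removal = 0.0
            for e in spec.edges_into(g):
                a = edge_rates.get((e.source, e.target))
                if a is None:
                    raise ValidationError(f"missing rate for edge {e.source}->{e.target}")
                src0 = _baseline_source_level(spec, e.source)
                if e.sign == ACTIVATION:
                    inflow += a * src0
                else:
                    removal += a * src0  # * baseline mRNA (=1)
            s_g = dm[g] * 1.0 - inflow + removal
            if s_g < 0:
                if strict:
                    raise ValidationError(
                        f"basally active regulation into {g!r} exceeds degradation "
                        f"(derived basal synthesis {s_g:.4g} < 0)"
                    )
                s_g = 0.0
            s[g] = s_g
        return cls(dm, dp, tl, s, edge_rates, stimulus_activation, autoregulation_rate)

    def protein_half_life(self, gene: str) -> float:
        """Derived view t_half = ln(2)/dp_g, hours."""
        return math.log(2.0) / self.protein_deg[gene]

    def estimated_rates(self, spec: ModelSpec) -> Dict[str, float]:
        """The rates subject to the [0.01, 1] estimation bounds, by name."""
        out: Dict[str, float] = {"k_act": self.stimulus_activation}
        if spec.gr_autoregulation:
            out["a_auto"] = self.autoregulation_rate
        for g in spec.observable_genes:
            out[f"dm_{g}"] = self.mrna_deg[g]
            out[f"dp_{g}"] = self.protein_deg[g]
        for e in spec.edges:
            out[f"a_{e.source}_{e.target}"] = self.edge_rates[(e.source, e.target)]
        return out

    def validate_bounds(self, spec: ModelSpec, bounds=PARAM_BOUNDS) -> None:
        lo, hi = bounds
        for name, v in self.estimated_rates(spec).items():
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValidationError(f"rate {name}={v:.4g} outside bounds [{lo}, {hi}]")


def _baseline_source_level(spec: ModelSpec, source: str) -> float:
    """Pre-stimulus level of an edge's effective source species.

    GR-sourced edges act through GRa (0 before stimulus); latent genes
    start at 0; every other protein starts at its unit baseline.
    """
    if source == "GR":
        return 0.0
    if source in spec.latent_species:
        return 0.0
    return 1.0


def state_labels(spec: ModelSpec) -> List[str]:
    """Flat state-vector layout: [mrna_g, protein_g per gene ...] + [GRa]."""
    labels: List[str] = []
    for g in spec.genes:
        labels.append(f"mrna_{g}")
        labels.append(f"protein_{g}")
    labels.append("GRa")
    return labels


def baseline_state(spec: ModelSpec, params: RateParameters) -> np.ndarray:
    """Pre-stimulus steady state: observables at 1, latent species and GRa at 0."""
    y0 = np.empty(2 * len(spec.genes) + 1)
    for i, g in enumerate(spec.genes):
        v = 0.0 if g in spec.latent_species else 1.0
        y0[2 * i] = v
        y0[2 * i + 1] = v
    y0[-1] = 0.0
    return y0


def make_rhs(spec: ModelSpec, params: RateParameters, stimulus: float):
    """Compile the mass-action right-hand side for one topology.

    Returns ``f(t, y) -> dy`` over the ``state_labels`` layout.  The
    stimulus D is constant over an integration leg (step input switched
    at t=0, so each leg sees D=0 or D=1).
    """
    genes = spec.genes
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    s = np.array([params.basal_synthesis[g] for g in genes])
    dm = np.array([params.mrna_deg[g] for g in genes])
    tl = np.array([params.translation[g] for g in genes])
    dp = np.array([params.protein_deg[g] for g in genes])
    # ad-hoc specs without a GR gene (single-gene fixtures) have an inert
    # activation pool: GRa stays wherever it starts
    gr = idx.get("GR")
    igra = 2 * n
    kact = params.stimulus_activation * stimulus if gr is not None else 0.0
    dp_gr = params.protein_deg["GR"] if gr is not None else 0.0

    # (source state index or GRA sentinel, target gene index, rate, is_repression)
    GRA = -1
    terms = []
    for e in spec.edges:
        a = params.edge_rates[(e.source, e.target)]
        src = GRA if e.source == "GR" else 2 * idx[e.source] + 1
        terms.append((src, idx[e.target], a, e.sign == REPRESSION))
    if spec.gr_autoregulation:
        terms.append((GRA, gr, params.autoregulation_rate, False))

    def rhs(t, y):
        m = y[0:2 * n:2]
        p = y[1:2 * n:2]
        gra = y[igra]
        dmdt = s - dm * m
        dpdt = tl * m - dp * p
        for src, tgt, a, rep in terms:
            level = gra if src == GRA else y[src]
            if rep:
                dmdt[tgt] -= a * level * m[tgt]
            else:
                dmdt[tgt] += a * level
        dy = np.empty_like(y)
        dy[0:2 * n:2] = dmdt
        dy[1:2 * n:2] = dpdt
        dy[igra] = (kact * p[gr] - dp_gr * gra) if gr is not None else 0.0
        return dy

    return rhs


def odes(
    spec: ModelSpec,
    params: RateParameters,
    state: Sequence[float],
    t: float = 0.0,
    stimulus: float = 1.0,
) -> np.ndarray:
    """Evaluate the model's state derivative at one point.

    Rejects negative state components (an integration fault upstream);
    a tiny negative round-off margin of 1e-9 is tolerated.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (2 * len(spec.genes) + 1,):
        raise ValidationError(
            f"state length {y.size} != {2 * len(spec.genes) + 1} for {len(spec.genes)} genes"
        )
    if np.any(y < -1e-9):
        raise SimulationError("negative state component passed to odes",
                              model_id=spec.model_id, params=params)
    return make_rhs(spec, params, stimulus)(t, y)
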