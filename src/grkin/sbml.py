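"""SBML Level 3 export/import of the mass-action models.

The exporter writes one species per state variable (mRNA/protein per
gene, plus the active receptor GRa), one reaction per mass-action term
(basal synthesis, degradation, translation, regulatory edges, stimulus
activation) and global parameters in h^-1; the hormone step input is the
constant parameter ``D``.  Kinetic laws are plain products of a rate
constant with species concentrations, so the importer only needs a
restricted MathML subset (``<ci>`` and ``<apply><times/>``) to rebuild
the exact right-hand side; the round trip reproduces the native ODEs to
floating-point agreement.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from lxml import etree

from .errors import ValidationError
from .models import ACTIVATION, ModelSpec, RateParameters, state_labels

__all__ = ["export_sbml", "rhs_from_sbml", "validate_sbml", "roundtrip_rhs_error"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _species_id(gene: str, level: str) -> str:
    return f"{level}_{gene}"


def _math(*factors: str) -> etree._Element:
    math = etree.Element(f"{{{MATHML_NS}}}math")
    if len(factors) == 1:
        ci = etree.SubElement(math, f"{{{MATHML_NS}}}ci")
        ci.text = f" {factors[0]} "
    else:
        apply = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply, f"{{{MATHML_NS}}}times")
        for f in factors:
            ci = etree.SubElement(apply, f"{{{MATHML_NS}}}ci")
            ci.text = f" {f} "
    return math


class _ModelWriter:
    def __init__(self, spec: ModelSpec, params: RateParameters, stimulus_on: bool):
        self.spec = spec
        self.params = params
        self.root = etree.Element(f"{{{SBML_NS}}}sbml",
                                  nsmap={None: SBML_NS}, level="3", version="2")
        self.model = etree.SubElement(self.root, f"{{{SBML_NS}}}model",
                                      id=f"grkin_model_{spec.model_id}",
                                      name=spec.name or f"model_{spec.model_id}")
        units = etree.SubElement(self.model, f"{{{SBML_NS}}}listOfUnitDefinitions")
        per_hour = etree.SubElement(units, f"{{{SBML_NS}}}unitDefinition", id="per_hour")
        lst = etree.SubElement(per_hour, f"{{{SBML_NS}}}listOfUnits")
        etree.SubElement(lst, f"{{{SBML_NS}}}unit", kind="second", exponent="-1",
                         scale="0", multiplier="3600")
        comps = etree.SubElement(self.model, f"{{{SBML_NS}}}listOfCompartments")
        etree.SubElement(comps, f"{{{SBML_NS}}}compartment", id="cell", size="1",
                         spatialDimensions="3", constant="true")
        self.species = etree.SubElement(self.model, f"{{{SBML_NS}}}listOfSpecies")
        self.parameters = etree.SubElement(self.model, f"{{{SBML_NS}}}listOfParameters")
        self.reactions = etree.SubElement(self.model, f"{{{SBML_NS}}}listOfReactions")
        self._add_parameter("D", 1.0 if stimulus_on else 0.0)

    def _add_species(self, sid: str, initial: float) -> None:
        etree.SubElement(self.species, f"{{{SBML_NS}}}species", id=sid,
                         compartment="cell", initialConcentration=repr(float(initial)),
                         hasOnlySubstanceUnits="false", boundaryCondition="false",
                         constant="false")

    def _add_parameter(self, pid: str, value: float) -> None:
        etree.SubElement(self.parameters, f"{{{SBML_NS}}}parameter", id=pid,
                         value=repr(float(value)), constant="true", units="per_hour")

    def _add_reaction(self, rid: str, reactants: Sequence[str], products: Sequence[str],
                      modifiers: Sequence[str], factors: Sequence[str]) -> None:
        r = etree.SubElement(self.reactions, f"{{{SBML_NS}}}reaction", id=rid,
                             reversible="false")
        if reactants:
            lst = etree.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for s in reactants:
                etree.SubElement(lst, f"{{{SBML_NS}}}speciesReference", species=s,
                                 stoichiometry="1", constant="true")
        if products:
            lst = etree.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for s in products:
                etree.SubElement(lst, f"{{{SBML_NS}}}speciesReference", species=s,
                                 stoichiometry="1", constant="true")
        if modifiers:
            lst = etree.SubElement(r, f"{{{SBML_NS}}}listOfModifiers")
            for s in modifiers:
                etree.SubElement(lst, f"{{{SBML_NS}}}modifierSpeciesReference", species=s)
        kl = etree.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_math(*factors))

    def build(self) -> etree._Element:
        spec, p = self.spec, self.params
        for g in spec.genes:
            baseline = 0.0 if g in spec.latent_species else 1.0
            self._add_species(_species_id(g, "mrna"), baseline)
            self._add_species(_species_id(g, "protein"), baseline)
        self._add_species("GRa", 0.0)

        for g in spec.genes:
            self._add_parameter(f"s_{g}", p.basal_synthesis[g])
            self._add_parameter(f"dm_{g}", p.mrna_deg[g])
            self._add_parameter(f"tl_{g}", p.translation[g])
            self._add_parameter(f"dp_{g}", p.protein_deg[g])
        for (src, tgt), a in sorted(p.edge_rates.items()):
            self._add_parameter(f"a_{src}_{tgt}", a)
        if spec.gr_autoregulation:
            self._add_parameter("a_auto", p.autoregulation_rate)
        self._add_parameter("k_act", p.stimulus_activation)

        for g in spec.genes:
            m, pr = _species_id(g, "mrna"), _species_id(g, "protein")
            if p.basal_synthesis[g] > 0:
                self._add_reaction(f"synthesis_mrna_{g}", [], [m], [], [f"s_{g}"])
            self._add_reaction(f"degradation_mrna_{g}", [m], [], [], [f"dm_{g}", m])
            self._add_reaction(f"translation_{g}", [], [pr], [m], [f"tl_{g}", m])
            self._add_reaction(f"degradation_protein_{g}", [pr], [], [], [f"dp_{g}", pr])
        for e in spec.edges:
            src_sp = "GRa" if e.source == "GR" else _species_id(e.source, "protein")
            tgt_m = _species_id(e.target, "mrna")
            aid = f"a_{e.source}_{e.target}"
            if e.sign == ACTIVATION:
                self._add_reaction(f"activation_{e.source}_{e.target}", [], [tgt_m],
                                   [src_sp], [aid, src_sp])
            else:
                self._add_reaction(f"repression_{e.source}_{e.target}", [tgt_m], [],
                                   [src_sp], [aid, src_sp, tgt_m])
        if spec.gr_autoregulation:
            self._add_reaction("gr_autoregulation", [], [_species_id("GR", "mrna")],
                               ["GRa"], ["a_auto", "GRa"])
        self._add_reaction("gr_activation", [], ["GRa"], [_species_id("GR", "protein")],
                           ["k_act", "D", _species_id("GR", "protein")])
        self._add_reaction("degradation_GRa", ["GRa"], [], [], ["dp_GR", "GRa"])
        return self.root


def export_sbml(
    spec: ModelSpec,
    params: RateParameters,
    path: Optional[Union[str, Path]] = None,
    stimulus_on: bool = True,
) -> bytes:
    """Serialise one topology + rates as an SBML Level 3 document.

    Returns the XML bytes; also writes them to ``path`` when given.
    """
    if "GR" not in spec.genes:
        raise ValidationError("spec has no GR gene; cannot export")
    for g in spec.genes:
        if g not in params.mrna_deg:
            raise ValidationError(f"params missing rates for gene {g!r}")
    root = _ModelWriter(spec, params, stimulus_on).build()
    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    if path is not None:
        Path(path).write_bytes(data)
    return data


def _parse(doc: Union[bytes, str, Path]) -> etree._Element:
    if isinstance(doc, Path) or (isinstance(doc, str) and not doc.lstrip().startswith("<")):
        data = Path(doc).read_bytes()
    elif isinstance(doc, str):
        data = doc.encode()
    else:
        data = doc
    try:
        return etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"not well-formed XML: {exc}")


def _math_factors(kl: etree._Element) -> List[str]:
    math = kl.find(f"{{{MATHML_NS}}}math")
    if math is None:
        raise ValidationError("kineticLaw without math element")
    child = math[0]
    tag = etree.QName(child).localname
    if tag == "ci":
        return [child.text.strip()]
    if tag == "apply" and len(child) and etree.QName(child[0]).localname == "times":
        out = []
        for ci in child[1:]:
            if etree.QName(ci).localname != "ci":
                raise ValidationError("unsupported kinetic law (expected product of <ci>)")
            out.append(ci.text.strip())
        return out
    raise ValidationError(f"unsupported kinetic law element <{tag}>")


def rhs_from_sbml(doc) -> Tuple[List[str], Callable[[np.ndarray], np.ndarray]]:
    """Rebuild the ODE right-hand side from an exported document.

    Returns ``(species_ids, f)`` with ``f(y) -> dy`` over the document's
    species order (identical to :func:`grkin.models.state_labels` for
    documents this package wrote).  Supports the restricted mass-action
    kinetic-law form the exporter emits.
    """
    root = _parse(doc)
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ValidationError("no <model> element")
    species = [s.get("id") for s in model.findall(
        f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")]
    sidx = {s: i for i, s in enumerate(species)}
    pvals = {p.get("id"): float(p.get("value"))
             for p in model.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")}

    # (param product, [species indices in rate], [(state index, +-1)])
    compiled = []
    for rxn in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        kl = rxn.find(f"{{{SBML_NS}}}kineticLaw")
        factors = _math_factors(kl)
        const = 1.0
        sp_factors = []
        for f in factors:
            if f in pvals:
                const *= pvals[f]
            elif f in sidx:
                sp_factors.append(sidx[f])
            else:
                raise ValidationError(f"kinetic law references unknown id {f!r}")
        stoich = []
        for ref in rxn.findall(f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"):
            stoich.append((sidx[ref.get("species")], -float(ref.get("stoichiometry", 1))))
        for ref in rxn.findall(f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"):
            stoich.append((sidx[ref.get("species")], +float(ref.get("stoichiometry", 1))))
        compiled.append((const, sp_factors, stoich))

    def rhs(y: np.ndarray) -> np.ndarray:
        dy = np.zeros(len(species))
        for const, sp, stoich in compiled:
            rate = const
            for i in sp:
                rate *= y[i]
            for i, nu in stoich:
                dy[i] += nu * rate
        return dy

    return species, rhs


def validate_sbml(doc) -> List[str]:
    """Structural consistency checks; returns a list of issues (empty = valid)."""
    issues: List[str] = []
    try:
        root = _parse(doc)
    except ValidationError as exc:
        return [str(exc)]
    if etree.QName(root).localname != "sbml" or etree.QName(root).namespace != SBML_NS:
        issues.append("root element is not SBML Level 3 <sbml>")
        return issues
    if root.get("level") != "3":
        issues.append(f"unexpected level {root.get('level')!r}")
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        return issues + ["no <model> element"]
    comp_ids = {c.get("id") for c in model.findall(
        f"{{{SBML_NS}}}listOfCompartments/{{{SBML_NS}}}compartment")}
    species = model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")
    sp_ids = [s.get("id") for s in species]
    param_ids = [p.get("id") for p in model.findall(
        f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")]
    all_ids = sp_ids + param_ids + list(comp_ids)
    dup = {i for i in all_ids if all_ids.count(i) > 1}
    if dup:
        issues.append(f"duplicate ids: {sorted(dup)}")
    for s in species:
        if s.get("compartment") not in comp_ids:
            issues.append(f"species {s.get('id')} references unknown compartment")
    known = set(sp_ids) | set(param_ids)
    for rxn in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        rid = rxn.get("id")
        for ref in rxn.iter(f"{{{SBML_NS}}}speciesReference",
                            f"{{{SBML_NS}}}modifierSpeciesReference"):
            if ref.get("species") not in sp_ids:
                issues.append(f"reaction {rid}: unknown species {ref.get('species')!r}")
        kl = rxn.find(f"{{{SBML_NS}}}kineticLaw")
        if kl is None:
            issues.append(f"reaction {rid}: missing kineticLaw")
            continue
        try:
            for f in _math_factors(kl):
                if f not in known:
                    issues.append(f"reaction {rid}: kinetic law references unknown id {f!r}")
        except ValidationError as exc:
            issues.append(f"reaction {rid}: {exc}")
    return issues


def roundtrip_rhs_error(
    spec: ModelSpec,
    params: RateParameters,
    n_states: int = 100,
    seed: int = 0,
    stimulus_on: bool = True,
) -> float:
    """Max |native ODE - reimported SBML ODE| over random non-negative states."""
    from .models import make_rhs  # deferred: keep module import order flat

    doc = export_sbml(spec, params, stimulus_on=stimulus_on)
    species, f_sbml = rhs_from_sbml(doc)
    native_order = state_labels(spec)
    if species != native_order:
        perm = [species.index(s) for s in native_order]
    else:
        perm = None
    f_native = make_rhs(spec, params, 1.0 if stimulus_on else 0.0)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_states):
        y = rng.uniform(0.0, 3.0, size=len(native_order))
        d_native = f_native(0.0, y)
        if perm is None:
            d_sbml = f_sbml(y)
        else:
            y_doc = np.empty_like(y)
            for doc_i, nat_lab in enumerate(species):
                y_doc[doc_i] = y[native_order.index(nat_lab)]
            d_sbml = f_sbml(y_doc)[perm]
        worst = max(worst, float(np.max(np.abs(d_native - d_sbml))))
    return worst
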