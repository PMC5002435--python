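"""Stoichiometric model container, standard-format I/O, and elemental balance.

Models are stored with BiGG-style canonical identifiers (e.g. ``glcglyc_c``,
``EX_glcglyc(e)``); SBML escaping (``_DASH_``, ``_LPAREN_``, ``_RPAREN_`` and
the ``M_``/``R_`` prefixes) is applied only at (de)serialization.  Two dialects
are supported: SBML Level 3 with the fbc package, and BiGG/cobrapy-style JSON
(the native format).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "StoichiometricMatrix",
    "ElementBalance",
    "ModelError",
    "ParseError",
    "MissingObjectiveError",
    "load_model",
    "write_model",
    "build_stoichiometric_matrix",
    "element_balance",
    "parse_formula",
    "canonicalize_sbml_id",
    "escape_sbml_id",
    "BUNDLED_FORMULAS",
    "DEFAULT_LOWER_BOUND",
    "DEFAULT_UPPER_BOUND",
]

DEFAULT_LOWER_BOUND = -1000.0
DEFAULT_UPPER_BOUND = 1000.0

COMPARTMENTS = {"c": "cytosol", "p": "periplasm", "e": "extracellular"}

#: Elemental formulas for the glucosylglycerol-pathway species, applied when a
#: source model carries none.  Neutral (fully protonated) forms are used so
#: that hydrolysis/phosphorolysis balance exactly in C, H, O and P.
BUNDLED_FORMULAS: dict[str, str] = {
    "glcglyc": "C9H18O8",   # glucosylglycerol
    "glyc": "C3H8O3",       # glycerol
    "glc__D": "C6H12O6",    # D-glucose
    "g1p": "C6H13O9P",      # glucose 1-phosphate
    "g6p": "C6H13O9P",      # glucose 6-phosphate
    "h2o": "H2O",
    "pi": "H3O4P",          # inorganic phosphate
    "co2": "CO2",
}

#: Canonical spellings of the glucosylglycerol extension reaction ids.  SBML
#: sources spell these in a variety of cases and escapes; after unescaping,
#: a case-insensitive match against this table restores the canonical form.
_CANONICAL_IDS = [
    "EX_glcglyc(e)",
    "GLCGLYCtex",
    "GLCGLYCABCpp_syn",
    "glcglyctpp",
    "GLCGLYCstorage",
    "GLCGLYCHyd",
    "GLCGLYCPhosphorylase",
    "glcglyc_c",
    "glcglyc_p",
    "glcglyc_e",
]
_CANONICAL_BY_LOWER = {s.lower(): s for s in _CANONICAL_IDS}


class ModelError(ValueError):
    """Invalid model structure (duplicate ids, dangling references, ...)."""


class ParseError(ModelError):
    """A source file could not be parsed; the message names the element."""


class MissingObjectiveError(ModelError):
    """A non-empty model declares no biomass objective."""


# ---------------------------------------------------------------------------
# identifiers and formulas
# ---------------------------------------------------------------------------

def canonicalize_sbml_id(sbml_id: str) -> str:
    """Map an SBML-escaped identifier to canonical BiGG form.

    ``R_EX_GLCGLYC_LPAREN_e_RPAREN`` -> ``EX_glcglyc(e)``;
    ``M_glc_DASH_D_c`` -> ``glc__D_c``.  A trailing ``_RPAREN`` carries no
    final underscore, per the BiGG SBML convention.
    """
    out = sbml_id
    if out.startswith(("R_", "M_", "S_")):
        out = out[2:]
    out = out.replace("_DASH_", "__").replace("_LPAREN_", "(")
    out = re.sub(r"_RPAREN_", ")", out)
    out = re.sub(r"_RPAREN$", ")", out)
    return _CANONICAL_BY_LOWER.get(out.lower(), out)


def escape_sbml_id(canonical_id: str, prefix: str) -> str:
    """Inverse of :func:`canonicalize_sbml_id` (``prefix`` is ``R_`` or ``M_``)."""
    out = canonical_id.replace("__", "_DASH_").replace("(", "_LPAREN_")
    out = re.sub(r"\)(?=.)", "_RPAREN_", out)
    out = re.sub(r"\)$", "_RPAREN", out)
    return prefix + out


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``C9H18O8`` into element counts."""
    if not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula or ""):
        raise ValueError(f"unparseable formula: {formula!r}")
    counts: dict[str, int] = {}
    for element, digits in _FORMULA_TOKEN.findall(formula):
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    return counts


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    """A model species with a BiGG-style compartment-suffixed id."""

    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.compartment:
            self.compartment = self.id.rsplit("_", 1)[-1] if "_" in self.id else ""
        if self.compartment not in COMPARTMENTS:
            raise ModelError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not one of {sorted(COMPARTMENTS)}"
            )
        if "_" in self.id and self.id.rsplit("_", 1)[-1] in COMPARTMENTS:
            if self.id.rsplit("_", 1)[-1] != self.compartment:
                raise ModelError(
                    f"metabolite {self.id!r}: id suffix disagrees with "
                    f"compartment {self.compartment!r}"
                )

    @property
    def elements(self) -> dict[str, int] | None:
        return None if self.formula is None else parse_formula(self.formula)


@dataclass
class Reaction:
    """A stoichiometric reaction; negative coefficients are consumed.

    Fluxes are in mmol·gDW⁻¹·h⁻¹ (the biomass objective in h⁻¹).  Exchange and
    sink reactions touch exactly one metabolite, written ``metabolite ⇒`` so
    that export is positive flux and uptake is negative.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = DEFAULT_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND
    gene_association: str | None = None
    is_exchange: bool = False
    is_sink: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if (self.is_exchange or self.is_sink) and len(self.stoichiometry) != 1:
            raise ModelError(
                f"reaction {self.id!r}: exchange/sink must touch exactly one metabolite"
            )

    @property
    def is_boundary(self) -> bool:
        return self.is_exchange or self.is_sink

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gene_association=self.gene_association,
            is_exchange=self.is_exchange,
            is_sink=self.is_sink,
        )


@dataclass
class MetabolicModel:
    """Metabolites, reactions and a biomass objective: the data behind S, v, lb/ub, c."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_reaction_id: str | None = None
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ------------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def has_metabolite(self, met_id: str) -> bool:
        return any(m.id == met_id for m in self.metabolites)

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        for label, ids in (("metabolite", met_ids), ("reaction", rxn_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ModelError(f"duplicate {label} id {i!r}")
                seen.add(i)
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {r.id!r} references unknown metabolites: {sorted(missing)}"
                )
        if self.objective_reaction_id is not None and self.objective_reaction_id not in rxn_ids:
            raise ModelError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        if self.reactions and self.objective_reaction_id is None:
            raise MissingObjectiveError(f"model {self.id!r} declares no objective reaction")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[Metabolite(m.id, m.name, m.compartment, m.formula, m.charge)
                         for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective_reaction_id=self.objective_reaction_id,
            id=self.id,
        )


@dataclass
class StoichiometricMatrix:
    """Sparse S with its metabolite (row) and reaction (column) orderings."""

    rows: list[str]
    cols: list[str]
    matrix: sp.csc_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def entry(self, met_id: str, rxn_id: str) -> float:
        return float(self.matrix[self.rows.index(met_id), self.cols.index(rxn_id)])

    def to_tsv(self, path: str | Path) -> None:
        dense = self.to_dense()
        with open(path, "w") as fh:
            fh.write("metabolite\t" + "\t".join(self.cols) + "\n")
            for met, row in zip(self.rows, dense):
                fh.write(met + "\t" + "\t".join(format(x, "g") for x in row) + "\n")


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble sparse S: entry (m, r) is reaction r's coefficient for metabolite m."""
    model.validate()
    rows = model.metabolite_ids
    cols = model.reaction_ids
    row_index = {m: i for i, m in enumerate(rows)}
    data, ri, ci = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            if coef != 0:
                data.append(float(coef))
                ri.append(row_index[met])
                ci.append(j)
    matrix = sp.csc_matrix((data, (ri, ci)), shape=(len(rows), len(cols)))
    return StoichiometricMatrix(rows=rows, cols=cols, matrix=matrix)


# ---------------------------------------------------------------------------
# elemental balance
# ---------------------------------------------------------------------------


@dataclass
class ElementBalance:
    """Per-element net atom count of a reaction.

    ``status`` is one of ``balanced``, ``unbalanced``, ``boundary`` (exchange
    or sink: unbalanced by construction and skipped), or ``unknown`` (some
    participant lacks a formula — never silently reported as zero).
    """

    reaction_id: str
    status: str
    net: dict[str, float] = field(default_factory=dict)
    missing_formulas: list[str] = field(default_factory=list)

    @property
    def is_balanced(self) -> bool:
        return self.status == "balanced"


def element_balance(reaction: Reaction, model: MetabolicModel,
                    tol: float = 1e-9) -> ElementBalance:
    """Net atoms per element: sum over participants of coefficient × atom count."""
    if reaction.is_boundary:
        return ElementBalance(reaction.id, "boundary")
    missing = [mid for mid in reaction.stoichiometry
               if model.metabolite(mid).formula is None]
    if missing:
        return ElementBalance(reaction.id, "unknown", missing_formulas=sorted(missing))
    net: dict[str, float] = {}
    for mid, coef in reaction.stoichiometry.items():
        for element, count in parse_formula(model.metabolite(mid).formula).items():
            net[element] = net.get(element, 0.0) + coef * count
    status = "balanced" if all(abs(v) <= tol for v in net.values()) else "unbalanced"
    return ElementBalance(reaction.id, status, net=net)


def apply_bundled_formulas(model: MetabolicModel) -> None:
    """Fill missing formulas from the bundled annotation table, in place."""
    for met in model.metabolites:
        if met.formula is None:
            stem = met.id.rsplit("_", 1)[0] if "_" in met.id else met.id
            if stem in BUNDLED_FORMULAS:
                met.formula = BUNDLED_FORMULAS[stem]


# ---------------------------------------------------------------------------
# I/O: BiGG-style JSON (native) and SBML L3 + fbc
# ---------------------------------------------------------------------------


def _looks_like_path(source: str | Path) -> bool:
    if isinstance(source, Path):
        return True
    s = source.lstrip()
    return not (s.startswith("{") or s.startswith("<")) and len(source) < 4096


def _read_source(source: str | Path) -> str:
    if _looks_like_path(source):
        p = Path(source)
        if not p.exists():
            raise FileNotFoundError(f"model file not found: {p}")
        return p.read_text()
    return str(source)


def load_model(source: str | Path, dialect: str | None = None) -> MetabolicModel:
    """Load a model from SBML L3+fbc (``sbml-fbc``) or BiGG JSON (``bigg-json``).

    Ids are canonicalized to BiGG form; bounds default to ±1000 (reversible)
    or 0/1000 (irreversible) when the source omits them; bundled formulas for
    the glucosylglycerol pathway species are applied when absent.
    """
    text = _read_source(source)
    if dialect is None:
        dialect = "sbml-fbc" if text.lstrip().startswith("<") else "bigg-json"
    if dialect == "bigg-json":
        model = _load_json(text)
    elif dialect == "sbml-fbc":
        model = _load_sbml(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    apply_bundled_formulas(model)
    return model


def write_model(model: MetabolicModel, path: str | Path | None = None,
                dialect: str = "bigg-json") -> str:
    """Serialize a model; returns the text and optionally writes it to ``path``."""
    if dialect == "bigg-json":
        text = _dump_json(model)
    elif dialect == "sbml-fbc":
        text = _dump_sbml(model)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


# -- JSON -------------------------------------------------------------------


def _classify_boundary(rxn_id: str, stoich: dict[str, float],
                       compartments: dict[str, str]) -> tuple[bool, bool]:
    """Single-metabolite reactions are exchanges (extracellular) or sinks."""
    if len(stoich) != 1:
        return False, False
    (mid,) = stoich
    comp = compartments.get(mid, mid.rsplit("_", 1)[-1] if "_" in mid else "")
    if comp == "e" or rxn_id.startswith("EX_"):
        return True, False
    return False, True


def _load_json(text: str) -> MetabolicModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON model: {exc}") from exc
    mets = []
    comp_of: dict[str, str] = {}
    for entry in doc.get("metabolites", []):
        if "id" not in entry:
            raise ParseError(f"metabolite entry without id: {entry!r}")
        mid = canonicalize_sbml_id(entry["id"])
        comp = entry.get("compartment") or ""
        formula = entry.get("formula") or None
        charge = entry.get("charge")
        mets.append(Metabolite(mid, entry.get("name", ""), comp, formula, charge))
        comp_of[mid] = mets[-1].compartment
    rxns = []
    objective = None
    for entry in doc.get("reactions", []):
        if "id" not in entry:
            raise ParseError(f"reaction entry without id: {entry!r}")
        rid = canonicalize_sbml_id(entry["id"])
        stoich = {canonicalize_sbml_id(k): float(v)
                  for k, v in entry.get("metabolites", {}).items()}
        reversible_default = True
        lb = entry.get("lower_bound")
        ub = entry.get("upper_bound")
        if lb is None:
            lb = DEFAULT_LOWER_BOUND if reversible_default else 0.0
        if ub is None:
            ub = DEFAULT_UPPER_BOUND
        is_ex, is_sink = _classify_boundary(rid, stoich, comp_of)
        rxns.append(Reaction(
            id=rid, name=entry.get("name", ""), stoichiometry=stoich,
            lower_bound=float(lb), upper_bound=float(ub),
            gene_association=entry.get("gene_reaction_rule") or None,
            is_exchange=is_ex, is_sink=is_sink,
        ))
        if entry.get("objective_coefficient"):
            objective = rid
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           objective_reaction_id=objective,
                           id=doc.get("id", "model"))
    return model


def _dump_json(model: MetabolicModel) -> str:
    """cobrapy-compatible BiGG JSON; deterministic key order for reproducibility."""
    doc = {
        "id": model.id,
        "version": "1",
        "compartments": {c: COMPARTMENTS[c]
                         for c in sorted({m.compartment for m in model.metabolites})},
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula or "",
                "charge": m.charge if m.charge is not None else 0,
                "notes": {},
                "annotation": {},
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gene_association or "",
                "objective_coefficient": 1.0 if r.id == model.objective_reaction_id else 0.0,
                "notes": {},
                "annotation": {},
            }
            for r in model.reactions
        ],
        "genes": [],
    }
    return json.dumps(doc, indent=1, sort_keys=False)


# -- SBML L3 + fbc ------------------------------------------------------------


def _load_sbml(text: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ParseError(
                    f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
                )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ParseError("SBML document contains no model element")

    mets = []
    comp_of: dict[str, str] = {}
    for s in sbml_model.getListOfSpecies():
        mid = canonicalize_sbml_id(s.getId())
        comp = s.getCompartment() or ""
        formula, charge = None, None
        fplug = s.getPlugin("fbc")
        if fplug is not None:
            if fplug.isSetChemicalFormula():
                formula = fplug.getChemicalFormula() or None
            if fplug.isSetCharge():
                charge = fplug.getCharge()
        mets.append(Metabolite(mid, s.getName() or "", comp, formula, charge))
        comp_of[mid] = mets[-1].compartment

    def _bound_value(param_id: str | None, default: float) -> float:
        if not param_id:
            return default
        param = sbml_model.getParameter(param_id)
        if param is None:
            raise ParseError(f"flux-bound parameter {param_id!r} not defined")
        return param.getValue()

    rxns = []
    for r in sbml_model.getListOfReactions():
        rid = canonicalize_sbml_id(r.getId())
        stoich: dict[str, float] = {}
        for ref in r.getListOfReactants():
            mid = canonicalize_sbml_id(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for ref in r.getListOfProducts():
            mid = canonicalize_sbml_id(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        rev = r.getReversible()
        default_lb = DEFAULT_LOWER_BOUND if rev else 0.0
        if rplug is not None and (rplug.isSetLowerFluxBound() or rplug.isSetUpperFluxBound()):
            lb = _bound_value(rplug.getLowerFluxBound(), default_lb)
            ub = _bound_value(rplug.getUpperFluxBound(), DEFAULT_UPPER_BOUND)
        else:
            lb, ub = default_lb, DEFAULT_UPPER_BOUND
        gene = None
        if rplug is not None:
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                gene = gpa.getAssociation().toInfix() or None
        is_ex, is_sink = _classify_boundary(rid, stoich, comp_of)
        rxns.append(Reaction(id=rid, name=r.getName() or "", stoichiometry=stoich,
                             lower_bound=lb, upper_bound=ub, gene_association=gene,
                             is_exchange=is_ex, is_sink=is_sink))

    objective = None
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None:
        obj = mplug.getActiveObjective() or (
            mplug.getObjective(0) if mplug.getNumObjectives() else None)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective = canonicalize_sbml_id(obj.getFluxObjective(0).getReaction())

    return MetabolicModel(metabolites=mets, reactions=rxns,
                          objective_reaction_id=objective,
                          id=canonicalize_sbml_id(sbml_model.getId() or "model"))


def _dump_sbml(model: MetabolicModel) -> str:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    m = doc.createModel()
    m.setId(escape_sbml_id(model.id, "") or "model")
    mplug = m.getPlugin("fbc")
    mplug.setStrict(False)

    for cid in sorted({met.compartment for met in model.metabolites} | {"c"}):
        comp = m.createCompartment()
        comp.setId(cid)
        comp.setName(COMPARTMENTS[cid])
        comp.setConstant(True)

    for met in model.metabolites:
        s = m.createSpecies()
        s.setId(escape_sbml_id(met.id, "M_"))
        s.setName(met.name or met.id)
        s.setCompartment(met.compartment)
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)
        fplug = s.getPlugin("fbc")
        if met.formula is not None:
            fplug.setChemicalFormula(met.formula)
        if met.charge is not None:
            fplug.setCharge(int(met.charge))

    bound_params: dict[float, str] = {}

    def _param_for(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = m.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        r = m.createReaction()
        r.setId(escape_sbml_id(rxn.id, "R_"))
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for mid, coef in sorted(rxn.stoichiometry.items()):
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(escape_sbml_id(mid, "M_"))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(_param_for(rxn.lower_bound))
        rplug.setUpperFluxBound(_param_for(rxn.upper_bound))

    if model.objective_reaction_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(escape_sbml_id(model.objective_reaction_id, "R_"))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    return libsbml.writeSBMLToString(doc)
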