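"""The glucosylglycerol (GG) transport/degradation/storage extension and the
mutant genotypes expressed as flux-constraint sets.

GG is the main compatible solute of *Synechocystis* under salt stress.  The
extension wires its salvage into a stoichiometric model with seven reactions:
an extracellular exchange, extracellular↔periplasm transport, ABC-mediated
periplasm→cytosol uptake (GgtABCD), cytosol→periplasm leakage by diffusion, a
cytosolic storage sink (so accumulation is representable at steady state),
and the two candidate cleavage reactions catalysed by Slr1670 — hydrolysis
(yielding free glucose) and phosphorolysis (yielding glucose 1-phosphate,
which spares one ATP-equivalent at the glucokinase step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model_core import (
    BUNDLED_FORMULAS,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)

__all__ = [
    "ExtensionReactionSpec",
    "StrainSpec",
    "default_gg_extension",
    "extend_with_gg",
    "apply_strain",
    "builtin_strain",
    "BUILTIN_STRAINS",
    "GG_EXCHANGE_ID",
    "HYDROLASE_ID",
    "PHOSPHORYLASE_ID",
    "STORAGE_ID",
    "CLEAVAGE_IDS",
]

GG_EXCHANGE_ID = "EX_glcglyc(e)"
HYDROLASE_ID = "GLCGLYCHyd"
PHOSPHORYLASE_ID = "GLCGLYCPhosphorylase"
STORAGE_ID = "GLCGLYCstorage"
CLEAVAGE_IDS = (HYDROLASE_ID, PHOSPHORYLASE_ID)


@dataclass
class ExtensionReactionSpec:
    """One reaction of the GG extension; irreversible equations have lb = 0."""

    id: str
    equation: dict[str, float]
    bounds: tuple[float, float] = (0.0, 1000.0)
    name: str = ""
    gene_association: str | None = None
    add_if_absent: bool = True
    is_exchange: bool = False
    is_sink: bool = False

    def to_reaction(self) -> Reaction:
        return Reaction(
            id=self.id, name=self.name or self.id,
            stoichiometry=dict(self.equation),
            lower_bound=self.bounds[0], upper_bound=self.bounds[1],
            gene_association=self.gene_association,
            is_exchange=self.is_exchange, is_sink=self.is_sink,
        )


def default_gg_extension() -> list[ExtensionReactionSpec]:
    """The seven-reaction GG extension.

    The exchange ships closed to uptake (lb = 0); the exogenous-GG scenario
    opens it.  The storage sink is irreversible and carries no biomass
    contribution — it exists to absorb GG, not to reward it.
    """
    return [
        ExtensionReactionSpec(
            id=GG_EXCHANGE_ID, name="GG exchange",
            equation={"glcglyc_e": -1.0}, bounds=(0.0, 1000.0), is_exchange=True),
        ExtensionReactionSpec(
            id="GLCGLYCtex", name="GG transport, extracellular to periplasm",
            equation={"glcglyc_e": -1.0, "glcglyc_p": 1.0}, bounds=(-1000.0, 1000.0)),
        ExtensionReactionSpec(
            id="GLCGLYCABCpp_syn", name="GG ABC uptake, periplasm to cytosol (GgtABCD)",
            equation={"glcglyc_p": -1.0, "glcglyc_c": 1.0}, bounds=(0.0, 1000.0)),
        ExtensionReactionSpec(
            id="glcglyctpp", name="GG transport via diffusion (cytosol to periplasm)",
            equation={"glcglyc_c": -1.0, "glcglyc_p": 1.0}, bounds=(0.0, 1000.0)),
        ExtensionReactionSpec(
            id=STORAGE_ID, name="Glucosylglycerol storage (cytosol to sink)",
            equation={"glcglyc_c": -1.0}, bounds=(0.0, 1000.0), is_sink=True),
        ExtensionReactionSpec(
            id=HYDROLASE_ID, name="Glucosylglycerol hydrolase",
            equation={"h2o_c": -1.0, "glcglyc_c": -1.0, "glc__D_c": 1.0, "glyc_c": 1.0},
            bounds=(0.0, 1000.0), gene_association="slr1670"),
        ExtensionReactionSpec(
            id=PHOSPHORYLASE_ID, name="Glucosylglycerol phosphorylase",
            equation={"pi_c": -1.0, "glcglyc_c": -1.0, "g1p_c": 1.0, "glyc_c": 1.0},
            bounds=(0.0, 1000.0), gene_association="slr1670"),
    ]


def extend_with_gg(model: MetabolicModel,
                   specs: list[ExtensionReactionSpec] | None = None,
                   ) -> MetabolicModel:
    """Return a copy of ``model`` with the GG extension applied.

    Specs with ``add_if_absent`` whose id already exists leave the model
    unchanged (re-application is a no-op).  Metabolites referenced but absent
    are created from the bundled annotation table; anything else is an error.
    """
    if specs is None:
        specs = default_gg_extension()
    out = model.copy()
    for spec in specs:
        if out.has_reaction(spec.id):
            if spec.add_if_absent:
                continue
            raise ModelError(f"reaction {spec.id!r} already present in model")
        for mid in spec.equation:
            if not out.has_metabolite(mid):
                stem = mid.rsplit("_", 1)[0] if "_" in mid else mid
                if stem not in BUNDLED_FORMULAS:
                    raise ModelError(
                        f"extension reaction {spec.id!r} needs metabolite {mid!r}, "
                        "which is absent and not in the bundled annotation table"
                    )
                out.metabolites.append(
                    Metabolite(id=mid, name=stem, formula=BUNDLED_FORMULAS[stem]))
        out.reactions.append(spec.to_reaction())
    out.validate()
    return out


# ---------------------------------------------------------------------------
# strains
# ---------------------------------------------------------------------------


@dataclass
class StrainSpec:
    """A genotype as a set of reaction knockouts plus a GG-supply scenario.

    Scenario ``exogenous_GG`` opens the GG exchange for uptake (GG fed in the
    medium); ``salt_endogenous_GG`` keeps it closed (GG only from synthesis).
    """

    name: str
    knockout_reaction_ids: set[str] = field(default_factory=set)
    scenario: str = "exogenous_GG"

    def __post_init__(self) -> None:
        if self.scenario not in ("exogenous_GG", "salt_endogenous_GG"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


#: Built-in genotypes.  slr1670 encodes both candidate cleavage activities,
#: so its knockout removes hydrolase and phosphorylase together; the double
#: mutant is the union of the two singles.  Reaction ids follow the toy
#: model / extension convention; full-scale models can remap via overrides.
BUILTIN_STRAINS: dict[str, frozenset[str]] = {
    "WT": frozenset(),
    "dggpS": frozenset({"GGPS"}),
    "dglpK": frozenset({"GLYK"}),
    "dslr1670": frozenset({HYDROLASE_ID, PHOSPHORYLASE_ID}),
    "dglpK_dslr1670": frozenset({"GLYK", HYDROLASE_ID, PHOSPHORYLASE_ID}),
}


def builtin_strain(name: str, scenario: str = "exogenous_GG",
                   id_overrides: dict[str, str] | None = None) -> StrainSpec:
    """A named genotype; ``id_overrides`` remaps toy ids to a host model's ids."""
    if name not in BUILTIN_STRAINS:
        raise KeyError(
            f"unknown strain {name!r}; known: {sorted(BUILTIN_STRAINS)} or custom"
        )
    kos = set(BUILTIN_STRAINS[name])
    if id_overrides:
        kos = {id_overrides.get(rid, rid) for rid in kos}
    return StrainSpec(name=name, knockout_reaction_ids=kos, scenario=scenario)


def apply_strain(model: MetabolicModel, strain: StrainSpec,
                 gg_exchange_id: str = GG_EXCHANGE_ID) -> MetabolicModel:
    """Return a copy with the strain's knockouts (lb = ub = 0) applied.

    Other bounds are untouched, except the GG exchange lower bound, which the
    scenario controls (opened to −1000 for exogenous GG, left closed for the
    endogenous salt scenario).
    """
    out = model.copy()
    for rid in sorted(strain.knockout_reaction_ids):
        if not out.has_reaction(rid):
            raise ModelError(f"strain {strain.name!r}: unknown reaction {rid!r}")
        if rid == out.objective_reaction_id:
            raise ModelError(
                f"strain {strain.name!r}: refusing to knock out the objective {rid!r}"
            )
        rxn = out.reaction(rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    if out.has_reaction(gg_exchange_id):
        ex = out.reaction(gg_exchange_id)
        if strain.scenario == "exogenous_GG":
            ex.lower_bound = min(ex.lower_bound, -1000.0)
    return out
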