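"""Model container, id canonicalization, format round-trips, S assembly,
and elemental balance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ggflux.model_core import (
    BUNDLED_FORMULAS,
    MetabolicModel,
    Metabolite,
    MissingObjectiveError,
    ModelError,
    ParseError,
    Reaction,
    build_stoichiometric_matrix,
    canonicalize_sbml_id,
    element_balance,
    escape_sbml_id,
    load_model,
    parse_formula,
    write_model,
)


# ---------------------------------------------------------------------------
# identifiers and formulas
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("sbml_id, canonical", [
    ("R_EX_GLCGLYC_LPAREN_e_RPAREN", "EX_glcglyc(e)"),
    ("R_EX_glcglyc_LPAREN_e_RPAREN", "EX_glcglyc(e)"),
    ("M_glc_DASH_D_c", "glc__D_c"),
    ("M_glcglyc_c", "glcglyc_c"),
    ("R_GLCGLYCHyd", "GLCGLYCHyd"),
    ("R_glcglyctpp", "glcglyctpp"),
    ("R_BIOMASS_toy", "BIOMASS_toy"),
])
def test_sbml_id_canonicalization(sbml_id, canonical):
    assert canonicalize_sbml_id(sbml_id) == canonical


@pytest.mark.parametrize("canonical, prefix", [
    ("EX_glcglyc(e)", "R_"),
    ("glc__D_c", "M_"),
    ("GLCGLYCPhosphorylase", "R_"),
])
def test_escape_is_inverse_of_canonicalize(canonical, prefix):
    assert canonicalize_sbml_id(escape_sbml_id(canonical, prefix)) == canonical


def test_parse_formula_counts_atoms():
    assert parse_formula("C9H18O8") == {"C": 9, "H": 18, "O": 8}
    assert parse_formula("H2O") == {"H": 2, "O": 1}
    assert parse_formula("C6H13O9P") == {"C": 6, "H": 13, "O": 9, "P": 1}
    with pytest.raises(ValueError):
        parse_formula("not a formula!")


# ---------------------------------------------------------------------------
# container invariants
# ---------------------------------------------------------------------------


def test_metabolite_compartment_from_suffix_and_conflict():
    assert Metabolite(id="glcglyc_p").compartment == "p"
    with pytest.raises(ModelError):
        Metabolite(id="glcglyc_c", compartment="e")


def test_reaction_invariants():
    with pytest.raises(ModelError):
        Reaction(id="bad", lower_bound=1.0, upper_bound=0.0)
    with pytest.raises(ModelError):
        Reaction(id="EX_two", stoichiometry={"a_e": -1, "b_e": 1}, is_exchange=True)


def test_model_rejects_duplicates_and_dangling_references():
    m = Metabolite(id="a_c")
    with pytest.raises(ModelError):
        MetabolicModel(metabolites=[m, Metabolite(id="a_c")])
    with pytest.raises(ModelError):
        MetabolicModel(
            metabolites=[m],
            reactions=[Reaction(id="r", stoichiometry={"ghost_c": 1.0})],
            objective_reaction_id="r",
        )
    with pytest.raises(MissingObjectiveError):
        MetabolicModel(metabolites=[m],
                       reactions=[Reaction(id="r", stoichiometry={"a_c": 1.0})])


def test_empty_model_is_valid():
    empty = MetabolicModel()
    smat = build_stoichiometric_matrix(empty)
    assert smat.shape == (0, 0)


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------


def test_linear_chain_matrix():
    """A->B->C with exchanges for A and C: 3x4 S whose internal columns sum to 0."""
    mets = [Metabolite(id=x) for x in ("a_c", "b_c", "c_c")]
    rxns = [
        Reaction(id="v1", stoichiometry={"a_c": -1.0, "b_c": 1.0}, lower_bound=0),
        Reaction(id="v2", stoichiometry={"b_c": -1.0, "c_c": 1.0}, lower_bound=0),
        Reaction(id="in_a", stoichiometry={"a_c": 1.0}, is_sink=True),
        Reaction(id="out_c", stoichiometry={"c_c": -1.0}, is_sink=True),
    ]
    m = MetabolicModel(metabolites=mets, reactions=rxns, objective_reaction_id="v2")
    smat = build_stoichiometric_matrix(m)
    assert smat.shape == (3, 4)
    dense = smat.to_dense()
    assert dense[:, 0].sum() == 0 and dense[:, 1].sum() == 0
    assert smat.entry("a_c", "v1") == -1.0 and smat.entry("b_c", "v1") == 1.0


def test_toy_matrix_hydrolase_entry(toy_model):
    smat = build_stoichiometric_matrix(toy_model)
    assert smat.entry("glcglyc_c", "GLCGLYCHyd") == -1.0
    assert smat.entry("glc__D_c", "GLCGLYCHyd") == 1.0


@given(st.data())
def test_matrix_columns_reproduce_stoichiometries(data):
    """Rebuilding reactions from S's columns reproduces the input exactly."""
    n_mets = data.draw(st.integers(2, 6))
    n_rxns = data.draw(st.integers(1, 8))
    met_ids = [f"m{i}_c" for i in range(n_mets)]
    coeffs = data.draw(st.lists(
        st.lists(st.integers(-3, 3), min_size=n_mets, max_size=n_mets),
        min_size=n_rxns, max_size=n_rxns))
    rxns = [Reaction(id=f"r{j}",
                     stoichiometry={met_ids[i]: float(c) for i, c in enumerate(col) if c})
            for j, col in enumerate(coeffs)]
    model = MetabolicModel(metabolites=[Metabolite(id=m) for m in met_ids],
                           reactions=rxns, objective_reaction_id="r0")
    smat = build_stoichiometric_matrix(model)
    dense = smat.to_dense()
    for j, rxn in enumerate(model.reactions):
        rebuilt = {smat.rows[i]: dense[i, j] for i in range(n_mets) if dense[i, j]}
        assert rebuilt == rxn.stoichiometry


# ---------------------------------------------------------------------------
# round trips and parsing errors
# ---------------------------------------------------------------------------


def _models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    if a.objective_reaction_id != b.objective_reaction_id:
        return False
    if sorted(a.metabolite_ids) != sorted(b.metabolite_ids):
        return False
    for met in a.metabolites:
        other = b.metabolite(met.id)
        if (met.compartment, met.formula) != (other.compartment, other.formula):
            return False
    if sorted(a.reaction_ids) != sorted(b.reaction_ids):
        return False
    for rxn in a.reactions:
        other = b.reaction(rxn.id)
        if rxn.stoichiometry != other.stoichiometry:
            return False
        if (rxn.lower_bound, rxn.upper_bound) != (other.lower_bound, other.upper_bound):
            return False
    return True


@pytest.mark.parametrize("dialect", ["bigg-json", "sbml-fbc"])
def test_round_trip_is_identity(toy_model, dialect, tmp_path):
    path = tmp_path / f"toy.{dialect}"
    write_model(toy_model, path, dialect=dialect)
    reloaded = load_model(path, dialect)
    assert _models_equal(toy_model, reloaded)
    # and a second cycle is stable byte-wise modulo nothing
    assert write_model(reloaded, dialect=dialect) == write_model(toy_model, dialect=dialect)


def test_dialect_autodetection(toy_model):
    assert _models_equal(load_model(write_model(toy_model, dialect="bigg-json")),
                         toy_model)
    assert _models_equal(load_model(write_model(toy_model, dialect="sbml-fbc")),
                         toy_model)


def test_parse_errors_name_the_problem():
    with pytest.raises(ParseError):
        load_model('{"metabolites": [{"name": "no id"}], "reactions": []}',
                   "bigg-json")
    with pytest.raises(ParseError):
        load_model("<sbml>broken", "sbml-fbc")


def test_bundled_formulas_fill_missing():
    text = ('{"id": "mini", "metabolites": [{"id": "glcglyc_c", "compartment": "c"}],'
            ' "reactions": [{"id": "GLCGLYCstorage", "metabolites": {"glcglyc_c": -1},'
            ' "lower_bound": 0, "upper_bound": 1000, "objective_coefficient": 1}]}')
    model = load_model(text, "bigg-json")
    assert model.metabolite("glcglyc_c").formula == BUNDLED_FORMULAS["glcglyc"]


# ---------------------------------------------------------------------------
# elemental balance
# ---------------------------------------------------------------------------


def test_gg_hydrolysis_is_balanced(toy_model):
    bal = element_balance(toy_model.reaction("GLCGLYCHyd"), toy_model)
    assert bal.is_balanced
    assert all(abs(v) < 1e-12 for v in bal.net.values())


def test_gg_carbon_content_is_nine(toy_model):
    assert parse_formula(toy_model.metabolite("glcglyc_c").formula)["C"] == 9


def test_sink_flagged_unbalanced_by_construction(toy_model):
    bal = element_balance(toy_model.reaction("GLCGLYCstorage"), toy_model)
    assert bal.status == "boundary" and not bal.is_balanced


def test_missing_formula_reports_unknown_not_zero(toy_model):
    bal = element_balance(toy_model.reaction("LIGHT"), toy_model)
    assert bal.status == "unknown"
    assert "atp_c" in bal.missing_formulas
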