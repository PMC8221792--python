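"""Model container, I/O round-trips and model-editing operations."""

import json

import pytest

import fluxmaint as fm
from fluxmaint.errors import ConfigurationError, FormatError, ValidationError
from fluxmaint.model_core import (
    ADP_PER_AA,
    AMP_PER_AA,
    ATP_PER_AA,
    GDP_PER_AA,
    GTP_PER_AA,
    load_model,
    save_model,
)
from fluxmaint.fba_engine import fba
from fluxmaint.synthetic_data import bundled_model_path


class TestModelIO:
    @pytest.mark.parametrize("dialect,suffix", [("json", "json"), ("sbml", "xml")])
    def test_round_trip_preserves_network(self, toy_model, tmp_path, dialect, suffix):
        path = tmp_path / f"toy.{suffix}"
        save_model(toy_model, path, dialect)
        reloaded = load_model(path, dialect)
        assert set(reloaded.compartments) == {"e", "c", "m"}
        for rxn in toy_model.cobra_model.reactions:
            other = reloaded.cobra_model.reactions.get_by_id(rxn.id)
            assert other.bounds == rxn.bounds
            assert other.subsystem == rxn.subsystem
            assert {m.id: c for m, c in other.metabolites.items()} == {
                m.id: c for m, c in rxn.metabolites.items()
            }

    @pytest.mark.parametrize("dialect", ["json", "sbml"])
    def test_bundled_model_matches_builder(self, toy_model, dialect):
        bundled = load_model(bundled_model_path(dialect), dialect)
        for rxn in toy_model.cobra_model.reactions:
            other = bundled.cobra_model.reactions.get_by_id(rxn.id)
            assert {m.id: c for m, c in other.metabolites.items()} == {
                m.id: c for m, c in rxn.metabolites.items()
            }

    def test_unknown_metabolite_is_format_error(self, toy_model, tmp_path):
        path = tmp_path / "toy.json"
        save_model(toy_model, path, "json")
        doc = json.loads(path.read_text())
        doc["model"]["reactions"][0]["metabolites"]["not_a_species"] = 1.0
        path.write_text(json.dumps(doc))
        with pytest.raises(FormatError, match="not_a_species"):
            load_model(path, "json")

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            load_model(tmp_path / "nope.json", "json")

    def test_missing_maintenance_reaction_rejected(self, model):
        model.cobra_model.remove_reactions(["ATPM"])
        with pytest.raises(ConfigurationError):
            fm.MetabolicModel(cobra_model=model.cobra_model, maintenance_id="ATPM")


class TestCarbonCount:
    @pytest.mark.parametrize(
        "species,expected", [("glc__D_c", 6), ("lac__L_c", 3), ("nh4_c", 0), ("trp__L_c", 11)]
    )
    def test_counts_from_formula(self, toy_model, species, expected):
        met = toy_model.cobra_model.metabolites.get_by_id(species)
        assert fm.carbon_count(met) == expected

    def test_missing_formula_is_format_error(self, model):
        met = model.cobra_model.metabolites.get_by_id("glc__D_c")
        met.formula = ""
        with pytest.raises(FormatError):
            fm.carbon_count(met)


class TestProductSynthesis:
    COMPOSITION = {"ala__L": 0.4, "ser__L": 0.3, "lys__L": 0.3}

    def test_polymerization_energetics_per_mole_aa(self, model):
        fm.add_product_synthesis_reaction(model, self.COMPOSITION, "prod")
        rxn = model.cobra_model.reactions.get_by_id("SYNTH_prod")
        coeff = {m.id: c for m, c in rxn.metabolites.items()}
        assert coeff["atp_c"] == pytest.approx(-ATP_PER_AA)  # 1.306 consumed
        assert coeff["gtp_c"] == pytest.approx(-GTP_PER_AA)  # 2 consumed
        assert coeff["adp_c"] == pytest.approx(ADP_PER_AA)  # 0.306 produced
        assert coeff["amp_c"] == pytest.approx(AMP_PER_AA)
        assert coeff["gdp_c"] == pytest.approx(GDP_PER_AA)

    def test_chain_length_scales_coefficients(self, model):
        fm.add_product_synthesis_reaction(
            model, self.COMPOSITION, "prod", chain_length=100.0
        )
        rxn = model.cobra_model.reactions.get_by_id("SYNTH_prod")
        coeff = {m.id: c for m, c in rxn.metabolites.items()}
        assert coeff["gtp_c"] == pytest.approx(-200.0)
        assert coeff["atp_c"] == pytest.approx(-130.6)
        assert coeff["prod_e"] == pytest.approx(1.0)

    def test_reaction_is_elementally_and_charge_balanced(self, model):
        from fluxmaint.model_core import reaction_element_balance

        fm.add_product_synthesis_reaction(model, self.COMPOSITION, "prod", chain_length=42.0)
        rxn = model.cobra_model.reactions.get_by_id("SYNTH_prod")
        assert reaction_element_balance(rxn) == {}

    def test_product_is_exported_and_producible(self, model):
        fm.add_product_synthesis_reaction(model, self.COMPOSITION, "prod")
        model.exchange_for("glc__D").lower_bound = -1.0
        for aa in ("lys__L",):
            model.exchange_for(aa).lower_bound = -1.0
        v = fba(model, model.product_exchange_id, "max")
        assert v.optimal and v.objective_value > 0

    def test_unnormalized_composition_rejected(self, model):
        with pytest.raises(ValidationError):
            fm.add_product_synthesis_reaction(model, {"ala__L": 0.9}, "prod")

    def test_unknown_amino_acid_rejected(self, model):
        with pytest.raises(ConfigurationError):
            fm.add_product_synthesis_reaction(model, {"selenocysteine": 1.0}, "prod")


class TestExchangeConstraints:
    def _dataset(self, rates, **kwargs):
        defaults = dict(dataset_id="d", growth_rate=(0.03, 0.0))
        defaults.update(kwargs)
        return fm.ExchangeDataset(rates=rates, **defaults)

    def test_point_fix_sets_both_bounds(self, model):
        data = self._dataset({"glc__D": (-0.42, 0.02)})
        fm.apply_exchange_constraints(model, data, policy="point-fix")
        assert model.exchange_for("glc__D").bounds == (-0.42, -0.42)

    def test_interval_policy_sets_value_pm_sd(self, model):
        data = self._dataset({"glc__D": (-0.42, 0.02)})
        fm.apply_exchange_constraints(model, data, policy="interval")
        lb, ub = model.exchange_for("glc__D").bounds
        assert (lb, ub) == (pytest.approx(-0.44), pytest.approx(-0.40))

    def test_unmeasured_tryptophan_pinned_to_smallest_aa_uptake(self, model):
        data = self._dataset({"his__L": (-0.02, 0.0), "lys__L": (-0.003, 0.0)})
        fm.apply_exchange_constraints(model, data)
        assert model.exchange_for("trp__L").bounds == (-0.003, -0.003)

    def test_oxygen_never_constrained(self, model):
        before = model.exchange_for("o2").bounds
        data = self._dataset({"o2": (-0.5, 0.0), "glc__D": (-0.3, 0.0)})
        fm.apply_exchange_constraints(model, data)
        assert model.exchange_for("o2").bounds == before


class TestPoRatio:
    def test_default_model_measures_2_5(self, toy_model):
        assert fm.measure_po_ratio(toy_model) == pytest.approx(2.5, abs=1e-6)

    @pytest.mark.parametrize("po", [2.0, 2.25, 2.5, 2.75, 3.0])
    def test_configured_po_is_emergent(self, model, po):
        fm.set_po_ratio(model, po)
        assert fm.measure_po_ratio(model) == pytest.approx(po, abs=1e-6)

    def test_idempotent(self, model):
        fm.set_po_ratio(model, 2.5)
        first = {m.id: c for m, c in model.cobra_model.reactions.ETC_NADH.metabolites.items()}
        fm.set_po_ratio(model, 2.5)
        second = {m.id: c for m, c in model.cobra_model.reactions.ETC_NADH.metabolites.items()}
        assert first == second

    def test_out_of_range_warns_but_applies(self, model):
        with pytest.warns(UserWarning):
            fm.set_po_ratio(model, 1.5)
        assert fm.measure_po_ratio(model) == pytest.approx(1.5, abs=1e-6)
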