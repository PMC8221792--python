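"""Toy model construction and the ground-truth generators."""

import numpy as np
import pytest

import fluxmaint as fm
from fluxmaint.errors import ValidationError, WashoutError
from fluxmaint.model_core import reaction_element_balance
from fluxmaint.synthetic_data import (
    C13_NAMESPACE,
    ToyModelConfig,
    biomass_composition,
    default_mapping_table,
)

EXEMPT = {"ATPM", "BIOMASS_cho", "BIOMASS_cho_producing"}


class TestToyModelConstruction:
    def test_expected_compartments_and_annotations(self, toy_model):
        assert toy_model.compartments == {"e", "c", "m"}
        assert toy_model.maintenance_id == "ATPM"
        assert set(toy_model.biomass_ids) == {"BIOMASS_cho", "BIOMASS_cho_producing"}
        assert set(toy_model.essential_aa_ids) == {"his__L", "lys__L", "trp__L"}

    def test_internal_reactions_elementally_balanced(self, toy_model):
        for rxn in toy_model.cobra_model.reactions:
            if rxn.boundary or rxn.id in EXEMPT:
                continue
            assert reaction_element_balance(rxn) == {}, rxn.id

    def test_maintenance_is_atp_hydrolysis(self, toy_model):
        stoich = {
            m.id: c for m, c in toy_model.cobra_model.reactions.ATPM.metabolites.items()
        }
        assert stoich == {
            "atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1,
        }

    def test_biomass_variants_scale_protein_content(self, toy_model):
        low = biomass_composition(0.56)
        high = biomass_composition(0.70)
        for aa in ("ala__L", "lys__L", "trp__L"):
            assert high[aa] / low[aa] == pytest.approx(0.70 / 0.56, rel=1e-4)
        # the low-protein variant compensates with more carbohydrate/lipid
        assert low["g6p"] > high["g6p"]
        assert low["pyr"] > high["pyr"]

    def test_tryptophan_least_abundant_in_biomass(self, toy_model):
        comp = biomass_composition(0.56)
        aas = {k: v for k, v in comp.items() if k.endswith("__L") and k != "glu__L"}
        assert min(aas, key=aas.get) == "trp__L"

    def test_essential_amino_acids_cannot_be_synthesized(self, model):
        """With no amino acids supplied, growth is impossible."""
        model.exchange_for("glc__D").lower_bound = -10.0
        model.exchange_for("gln__L").lower_bound = -10.0
        v = fm.fba(model, "BIOMASS_cho", "max")
        assert v.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_build_is_deterministic(self):
        a = fm.build_toy_model()
        b = fm.build_toy_model()
        for ra in a.cobra_model.reactions:
            rb = b.cobra_model.reactions.get_by_id(ra.id)
            assert {m.id: c for m, c in ra.metabolites.items()} == {
                m.id: c for m, c in rb.metabolites.items()
            }
            assert ra.bounds == rb.bounds

    def test_invalid_protein_fraction_rejected(self):
        with pytest.raises(ValidationError):
            ToyModelConfig(protein_fraction=0.6)


class TestMappingNamespace:
    def test_covers_all_three_mapping_rules(self):
        table = default_mapping_table()
        entries = {e.c13_id: e.terms for e in table}
        multi_positive = [t for t in entries.values()
                          if len(t) >= 2 and all(s == 1 for _, s in t)]
        signed_net = [t for t in entries.values() if any(s == -1 for _, s in t)]
        singleton = [t for t in entries.values() if len(t) == 1]
        assert multi_positive, "need a compartment-merge / parallel-sum entry"
        assert signed_net, "need a signed net-flux entry"
        assert singleton, "need a one-to-one entry"

    def test_all_terms_resolve_in_the_model(self, toy_model):
        rxn_ids = {r.id for r in toy_model.cobra_model.reactions}
        for _, _, terms in C13_NAMESPACE:
            for rid, _ in terms:
                assert rid in rxn_ids, rid

    def test_subsystems_cover_the_reported_pathways(self):
        subsystems = {s for _, s, _ in C13_NAMESPACE}
        assert {"Glycolysis", "PPP", "TCA", "Pyr metabolism", "AA metabolism"} <= subsystems


class TestC13Generator:
    def test_same_seed_identical_outputs(self, toy_model):
        t = fm.SyntheticTruth(true_matp=6.0, noise_cv=0.1, seed=9)
        ex1, c13_1, _ = fm.simulate_c13_dataset(toy_model, t, "dup")
        ex2, c13_2, _ = fm.simulate_c13_dataset(toy_model, t, "dup")
        assert ex1.rates == ex2.rates
        assert c13_1.fluxes == c13_2.fluxes

    def test_different_dataset_ids_differ(self, toy_model):
        t = fm.SyntheticTruth(true_matp=6.0, noise_cv=0.0, seed=9)
        ex1, _, _ = fm.simulate_c13_dataset(toy_model, t, "a")
        ex2, _, _ = fm.simulate_c13_dataset(toy_model, t, "b")
        assert ex1.rates != ex2.rates

    def test_confidence_intervals_follow_noise_level(self, toy_model):
        t = fm.SyntheticTruth(true_matp=6.0, noise_cv=0.1, seed=9)
        _, c13, _ = fm.simulate_c13_dataset(toy_model, t, "ci")
        for value, lo, hi in c13.fluxes.values():
            if abs(value) > 1e-9:
                assert hi - lo == pytest.approx(2 * 1.96 * 0.1 * abs(value), rel=0.5)

    def test_empirical_noise_matches_requested_cv(self, toy_model):
        """Across datasets the multiplicative scatter of one mapped flux
        has a coefficient of variation close to the configured 10%."""
        t = fm.SyntheticTruth(true_matp=6.0, noise_cv=0.10, seed=21)
        t0 = fm.SyntheticTruth(true_matp=6.0, noise_cv=0.0, seed=21)
        ratios = []
        for i in range(20):
            _, noisy, _ = fm.simulate_c13_dataset(toy_model, t, f"cv{i}")
            _, clean, _ = fm.simulate_c13_dataset(toy_model, t0, f"cv{i}")
            for key in noisy.fluxes:
                true = clean.fluxes[key][0]
                if abs(true) > 1e-6:
                    ratios.append(noisy.fluxes[key][0] / true)
        assert np.std(ratios) == pytest.approx(0.10, rel=0.25)

    def test_datasets_pass_consumer_preconditions(self, toy_model, noiseless_dataset):
        _, exchange, c13, table = noiseless_dataset
        assert c13.exchange is exchange
        kept = fm.filter_small_fluxes(c13)
        assert kept.fluxes  # something survives the 1% filter
        rxn_ids = {r.id for r in toy_model.cobra_model.reactions}
        for entry in table:
            assert all(rid in rxn_ids for rid, _ in entry.terms)


class TestChemostatGenerator:
    def test_washout_above_max_growth(self, toy_model):
        t = fm.SyntheticTruth(true_matp=6.0, noise_cv=0.0, seed=2)
        with pytest.raises(WashoutError):
            fm.simulate_chemostat(toy_model, t, [5.0])

    def test_deterministic_with_seed(self, toy_model):
        t1 = fm.SyntheticTruth(true_matp=6.0, noise_cv=0.1, seed=13)
        t2 = fm.SyntheticTruth(true_matp=6.0, noise_cv=0.1, seed=13)
        r1 = fm.simulate_chemostat(toy_model, t1, [0.02, 0.03])
        r2 = fm.simulate_chemostat(toy_model, t2, [0.02, 0.03])
        for a, b in zip(r1, r2):
            assert np.array_equal(a.feed_mass, b.feed_mass)
            for sid in a.concentrations:
                assert np.array_equal(a.concentrations[sid], b.concentrations[sid])

    def test_growth_exceeds_dilution_via_viability(self, toy_model, noiseless_chemostat):
        _, records = noiseless_chemostat
        for rec in records:
            assert np.all(rec.total_density >= rec.viable_density)

    def test_dilution_range_matches_configuration(self, toy_model, noiseless_chemostat):
        _, records = noiseless_chemostat
        from fluxmaint.chemostat_rates import dilution_rate

        ds = [dilution_rate(r)[0] for r in records]
        assert ds[0] == pytest.approx(0.016, rel=1e-6)
        assert ds[-1] == pytest.approx(0.035, rel=1e-6)

    def test_outlet_concentrations_non_negative(self, toy_model, noiseless_chemostat):
        _, records = noiseless_chemostat
        for rec in records:
            for series in rec.concentrations.values():
                assert np.all(series >= 0.0)
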