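"""Ground-truth generators: toy metabolic model, 13C datasets, chemostat runs.

The toy network is a compartmentalized (extracellular/cytosol/
mitochondrion) central-carbon model in the style of a genome-scale CHO
reconstruction, small enough for brute-force LP oracles: lumped
glycolysis, oxidative pentose phosphate branch, lactate overflow,
pyruvate oxidation and a lumped TCA cycle, glutaminolysis with ammonium
secretion, six amino acids (three essential, i.e. only available from
the medium), essential-amino-acid catabolism, two biomass variants
differing in protein content, a non-growth-associated maintenance
reaction (ATP hydrolysis), and a proton-explicit electron transport
chain in which the P/O ratio is an emergent property of the pumping
stoichiometry (default 10 H+ per NADH, 4 H+ per ATP => P/O 2.5).

Every internal reaction is elementally and charge balanced; the
builder closes each reaction with water and compartment protons and
raises if any other element fails to balance.  Only biomass,
maintenance-style hydrolysis bookkeeping and exchange pseudo-reactions
are exempt from the balance requirement (they are checked for C/N/P/S
conservation only where meaningful).

Synthetic datasets are generated by solving the model at a known true
maintenance value and perturbing every observation with multiplicative
Gaussian noise (truncated at +/-3 sigma so signs never flip), which
emulates the roughly magnitude-proportional uncertainties of 13C-MFA
flux estimates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import cobra
import numpy as np

from .chemostat_rates import ChemostatRecord
from .errors import EngineError, ValidationError, WashoutError
from .fba_engine import FluxVector, pfba
from .flux_mapping import C13Dataset, MappingEntry, MappingTable
from .model_core import (
    DRY_MASS_PG_DEFAULT,
    EtcSpec,
    ExchangeDataset,
    MetabolicModel,
    cells_per_ml_to_gdw_per_l,
)

# -- species table -------------------------------------------------------------

#: species id -> (name, formula, charge); formulas/charges follow the
#: conventions of the BiGG namespace
SPECIES: dict[str, tuple[str, str, int]] = {
    "glc__D": ("D-glucose", "C6H12O6", 0),
    "g6p": ("glucose 6-phosphate", "C6H11O9P", -2),
    "pyr": ("pyruvate", "C3H3O3", -1),
    "lac__L": ("L-lactate", "C3H5O3", -1),
    "ru5p__D": ("ribulose 5-phosphate", "C5H9O8P", -2),
    "accoa": ("acetyl-CoA", "C23H34N7O17P3S", -4),
    "coa": ("coenzyme A", "C21H32N7O16P3S", -4),
    "atp": ("ATP", "C10H12N5O13P3", -4),
    "adp": ("ADP", "C10H12N5O10P2", -3),
    "amp": ("AMP", "C10H12N5O7P", -2),
    "gtp": ("GTP", "C10H12N5O14P3", -4),
    "gdp": ("GDP", "C10H12N5O11P2", -3),
    "pi": ("phosphate", "HPO4", -2),
    "nad": ("NAD+", "C21H26N7O14P2", -1),
    "nadh": ("NADH", "C21H27N7O14P2", -2),
    "nadp": ("NADP+", "C21H25N7O17P3", -3),
    "nadph": ("NADPH", "C21H26N7O17P3", -4),
    "fad": ("FAD", "C27H31N9O15P2", -2),
    "fadh2": ("FADH2", "C27H33N9O15P2", -2),
    "h": ("proton", "H", 1),
    "h2o": ("water", "H2O", 0),
    "o2": ("oxygen", "O2", 0),
    "co2": ("carbon dioxide", "CO2", 0),
    "nh4": ("ammonium", "H4N", 1),
    "gln__L": ("L-glutamine", "C5H10N2O3", 0),
    "glu__L": ("L-glutamate", "C5H8NO4", -1),
    "ala__L": ("L-alanine", "C3H7NO2", 0),
    "asp__L": ("L-aspartate", "C4H6NO4", -1),
    "ser__L": ("L-serine", "C3H7NO3", 0),
    "his__L": ("L-histidine", "C6H9N3O2", 0),
    "lys__L": ("L-lysine", "C6H15N2O2", 1),
    "trp__L": ("L-tryptophan", "C11H12N2O2", 0),
}

EXTRACELLULAR = [
    "glc__D", "lac__L", "gln__L", "nh4", "o2", "co2", "h", "h2o", "pi",
    "ala__L", "asp__L", "ser__L", "his__L", "lys__L", "trp__L",
]

AMINO_ACIDS = ["ala__L", "asp__L", "ser__L", "his__L", "lys__L", "trp__L"]
ESSENTIAL_AAS = ["his__L", "lys__L", "trp__L"]

#: biomass amino-acid mole fractions (tryptophan is the least abundant)
AA_MOLE_FRACTIONS = {
    "ala__L": 0.28, "asp__L": 0.18, "ser__L": 0.14,
    "his__L": 0.10, "lys__L": 0.22, "trp__L": 0.08,
}

#: average residue molar mass used to convert protein mass fraction to
#: mmol of amino acids per gDW
MEAN_AA_MW = 110.0


@dataclass
class ToyModelConfig:
    """Construction parameters of the toy model (deterministic build)."""

    po_nadh: float = 2.5
    #: growth-associated ATP demand embedded in biomass (mmol per gDW).
    #: The default lumps macromolecule polymerization, transport and
    #: assembly costs, matching the order of magnitude of the ATP-vs-
    #: growth slope observed in mammalian chemostat cultures.
    gam: float = 150.0
    protein_fraction: float = 0.56  # selects the default biomass variant
    essential_aas: list[str] = field(default_factory=lambda: list(ESSENTIAL_AAS))

    def __post_init__(self) -> None:
        if self.protein_fraction not in (0.56, 0.70):
            raise ValidationError("protein_fraction must be 0.56 or 0.70")
        unknown = set(self.essential_aas) - set(AMINO_ACIDS)
        if unknown:
            raise ValidationError(f"unknown essential amino acids: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground truth planted in generated datasets.

    ``true_yatp`` (g biomass per mol ATP) is an emergent property of the
    network and the growth-associated maintenance; when left ``None`` it
    is computed by :func:`implied_atp_line` and filled in.
    """

    true_matp: float = 6.0  # mmol gDW^-1 h^-1
    true_yatp: float | None = None
    noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_matp < 0 or self.noise_cv < 0:
            raise ValidationError("true_matp and noise_cv must be non-negative")


# -- model construction --------------------------------------------------------


def _met(sid: str, comp: str) -> cobra.Metabolite:
    name, formula, charge = SPECIES[sid]
    return cobra.Metabolite(
        f"{sid}_{comp}", name=name, formula=formula, charge=charge, compartment=comp
    )


def _close_and_check(
    stoich: dict[cobra.Metabolite, float],
    mets: dict[str, cobra.Metabolite],
    h2o: str | None,
    h: str | None,
    rxn_id: str,
) -> dict[cobra.Metabolite, float]:
    """Close a reaction with water/protons and verify elemental balance.

    Oxygen imbalance is absorbed by the designated water species, the
    remaining hydrogen imbalance by the designated proton species; the
    result must then be balanced in every element and in charge, which
    guards the hand-written stoichiometries against slips.
    """
    def net() -> dict[str, float]:
        out: dict[str, float] = {}
        for m, c in stoich.items():
            for el, cnt in m.elements.items():
                out[el] = out.get(el, 0.0) + c * cnt
            out["charge"] = out.get("charge", 0.0) + c * (m.charge or 0)
        return out

    balance = net()
    for el in ("C", "N", "P", "S"):
        if abs(balance.get(el, 0.0)) > 1e-9:
            raise EngineError(f"{rxn_id}: element {el} off by {balance[el]}")
    if h2o is not None:
        d = balance.get("O", 0.0)
        if abs(d) > 1e-9:
            m = mets[h2o]
            stoich[m] = stoich.get(m, 0.0) - d
    if h is not None:
        d = net().get("H", 0.0)
        if abs(d) > 1e-9:
            m = mets[h]
            stoich[m] = stoich.get(m, 0.0) - d
    balance = net()
    bad = {k: v for k, v in balance.items() if abs(v) > 1e-9}
    if bad:
        raise EngineError(f"{rxn_id}: unbalanced after closure: {bad}")
    return stoich


def build_toy_model(config: ToyModelConfig | None = None) -> MetabolicModel:
    """Deterministically build the toy CHO-style model."""
    config = config or ToyModelConfig()
    cm = cobra.Model("toy_cho")
    cm.compartments = {"e": "extracellular", "c": "cytosol", "m": "mitochondrion"}

    mets: dict[str, cobra.Metabolite] = {}
    placement = {
        "e": EXTRACELLULAR,
        "c": [
            "glc__D", "g6p", "pyr", "lac__L", "ru5p__D", "atp", "adp", "amp",
            "gtp", "gdp", "pi", "nad", "nadh", "nadp", "nadph", "h", "h2o",
            "o2", "co2", "nh4", "gln__L", "glu__L",
            "ala__L", "asp__L", "ser__L", "his__L", "lys__L", "trp__L",
        ],
        "m": [
            "pyr", "accoa", "coa", "atp", "adp", "gtp", "gdp", "pi", "nad",
            "nadh", "fad", "fadh2", "h", "h2o", "o2", "co2", "nh4",
            "gln__L", "glu__L", "his__L", "lys__L", "trp__L",
        ],
    }
    for comp, sids in placement.items():
        for sid in sids:
            mets[f"{sid}_{comp}"] = _met(sid, comp)
    cm.add_metabolites(list(mets.values()))

    # (id, name, subsystem, stoichiometry, (lb, ub), (h2o_id, h_id) closure)
    FREE = (-1000.0, 1000.0)
    FWD = (0.0, 1000.0)
    reactions: list[tuple] = [
        # transporters (balanced as written; no closure species)
        ("GLCt", "glucose transport", "Transport", {"glc__D_e": -1, "glc__D_c": 1}, FREE, (None, None)),
        ("LACt", "lactate/H+ symport", "Transport", {"lac__L_c": -1, "h_c": -1, "lac__L_e": 1, "h_e": 1}, FREE, (None, None)),
        ("GLNt", "glutamine transport", "Transport", {"gln__L_e": -1, "gln__L_c": 1}, FREE, (None, None)),
        ("NH4t", "ammonium export", "Transport", {"nh4_c": -1, "nh4_e": 1}, FWD, (None, None)),
        ("O2t", "oxygen diffusion", "Transport", {"o2_e": -1, "o2_c": 1}, FREE, (None, None)),
        ("O2tm", "oxygen diffusion, mitochondrial", "Transport", {"o2_c": -1, "o2_m": 1}, FREE, (None, None)),
        ("CO2t", "CO2 diffusion", "Transport", {"co2_c": -1, "co2_e": 1}, FREE, (None, None)),
        ("CO2tm", "CO2 diffusion, mitochondrial", "Transport", {"co2_m": -1, "co2_c": 1}, FREE, (None, None)),
        ("H2Ot", "water diffusion", "Transport", {"h2o_e": -1, "h2o_c": 1}, FREE, (None, None)),
        ("H2Otm", "water diffusion, mitochondrial", "Transport", {"h2o_c": -1, "h2o_m": 1}, FREE, (None, None)),
        ("Ht", "proton diffusion, plasma membrane", "Transport", {"h_e": -1, "h_c": 1}, FREE, (None, None)),
        ("PIt", "phosphate/H+ symport", "Transport", {"pi_e": -1, "h_e": -1, "pi_c": 1, "h_c": 1}, FREE, (None, None)),
        ("ALAt", "alanine transport", "Transport", {"ala__L_e": -1, "ala__L_c": 1}, FREE, (None, None)),
        ("ASPt", "aspartate/H+ symport", "Transport", {"asp__L_e": -1, "h_e": -1, "asp__L_c": 1, "h_c": 1}, FREE, (None, None)),
        ("SERt", "serine transport", "Transport", {"ser__L_e": -1, "ser__L_c": 1}, FREE, (None, None)),
        ("HISt", "histidine transport", "Transport", {"his__L_e": -1, "his__L_c": 1}, FREE, (None, None)),
        ("LYSt", "lysine transport", "Transport", {"lys__L_e": -1, "lys__L_c": 1}, FREE, (None, None)),
        ("TRPt", "tryptophan transport", "Transport", {"trp__L_e": -1, "trp__L_c": 1}, FREE, (None, None)),
        ("HIStm", "histidine transport, mitochondrial", "Transport", {"his__L_c": -1, "his__L_m": 1}, FWD, (None, None)),
        ("LYStm", "lysine transport, mitochondrial", "Transport", {"lys__L_c": -1, "lys__L_m": 1}, FWD, (None, None)),
        ("TRPtm", "tryptophan transport, mitochondrial", "Transport", {"trp__L_c": -1, "trp__L_m": 1}, FWD, (None, None)),
        ("GLNtm", "glutamine transport, mitochondrial", "Transport", {"gln__L_c": -1, "gln__L_m": 1}, FWD, (None, None)),
        ("GLUtm", "glutamate/H+ symport, mitochondrial", "Transport", {"glu__L_c": -1, "h_c": -1, "glu__L_m": 1, "h_m": 1}, FWD, (None, None)),
        ("PYRtm", "pyruvate/H+ symport, mitochondrial", "Transport", {"pyr_c": -1, "h_c": -1, "pyr_m": 1, "h_m": 1}, FWD, (None, None)),
        ("NH4tm", "ammonium export, mitochondrial", "Transport", {"nh4_m": -1, "nh4_c": 1}, FWD, (None, None)),
        ("ANT", "adenine nucleotide translocase", "Transport", {"atp_m": -1, "adp_c": -1, "atp_c": 1, "adp_m": 1}, FREE, (None, None)),
        ("PItm", "phosphate/H+ symport, mitochondrial", "Transport", {"pi_c": -1, "h_c": -1, "pi_m": 1, "h_m": 1}, FWD, (None, None)),
        # glycolysis, PPP, overflow
        ("HK", "hexokinase", "Glycolysis", {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}, FWD, ("h2o_c", "h_c")),
        ("GLYC", "glycolysis glucose -> 2 pyruvate (lumped)", "Glycolysis",
         {"glc__D_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2, "pyr_c": 2, "atp_c": 2, "nadh_c": 2}, FWD, ("h2o_c", "h_c")),
        ("G6PASE", "glucose 6-phosphatase", "Glycolysis", {"g6p_c": -1, "h2o_c": -1, "glc__D_c": 1, "pi_c": 1}, FWD, (None, "h_c")),
        ("PPP", "oxidative pentose phosphate branch (lumped)", "PPP",
         {"g6p_c": -1, "nadp_c": -2, "ru5p__D_c": 1, "nadph_c": 2, "co2_c": 1}, FWD, ("h2o_c", "h_c")),
        ("PPP_NONOX", "non-oxidative pentose phosphate return (lumped)", "PPP",
         {"ru5p__D_c": -6, "g6p_c": 5, "pi_c": 1}, FWD, ("h2o_c", "h_c")),
        ("LDH", "lactate dehydrogenase", "Pyr metabolism",
         {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac__L_c": 1, "nad_c": 1}, FREE, (None, None)),
        ("MAS", "malate-aspartate shuttle (lumped)", "Transport",
         {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1}, FWD, (None, None)),
        # pyruvate oxidation and TCA
        ("PDH", "pyruvate dehydrogenase", "Pyr metabolism",
         {"pyr_m": -1, "coa_m": -1, "nad_m": -1, "accoa_m": 1, "co2_m": 1, "nadh_m": 1}, FWD, ("h2o_m", "h_m")),
        ("TCA", "TCA cycle (lumped)", "TCA",
         {"accoa_m": -1, "nad_m": -3, "fad_m": -1, "gdp_m": -1, "pi_m": -1,
          "coa_m": 1, "co2_m": 2, "nadh_m": 3, "fadh2_m": 1, "gtp_m": 1}, FWD, ("h2o_m", "h_m")),
        # oxidative phosphorylation (proton-explicit; pumping set below)
        ("ETC_NADH", "NADH dehydrogenase-ETC (lumped)", "OxPhos",
         {"nadh_m": -1, "o2_m": -0.5, "nad_m": 1, "h2o_m": 1, "h_c": 10.0}, FWD, (None, "h_m")),
        ("ETC_FADH2", "FADH2-ETC branch (lumped)", "OxPhos",
         {"fadh2_m": -1, "o2_m": -0.5, "fad_m": 1, "h2o_m": 1, "h_c": 6.0}, FWD, (None, "h_m")),
        ("ATPS", "ATP synthase", "OxPhos",
         {"adp_m": -1, "pi_m": -1, "h_c": -4, "atp_m": 1, "h2o_m": 1}, FWD, (None, "h_m")),
        ("NDPK_m", "nucleoside-diphosphate kinase, mitochondrial", "Nucleotides",
         {"atp_m": -1, "gdp_m": -1, "adp_m": 1, "gtp_m": 1}, FREE, (None, None)),
        ("NDPK_c", "nucleoside-diphosphate kinase", "Nucleotides",
         {"atp_c": -1, "gdp_c": -1, "adp_c": 1, "gtp_c": 1}, FREE, (None, None)),
        ("AK_c", "adenylate kinase", "Nucleotides",
         {"atp_c": -1, "amp_c": -1, "adp_c": 2}, FREE, (None, None)),
        # glutaminolysis (cytosolic and mitochondrial glutaminase)
        ("GLNASE_c", "glutaminase, cytosolic", "AA metabolism",
         {"gln__L_c": -1, "h2o_c": -1, "glu__L_c": 1, "nh4_c": 1}, FWD, (None, None)),
        ("GLNASE_m", "glutaminase, mitochondrial", "AA metabolism",
         {"gln__L_m": -1, "h2o_m": -1, "glu__L_m": 1, "nh4_m": 1}, FWD, (None, None)),
        ("GLUOX", "glutamate oxidation (lumped)", "AA metabolism",
         {"glu__L_m": -1, "nad_m": -8, "fad_m": -1, "gdp_m": -1, "pi_m": -1,
          "co2_m": 5, "nh4_m": 1, "nadh_m": 8, "fadh2_m": 1, "gtp_m": 1}, FWD, ("h2o_m", "h_m")),
        # nonessential amino-acid synthesis (reversible = catabolism)
        ("ALATA", "alanine synthesis (reductive amination, lumped)", "AA metabolism",
         {"pyr_c": -1, "nh4_c": -1, "nadh_c": -1, "ala__L_c": 1, "nad_c": 1}, FREE, ("h2o_c", "h_c")),
        ("ASPSYN", "aspartate synthesis (carboxylation, lumped)", "AA metabolism",
         {"pyr_c": -1, "co2_c": -1, "nh4_c": -1, "atp_c": -1, "nadh_c": -1,
          "asp__L_c": 1, "adp_c": 1, "pi_c": 1, "nad_c": 1}, FREE, ("h2o_c", "h_c")),
        ("SERSYN", "serine synthesis (amination, lumped)", "AA metabolism",
         {"pyr_c": -1, "nh4_c": -1, "ser__L_c": 1}, FREE, ("h2o_c", "h_c")),
        # essential amino-acid catabolism (fully oxidized)
        ("HISDEG", "histidine degradation (lumped)", "AA metabolism",
         {"his__L_m": -1, "nad_m": -9, "fad_m": -1,
          "co2_m": 6, "nh4_m": 3, "nadh_m": 9, "fadh2_m": 1}, FWD, ("h2o_m", "h_m")),
        ("LYSDEG", "lysine degradation (lumped)", "AA metabolism",
         {"lys__L_m": -1, "nad_m": -13, "fad_m": -1,
          "co2_m": 6, "nh4_m": 2, "nadh_m": 13, "fadh2_m": 1}, FWD, ("h2o_m", "h_m")),
        ("TRPDEG", "tryptophan degradation (lumped)", "AA metabolism",
         {"trp__L_m": -1, "nad_m": -22, "fad_m": -1,
          "co2_m": 11, "nh4_m": 2, "nadh_m": 22, "fadh2_m": 1}, FWD, ("h2o_m", "h_m")),
    ]

    built = []
    for rid, name, subsystem, spec, bounds, (h2o_id, h_id) in reactions:
        stoich = {mets[mid]: float(coeff) for mid, coeff in spec.items()}
        stoich = _close_and_check(stoich, mets, h2o_id, h_id, rid)
        rxn = cobra.Reaction(rid, name=name, lower_bound=bounds[0], upper_bound=bounds[1])
        rxn.subsystem = subsystem
        rxn.add_metabolites(stoich)
        built.append(rxn)

    # maintenance: non-growth-associated ATP hydrolysis
    atpm = cobra.Reaction("ATPM", name="maintenance ATP hydrolysis", lower_bound=0.0, upper_bound=1000.0)
    atpm.subsystem = "Maintenance"
    atpm.add_metabolites({
        mets["atp_c"]: -1, mets["h2o_c"]: -1,
        mets["adp_c"]: 1, mets["pi_c"]: 1, mets["h_c"]: 1,
    })
    built.append(atpm)

    built.extend(_biomass_reactions(mets, config.gam))
    cm.add_reactions(built)

    for sid in EXTRACELLULAR:
        ex = cm.add_boundary(mets[f"{sid}_e"], type="exchange")
        ex.bounds = _default_exchange_bounds(sid)

    default_biomass = _ordered_biomass_ids(config.protein_fraction)[0]
    cm.objective = cm.reactions.get_by_id(default_biomass)

    model = MetabolicModel(
        cobra_model=cm,
        biomass_ids=_ordered_biomass_ids(config.protein_fraction),
        maintenance_id="ATPM",
        amino_acid_ids=list(AMINO_ACIDS),
        essential_aa_ids=list(config.essential_aas),
        trp_id="trp__L",
        oxygen_id="o2",
        etc=EtcSpec(),
    )
    if config.po_nadh != 2.5:
        from .model_core import set_po_ratio

        set_po_ratio(model, config.po_nadh)
    return model


def _ordered_biomass_ids(protein_fraction: float) -> list[str]:
    ids = ["BIOMASS_cho", "BIOMASS_cho_producing"]
    return ids if protein_fraction == 0.56 else ids[::-1]


def biomass_composition(protein_fraction: float) -> dict[str, float]:
    """Precursor coefficients (mmol per gDW) of a biomass variant.

    The low-protein variant compensates with more carbohydrate, lipid
    and nucleotide mass, mirroring how the two CHO biomass equations
    differ.
    """
    total_aa = protein_fraction * 1000.0 / MEAN_AA_MW
    # 6-decimal coefficients survive SBML text round-trips exactly
    coeffs = {aa: round(frac * total_aa, 6) for aa, frac in AA_MOLE_FRACTIONS.items()}
    if protein_fraction == 0.56:
        coeffs.update({"g6p": 0.95, "ru5p__D": 0.22, "pyr": 1.80})
    else:
        coeffs.update({"g6p": 0.55, "ru5p__D": 0.12, "pyr": 1.00})
    coeffs["nadph"] = 2.0 * coeffs["pyr"]
    return coeffs


def _biomass_reactions(mets: dict[str, cobra.Metabolite], gam: float) -> list[cobra.Reaction]:
    out = []
    for rid, pf in (("BIOMASS_cho", 0.56), ("BIOMASS_cho_producing", 0.70)):
        comp = biomass_composition(pf)
        rxn = cobra.Reaction(rid, name=f"biomass, protein fraction {pf:.2f}", lower_bound=0.0, upper_bound=1000.0)
        rxn.subsystem = "Biomass"
        stoich: dict[cobra.Metabolite, float] = {}
        for sid, coeff in comp.items():
            stoich[mets[f"{sid}_c"]] = -coeff
        # NADPH is consumed as NADPH + H+ -> NADP+ during reductive biosynthesis
        stoich[mets["nadp_c"]] = comp["nadph"]
        stoich[mets["h_c"]] = -comp["nadph"]
        # growth-associated maintenance: gam * (ATP + H2O -> ADP + Pi + H)
        stoich[mets["atp_c"]] = stoich.get(mets["atp_c"], 0.0) - gam
        stoich[mets["h2o_c"]] = -gam
        stoich[mets["adp_c"]] = gam
        stoich[mets["pi_c"]] = gam
        stoich[mets["h_c"]] += gam
        rxn.add_metabolites(stoich)
        out.append(rxn)
    return out


def _default_exchange_bounds(sid: str) -> tuple[float, float]:
    if sid in ("o2", "h", "h2o", "pi"):
        return (-1000.0, 1000.0)
    if sid in ("co2", "nh4", "lac__L"):
        return (0.0, 1000.0)  # secretion only by default
    return (0.0, 1000.0)  # nutrients closed until constrained


def bundled_model_path(dialect: str = "json") -> str:
    """Path of the bundled toy model file (native JSON or SBML L3+FBC)."""
    from importlib import resources

    name = {"json": "toy_cho.json", "sbml": "toy_cho.xml"}.get(dialect)
    if name is None:
        raise ValidationError(f"unknown model dialect {dialect!r}")
    return str(resources.files("fluxmaint").joinpath("data", name))


# -- P/O measurement oracle ----------------------------------------------------


def measure_po_ratio(model: MetabolicModel) -> float:
    """Measure ATP made per NADH oxidized by FBA.

    All exchanges are closed, a unit NADH-regeneration flux
    (water-splitting: NAD+ + H2O -> NADH + 1/2 O2 + H+) is fixed in the
    matrix, and ATP hydrolysis is maximized; the objective value is the
    operational P/O ratio of the model.
    """
    cm = model.cobra_model
    with cm:
        for rxn in cm.boundary:
            rxn.bounds = (0.0, 0.0)
        comp = model.etc.matrix_h.rsplit("_", 1)[1]
        probe = cobra.Reaction("NADH_PROBE", name="NADH regeneration probe")
        probe.add_metabolites({
            cm.metabolites.get_by_id(f"nad_{comp}"): -1,
            cm.metabolites.get_by_id(f"h2o_{comp}"): -1,
            cm.metabolites.get_by_id(f"nadh_{comp}"): 1,
            cm.metabolites.get_by_id(f"o2_{comp}"): 0.5,
            cm.metabolites.get_by_id(f"h_{comp}"): 1,
        })
        probe.bounds = (1.0, 1.0)
        cm.add_reactions([probe])
        cm.objective = cm.reactions.get_by_id(model.maintenance_id)
        cm.objective_direction = "max"
        solution = cm.optimize()
        if solution.status != "optimal":
            raise EngineError(f"P/O measurement LP returned {solution.status}")
        return float(solution.objective_value)


# -- 13C dataset generation ----------------------------------------------------

#: the synthetic 13C namespace: (c13_id, subsystem, signed genome-scale terms)
C13_NAMESPACE: list[tuple[str, str, list[tuple[str, int]]]] = [
    ("HK_net", "Glycolysis", [("HK", 1), ("G6PASE", -1)]),          # lumped net (rule 3)
    ("GLYC", "Glycolysis", [("GLYC", 1)]),
    ("PPP_ox", "PPP", [("PPP", 1)]),
    ("LDH_net", "Pyr metabolism", [("LDH", 1)]),
    ("PDH", "Pyr metabolism", [("PDH", 1)]),
    ("PC_ASP", "Pyr metabolism", [("ASPSYN", 1)]),
    ("TCA_CS", "TCA", [("TCA", 1)]),
    ("AKG_OX", "TCA", [("GLUOX", 1)]),
    ("GLS", "AA metabolism", [("GLNASE_c", 1), ("GLNASE_m", 1)]),   # compartment merge (rule 2)
    ("AA_TO_PYR", "AA metabolism", [("ALATA", -1), ("SERSYN", -1)]),  # parallel sum (rule 1)
    ("ALATA", "AA metabolism", [("ALATA", 1)]),
    ("SERSYN", "AA metabolism", [("SERSYN", 1)]),
    ("ESS_DEG", "AA metabolism", [("HISDEG", 1), ("LYSDEG", 1), ("TRPDEG", 1)]),
]

#: species whose exchange rates are "measured" in generated datasets.
#: Ammonium and the nonessential amino acids are deliberately left
#: unmeasured: literature 13C datasets rarely report complete exchange
#: panels, and the resulting unconstrained waste routes are what lets
#: growth maximization respond to the maintenance constraint at all.
C13_MEASURED_SPECIES = [
    "glc__D", "gln__L", "lac__L", "his__L", "lys__L", "trp__L",
]


def default_mapping_table() -> MappingTable:
    return MappingTable(entries={
        c13_id: MappingEntry(c13_id=c13_id, terms=list(terms))
        for c13_id, _, terms in C13_NAMESPACE
    })


def _dataset_rng(seed: int, dataset_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(dataset_id.encode()) % 2**31])


def _noise_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0.0:
        return 1.0
    z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
    return 1.0 + cv * z


def simulate_c13_dataset(
    model: MetabolicModel,
    truth: SyntheticTruth,
    dataset_id: str,
    biomass_id: str | None = None,
    max_retries: int = 20,
) -> tuple[ExchangeDataset, C13Dataset, MappingTable]:
    """Generate one synthetic 13C-MFA dataset with known ground truth.

    A random feasible nutrient environment is sampled (seeded by
    ``truth.seed`` and the dataset id), the maintenance reaction is
    fixed at the true value, pFBA maximizes growth, and the solution is
    projected into the 13C namespace.  Every observation is then
    perturbed multiplicatively; confidence intervals are set to
    +/- 1.96 * cv * |value|.
    """
    biomass_id = biomass_id or model.biomass_ids[0]
    rng = _dataset_rng(truth.seed, dataset_id)
    # a fresh copy gives a fresh LP; re-using one solver across calls can
    # return optima differing in the last float digits (basis carry-over),
    # which would break the byte-identical determinism contract
    model = model.copy()
    cm = model.cobra_model

    solution: FluxVector | None = None
    for _ in range(max_retries):
        env = {
            "glc__D": -float(rng.uniform(0.20, 0.38)),
            "gln__L": -float(rng.uniform(0.03, 0.06)),
            "o2": -float(rng.uniform(3.0, 4.5)),
        }
        # essential amino acids are offered moderately above the biomass
        # requirement; the surplus is catabolized, as in rich media,
        # so the realized state is energy- rather than nitrogen-limited
        mu_cap = float(rng.uniform(0.05, 0.07))
        coeffs = biomass_composition(0.56 if biomass_id == "BIOMASS_cho" else 0.70)
        for aa in model.essential_aa_ids:
            env[aa] = -mu_cap * coeffs[aa]
        with cm:
            for sid, lb in env.items():
                model.exchange_for(sid).lower_bound = lb
            maint = cm.reactions.get_by_id(model.maintenance_id)
            maint.bounds = (truth.true_matp, truth.true_matp)
            candidate = pfba(model, objective=biomass_id, direction="max")
        if candidate.optimal and candidate.objective_value > 0.005:
            solution = candidate
            break
    if solution is None:
        raise EngineError(
            f"no feasible synthetic environment found for {dataset_id!r} "
            f"after {max_retries} attempts"
        )

    cv = truth.noise_cv
    rates: dict[str, tuple[float, float]] = {}
    for sid in C13_MEASURED_SPECIES:
        value = solution.fluxes[model.exchange_for(sid).id]
        noisy = value * _noise_factor(rng, cv)
        rates[sid] = (noisy, cv * abs(value))
    mu_true = solution.objective_value
    growth = (mu_true * _noise_factor(rng, cv), cv * mu_true)

    exchange = ExchangeDataset(
        dataset_id=dataset_id,
        rates=rates,
        growth_rate=growth,
        productivity=(0.0, 0.0),
        dry_mass=DRY_MASS_PG_DEFAULT,
    )

    table = default_mapping_table()
    fluxes: dict[str, tuple[float, float, float]] = {}
    subsystem: dict[str, str] = {}
    for c13_id, subsys, terms in C13_NAMESPACE:
        true_value = sum(sign * solution.fluxes[rid] for rid, sign in terms)
        noisy = true_value * _noise_factor(rng, cv)
        half = 1.96 * cv * abs(true_value)
        fluxes[c13_id] = (noisy, noisy - half, noisy + half)
        subsystem[c13_id] = subsys
    c13 = C13Dataset(
        dataset_id=dataset_id, fluxes=fluxes, subsystem=subsystem, exchange=exchange
    )
    return exchange, c13, table


# -- chemostat generation ------------------------------------------------------

#: feed concentrations (mM) emulating a chemically defined CHO medium
#: supplemented with 8 mM glutamine
DEFAULT_FEED = {
    "glc__D": 35.0, "gln__L": 8.0,
    "his__L": 6.0, "lys__L": 10.0, "trp__L": 4.0,
    "ala__L": 0.0, "asp__L": 0.0, "ser__L": 2.0,
    "lac__L": 0.0, "nh4": 0.0, "co2": 0.0,
}

#: glutamine uptake scales with growth in the generator (mmol gDW^-1
#: per unit growth rate), keeping all growth-dependent energy terms
#: proportional to mu so the maintenance intercept stays interpretable
GLN_PER_MU = 2.0

CHEMOSTAT_VIABILITY = 0.95
RESIDUAL_GLUCOSE_MM = 2.0


def _chemostat_steady_state(
    model: MetabolicModel,
    truth: SyntheticTruth,
    mu: float,
    biomass_id: str,
) -> FluxVector:
    """Solve the per-gDW steady-state flux state at growth rate ``mu``.

    Maintenance is fixed at the true value, essential amino-acid
    availability scales with mu (they are used for biomass only),
    glutamine uptake scales with mu, and glucose uptake is minimized:
    at steady state the culture is substrate-limited and wastes nothing.
    """
    model = model.copy()  # fresh LP for strict determinism
    cm = model.cobra_model
    coeffs = biomass_composition(0.56 if biomass_id == "BIOMASS_cho" else 0.70)
    cm.reactions.get_by_id(model.maintenance_id).bounds = (truth.true_matp, truth.true_matp)
    for bid in model.biomass_ids:
        cm.reactions.get_by_id(bid).bounds = (mu, mu) if bid == biomass_id else (0.0, 0.0)
    for aa in model.essential_aa_ids:
        model.exchange_for(aa).lower_bound = -mu * coeffs[aa]
    model.exchange_for("gln__L").lower_bound = -GLN_PER_MU * mu
    glc_ex = model.exchange_for("glc__D")
    glc_ex.bounds = (-1000.0, 0.0)
    # minimize uptake magnitude = maximize the (negative) exchange flux
    return pfba(model, objective=glc_ex.id, direction="max")


def implied_atp_line(
    model: MetabolicModel,
    truth: SyntheticTruth,
    biomass_id: str | None = None,
    mu_probe: tuple[float, float] = (0.02, 0.04),
) -> tuple[float, float]:
    """Ground-truth (intercept, slope) of total ATP production vs growth.

    Probes the steady-state generator at two growth rates and returns
    the implied line; the intercept equals the true maintenance and the
    slope is the growth-associated ATP cost of the network (its inverse
    x 1000 is the true maximal biomass yield per ATP in g/mol).
    """
    from .fba_engine import total_ntp_production

    biomass_id = biomass_id or model.biomass_ids[0]
    atp = []
    for mu in mu_probe:
        v = _chemostat_steady_state(model, truth, mu, biomass_id)
        if not v.optimal:
            raise EngineError(f"steady-state probe infeasible at mu={mu}")
        atp.append(total_ntp_production(v, model))
    slope = (atp[1] - atp[0]) / (mu_probe[1] - mu_probe[0])
    intercept = atp[0] - slope * mu_probe[0]
    return intercept, slope


def simulate_chemostat(
    model: MetabolicModel,
    truth: SyntheticTruth,
    dilution_rates: list[float],
    feed: dict[str, float] | None = None,
    biomass_id: str | None = None,
    viability: float = CHEMOSTAT_VIABILITY,
    n_samples: int = 5,
    window_h: float = 48.0,
    volume_ml: float = 270.0,
) -> list[ChemostatRecord]:
    """Simulate steady-state continuous cultures at the given dilution rates.

    For each dilution rate D the per-cell state is solved at growth rate
    mu = D / viability, the biomass concentration follows from the
    glucose balance at a fixed residual glucose, and outlet
    concentrations follow from mass balance Cout = Cin + q X / D, so the
    run is carbon-balanced by construction.  Measurement noise
    (multiplicative, CV ``truth.noise_cv``) is applied to concentration,
    cell-count and feed-mass readings.  If ``truth.true_yatp`` is unset
    it is filled in from :func:`implied_atp_line`.
    """
    feed = dict(DEFAULT_FEED if feed is None else feed)
    biomass_id = biomass_id or model.biomass_ids[0]
    rng = _dataset_rng(truth.seed, "chemostat")
    if truth.true_yatp is None:
        _, slope = implied_atp_line(model, truth, biomass_id)
        truth.true_yatp = 1000.0 / slope

    records: list[ChemostatRecord] = []
    for i, D in enumerate(dilution_rates):
        mu = D / viability
        v = _chemostat_steady_state(model, truth, mu, biomass_id)
        if not v.optimal:
            raise WashoutError(
                f"dilution rate {D} (growth {mu:.4f}) is infeasible for the model"
            )
        q = {
            sid: v.fluxes[model.exchange_for(sid).id]
            for sid in feed
        }
        q_glc = q["glc__D"]
        if q_glc >= 0:
            raise WashoutError(f"no glucose uptake at dilution rate {D}")
        X = D * (feed["glc__D"] - RESIDUAL_GLUCOSE_MM) / (-q_glc)  # gDW L^-1
        nv = X * 1e6 / DRY_MASS_PG_DEFAULT  # cells mL^-1

        cout = {}
        for sid, cin in feed.items():
            cout[sid] = cin + q[sid] * X / D
            if cout[sid] < -1e-9:
                # the feed cannot supply the culture's demand at this
                # dilution rate: no steady state exists, the culture
                # washes out
                raise WashoutError(
                    f"feed cannot sustain D={D}: {sid!r} outlet would be "
                    f"{cout[sid]:.3f} mM"
                )

        times = np.linspace(0.0, window_h, n_samples)
        cv = truth.noise_cv
        F = D * volume_ml  # mL h^-1, medium density 1 g mL^-1
        feed_mass = np.array([
            F * t * (1.0 + 0.2 * cv * float(np.clip(rng.standard_normal(), -3, 3)))
            for t in times
        ])
        nv_series = np.array([nv * _noise_factor(rng, cv) for _ in times])
        viab_meas = np.minimum(
            1.0, viability * np.array([_noise_factor(rng, 0.2 * cv) for _ in times])
        )
        nt_series = nv_series / viab_meas
        conc = {
            sid: np.array([max(cout[sid], 0.0) * _noise_factor(rng, cv) for _ in times])
            for sid in feed
        }
        records.append(
            ChemostatRecord(
                record_id=f"DR{i + 1}",
                times=times,
                feed_mass=feed_mass,
                volume_ml=volume_ml,
                viable_density=nv_series,
                total_density=nt_series,
                concentrations=conc,
                feed_concentrations=dict(feed),
                dry_mass=DRY_MASS_PG_DEFAULT,
            )
        )
    return records


# -- random small models for LP oracles ----------------------------------------


def random_small_model(seed: int, n_reactions: int = 8, n_metabolites: int = 4) -> cobra.Model:
    """A random bounded LP network for cross-checking the FBA/pFBA engine.

    Stoichiometric coefficients are small integers, every reaction has
    finite bounds containing zero (so the model is always feasible and
    bounded), and roughly a third of the reactions are exchanges.
    """
    rng = np.random.default_rng(seed)
    cm = cobra.Model(f"random_{seed}")
    mets = [
        cobra.Metabolite(f"M{j}", compartment="c") for j in range(n_metabolites)
    ]
    cm.add_metabolites(mets)
    rxns = []
    for i in range(n_reactions):
        rxn = cobra.Reaction(f"R{i}")
        n_terms = int(rng.integers(1, 3)) if i < n_reactions // 3 else int(rng.integers(2, 4))
        chosen = rng.choice(n_metabolites, size=min(n_terms, n_metabolites), replace=False)
        stoich = {}
        for j in chosen:
            coeff = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
            stoich[mets[j]] = coeff
        rxn.add_metabolites(stoich)
        lb = -float(rng.integers(0, 6))
        ub = float(rng.integers(1, 6))
        rxn.bounds = (lb, ub)
        rxns.append(rxn)
    cm.add_reactions(rxns)
    return cm
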