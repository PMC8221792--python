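"""Stoichiometric model container, model I/O and model-editing operations.

The in-memory representation wraps a :class:`cobra.Model` and adds the
pipeline-level annotations constraint-based CHO workflows need: which
reactions are biomass variants, which one is the non-growth-associated
maintenance (ATP hydrolysis) reaction, which extracellular species are
amino acids, and how the electron transport chain is parameterized so
that the P/O ratio is an emergent, sweepable property.

Units: all fluxes are mmol gDW^-1 h^-1, growth rates h^-1.
Sign convention for exchange fluxes: uptake < 0, secretion > 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import pandas as pd
from cobra.io import (
    model_from_dict,
    model_to_dict,
    read_sbml_model,
    write_sbml_model,
)

from .errors import ConfigurationError, FormatError, MappingError, ValidationError

#: average dry mass of a CHO cell in picograms, used when a dataset does
#: not provide its own value.
DRY_MASS_PG_DEFAULT = 264.0

#: energetics of peptide-bond formation per mole of polymerized amino
#: acids: 2 GTP and 1.306 ATP are hydrolysed to 2 GDP, 1 AMP and 0.306 ADP.
GTP_PER_AA = 2.0
ATP_PER_AA = 1.306
GDP_PER_AA = 2.0
AMP_PER_AA = 1.0
ADP_PER_AA = 0.306

#: constraint policies for exchange bounds
POINT_FIX = "point-fix"
INTERVAL = "interval"


def cells_per_ml_to_gdw_per_l(cells_per_ml: float, dry_mass_pg: float = DRY_MASS_PG_DEFAULT) -> float:
    """Convert a cell density to a biomass concentration in gDW L^-1.

    ``cells mL^-1 * pg cell^-1 = pg mL^-1 = 1e-9 g mL^-1 = 1e-6 g L^-1``.
    """
    return cells_per_ml * dry_mass_pg * 1e-6


@dataclass
class EtcSpec:
    """How oxidative phosphorylation is encoded in the model.

    The NADH-dehydrogenase/ETC lump pumps ``h_per_atp * po_nadh`` protons
    out of the matrix per NADH (plus one proton consumed chemically), the
    ATP synthase translocates ``h_per_atp`` protons per ATP, and the
    FADH2 branch pumps ``fadh2_scale`` times the NADH amount.  With the
    defaults (10 H+ per NADH, 4 H+ per ATP) the P/O ratio for NADH is 2.5
    and 1.5 for FADH2.
    """

    nadh_reaction: str = "ETC_NADH"
    fadh2_reaction: str = "ETC_FADH2"
    h_per_atp: float = 4.0
    fadh2_scale: float = 0.6
    matrix_h: str = "h_m"
    pumped_h: str = "h_c"


@dataclass
class MetabolicModel:
    """A stoichiometric network plus the annotations the pipeline needs."""

    cobra_model: cobra.Model
    biomass_ids: list[str] = field(default_factory=list)
    maintenance_id: str = "ATPM"
    amino_acid_ids: list[str] = field(default_factory=list)
    essential_aa_ids: list[str] = field(default_factory=list)
    trp_id: str = "trp__L"
    oxygen_id: str = "o2"
    product_exchange_id: str | None = None
    etc: EtcSpec = field(default_factory=EtcSpec)

    def __post_init__(self) -> None:
        if self.maintenance_id not in self.cobra_model.reactions:
            raise ConfigurationError(
                f"maintenance reaction {self.maintenance_id!r} not present in model"
            )
        for rid in self.biomass_ids:
            if rid not in self.cobra_model.reactions:
                raise ConfigurationError(f"biomass reaction {rid!r} not present in model")

    # -- convenience accessors -------------------------------------------------

    @property
    def compartments(self) -> set[str]:
        return set(self.cobra_model.compartments)

    @property
    def reactions(self):
        return self.cobra_model.reactions

    @property
    def metabolites(self):
        return self.cobra_model.metabolites

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            cobra_model=self.cobra_model.copy(),
            biomass_ids=list(self.biomass_ids),
            maintenance_id=self.maintenance_id,
            amino_acid_ids=list(self.amino_acid_ids),
            essential_aa_ids=list(self.essential_aa_ids),
            trp_id=self.trp_id,
            oxygen_id=self.oxygen_id,
            product_exchange_id=self.product_exchange_id,
            etc=EtcSpec(**vars(self.etc)),
        )

    def exchange_for(self, species_id: str) -> cobra.Reaction:
        """Return the exchange reaction of an extracellular species.

        ``species_id`` is compartment-free (e.g. ``"glc__D"``); the
        boundary metabolite is looked up as ``<species_id>_e``.
        """
        met_id = f"{species_id}_e"
        try:
            met = self.cobra_model.metabolites.get_by_id(met_id)
        except KeyError:
            raise MappingError(f"no extracellular metabolite {met_id!r} in model")
        for rxn in met.reactions:
            if rxn.boundary:
                return rxn
        raise MappingError(f"metabolite {met_id!r} has no exchange reaction")


# -- formula handling ----------------------------------------------------------


def carbon_count(metabolite: cobra.Metabolite) -> int:
    """Number of carbon atoms per molecule, read from the elemental formula."""
    if not metabolite.formula:
        raise FormatError(f"metabolite {metabolite.id!r} has no formula")
    try:
        elements = metabolite.elements
    except Exception as exc:  # cobra raises plain ValueError on bad formulas
        raise FormatError(f"unparseable formula {metabolite.formula!r}") from exc
    n = elements.get("C", 0)
    if n < 0 or any(v < 0 for v in elements.values()):
        raise FormatError(f"negative element count in formula {metabolite.formula!r}")
    return int(n)


def reaction_element_balance(reaction: cobra.Reaction) -> dict[str, float]:
    """Net element and charge production of a reaction (empty dict = balanced)."""
    net: dict[str, float] = {}
    for met, coeff in reaction.metabolites.items():
        for el, cnt in met.elements.items():
            net[el] = net.get(el, 0.0) + coeff * cnt
        net["charge"] = net.get("charge", 0.0) + coeff * (met.charge or 0)
    return {k: v for k, v in net.items() if abs(v) > 1e-9}


# -- datasets ------------------------------------------------------------------


@dataclass
class ExchangeDataset:
    """Measured exchange rates of one cultivation dataset.

    ``rates`` maps compartment-free species ids to ``(value, sd)`` in
    mmol gDW^-1 h^-1 with uptake negative.  ``productivity`` is the
    specific secretion rate of the recombinant product (0 for
    non-producers).
    """

    dataset_id: str
    rates: dict[str, tuple[float, float]]
    growth_rate: tuple[float, float]
    productivity: tuple[float, float] = (0.0, 0.0)
    product_aa_composition: dict[str, float] = field(default_factory=dict)
    dry_mass: float = DRY_MASS_PG_DEFAULT

    def __post_init__(self) -> None:
        for sid, (_, sd) in self.rates.items():
            if sd < 0:
                raise ValidationError(f"negative sd for {sid!r} in {self.dataset_id}")
        if self.productivity[0] > 0 and self.product_aa_composition:
            total = sum(self.product_aa_composition.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValidationError(
                    f"product amino-acid mole fractions sum to {total}, expected 1"
                )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"species": sid, "rate": v, "sd": sd} for sid, (v, sd) in self.rates.items()
        ]
        rows.append({"species": "growth_rate", "rate": self.growth_rate[0], "sd": self.growth_rate[1]})
        rows.append({"species": "productivity", "rate": self.productivity[0], "sd": self.productivity[1]})
        df = pd.DataFrame(rows)
        df.insert(0, "dataset_id", self.dataset_id)
        df["dry_mass_pg"] = self.dry_mass
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExchangeDataset":
        df = pd.read_csv(path, sep="\t")
        required = {"dataset_id", "species", "rate", "sd"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        rates: dict[str, tuple[float, float]] = {}
        growth = (float("nan"), 0.0)
        productivity = (0.0, 0.0)
        for _, row in df.iterrows():
            entry = (float(row["rate"]), float(row["sd"]))
            if row["species"] == "growth_rate":
                growth = entry
            elif row["species"] == "productivity":
                productivity = entry
            else:
                rates[str(row["species"])] = entry
        dry_mass = float(df["dry_mass_pg"].iloc[0]) if "dry_mass_pg" in df.columns else DRY_MASS_PG_DEFAULT
        return cls(
            dataset_id=str(df["dataset_id"].iloc[0]),
            rates=rates,
            growth_rate=growth,
            productivity=productivity,
            dry_mass=dry_mass,
        )


# -- model I/O -----------------------------------------------------------------

_NATIVE_FORMAT = "fluxmaint-model-1"


def save_model(model: MetabolicModel, path: str | Path, dialect: str = "json") -> None:
    """Write a model in the native JSON dialect or as SBML L3 + FBC."""
    path = Path(path)
    if dialect == "json":
        doc = {
            "format": _NATIVE_FORMAT,
            "biomass_ids": model.biomass_ids,
            "maintenance_id": model.maintenance_id,
            "amino_acid_ids": model.amino_acid_ids,
            "essential_aa_ids": model.essential_aa_ids,
            "trp_id": model.trp_id,
            "oxygen_id": model.oxygen_id,
            "product_exchange_id": model.product_exchange_id,
            "etc": vars(model.etc),
            "model": model_to_dict(model.cobra_model),
        }
        path.write_text(json.dumps(doc, indent=1, default=float))
    elif dialect == "sbml":
        # subsystem groups are added to the model (idempotently); cobra's
        # context manager does not track group addition
        cm = model.cobra_model
        _subsystems_to_groups(cm)
        write_sbml_model(cm, str(path))
    else:
        raise FormatError(f"unknown model dialect {dialect!r}")


def _subsystems_to_groups(cm: cobra.Model) -> None:
    """Mirror reaction subsystems as SBML groups so they survive export."""
    by_subsystem: dict[str, list[cobra.Reaction]] = {}
    for rxn in cm.reactions:
        if rxn.subsystem:
            by_subsystem.setdefault(rxn.subsystem, []).append(rxn)
    groups = []
    for name, members in by_subsystem.items():
        gid = "g_" + "".join(c if c.isalnum() else "_" for c in name)
        if gid in cm.groups:
            continue
        group = cobra.core.Group(gid, name=name, members=members, kind="partonomy")
        groups.append(group)
    if groups:
        cm.add_groups(groups)


def _groups_to_subsystems(cm: cobra.Model) -> None:
    """Restore reaction subsystems from SBML groups after import."""
    for group in cm.groups:
        for member in group.members:
            if isinstance(member, cobra.Reaction) and not member.subsystem:
                member.subsystem = group.name or group.id


def load_model(
    path: str | Path,
    dialect: str = "json",
    biomass_ids: Iterable[str] | None = None,
    maintenance_id: str | None = None,
) -> MetabolicModel:
    """Load a model from the native JSON dialect or from SBML.

    SBML carries no pipeline annotations, so biomass reactions are
    discovered by the ``BIOMASS`` id prefix and the maintenance reaction
    defaults to ``ATPM`` unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file {path} does not exist")
    if dialect == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
        if doc.get("format") != _NATIVE_FORMAT:
            raise FormatError(f"{path}: not a {_NATIVE_FORMAT} document")
        try:
            cm = model_from_dict(doc["model"])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: malformed model section ({exc})") from exc
        _check_stoichiometry_resolves(doc["model"])
        return MetabolicModel(
            cobra_model=cm,
            biomass_ids=list(biomass_ids) if biomass_ids else list(doc["biomass_ids"]),
            maintenance_id=maintenance_id or doc["maintenance_id"],
            amino_acid_ids=list(doc.get("amino_acid_ids", [])),
            essential_aa_ids=list(doc.get("essential_aa_ids", [])),
            trp_id=doc.get("trp_id", "trp__L"),
            oxygen_id=doc.get("oxygen_id", "o2"),
            product_exchange_id=doc.get("product_exchange_id"),
            etc=EtcSpec(**doc.get("etc", {})),
        )
    if dialect == "sbml":
        try:
            cm = read_sbml_model(str(path))
        except Exception as exc:
            raise FormatError(f"{path}: SBML parse failure ({exc})") from exc
        _groups_to_subsystems(cm)
        if biomass_ids is None:
            biomass_ids = [r.id for r in cm.reactions if r.id.upper().startswith("BIOMASS")]
        return MetabolicModel(
            cobra_model=cm,
            biomass_ids=list(biomass_ids),
            maintenance_id=maintenance_id or "ATPM",
        )
    raise FormatError(f"unknown model dialect {dialect!r}")


def _check_stoichiometry_resolves(model_dict: Mapping) -> None:
    met_ids = {m["id"] for m in model_dict.get("metabolites", [])}
    for rxn in model_dict.get("reactions", []):
        for mid in rxn.get("metabolites", {}):
            if mid not in met_ids:
                raise FormatError(
                    f"reaction {rxn.get('id')!r} references unknown metabolite {mid!r}"
                )


# -- model editing -------------------------------------------------------------


def add_product_synthesis_reaction(
    model: MetabolicModel,
    composition: Mapping[str, float],
    product_id: str = "igg",
    chain_length: float = 1.0,
    compartment_suffix: str = "c",
) -> MetabolicModel:
    """Add a recombinant-product synthesis reaction plus its exchange.

    Per mole of polymerized amino acids the reaction consumes the
    composition's amino acids together with 2 GTP and 1.306 ATP and
    produces 2 GDP, 1 AMP and 0.306 ADP.  Phosphate, water and protons
    are included explicitly so the reaction is elementally and charge
    balanced; one water per peptide bond is released by condensation.
    ``chain_length`` scales all coefficients so that one flux unit makes
    one whole chain (e.g. 100 for a 100-residue protein).

    The model is modified in place and returned.
    """
    total = sum(composition.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValidationError(f"composition fractions sum to {total}, expected 1")
    cm = model.cobra_model
    suffix = compartment_suffix
    try:
        aa_mets = {aa: cm.metabolites.get_by_id(f"{aa}_{suffix}") for aa in composition}
        cof = {
            name: cm.metabolites.get_by_id(f"{name}_{suffix}")
            for name in ("atp", "gtp", "adp", "gdp", "amp", "pi", "h2o", "h")
        }
    except KeyError as exc:
        raise ConfigurationError(f"species missing from model: {exc}") from exc

    # residue composition of the product: weighted amino acids minus one
    # water per peptide bond
    elements: dict[str, float] = {}
    charge = 0.0
    for aa, frac in composition.items():
        for el, cnt in aa_mets[aa].elements.items():
            elements[el] = elements.get(el, 0.0) + frac * cnt
        charge += frac * (aa_mets[aa].charge or 0)
    elements["H"] = elements.get("H", 0.0) - 2.0
    elements["O"] = elements.get("O", 0.0) - 1.0
    formula = "".join(
        f"{el}{round(cnt * chain_length, 6):g}" for el, cnt in sorted(elements.items()) if cnt
    )

    prod_e = cobra.Metabolite(
        f"{product_id}_e",
        formula=formula,
        charge=charge * chain_length,
        name=f"{product_id} (recombinant product)",
        compartment="e",
    )

    # NTP hydrolysis bookkeeping per mole of amino acids:
    #   2 GTP + 2 H2O -> 2 GDP + 2 Pi + 2 H
    #   1 ATP + 2 H2O -> 1 AMP + 2 Pi + 2 H   (pyrophosphate hydrolysis lumped)
    #   0.306 ATP + 0.306 H2O -> 0.306 ADP + 0.306 Pi + 0.306 H
    # and one water released per peptide bond.
    pi_per_aa = 2.0 * GDP_PER_AA / 2 + 2.0 * AMP_PER_AA + ADP_PER_AA  # = 4.306
    h2o_consumed = pi_per_aa - 1.0  # condensation returns one water per bond

    L = chain_length
    rxn = cobra.Reaction(f"SYNTH_{product_id}", name=f"{product_id} synthesis and secretion")
    rxn.subsystem = "Product synthesis"
    stoich: dict[cobra.Metabolite, float] = {prod_e: 1.0}
    for aa, frac in composition.items():
        stoich[aa_mets[aa]] = stoich.get(aa_mets[aa], 0.0) - frac * L
    stoich[cof["gtp"]] = -GTP_PER_AA * L
    stoich[cof["atp"]] = -ATP_PER_AA * L
    stoich[cof["h2o"]] = -h2o_consumed * L
    stoich[cof["gdp"]] = GDP_PER_AA * L
    stoich[cof["amp"]] = AMP_PER_AA * L
    stoich[cof["adp"]] = ADP_PER_AA * L
    stoich[cof["pi"]] = pi_per_aa * L
    stoich[cof["h"]] = pi_per_aa * L
    rxn.add_metabolites(stoich)
    rxn.bounds = (0.0, 1000.0)
    cm.add_reactions([rxn])
    ex = cm.add_boundary(prod_e, type="exchange")
    ex.bounds = (0.0, 1000.0)
    model.product_exchange_id = ex.id
    return model


def apply_exchange_constraints(
    model: MetabolicModel,
    data: ExchangeDataset,
    policy: str = POINT_FIX,
) -> MetabolicModel:
    """Constrain exchange bounds to the measured rates of a dataset.

    ``point-fix`` sets both bounds to the measured value; ``interval``
    sets them to value +/- sd.  Oxygen is never constrained.  If
    tryptophan was not measured, its uptake is fixed to the
    smallest-magnitude measured amino-acid uptake (it is the least
    abundant amino acid in biomass).  The model is modified in place.
    """
    if policy not in (POINT_FIX, INTERVAL):
        raise ValidationError(f"unknown constraint policy {policy!r}")
    for sid, (value, sd) in data.rates.items():
        if sid == model.oxygen_id:
            continue
        rxn = model.exchange_for(sid)
        if policy == POINT_FIX:
            rxn.bounds = (value, value)
        else:
            rxn.bounds = (value - sd, value + sd)

    measured_aa_uptakes = {
        aa: v for aa, (v, _) in data.rates.items()
        if aa in model.amino_acid_ids and v < 0
    }
    if model.trp_id not in data.rates and measured_aa_uptakes:
        smallest = max(measured_aa_uptakes.values())  # closest to zero
        trp_rxn = model.exchange_for(model.trp_id)
        trp_rxn.bounds = (smallest, smallest)

    if data.productivity[0] > 0 and model.product_exchange_id is not None:
        prod_rxn = model.cobra_model.reactions.get_by_id(model.product_exchange_id)
        v, sd = data.productivity
        if policy == POINT_FIX:
            prod_rxn.bounds = (v, v)
        else:
            prod_rxn.bounds = (v - sd, v + sd)
    return model


def set_po_ratio(model: MetabolicModel, po_nadh: float) -> MetabolicModel:
    """Rescale ETC proton pumping so that ATP per NADH equals ``po_nadh``.

    With the ATP synthase translocating ``h_per_atp`` protons per ATP,
    the NADH lump must pump ``h_per_atp * po_nadh`` protons (one further
    matrix proton is consumed by the oxygen chemistry).  The FADH2
    branch is rescaled proportionally.  Values outside [2, 3] are
    allowed but flagged with a warning.  The model is modified in place.
    """
    import warnings

    if not 2.0 <= po_nadh <= 3.0:
        warnings.warn(f"P/O ratio {po_nadh} outside the conventional range [2, 3]")
    cm = model.cobra_model
    spec = model.etc
    try:
        nadh_rxn = cm.reactions.get_by_id(spec.nadh_reaction)
        fadh2_rxn = cm.reactions.get_by_id(spec.fadh2_reaction)
        h_m = cm.metabolites.get_by_id(spec.matrix_h)
        h_c = cm.metabolites.get_by_id(spec.pumped_h)
    except KeyError as exc:
        raise ConfigurationError(
            "model does not use the proton-explicit ETC formulation"
        ) from exc

    pumped = spec.h_per_atp * po_nadh
    nadh_rxn.add_metabolites({h_m: -(pumped + 1.0), h_c: pumped}, combine=False)
    pumped_f = spec.h_per_atp * spec.fadh2_scale * po_nadh
    fadh2_rxn.add_metabolites({h_m: -pumped_f, h_c: pumped_f}, combine=False)
    return model
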