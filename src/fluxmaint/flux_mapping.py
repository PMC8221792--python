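"""Reconciling coarse 13C-MFA reaction namespaces with the genome-scale one.

Small 13C models lump, split and duplicate reactions relative to a
genome-scale reconstruction, so a one-to-one mapping is impossible.
Each 13C reaction therefore maps to a signed set of genome-scale
reactions whose fluxes are summed: parallel routes and compartment
duplicates enter with sign +1, reverse partners of lumped net
conversions with sign -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, MappingError, ValidationError
from .fba_engine import FluxVector
from .model_core import ExchangeDataset

#: default relative-magnitude cutoff below which experimental fluxes are
#: excluded from error scoring
SMALL_FLUX_THRESHOLD = 0.01


@dataclass
class MappingEntry:
    """One 13C reaction and its signed genome-scale terms."""

    c13_id: str
    terms: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError(f"mapping entry {self.c13_id!r} has no terms")
        for rid, sign in self.terms:
            if sign not in (1, -1):
                raise ValidationError(
                    f"mapping entry {self.c13_id!r}: sign must be +1 or -1, got {sign}"
                )


@dataclass
class MappingTable:
    """A 13C -> genome-scale reaction correspondence."""

    entries: dict[str, MappingEntry]

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"c13_id": e.c13_id, "gsmm_id": rid, "sign": sign}
            for e in self.entries.values()
            for rid, sign in e.terms
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MappingTable":
        df = pd.read_csv(path, sep="\t")
        required = {"c13_id", "gsmm_id", "sign"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        entries: dict[str, MappingEntry] = {}
        for c13_id, group in df.groupby("c13_id", sort=False):
            entries[str(c13_id)] = MappingEntry(
                c13_id=str(c13_id),
                terms=[(str(r), int(s)) for r, s in zip(group["gsmm_id"], group["sign"])],
            )
        return cls(entries=entries)


@dataclass
class C13Dataset:
    """Experimentally determined intracellular fluxes of one dataset.

    ``fluxes`` maps 13C reaction ids to ``(value, ci_low, ci_high)`` in
    mmol gDW^-1 h^-1; ``subsystem`` assigns each id to a pathway group
    used for per-subsystem reporting.
    """

    dataset_id: str
    fluxes: dict[str, tuple[float, float, float]]
    subsystem: dict[str, str] = field(default_factory=dict)
    exchange: ExchangeDataset | None = None

    def __post_init__(self) -> None:
        for c13_id, (value, lo, hi) in self.fluxes.items():
            if not (lo <= value <= hi):
                raise ValidationError(
                    f"{self.dataset_id}/{c13_id}: flux {value} outside CI [{lo}, {hi}]"
                )

    @property
    def values(self) -> dict[str, float]:
        return {k: v[0] for k, v in self.fluxes.items()}

    def ci_widths(self) -> dict[str, float]:
        return {k: hi - lo for k, (_, lo, hi) in self.fluxes.items()}

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "dataset_id": self.dataset_id,
                "c13_id": k,
                "flux": v,
                "ci_low": lo,
                "ci_high": hi,
                "subsystem": self.subsystem.get(k, ""),
            }
            for k, (v, lo, hi) in self.fluxes.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "C13Dataset":
        df = pd.read_csv(path, sep="\t")
        required = {"dataset_id", "c13_id", "flux", "ci_low", "ci_high"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        fluxes = {
            str(r["c13_id"]): (float(r["flux"]), float(r["ci_low"]), float(r["ci_high"]))
            for _, r in df.iterrows()
        }
        subsystem = (
            {str(r["c13_id"]): str(r["subsystem"]) for _, r in df.iterrows()}
            if "subsystem" in df.columns
            else {}
        )
        return cls(dataset_id=str(df["dataset_id"].iloc[0]), fluxes=fluxes, subsystem=subsystem)


def map_fluxes(v: FluxVector, table: MappingTable) -> dict[str, float]:
    """Project a genome-scale flux vector into the 13C namespace.

    ``mapped[c13_id] = sum over terms of sign * v[gsmm_id]``.  Compartment
    duplicates, parallel routes and lumped net conversions are all
    handled through the signed terms.
    """
    mapped: dict[str, float] = {}
    for entry in table:
        total = 0.0
        for rid, sign in entry.terms:
            if rid not in v.fluxes:
                raise MappingError(
                    f"mapping entry {entry.c13_id!r}: reaction {rid!r} not in flux vector"
                )
            total += sign * v.fluxes[rid]
        mapped[entry.c13_id] = total
    return mapped


def filter_small_fluxes(
    data: C13Dataset, threshold: float = SMALL_FLUX_THRESHOLD
) -> C13Dataset:
    """Drop entries with |v_e| below ``threshold`` of the dataset maximum.

    Tiny experimental fluxes have near-zero denominators in the relative
    error and would dominate the scoring; the conventional cutoff is 1%
    of the largest absolute flux of the same dataset.
    """
    import warnings

    if not data.fluxes:
        raise ValidationError(f"dataset {data.dataset_id!r} has no fluxes")
    max_abs = max(abs(v) for v, _, _ in data.fluxes.values())
    if max_abs == 0.0:
        warnings.warn(f"dataset {data.dataset_id!r} is all-zero; filter returns empty set")
        kept: dict[str, tuple[float, float, float]] = {}
    else:
        kept = {
            k: entry
            for k, entry in data.fluxes.items()
            if abs(entry[0]) / max_abs >= threshold
        }
    return C13Dataset(
        dataset_id=data.dataset_id,
        fluxes=kept,
        subsystem={k: s for k, s in data.subsystem.items() if k in kept},
        exchange=data.exchange,
    )
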