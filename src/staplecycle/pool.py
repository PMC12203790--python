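"""Staple species, synthesis purity, and folding-pool state.

A DNA-origami folding reaction mixes a long circular scaffold with a molar
excess of short synthetic staple oligonucleotides.  Solid-phase synthesis is
imperfect: each coupling step succeeds with probability ``y`` (typically
~0.99), so a strand of ``n`` nucleotides is full length with probability
``y**(n-1)``.  For a typical 42-mer roughly a third of the product carries a
truncation and, if the strand was designed with a 5' cargo, lacks its payload.

This module keeps per-species book of full-length and truncated amounts in a
reaction or recovered mix.  Truncations are lumped into a single class per
species: the downstream reasoning only distinguishes full-length (feature
bearing) from flawed strands.  Amounts are moles internally; the stochastic
sampler converts to copy counts when it needs integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SynthesisModel",
    "StapleCategory",
    "StapleSpecies",
    "PoolState",
    "full_length_fraction",
    "fold_excess_from_conc",
    "init_pool",
    "load_design_table",
    "design_to_frame",
]

AVOGADRO = 6.02214076e23


class StapleCategory(str, Enum):
    """Functional role of a staple species in the design."""

    CORE = "core"
    HANDLE = "handle"
    FUNCTIONAL = "functional"
    LABEL = "label"


@dataclass(frozen=True)
class SynthesisModel:
    """Per-coupling-step yield of solid-phase oligonucleotide synthesis.

    Parameters
    ----------
    stepwise_yield : float
        Probability that a single coupling step succeeds.  A strand of
        length ``n`` then comes out full length with probability
        ``stepwise_yield ** (n - 1)`` (there are ``n - 1`` couplings).
        Default 0.99, typical of commercial phosphoramidite synthesis.
    """

    stepwise_yield: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 < self.stepwise_yield <= 1.0):
            raise ValueError(
                f"stepwise_yield must be in (0, 1], got {self.stepwise_yield}"
            )

    def full_length_fraction(self, length_nt: int) -> float:
        return full_length_fraction(length_nt, self)


#: Ideal synthesis (every strand full length); used for pure fresh stocks.
PURE_SYNTHESIS = SynthesisModel(stepwise_yield=1.0)


def full_length_fraction(
    length_nt: int, synthesis_model: SynthesisModel | float = SynthesisModel()
) -> float:
    """Fraction of strands of length ``length_nt`` synthesized to full length.

    Equals ``y ** (n - 1)`` for stepwise coupling yield ``y``: a strand of
    ``n`` nucleotides requires ``n - 1`` successful couplings.

    Parameters
    ----------
    length_nt : int
        Strand length in nucleotides, >= 1.
    synthesis_model : SynthesisModel or float
        The synthesis model, or the stepwise yield directly.

    Returns
    -------
    float
        Full-length fraction in (0, 1].
    """
    if isinstance(synthesis_model, (int, float)):
        synthesis_model = SynthesisModel(stepwise_yield=float(synthesis_model))
    n = int(length_nt)
    if n < 1:
        raise ValueError(f"length_nt must be >= 1, got {length_nt}")
    return synthesis_model.stepwise_yield ** (n - 1)


def fold_excess_from_conc(stock_conc_uM: float, scaffold_conc_nM: float) -> float:
    """Molar fold-excess of a staple over scaffold, from reaction concentrations.

    A 1 uM staple over a 50 nM scaffold is a 20-fold excess.
    """
    if stock_conc_uM <= 0 or scaffold_conc_nM <= 0:
        raise ValueError("concentrations must be positive")
    return stock_conc_uM * 1000.0 / scaffold_conc_nM


@dataclass(frozen=True)
class StapleSpecies:
    """One staple type: its length, excess, stock, price, and modification.

    ``fold_excess`` (E) is the molar ratio of this staple to the scaffold in
    the folding reaction; one fold consumes one scaffold-equivalent of it.
    ``price_per_equivalent`` is the cost of one scaffold-equivalent of fresh
    strand, so the cycle-0 purchase of this species costs ``E * price``.
    ``replenish_fraction_override``, if set, replaces the volume-equation
    amount during typical replenishment by a fixed fraction of the amount
    initially used (e.g. a fluorophore labeling strand topped up at 1/5).
    """

    species_id: str
    length_nt: int
    category: StapleCategory = StapleCategory.CORE
    fold_excess: float = 10.0
    stock_conc_uM: float = 100.0
    price_per_equivalent: float = 1.0
    modified: bool = False
    replenish_fraction_override: float | None = None

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValueError(f"{self.species_id}: length_nt must be >= 1")
        if self.fold_excess <= 0:
            raise ValueError(f"{self.species_id}: fold_excess must be > 0")
        if self.fold_excess < 1:
            warnings.warn(
                f"{self.species_id}: fold_excess {self.fold_excess} < 1 is "
                "sub-stoichiometric; the first fold will exhaust the pool",
                stacklevel=2,
            )
        if self.price_per_equivalent < 0:
            raise ValueError(f"{self.species_id}: price must be >= 0")
        if self.stock_conc_uM <= 0:
            raise ValueError(f"{self.species_id}: stock_conc_uM must be > 0")
        ov = self.replenish_fraction_override
        if ov is not None and not (0.0 <= ov <= 1.0):
            raise ValueError(
                f"{self.species_id}: replenish_fraction_override must be in [0, 1]"
            )


@dataclass
class PoolState:
    """Per-species full-length/truncated amounts in a mix at a given cycle.

    ``amounts`` is a DataFrame indexed by species_id with float columns
    ``full_length`` and ``truncated`` (moles).  ``purity`` of a species is
    FL / (FL + TR), defined only when the species has material left.
    """

    amounts: pd.DataFrame
    volume_ul: float
    cycle_index: int = 0

    def __post_init__(self) -> None:
        required = {"full_length", "truncated"}
        if not required.issubset(self.amounts.columns):
            raise ValueError(f"amounts must have columns {sorted(required)}")
        if (self.amounts[list(required)] < -1e-30).any().any():
            raise ValueError("pool amounts must be non-negative")
        if self.cycle_index < 0:
            raise ValueError("cycle_index must be >= 0")

    @property
    def species_ids(self) -> list[str]:
        return list(self.amounts.index)

    def total(self, species_id: str | None = None) -> float:
        """Total moles of one species, or of the whole pool."""
        if species_id is None:
            return float(self.amounts[["full_length", "truncated"]].sum().sum())
        row = self._row(species_id)
        return float(row["full_length"] + row["truncated"])

    def purity(self, species_id: str) -> float:
        """Full-length fraction FL / (FL + TR) of one species."""
        row = self._row(species_id)
        tot = row["full_length"] + row["truncated"]
        if tot <= 0:
            raise ValueError(f"purity undefined: species {species_id!r} is empty")
        return float(row["full_length"] / tot)

    def purities(self) -> pd.Series:
        """Per-species purity; NaN where a species is exhausted."""
        tot = self.amounts["full_length"] + self.amounts["truncated"]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.amounts["full_length"] / tot
        return p.where(tot > 0)

    def copy(self) -> "PoolState":
        return PoolState(
            amounts=self.amounts.copy(),
            volume_ul=self.volume_ul,
            cycle_index=self.cycle_index,
        )

    def _row(self, species_id: str) -> pd.Series:
        try:
            return self.amounts.loc[species_id]
        except KeyError:
            raise KeyError(f"unknown species {species_id!r}") from None


def init_pool(
    design: Iterable[StapleSpecies] | pd.DataFrame,
    scaffold_conc_nM: float = 50.0,
    reaction_volume_ul: float = 100.0,
    synthesis_model: SynthesisModel = SynthesisModel(),
) -> PoolState:
    """Build the cycle-0 folding pool from a staple design.

    Each species starts at ``fold_excess`` times the scaffold amount
    (``scaffold_conc * volume``), split into full-length and truncated
    portions according to the synthesis model and the species length.

    Parameters
    ----------
    design : iterable of StapleSpecies or DataFrame
        The staple design table (see :func:`load_design_table`).
    scaffold_conc_nM : float
        Scaffold concentration in the reaction (nM); 50 nM is typical.
    reaction_volume_ul : float
        Reaction volume in microliters.
    synthesis_model : SynthesisModel
        Purity model for the purchased (unpurified) staples.

    Returns
    -------
    PoolState
        Fresh pool at cycle 0.
    """
    species = as_species_list(design)
    if not species:
        raise ValueError("design table is empty")
    ids = [s.species_id for s in species]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate species_id in design: {dupes}")
    if scaffold_conc_nM <= 0 or reaction_volume_ul <= 0:
        raise ValueError("scaffold concentration and volume must be positive")

    scaffold_moles = scaffold_conc_nM * 1e-9 * reaction_volume_ul * 1e-6
    fl, tr = [], []
    for s in species:
        total = s.fold_excess * scaffold_moles
        f = full_length_fraction(s.length_nt, synthesis_model)
        fl.append(total * f)
        tr.append(total * (1.0 - f))
    amounts = pd.DataFrame(
        {"full_length": fl, "truncated": tr}, index=pd.Index(ids, name="species_id")
    )
    return PoolState(amounts=amounts, volume_ul=reaction_volume_ul, cycle_index=0)


def as_species_list(
    design: Iterable[StapleSpecies] | pd.DataFrame,
) -> list[StapleSpecies]:
    """Normalize a design (DataFrame or iterable) to a list of StapleSpecies."""
    if isinstance(design, pd.DataFrame):
        return _frame_to_species(design)
    out = list(design)
    for s in out:
        if not isinstance(s, StapleSpecies):
            raise TypeError(f"expected StapleSpecies, got {type(s).__name__}")
    return out


def _frame_to_species(df: pd.DataFrame) -> list[StapleSpecies]:
    required = {"species_id", "length_nt", "category", "fold_excess"}
    frame = df.reset_index() if "species_id" not in df.columns else df
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    species = []
    for _, row in frame.iterrows():
        override = row.get("replenish_override", None)
        if override is not None and (pd.isna(override) or override == ""):
            override = None
        species.append(
            StapleSpecies(
                species_id=str(row["species_id"]),
                length_nt=int(row["length_nt"]),
                category=StapleCategory(str(row["category"])),
                fold_excess=float(row["fold_excess"]),
                stock_conc_uM=float(row.get("stock_conc_uM", 100.0)),
                price_per_equivalent=float(row.get("price_per_equivalent", 1.0)),
                modified=_as_bool(row.get("modified", False)),
                replenish_fraction_override=(
                    float(override) if override is not None else None
                ),
            )
        )
    return species


def _as_bool(value: object) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    return bool(value)


def design_to_frame(species: Iterable[StapleSpecies]) -> pd.DataFrame:
    """Serialize a design to the CSV dialect used on disk."""
    rows = []
    for s in as_species_list(species):
        rows.append(
            {
                "species_id": s.species_id,
                "length_nt": s.length_nt,
                "category": s.category.value,
                "fold_excess": s.fold_excess,
                "stock_conc_uM": s.stock_conc_uM,
                "price_per_equivalent": s.price_per_equivalent,
                "modified": s.modified,
                "replenish_override": (
                    "" if s.replenish_fraction_override is None
                    else s.replenish_fraction_override
                ),
            }
        )
    return pd.DataFrame(rows)


def load_design_table(path: str | Path) -> list[StapleSpecies]:
    """Read a staple design table CSV.

    Expected header: ``species_id,length_nt,category,fold_excess,
    stock_conc_uM,price_per_equivalent,modified,replenish_override``
    (UTF-8, '.' decimal separator; the last four columns are optional).
    """
    df = pd.read_csv(path)
    return _frame_to_species(df)
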