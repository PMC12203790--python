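"""Post-fold staple recovery, QC, and the two replenishment policies.

After folding, PEG precipitation pellets the origami and leaves the excess
staples in the supernatant; ethanol precipitation then retrieves them with a
measured recovery yield.  Recovery is treated as composition-neutral by
default (ethanol precipitation is not length-selective over staple-sized
oligos), so full-length and truncated strands are scaled alike and purity is
preserved.  A 260/230 absorbance check flags salt carryover: ratios well
above ~2.2 call for repeating the precipitation.

Replenishment policies:

* ``typical`` — per species, add fresh stock in the volume

      original_volume * (1 - recovery_yield + recovery_yield / excess)

  which replaces both the scaffold-equivalent the previous fold consumed
  (original_volume / excess) and the recovery loss
  (original_volume * (1 - recovery_yield)).  Species with a
  ``replenish_fraction_override`` instead get that fixed fraction of their
  originally-used amount (e.g. a Cy5 labeling strand topped up at 1/5).
* ``alternative`` — appropriate when all species share one excess: dilute
  the recovered strands back to the original stock concentration and top up
  with fresh stock, in the design's original per-species proportions, until
  the original total ssDNA amount and volume are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pool import (
    PoolState,
    StapleSpecies,
    SynthesisModel,
    as_species_list,
    full_length_fraction,
)

__all__ = [
    "RecoveryConfig",
    "ReplenishmentKind",
    "ReplenishmentPolicy",
    "QCResult",
    "replenish_volume",
    "apply_recovery",
    "qc_260_230",
    "replenish",
    "original_volumes",
]


@dataclass(frozen=True)
class RecoveryConfig:
    """Ethanol-precipitation recovery of leftover staples.

    ``recovery_yield`` is the fraction of each species retrieved, either a
    single value for every cycle or a per-cycle sequence.  The default 1.0
    models ideal recovery; measured yields are typically below that.
    ``composition_neutral`` keeps purity unchanged by recovery (default);
    switching it off would require a length-selectivity model, which this
    package deliberately does not include.
    """

    recovery_yield: float | Sequence[float] = 1.0
    a260_230_threshold: float = 2.2
    composition_neutral: bool = True

    def __post_init__(self) -> None:
        for y in np.atleast_1d(np.asarray(self.recovery_yield, dtype=float)):
            if not (0.0 <= y <= 1.0):
                raise ValueError(f"recovery_yield must be in [0, 1], got {y}")
        if self.a260_230_threshold <= 0:
            raise ValueError("a260_230_threshold must be > 0")

    def yield_at(self, cycle: int) -> float:
        ys = np.atleast_1d(np.asarray(self.recovery_yield, dtype=float))
        if ys.size == 1:
            return float(ys[0])
        return float(ys[min(cycle, ys.size - 1)])


class ReplenishmentKind(str, Enum):
    NONE = "none"
    TYPICAL = "typical"
    ALTERNATIVE = "alternative"


@dataclass(frozen=True)
class ReplenishmentPolicy:
    """Which replenishment scheme to run, and how pure the fresh strands are."""

    kind: ReplenishmentKind = ReplenishmentKind.TYPICAL
    fresh_purity_source: SynthesisModel = field(default_factory=SynthesisModel)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ReplenishmentKind(self.kind))


class QCResult(str, Enum):
    PASS = "pass"
    REPEAT_PRECIPITATION = "repeat_precipitation"


def replenish_volume(
    original_volume: float, recovery_yield: float, excess: float
) -> float:
    """Volume of fresh stock to add for one species under the typical policy.

    ``original_volume * (1 - recovery_yield + recovery_yield / excess)``:
    the first term replaces what recovery lost, the second the one
    scaffold-equivalent (1/excess of the stock) the previous fold consumed.

    Examples
    --------
    Total loss replaces everything; perfect recovery at 5-fold excess
    replaces only the consumed fifth:

    >>> replenish_volume(10.0, 0.0, 5.0)
    10.0
    >>> replenish_volume(10.0, 1.0, 5.0)
    2.0
    """
    if excess <= 0:
        raise ValueError(f"excess must be > 0, got {excess}")
    if not (0.0 <= recovery_yield <= 1.0):
        raise ValueError(f"recovery_yield must be in [0, 1], got {recovery_yield}")
    if original_volume < 0:
        raise ValueError("original_volume must be >= 0")
    return original_volume * (1.0 - recovery_yield + recovery_yield / excess)


def apply_recovery(
    pool: PoolState, recovery: RecoveryConfig | float, seed: int | None = None
) -> PoolState:
    """Scale the pool by the recovery yield (composition-neutral).

    Full-length and truncated amounts of every species are multiplied by the
    cycle's recovery yield, so per-species purity is unchanged.  ``seed`` is
    accepted for interface symmetry with the stochastic fold; the neutral
    recovery model is deterministic.
    """
    if isinstance(recovery, (int, float)):
        recovery = RecoveryConfig(recovery_yield=float(recovery))
    y = recovery.yield_at(pool.cycle_index)
    amounts = pool.amounts.copy()
    amounts[["full_length", "truncated"]] *= y
    return PoolState(
        amounts=amounts, volume_ul=pool.volume_ul, cycle_index=pool.cycle_index
    )


def qc_260_230(ratio: float, threshold: float = 2.2) -> QCResult:
    """Salt-contamination QC on recovered oligos from the 260/230 ratio.

    Ratios much larger than ~2.2 indicate excessive salt carryover and call
    for another round of ethanol precipitation.  Exactly at the threshold
    passes: the rule triggers on ratios *above* it.
    """
    if ratio <= 0:
        raise ValueError(f"260/230 ratio must be > 0, got {ratio}")
    if ratio > threshold:
        return QCResult.REPEAT_PRECIPITATION
    return QCResult.PASS


def original_volumes(
    design, scaffold_amount: float
) -> dict[str, float]:
    """Per-species volume (uL) of stock initially used for one reaction.

    The volume that delivers ``fold_excess`` scaffold-equivalents of each
    species at its stock concentration.
    """
    out = {}
    for s in as_species_list(design):
        moles = s.fold_excess * scaffold_amount
        out[s.species_id] = moles / (s.stock_conc_uM * 1e-6) * 1e6  # L -> uL
    return out


def replenish(
    pool: PoolState,
    policy: ReplenishmentPolicy,
    design,
    original_volumes: Mapping[str, float],
    recovery_yield: float = 1.0,
) -> PoolState:
    """Top up a post-recovery pool with fresh strands.

    Parameters
    ----------
    pool : PoolState
        Post-recovery pool.
    policy : ReplenishmentPolicy
    design : design table (StapleSpecies list or DataFrame)
    original_volumes : mapping species_id -> uL
        Stock volumes used in the initial fresh reaction (see
        :func:`original_volumes`).
    recovery_yield : float
        The yield measured for the recovery step preceding this
        replenishment; enters the typical policy's volume equation.
    """
    species = {s.species_id: s for s in as_species_list(design)}
    missing = [sid for sid in pool.amounts.index if sid not in species]
    if missing:
        raise KeyError(f"species in pool missing from design: {missing}")

    if policy.kind is ReplenishmentKind.NONE:
        return pool.copy()

    fresh = policy.fresh_purity_source
    amounts = pool.amounts.copy()

    if policy.kind is ReplenishmentKind.TYPICAL:
        for sid in amounts.index:
            s = species[sid]
            orig_vol = float(original_volumes[sid])
            orig_amount = orig_vol * 1e-6 * s.stock_conc_uM * 1e-6  # moles
            if s.replenish_fraction_override is not None:
                added = s.replenish_fraction_override * orig_amount
            else:
                vol = replenish_volume(orig_vol, recovery_yield, s.fold_excess)
                added = vol * 1e-6 * s.stock_conc_uM * 1e-6
            f = full_length_fraction(s.length_nt, fresh)
            amounts.loc[sid, "full_length"] += added * f
            amounts.loc[sid, "truncated"] += added * (1.0 - f)
    else:  # ALTERNATIVE: restore the original total, in original proportions
        orig_amounts = {
            sid: float(original_volumes[sid]) * 1e-6 * species[sid].stock_conc_uM * 1e-6
            for sid in amounts.index
        }
        orig_total = sum(orig_amounts.values())
        current_total = float(
            amounts["full_length"].sum() + amounts["truncated"].sum()
        )
        deficit = max(orig_total - current_total, 0.0)
        for sid in amounts.index:
            share = orig_amounts[sid] / orig_total
            added = deficit * share
            f = full_length_fraction(species[sid].length_nt, fresh)
            amounts.loc[sid, "full_length"] += added * f
            amounts.loc[sid, "truncated"] += added * (1.0 - f)

    return PoolState(
        amounts=amounts, volume_ul=pool.volume_ul, cycle_index=pool.cycle_index
    )
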