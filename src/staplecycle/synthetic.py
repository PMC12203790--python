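"""Synthetic-data generators for the whole pipeline.

Every observable the analysis modules consume can be generated here with
known ground truth: cargo-count tables (stand-ins for TEM particle counts),
gel-lane intensity profiles (stand-ins for densitometry traces), and noisy
per-cycle yield trajectories (stand-ins for gel-yield series).  Each
generator takes an explicit seed, draws from its own RNG stream, and returns
the ground-truth parameters alongside the data so parameter-recovery tests
are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .campaign import CampaignConfig, run_campaign
from .densitometry import LaneProfile
from .occupancy import CargoCounts, forward_probabilities

__all__ = [
    "gen_cargo_counts",
    "gen_lane_profile",
    "gen_yield_trajectory",
    "GaussianBand",
]


def gen_cargo_counts(
    p1: float,
    p2: float,
    n_particles: int,
    seed: int = 0,
    sample_id: str = "synthetic",
    cycle: int = 0,
) -> CargoCounts:
    """Simulate a TEM cargo-count table from known handle probabilities.

    Each particle makes two independent Bernoulli draws with probabilities
    ``p1`` and ``p2``; the table counts particles with 0, 1, or 2 successes.
    """
    if n_particles <= 0:
        raise ValueError("n_particles must be > 0")
    probs = forward_probabilities(p1, p2)  # validates p1, p2
    rng = np.random.default_rng(seed)
    n0, n1, n2 = rng.multinomial(n_particles, probs)
    return CargoCounts(
        n0=int(n0), n1=int(n1), n2=int(n2), sample_id=sample_id, cycle=cycle
    )


@dataclass(frozen=True)
class GaussianBand:
    """One gel band: a Gaussian peak with a given integrated area."""

    center: float
    area: float
    width: float  # Gaussian sigma, in position units

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("band area must be > 0")
        if self.width <= 0:
            raise ValueError("zero-width band")


def gen_lane_profile(
    bands: Sequence[GaussianBand | tuple[float, float, float]],
    noise_sigma: float = 0.0,
    seed: int = 0,
    baseline_level: float = 2.0,
    positions: np.ndarray | None = None,
) -> tuple[LaneProfile, dict]:
    """Synthesize a gel-lane trace as Gaussian bands on a noisy flat baseline.

    Returns the profile together with a truth dict holding the band
    parameters and their pairwise area fractions.  Negative excursions from
    noise are clipped at zero (photometric intensities are non-negative).
    """
    bands = [b if isinstance(b, GaussianBand) else GaussianBand(*b) for b in bands]
    if positions is None:
        positions = np.linspace(0.0, 100.0, 2001)
    positions = np.asarray(positions, dtype=float)
    rng = np.random.default_rng(seed)
    inten = np.full_like(positions, float(baseline_level))
    for b in bands:
        inten += (
            b.area
            / (b.width * np.sqrt(2.0 * np.pi))
            * np.exp(-0.5 * ((positions - b.center) / b.width) ** 2)
        )
    if noise_sigma > 0:
        inten += rng.normal(0.0, noise_sigma, size=positions.size)
    inten = np.clip(inten, 0.0, None)
    truth = {
        "bands": [
            {"center": b.center, "area": b.area, "width": b.width} for b in bands
        ],
        "total_area": sum(b.area for b in bands),
        "area_fractions": [
            b.area / sum(x.area for x in bands) for b in bands
        ]
        if bands
        else [],
        "baseline_level": baseline_level,
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return LaneProfile(positions=positions, intensities=inten), truth


def gen_yield_trajectory(
    campaign_config: CampaignConfig,
    true_bias: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Noisy per-cycle yield observations from a known incorporation bias.

    Runs the expectation-mode simulator at ``true_bias``, adds i.i.d.
    Gaussian noise, and clips to [0, 1].  Returns the observed trajectory
    and a truth dict with the noiseless trajectory and parameters.
    """
    cfg = replace(campaign_config, bias=float(true_bias), mode="expectation")
    clean = run_campaign(cfg).quality_scores
    rng = np.random.default_rng(seed)
    observed = clean.copy()
    if noise_sigma > 0:
        observed = np.clip(observed + rng.normal(0.0, noise_sigma, clean.size), 0, 1)
    truth = {
        "true_bias": float(true_bias),
        "noise_sigma": float(noise_sigma),
        "seed": seed,
        "clean_trajectory": clean.tolist(),
    }
    return observed, truth
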