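"""Cargo-occupancy inference from 0/1/2-cargo particle counts.

An origami displays two handle positions for a cargo (a fluorophore, a
nanocube, a barrel...).  Counting, in micrographs, how many particles carry
zero, one, or two cargoes lets us infer the per-handle incorporation
probability under a model of two independent Bernoulli handles:

* equal handles (p, p):  P0 = (1-p)^2, P1 = 2p(1-p), P2 = p^2.  The MLE is
  the fraction of occupied handle slots, p_hat = (n1 + 2 n2) / (2 N), with a
  Wilson score interval on the 2N Bernoulli trials (Wilson behaves better
  than Wald at small counts and extreme p).
* unequal handles (p1, p2): the observed fractions pin down the elementary
  symmetric functions p1 + p2 = P1 + 2 P2 and p1 p2 = P2, so (p1, p2) are
  the roots of x^2 - (P1 + 2 P2) x + P2 = 0, ordered p1 >= p2.  A negative
  discriminant means the counts are over-dispersed relative to independent
  handles, and the estimate is flagged infeasible.

A chi-square homogeneity test compares count tables across reuse cycles;
when expected cells are small the null distribution is obtained by seeded
multinomial resampling instead of the asymptotic chi-square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CargoCounts",
    "OccupancyEstimate",
    "CargoOccupancyModel",
    "OccupancyResults",
    "estimate_equal_p",
    "estimate_unequal",
    "compare_across_cycles",
    "forward_probabilities",
    "read_counts_csv",
]


@dataclass(frozen=True)
class CargoCounts:
    """Particles observed with 0, 1, or 2 bound cargoes in one sample."""

    n0: int
    n1: int
    n2: int
    sample_id: str = ""
    cycle: int = 0

    def __post_init__(self) -> None:
        for name in ("n0", "n1", "n2"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.n_total == 0:
            raise ValueError("counts must include at least one particle")

    @property
    def n_total(self) -> int:
        return self.n0 + self.n1 + self.n2

    @property
    def frequencies(self) -> tuple[float, float, float]:
        n = self.n_total
        return (self.n0 / n, self.n1 / n, self.n2 / n)


@dataclass
class OccupancyEstimate:
    """Per-handle incorporation probabilities inferred from one sample."""

    p_equal: float
    conf_int: tuple[float, float]
    log_likelihood: float
    p_pair: tuple[float, float] | None = None
    feasible: bool = True
    message: str = ""


def forward_probabilities(p1: float, p2: float) -> tuple[float, float, float]:
    """(P0, P1, P2) for two independent handles with probabilities p1, p2."""
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability out of [0, 1]: {p}")
    return (
        (1.0 - p1) * (1.0 - p2),
        p1 * (1.0 - p2) + p2 * (1.0 - p1),
        p1 * p2,
    )


def _wilson_interval(successes: float, trials: float, alpha: float = 0.05):
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    phat = successes / trials
    denom = 1.0 + z * z / trials
    center = (phat + z * z / (2.0 * trials)) / denom
    half = (
        z
        * math.sqrt(phat * (1.0 - phat) / trials + z * z / (4.0 * trials * trials))
        / denom
    )
    return (max(0.0, center - half), min(1.0, center + half))


def _trinomial_loglike(counts: CargoCounts, p: float) -> float:
    probs = np.clip(forward_probabilities(p, p), 1e-300, 1.0)
    return float(
        stats.multinomial.logpmf(
            [counts.n0, counts.n1, counts.n2], counts.n_total, probs
        )
    )


def estimate_equal_p(
    counts: CargoCounts, alpha: float = 0.05
) -> OccupancyEstimate:
    """MLE of a common per-handle probability from one count table.

    Under two independent identical handles each particle contributes two
    Bernoulli trials, so p_hat = (n1 + 2 n2) / (2 N); the Wilson score
    interval is computed on those 2 N trials and the trinomial
    log-likelihood at p_hat is reported.
    """
    trials = 2 * counts.n_total
    successes = counts.n1 + 2 * counts.n2
    p_hat = successes / trials
    return OccupancyEstimate(
        p_equal=p_hat,
        conf_int=_wilson_interval(successes, trials, alpha),
        log_likelihood=_trinomial_loglike(counts, p_hat),
    )


def estimate_unequal(
    frequencies_or_counts: CargoCounts | Sequence[float], atol: float = 1e-6
) -> OccupancyEstimate:
    """Moment estimate of two unequal handle probabilities.

    Accepts either a :class:`CargoCounts` (frequencies are computed) or the
    observed fractions (P0, P1, P2).  Solves p1 + p2 = P1 + 2 P2 and
    p1 p2 = P2; returns the roots ordered p1 >= p2.  Infeasible (negative
    discriminant or roots outside [0, 1]) count patterns are flagged rather
    than raising: over-dispersion relative to independent handles is a
    legitimate empirical outcome.
    """
    if isinstance(frequencies_or_counts, CargoCounts):
        counts = frequencies_or_counts
        P0, P1, P2 = counts.frequencies
        base = estimate_equal_p(counts)
    else:
        P = np.asarray(frequencies_or_counts, dtype=float)
        if P.shape != (3,):
            raise ValueError("expected three frequencies (P0, P1, P2)")
        if abs(P.sum() - 1.0) > atol:
            raise ValueError(f"frequencies must sum to 1, got {P.sum():.6g}")
        if (P < -atol).any():
            raise ValueError("frequencies must be non-negative")
        P0, P1, P2 = (float(x) for x in P)
        p_hat = (P1 + 2 * P2) / 2.0
        base = OccupancyEstimate(
            p_equal=p_hat, conf_int=(np.nan, np.nan), log_likelihood=np.nan
        )

    s = P1 + 2.0 * P2  # p1 + p2
    q = P2  # p1 * p2
    disc = s * s - 4.0 * q
    if disc < 0:
        base.feasible = False
        base.p_pair = None
        base.message = (
            "over-dispersed counts inconsistent with independent handles "
            f"(discriminant {disc:.4g} < 0)"
        )
        return base
    root = math.sqrt(disc)
    p1 = (s + root) / 2.0
    p2 = (s - root) / 2.0
    if not (0.0 <= p2 <= p1 <= 1.0 + 1e-12):
        base.feasible = False
        base.p_pair = None
        base.message = f"moment roots outside [0, 1]: ({p1:.4g}, {p2:.4g})"
        return base
    base.p_pair = (min(p1, 1.0), p2)
    base.feasible = True
    return base


def compare_across_cycles(
    samples: Sequence[CargoCounts],
    seed: int = 0,
    n_resamples: int = 2000,
    min_expected: float = 5.0,
):
    """Chi-square homogeneity test of 0/1/2 count tables across samples.

    Tests whether the cargo-count distribution is the same across samples
    (e.g. across staple-reuse cycles).  When any expected cell is below
    ``min_expected`` the p-value comes from seeded multinomial resampling
    under the pooled null rather than the asymptotic chi-square.

    Returns
    -------
    (statistic, p_value, method) : (float, float, str)
    """
    if len(samples) < 2:
        raise ValueError("homogeneity test needs at least two samples")
    table = np.array([[s.n0, s.n1, s.n2] for s in samples], dtype=float)
    table = table[:, table.sum(axis=0) > 0]  # drop all-zero columns
    if table.shape[1] < 2:
        return 0.0, 1.0, "degenerate"
    stat, p, dof, expected = stats.chi2_contingency(table)
    if (expected >= min_expected).all():
        return float(stat), float(p), "asymptotic"

    rng = np.random.default_rng(seed)
    pooled = table.sum(axis=0) / table.sum()
    row_totals = table.sum(axis=1).astype(int)
    exceed = 0
    for _ in range(n_resamples):
        sim = np.array([rng.multinomial(n, pooled) for n in row_totals], dtype=float)
        keep = sim.sum(axis=0) > 0
        if keep.sum() < 2:
            sim_stat = 0.0
        else:
            sim_stat = stats.chi2_contingency(sim[:, keep])[0]
        if sim_stat >= stat - 1e-12:
            exceed += 1
    return float(stat), (1 + exceed) / (1 + n_resamples), "resampling"


class CargoOccupancyModel:
    """Two-independent-Bernoulli-handles model for cargo counts.

    Statsmodels-style front end: build from one or more count tables, call
    :meth:`fit` for an :class:`OccupancyResults` with estimates, intervals
    and a summary table.

    Parameters
    ----------
    counts : CargoCounts or sequence of CargoCounts or DataFrame
        A DataFrame must have columns ``sample_id, cycle, n0, n1, n2``.
    """

    def __init__(self, counts):
        if isinstance(counts, pd.DataFrame):
            counts = [
                CargoCounts(
                    n0=int(r.n0),
                    n1=int(r.n1),
                    n2=int(r.n2),
                    sample_id=str(getattr(r, "sample_id", i)),
                    cycle=int(getattr(r, "cycle", 0)),
                )
                for i, r in enumerate(counts.itertuples())
            ]
        elif isinstance(counts, CargoCounts):
            counts = [counts]
        else:
            counts = list(counts)
        if not counts:
            raise ValueError("no count tables given")
        self.counts: list[CargoCounts] = counts

    def fit(
        self, kind: str = "equal", alpha: float = 0.05, seed: int = 0
    ) -> "OccupancyResults":
        """Estimate per-handle probabilities for every sample.

        ``kind`` is ``"equal"`` (common p per sample) or ``"unequal"``
        (moment solution for (p1, p2) per sample); both always report the
        equal-p MLE.  With >= 2 samples a cross-sample homogeneity test is
        run with the given seed.
        """
        if kind not in ("equal", "unequal"):
            raise ValueError(f"kind must be 'equal' or 'unequal', got {kind!r}")
        estimates = []
        for c in self.counts:
            est = estimate_equal_p(c, alpha)
            if kind == "unequal":
                est = estimate_unequal(c)
                est.conf_int = estimate_equal_p(c, alpha).conf_int
            estimates.append(est)
        homogeneity = None
        if len(self.counts) >= 2:
            homogeneity = compare_across_cycles(self.counts, seed=seed)
        return OccupancyResults(
            model=self, kind=kind, estimates=estimates, homogeneity=homogeneity
        )


@dataclass
class OccupancyResults:
    """Fitted per-handle probabilities with intervals and diagnostics."""

    model: CargoOccupancyModel
    kind: str
    estimates: list[OccupancyEstimate]
    homogeneity: tuple[float, float, str] | None = None

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for c, e in zip(self.model.counts, self.estimates):
            row = {
                "sample_id": c.sample_id,
                "cycle": c.cycle,
                "n_particles": c.n_total,
                "p_equal": e.p_equal,
                "ci_low": e.conf_int[0],
                "ci_high": e.conf_int[1],
                "log_likelihood": e.log_likelihood,
                "feasible": e.feasible,
            }
            if self.kind == "unequal":
                row["p1"], row["p2"] = e.p_pair if e.p_pair else (np.nan, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.as_frame()
        lines = [
            f"Cargo occupancy model ({self.kind} handles)",
            "=" * 44,
            df.to_string(index=False, float_format=lambda x: f"{x:.4f}"),
        ]
        if self.homogeneity is not None:
            stat, p, method = self.homogeneity
            lines.append(
                f"homogeneity across samples: chi2 = {stat:.3f}, "
                f"p = {p:.4f} ({method})"
            )
        return "\n".join(lines)


def read_counts_csv(path: str | Path) -> list[CargoCounts]:
    """Read a counts CSV with header ``sample_id,cycle,n0,n1,n2``."""
    df = pd.read_csv(path)
    return [
        CargoCounts(
            n0=int(r["n0"]),
            n1=int(r["n1"]),
            n2=int(r["n2"]),
            sample_id=str(r.get("sample_id", i)),
            cycle=int(r.get("cycle", 0)),
        )
        for i, r in df.iterrows()
    ]
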