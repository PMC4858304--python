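"""Poisson quantification, reaction merging, Fieller ratio CIs, replicate CIs.

With ``n_t`` partitions read out and ``n_neg`` of them negative, the empty
probability and mean occupancy are

    p0_hat     = n_neg / n_t
    lambda_hat = -ln(p0_hat)

and the 95% confidence bounds on lambda are

    lambda_hat +/- 1.96 * sqrt((n_t - n_neg) / (n_t * n_neg)).

The transgene:endogene ratio (GM ratio, in haploid genome equivalents) is
``r = lambda_tr / lambda_en``; its 95% interval comes from Fieller's theorem
for a ratio of independent, approximately normal estimates, with standard
errors taken from the Poisson confidence half-widths.

Reactions assumed to share lambda can be *merged* by summing their positive
and negative partition counts, which tightens the Poisson bounds.  Because
Poisson bounds ignore dilution/preparation variability, the module also
provides replicate-based intervals ``mean +/- 1.96 * sd`` over repeated
quantifications (the A1, A2, B1, B2 sub-sample x duplicate scheme), which
capture the full analytical chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PoissonEstimate",
    "RatioEstimate",
    "ReplicateStats",
    "SaturatedReactionError",
    "Z95",
    "estimate_poisson",
    "merge_reactions",
    "gm_ratio",
    "replicate_ci",
    "coverage_assessment",
    "mass_to_copies",
    "copies_to_mass",
]

#: standard normal 97.5% quantile used throughout for 95% intervals
Z95 = 1.96


class SaturatedReactionError(ValueError):
    """All partitions positive: lambda is unbounded above.

    Merging with further reactions at the same concentration (summing
    positive and negative counts) may restore an estimate.
    """


@dataclass
class PoissonEstimate:
    """Occupancy estimate for one (possibly merged) reaction.

    ``cb_low``/``cb_high`` are the 95% Poisson confidence bounds on
    ``lambda_hat``; ``one_sided`` marks the all-negative boundary case
    where only an upper bound is meaningful.  Copy concentrations are
    derived from the partition volume (µl).
    """

    n_total: int
    n_neg: int
    p0_hat: float
    lambda_hat: float
    cb_low: float
    cb_high: float
    partition_volume_ul: float | None = None
    one_sided: bool = False

    @property
    def half_width(self) -> float:
        return 0.5 * (self.cb_high - self.cb_low)

    @property
    def copies_per_reaction(self) -> float:
        return self.lambda_hat * self.n_total

    @property
    def copies_per_ul(self) -> float | None:
        if self.partition_volume_ul is None:
            return None
        return self.lambda_hat / self.partition_volume_ul


@dataclass
class RatioEstimate:
    """Transgene:endogene ratio with a Fieller 95% interval.

    ``E`` and ``T`` are the absolute Poisson confidence half-widths of the
    endogene and transgene occupancy estimates; ``unbounded`` is set when
    the denominator interval reaches 0 and the Fieller interval is not a
    finite segment.
    """

    lambda_tr: PoissonEstimate
    lambda_en: PoissonEstimate
    r_gm: float
    ci_low: float
    ci_high: float
    E: float
    T: float
    unbounded: bool = False

    @property
    def inverse(self) -> float:
        """Endogene-to-transgene ratio (the reciprocal reading)."""
        return 1.0 / self.r_gm if self.r_gm != 0 else np.inf


@dataclass
class ReplicateStats:
    """Replicate-based summary: ``mean +/- 1.96 * sd`` interval."""

    estimates: np.ndarray
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    sigma2_pois: float | None = None
    sigma2_prep: float | None = None


def estimate_poisson(
    n_neg: int,
    n_total: int,
    partition_volume_ul: float | None = None,
) -> PoissonEstimate:
    """Estimate mean occupancy lambda from negative/total partition counts.

    Raises :class:`SaturatedReactionError` when no negative partitions
    remain (lambda undefined).  The all-negative case returns
    ``lambda_hat = 0`` with a one-sided flag; its upper bound is computed
    conservatively from ``n_neg = n_total - 1`` (the bound formula is
    undefined at the boundary, and one phantom positive partition is the
    smallest detectable departure).
    """
    if not 0 <= n_neg <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_neg <= n_total and n_total >= 1")
    if partition_volume_ul is not None and partition_volume_ul <= 0:
        raise ValueError("partition_volume_ul must be positive")
    if n_neg == 0:
        raise SaturatedReactionError(
            "all partitions positive: lambda is unbounded; merge with "
            "additional reactions at the same concentration or dilute"
        )
    p0 = n_neg / n_total
    if n_neg == n_total:
        hw = Z95 * np.sqrt(1.0 / (n_total * (n_total - 1))) if n_total > 1 else np.inf
        return PoissonEstimate(
            n_total=n_total,
            n_neg=n_neg,
            p0_hat=1.0,
            lambda_hat=0.0,
            cb_low=0.0,
            cb_high=float(hw),
            partition_volume_ul=partition_volume_ul,
            one_sided=True,
        )
    lam = -np.log(p0)
    hw = Z95 * np.sqrt((n_total - n_neg) / (n_total * n_neg))
    return PoissonEstimate(
        n_total=n_total,
        n_neg=n_neg,
        p0_hat=float(p0),
        lambda_hat=float(lam),
        cb_low=float(lam - hw),
        cb_high=float(lam + hw),
        partition_volume_ul=partition_volume_ul,
    )


def merge_reactions(
    counts: Iterable[tuple[int, int]],
    partition_volume_ul: float | None = None,
) -> PoissonEstimate:
    """Merge reactions assumed to share lambda by summing their counts.

    ``counts`` is an iterable of ``(n_neg, n_total)`` pairs.  Exactly
    equivalent to :func:`estimate_poisson` on the pooled counts.
    """
    pairs = list(counts)
    if not pairs:
        raise ValueError("merge_reactions needs at least one reaction")
    n_neg = sum(int(p[0]) for p in pairs)
    n_total = sum(int(p[1]) for p in pairs)
    return estimate_poisson(n_neg, n_total, partition_volume_ul)


def gm_ratio(tr: PoissonEstimate, en: PoissonEstimate) -> RatioEstimate:
    """GM ratio ``lambda_tr / lambda_en`` with a Fieller 95% interval.

    Each occupancy estimate is treated as normal with standard error equal
    to its Poisson confidence half-width divided by 1.96, and the two are
    independent.  With ``g = (z * se_en / lambda_en)^2 < 1`` the interval
    is the usual finite Fieller segment; ``g >= 1`` (denominator interval
    reaching 0) sets the unbounded flag and returns infinite bounds.  As
    both half-widths shrink to zero the interval collapses to the point
    ratio.
    """
    if en.lambda_hat <= 0:
        raise ValueError("endogene lambda_hat must be positive for a ratio")
    a, b = tr.lambda_hat, en.lambda_hat
    T = tr.half_width
    E = en.half_width
    se_a = T / Z95
    se_b = E / Z95
    r = a / b
    g = (Z95 * se_b / b) ** 2
    if g >= 1:
        return RatioEstimate(
            lambda_tr=tr,
            lambda_en=en,
            r_gm=float(r),
            ci_low=-np.inf,
            ci_high=np.inf,
            E=float(E),
            T=float(T),
            unbounded=True,
        )
    disc = se_a**2 + r**2 * se_b**2 - g * se_a**2
    half = (Z95 / b) * np.sqrt(max(disc, 0.0))
    low = (r - half) / (1.0 - g)
    high = (r + half) / (1.0 - g)
    return RatioEstimate(
        lambda_tr=tr,
        lambda_en=en,
        r_gm=float(r),
        ci_low=float(low),
        ci_high=float(high),
        E=float(E),
        T=float(T),
    )


def replicate_ci(estimates: Sequence[float]) -> ReplicateStats:
    """Replicate-based 95% interval ``mean +/- 1.96 * sd``.

    ``sd`` is the sample standard deviation (n-1 denominator) of the
    per-reaction estimates (occupancies or ratios).  Requires at least two
    values.  Unlike the Poisson bounds, this captures dilution and
    preparation variability, which dominates at high occupancy.
    """
    x = np.asarray(list(estimates), dtype=float)
    if x.size < 2:
        raise ValueError("replicate_ci needs at least two estimates")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return ReplicateStats(
        estimates=x,
        mean=mean,
        sd=sd,
        ci_low=mean - Z95 * sd,
        ci_high=mean + Z95 * sd,
    )


def coverage_assessment(
    intervals: Sequence[tuple[float, float]], truth: float
) -> float:
    """Fraction of ``(low, high)`` intervals containing the true value."""
    pairs = list(intervals)
    if not pairs:
        raise ValueError("coverage_assessment needs at least one interval")
    hits = sum(1 for low, high in pairs if low <= truth <= high)
    return hits / len(pairs)


def mass_to_copies(mass_ng: float, c_value_pg: float) -> float:
    """Convert a DNA mass (ng) to haploid genome copies via the 1C value (pg)."""
    if mass_ng <= 0 or c_value_pg <= 0:
        raise ValueError("mass and 1C value must be positive")
    return mass_ng * 1000.0 / c_value_pg


def copies_to_mass(copies: float, c_value_pg: float) -> float:
    """Inverse of :func:`mass_to_copies`: genome copies to DNA mass in ng."""
    if copies <= 0 or c_value_pg <= 0:
        raise ValueError("copies and 1C value must be positive")
    return copies * c_value_pg / 1000.0
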