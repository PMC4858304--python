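"""In-silico studies behind the assay acceptance limits.

Four studies are implemented:

* **Poisson CI width / optimal load** — the relative width of the Poisson
  confidence interval as a function of mean occupancy, whose minimum (the
  root of ``lambda = 2*(1 - exp(-lambda))``, ~1.59 targets per partition)
  is the optimal loading concentration for absolute quantification.
* **Misclassification tolerance** — the closed-form relative error on the
  transgene:endogene ratio when a share ``f`` of all partitions are true
  positives relabelled negative (endogene quantified exactly), and its
  inversion: the largest ``f`` tolerable before a given error (default
  25%) is reached.  The worst-case "hidden rain" budget multiplies that
  tolerance by the reciprocal of the share of rain assumed concealed
  inside the negative cloud.
* **Dynamic range** — a parametric bootstrap locating the lowest and
  highest occupancies at which 95% of reactions quantify within 25%
  relative error, for a given partition count and number of averaged
  repeats.
* **Sub-sampling** — a parametric bootstrap of a duplex reaction in which
  only a fraction of the generated droplets is analysed, measuring the
  probability that the ratio estimate errs by more than 25%.

All stochastic routines draw from an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from dropstat.quantify import Z95

__all__ = [
    "SimGrid",
    "MisclassSpec",
    "DynamicRangeResult",
    "ci_relative_width",
    "optimal_lambda",
    "misclassification_error",
    "tolerable_misclassification",
    "hidden_rain_budget",
    "dynamic_range_bootstrap",
    "subsampling_error_prob",
]

#: relative-error acceptance criterion for quantification
DEFAULT_MAX_ERROR = 0.25
#: required fraction of acceptable reactions
DEFAULT_CONFIDENCE = 0.95
#: QX200 droplet generation maximum
DEFAULT_PLATFORM_MAX = 23530


@dataclass
class SimGrid:
    """Grid and bootstrap sizes for the dynamic-range study.

    ``lambda_low`` / ``lambda_high`` are log-spaced grids (strictly
    increasing) probing the low and high end of the dynamic range; when
    omitted they are placed around the analytic crossing points for the
    given partition count and repeat scheme (roughly where 60 positive or
    3 negative partitions are expected in total across the averaged
    repeats: 60/(n*repeats) at the low end, ln(n*repeats/3) at the high
    end), spanning a factor of 2 below to 2 above at
    the low end and 1.5 at the high end with ``n_grid`` points, so that
    the grid resolves the crossing to about 1-2% in occupancy.
    """

    n_partitions: int = 20000
    repeats: int = 1
    n_boot: int = 2000
    n_grid: int = 75
    seed: int = 0
    max_error: float = DEFAULT_MAX_ERROR
    confidence_level: float = DEFAULT_CONFIDENCE
    lambda_low: np.ndarray | None = None
    lambda_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_partitions < 2:
            raise ValueError("n_partitions must be >= 2")
        if self.repeats < 1 or self.n_boot < 1 or self.n_grid < 2:
            raise ValueError("repeats, n_boot >= 1 and n_grid >= 2 required")
        if not self.max_error > 0:
            raise ValueError("max_error must be positive")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must be in (0, 1)")
        if self.lambda_low is None:
            center = 60.0 / (self.n_partitions * self.repeats)
            self.lambda_low = np.geomspace(center / 2, center * 2, self.n_grid)
        if self.lambda_high is None:
            center = np.log(self.n_partitions * self.repeats / 3.0)
            self.lambda_high = np.geomspace(center / 1.5, center * 1.5, self.n_grid)
        for grid in (self.lambda_low, self.lambda_high):
            if np.any(np.diff(grid) <= 0):
                raise ValueError("lambda grids must be strictly increasing")


@dataclass
class MisclassSpec:
    """Misclassification scenario for ratio quantification.

    ``f`` is the misclassified share of *all* partitions (true positives
    relabelled negative); ``p`` and ``p_prime`` expose the true and
    observed positive fractions of the transgene.  The endogene is assumed
    quantified exactly.
    """

    lambda_en: float
    ratio: float
    f: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_en <= 0 or self.ratio <= 0:
            raise ValueError("lambda_en and ratio must be positive")
        if self.f < 0:
            raise ValueError("f must be >= 0")
        if self.f > self.p:
            raise ValueError("f cannot exceed the true positive fraction")

    @property
    def lambda_tr(self) -> float:
        return self.ratio * self.lambda_en

    @property
    def p(self) -> float:
        """True positive fraction of the transgene, ``1 - exp(-lambda_tr)``."""
        return 1.0 - np.exp(-self.lambda_tr)

    @property
    def p_prime(self) -> float:
        """Observed positive fraction after misclassification."""
        return self.p - self.f


def ci_relative_width(lam: float, n_partitions: int) -> float:
    """Relative width of the 95% Poisson interval at expected counts.

    With expected negatives ``n0 = n * exp(-lambda)`` the width is
    ``2 * 1.96 * sqrt((n - n0) / (n * n0)) / lambda``.  Diverges at both
    ends: as lambda -> 0 there are too few positives, at large lambda the
    negatives die out (fewer than one expected negative raises).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    n = n_partitions
    n0 = n * np.exp(-lam)
    if n0 < 1.0:
        raise ValueError(
            f"fewer than one expected negative partition at lambda={lam:g}, "
            f"n={n}: interval undefined"
        )
    return 2.0 * Z95 * np.sqrt((n - n0) / (n * n0)) / lam


def optimal_lambda(n_partitions: int = 20000) -> float:
    """Occupancy minimizing the relative Poisson CI width (~1.59).

    The partition count scales the width but not the argmin, which solves
    the stationarity condition ``lambda = 2 * (1 - exp(-lambda))``.
    Located numerically on the width curve itself.
    """
    if n_partitions < 2:
        raise ValueError("n_partitions must be >= 2")
    result = optimize.minimize_scalar(
        lambda lam: ci_relative_width(lam, n_partitions),
        bounds=(0.05, 5.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(result.x)


def misclassification_error(spec: MisclassSpec) -> float:
    """Relative error on the GM ratio from misclassified transgene positives.

    Relabelling a share ``f`` of all partitions from positive to negative
    turns the observed positive fraction into ``p' = p - f``; the ratio
    error (endogene exact) is ``(lambda_tr - lambda') / lambda_tr`` with
    ``lambda' = -ln(1 - p')``.  Underestimation gives a positive error.
    """
    if spec.p_prime <= 0:
        raise ValueError(
            "misclassification wipes out all positives (p' <= 0): total loss"
        )
    if spec.f == 0:
        return 0.0
    lam_tr = spec.lambda_tr
    lam_obs = -np.log(1.0 - spec.p_prime)
    return float((lam_tr - lam_obs) / lam_tr)


def tolerable_misclassification(
    lambda_en: float,
    ratio: float,
    max_error: float = DEFAULT_MAX_ERROR,
    n_partitions: int = 20000,
) -> tuple[float, int]:
    """Largest misclassified share before ``max_error`` is reached.

    Closed-form inversion of :func:`misclassification_error`:
    ``f* = (1 - exp(-lambda_tr)) - (1 - exp(-(1 - max_error) * lambda_tr))``.
    Returns ``(f*, droplets)`` with the droplet count rounded at the given
    partition count.
    """
    if lambda_en <= 0 or ratio <= 0:
        raise ValueError("lambda_en and ratio must be positive")
    if not 0 < max_error < 1:
        raise ValueError("max_error must be in (0, 1)")
    lam_tr = ratio * lambda_en
    f_star = (1.0 - np.exp(-lam_tr)) - (1.0 - np.exp(-(1.0 - max_error) * lam_tr))
    return float(f_star), int(round(n_partitions * f_star))


def hidden_rain_budget(
    lambda_en: float,
    ratio: float,
    hidden_share: float = 0.10,
    n_partitions: int = 20000,
    max_error: float = DEFAULT_MAX_ERROR,
) -> tuple[int, float]:
    """Total rain tolerable when a share of it hides in the negative cloud.

    Rain concealed inside the negative cloud is always misclassified, so if
    only ``hidden_share`` of the rain is concealed, the reaction tolerates
    ``1 / hidden_share`` times the misclassification budget in total rain.
    Returns ``(droplets, fraction_of_partitions)``: at the 1% level with
    endogene occupancy 1 this is the 10 x 50 = 500 droplets (~2.5% of
    20000) behind the rain acceptance limit.
    """
    if not 0 < hidden_share <= 1:
        raise ValueError("hidden_share must be in (0, 1]")
    _, droplets = tolerable_misclassification(
        lambda_en, ratio, max_error=max_error, n_partitions=n_partitions
    )
    budget = int(round(droplets / hidden_share))
    return budget, budget / n_partitions


#: moving-average window (grid points) for smoothing the error-fraction curve
SMOOTH_WINDOW = 5


def _smooth(y: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average damping Monte-Carlo noise in the curve.

    The true error-fraction curve is saw-toothed (the acceptable negative
    count is an integer cutoff that jumps along the grid), so the smoothing
    window is kept small: it must suppress bootstrap noise without erasing
    the genuine dips of the sawtooth that define the outermost acceptable
    occupancies.
    """
    y = np.asarray(y, dtype=float)
    kernel = np.ones(window) / window
    padded = np.concatenate([np.repeat(y[0], window // 2), y, np.repeat(y[-1], window // 2)])
    return np.convolve(padded, kernel, mode="valid")


@dataclass
class DynamicRangeResult:
    """Bounds of the usable occupancy range plus the raw error curves."""

    lambda_lower: float
    lambda_upper: float
    copies_lower: float
    copies_upper: float
    grid_low: np.ndarray = field(repr=False, default=None)
    frac_low: np.ndarray = field(repr=False, default=None)
    grid_high: np.ndarray = field(repr=False, default=None)
    frac_high: np.ndarray = field(repr=False, default=None)


def _error_fraction_curve(
    grid: np.ndarray,
    n: int,
    repeats: int,
    n_boot: int,
    max_error: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fraction of bootstrap reactions exceeding ``max_error`` per grid point.

    Each bootstrap draws ``repeats`` reactions of ``n`` partitions with
    negatives ~ Binomial(n, exp(-lambda)) and combines them by averaging
    the observed empty-partition fractions — equivalent to merging the
    reactions' counts, and the only combination rule under which adding
    repeats widens the usable range at both ends (averaging the per-repeat
    log estimates instead would let a single saturated repeat spoil the
    whole bootstrap, and the upper bound would *shrink* with repeats).
    Draws with zero negatives overall leave the occupancy undefined and
    are counted as exceeding the criterion (conservative).
    """
    n_pooled = n * repeats
    frac = np.empty(grid.size)
    for i, lam in enumerate(grid):
        p0 = np.exp(-lam)
        n_neg = rng.binomial(n_pooled, p0, size=n_boot)
        with np.errstate(divide="ignore"):
            lam_hat = np.where(n_neg > 0, -np.log(n_neg / n_pooled), np.inf)
        rel_err = np.abs(lam_hat - lam) / lam
        frac[i] = np.mean(rel_err > max_error)
    return frac


def _crossing(
    grid: np.ndarray, frac: np.ndarray, level: float, increasing: bool
) -> float:
    """Boundary of the acceptable region on a smoothed error-fraction curve.

    ``increasing`` describes the macroscopic trend of the error fraction
    along the grid (False at the low end, where error falls as occupancy
    rises).  The bound is the *outermost* acceptable occupancy: the
    smallest grid value whose smoothed fraction is at or below ``level``
    at the low end, the largest at the high end — matching the definition
    of the range as the lowest and highest occupancy at which the required
    share of reactions quantifies accurately.  The crossing into the
    adjacent unacceptable grid point is refined by interpolation in
    log-occupancy.  If no grid point is acceptable, the acceptable-side
    grid end is returned.
    """
    smooth = _smooth(frac)
    ok = np.flatnonzero(smooth <= level)
    if increasing:
        if ok.size == 0:
            return float(grid[0])
        last = int(ok[-1])
        if last == grid.size - 1:
            return float(grid[-1])
        f0, f1 = smooth[last], smooth[last + 1]
        t = 0.0 if f1 == f0 else (level - f0) / (f1 - f0)
        return float(grid[last] * (grid[last + 1] / grid[last]) ** t)
    if ok.size == 0:
        return float(grid[-1])
    first = int(ok[0])
    if first == 0:
        return float(grid[0])
    f0, f1 = smooth[first - 1], smooth[first]
    t = 1.0 if f1 == f0 else (level - f0) / (f1 - f0)
    return float(grid[first - 1] * (grid[first] / grid[first - 1]) ** t)


def dynamic_range_bootstrap(grid: SimGrid) -> DynamicRangeResult:
    """Parametric bootstrap of the quantifiable occupancy range.

    For every grid occupancy, ``n_boot`` reactions are simulated (negatives
    binomial at ``exp(-lambda)``, ``repeats`` reactions averaged) and the
    fraction exceeding ``max_error`` relative error is recorded.  The
    range bounds are the outermost occupancies at which the smoothed
    fraction stays at or below ``1 - confidence_level`` — by default the
    lowest and highest occupancy at which 95% of reactions quantify within
    25% error.  Copies bounds are ``round(lambda * n)``.
    """
    rng = np.random.default_rng(grid.seed)
    frac_low = _error_fraction_curve(
        grid.lambda_low, grid.n_partitions, grid.repeats, grid.n_boot, grid.max_error, rng
    )
    frac_high = _error_fraction_curve(
        grid.lambda_high, grid.n_partitions, grid.repeats, grid.n_boot, grid.max_error, rng
    )
    level = 1.0 - grid.confidence_level
    lam_lo = _crossing(grid.lambda_low, frac_low, level, increasing=False)
    lam_hi = _crossing(grid.lambda_high, frac_high, level, increasing=True)
    return DynamicRangeResult(
        lambda_lower=lam_lo,
        lambda_upper=lam_hi,
        copies_lower=round(lam_lo * grid.n_partitions),
        copies_upper=round(lam_hi * grid.n_partitions),
        grid_low=grid.lambda_low,
        frac_low=frac_low,
        grid_high=grid.lambda_high,
        frac_high=frac_high,
    )


def subsampling_error_prob(
    fraction: float,
    lambda_en: float,
    ratio: float,
    n_boot: int = 10000,
    platform_max: int = DEFAULT_PLATFORM_MAX,
    max_error: float = DEFAULT_MAX_ERROR,
    seed: int = 0,
) -> float:
    """Probability that sub-sampling pushes the ratio error beyond 25%.

    Emulates a duplex reaction on a platform generating ``platform_max``
    droplets of which only ``fraction`` are accepted: per bootstrap, full
    positive counts are drawn for both targets (binomial at the occupancy),
    the accepted subset is drawn hypergeometrically, and the ratio is
    re-estimated from the sub-sample.  Sub-samples with zero positives or
    zero negatives for either target leave the ratio undefined and count
    as failures.  Returns the fraction of ``n_boot`` bootstraps whose
    ratio errs by more than ``max_error``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if lambda_en <= 0 or ratio <= 0:
        raise ValueError("lambda_en and ratio must be positive")
    rng = np.random.default_rng(seed)
    n_full = platform_max
    m = int(round(fraction * n_full))
    if m < 1:
        raise ValueError("sub-sample contains no droplets")
    lam_tr = ratio * lambda_en
    p_en = 1.0 - np.exp(-lambda_en)
    p_tr = 1.0 - np.exp(-lam_tr)

    pos_en_full = rng.binomial(n_full, p_en, size=n_boot)
    pos_tr_full = rng.binomial(n_full, p_tr, size=n_boot)
    pos_en = rng.hypergeometric(pos_en_full, n_full - pos_en_full, m)
    pos_tr = rng.hypergeometric(pos_tr_full, n_full - pos_tr_full, m)

    neg_en = m - pos_en
    neg_tr = m - pos_tr
    bad = (pos_en == 0) | (neg_en == 0) | (pos_tr == 0) | (neg_tr == 0)
    rel_err = np.full(n_boot, np.inf)
    ok = ~bad
    lam_en_hat = -np.log(neg_en[ok] / m)
    lam_tr_hat = -np.log(neg_tr[ok] / m)
    r_hat = lam_tr_hat / lam_en_hat
    rel_err[ok] = np.abs(r_hat - ratio) / ratio
    return float(np.mean(rel_err > max_error))
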