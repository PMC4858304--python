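"""Kernel-density droplet categorization.

The classifier takes the droplets' end-point fluorescence readings as its
only input and proceeds in five stages:

1. A Gaussian kernel density estimate of the fluorescence with a bandwidth
   floor of 50 fluorescence units (below that, instrument noise produces
   spurious modes).
2. Sliding-window peak finding on the density curve.
3. Initial population estimates: the outermost peaks seed the negative and
   positive populations; the peak position is the initial median and half
   the peak width at 60.65% of its height (the ``exp(-1/2)`` level, which
   for a Gaussian falls exactly one standard deviation from the mode) is
   the initial scale.
4. Robust refinement, three iterations per population: droplets within
   ``mu +/- a*sigma`` (initially ``a = 4``) are selected; the median and
   the scaled median absolute deviation re-estimate location and scale; the
   Pearson (non-excess) kurtosis ``k`` of the selected members updates the
   bound multiplier ``a = 4.55 + 0.35*ln(k) + 0.045*ln(k)^2``, so heavier
   tails widen the population bounds toward ~99% coverage.
5. A threshold ``theta = mu_n + 1.5*a_n*sigma_n`` above the negative
   population.  Droplets above ``theta`` count positive, droplets between
   the negative upper bound and the positive lower bound are flagged as
   rain (reported separately, but counted positive for quantification since
   rain droplets generally contain target).  If population bounds overlap
   or the threshold lands inside the positive population, the offending
   boundary/threshold is replaced by the kernel-density minimum between the
   peaks and ``fallback_used`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from dropstat.io import AmplitudeTable

__all__ = [
    "DensityEstimate",
    "PopulationModel",
    "ClassificationResult",
    "DegenerateInputError",
    "bound_multiplier",
    "estimate_density",
    "find_density_peaks",
    "initial_population_estimates",
    "refine_population",
    "set_threshold",
    "classify_droplets",
]

#: minimum KDE bandwidth in fluorescence units
MIN_BANDWIDTH = 50.0
#: density height fraction at which the peak width is measured: exp(-1/2)
WIDTH_HEIGHT_FRACTION = 0.6065
#: initial bound multiplier before kurtosis refinement
INITIAL_A = 4.0
#: refinement iterations (stable in the first decimal place after three)
N_REFINE_ITERATIONS = 3
#: Gaussian-consistency factor for the median absolute deviation
MAD_SCALE = 1.4826
#: kurtosis floor guarding the log terms against tiny-sample pathologies
KURTOSIS_FLOOR = 1.05
#: sliding window width as a fraction of the observed fluorescence range
PEAK_WINDOW_FRACTION = 1.0 / 20.0
#: peaks below this fraction of the maximum density are ignored
PEAK_PROMINENCE_FLOOR = 0.01
#: threshold distance above the negative median, in units of a*sigma
THRESHOLD_FACTOR = 1.5
#: minimum droplets for a full classification
MIN_DROPLETS = 100
#: minimum members for a population refinement window
MIN_MEMBERS = 5
#: number of evaluation points for the density grid
GRID_SIZE = 512


class DegenerateInputError(ValueError):
    """Amplitude input cannot support a density estimate (e.g. constant)."""


def bound_multiplier(k: float) -> float:
    """Population bound multiplier from Pearson kurtosis.

    ``a = 4.55 + 0.35*ln(k) + 0.045*ln(k)^2`` — an empirical map from the
    kurtosis of a fluorescence population to the number of robust standard
    deviations needed to cover ~99% of its readings; at the Gaussian
    kurtosis of 3 it gives a ~ 4.99, and it grows with tail weight.  ``k``
    is floored at ``KURTOSIS_FLOOR`` to keep the log terms tame on tiny
    samples.
    """
    k = max(float(k), KURTOSIS_FLOOR)
    log_k = np.log(k)
    return float(4.55 + 0.35 * log_k + 0.045 * log_k**2)


@dataclass
class DensityEstimate:
    """Gaussian KDE of droplet fluorescence on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])


@dataclass
class PopulationModel:
    """Robust location/scale/kurtosis model of one droplet population.

    ``lower``/``upper`` are the population fluorescence bounds
    ``mu +/- a*sigma``; the refinement keeps ``a >= 4`` (the kurtosis floor
    maps to ``a ~ 4.57``).
    """

    mu: float
    sigma: float
    k: float
    a: float
    n_members: int
    fallback: bool = False

    @property
    def lower(self) -> float:
        return self.mu - self.a * self.sigma

    @property
    def upper(self) -> float:
        return self.mu + self.a * self.sigma


@dataclass
class ClassificationResult:
    """Outcome of the full categorization pipeline for one well/channel."""

    theta: float
    labels: np.ndarray  # {"negative", "positive", "rain"} per droplet
    n_neg: int
    n_pos: int
    n_rain: int
    n_total: int
    populations: list[PopulationModel] = field(default_factory=list)
    n_populations: int = 0
    fallback_used: bool = False
    single_population: bool = False

    @property
    def negative(self) -> PopulationModel | None:
        return self.populations[0] if self.populations else None

    @property
    def positive(self) -> PopulationModel | None:
        return self.populations[-1] if len(self.populations) > 1 else None


def _nrd0_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth (R's ``bw.nrd0``)."""
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        spread = abs(float(x[0])) or 1.0
    return 0.9 * spread * x.size ** (-0.2)


def estimate_density(
    amplitudes: np.ndarray | AmplitudeTable,
    bandwidth_floor: float = MIN_BANDWIDTH,
) -> DensityEstimate:
    """Gaussian KDE with ``bandwidth = max(bandwidth_floor, rule-of-thumb)``.

    Evaluated on a 512-point grid extended three bandwidths beyond the data
    range.  Raises :class:`DegenerateInputError` for constant input.
    """
    if isinstance(amplitudes, AmplitudeTable):
        amplitudes = amplitudes.amplitudes
    x = np.asarray(amplitudes, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise DegenerateInputError(
            "density estimation needs at least two distinct amplitudes"
        )
    bandwidth = max(bandwidth_floor, _nrd0_bandwidth(x))
    grid = np.linspace(x.min() - 3 * bandwidth, x.max() + 3 * bandwidth, GRID_SIZE)
    kde = stats.gaussian_kde(x, bw_method=bandwidth / x.std(ddof=1))
    density = kde(grid)
    return DensityEstimate(grid=grid, density=density, bandwidth=bandwidth)


def find_density_peaks(
    density: DensityEstimate,
    window_fraction: float = PEAK_WINDOW_FRACTION,
    prominence_floor: float = PEAK_PROMINENCE_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate density peaks with a sliding-window maximum filter.

    A grid point is a peak when it carries the maximum density within a
    window spanning ``window_fraction`` of the observed fluorescence range
    and its height exceeds ``prominence_floor`` times the global maximum.
    Returns ``(locations, heights)`` sorted by fluorescence.
    """
    d = density.density
    half = max(1, int(round(window_fraction * d.size / 2)))
    is_peak = np.ones(d.size, dtype=bool)
    for shift in range(1, half + 1):
        is_peak[shift:] &= d[shift:] >= d[:-shift]
        is_peak[:-shift] &= d[:-shift] >= d[shift:]
    is_peak &= d > prominence_floor * d.max()
    idx = np.flatnonzero(is_peak)
    if idx.size > 1:
        # a flat-topped window maximum yields a run of indices: keep centers
        keep = []
        run = [idx[0]]
        for i in idx[1:]:
            if i - run[-1] <= half:
                run.append(i)
            else:
                keep.append(run[len(run) // 2])
                run = [i]
        keep.append(run[len(run) // 2])
        idx = np.array(keep)
    return density.grid[idx], d[idx]


def _find_density_minimum(density: DensityEstimate, lo: float, hi: float) -> float:
    """Location of the lowest density between two fluorescence positions."""
    mask = (density.grid > lo) & (density.grid < hi)
    if not mask.any():
        return 0.5 * (lo + hi)
    segment = np.flatnonzero(mask)
    return float(density.grid[segment[np.argmin(density.density[segment])]])


def _width_at_height(
    density: DensityEstimate, peak_loc: float, peak_height: float
) -> float | None:
    """Full peak width at ``WIDTH_HEIGHT_FRACTION`` of the peak height.

    Walks outward from the peak until the curve drops below the level,
    interpolating the crossing.  Returns ``None`` when either side runs off
    the grid before crossing (peak too close to the edge).
    """
    level = WIDTH_HEIGHT_FRACTION * peak_height
    grid, dens = density.grid, density.density
    i_peak = int(np.argmin(np.abs(grid - peak_loc)))

    def _cross(direction: int) -> float | None:
        i = i_peak
        while 0 <= i + direction < grid.size:
            j = i + direction
            if dens[j] < level:
                # linear interpolation between grid[i] and grid[j]
                frac = (dens[i] - level) / (dens[i] - dens[j])
                return float(grid[i] + frac * (grid[j] - grid[i]))
            i = j
        return None

    left = _cross(-1)
    right = _cross(+1)
    if left is None or right is None:
        return None
    return right - left


def initial_population_estimates(
    density: DensityEstimate, peaks: tuple[np.ndarray, np.ndarray]
) -> list[tuple[float, float, bool]]:
    """Seed ``(mu0, sigma0, fallback)`` for the outer populations.

    The fluorescence range is split into parts according to the number of
    peaks found: with two or more peaks, the lowest peak seeds the negative
    population and the highest the positive one (interior peaks belong to
    extra populations and are not seeded here).  With a single peak, the
    peak seeds the negative population when it sits below the midpoint of
    the grid, else the positive one.  ``sigma0`` is half the peak width at
    60.65% of the peak height; when the width cannot be measured (peak at
    the grid edge) the bandwidth stands in and the fallback flag is set.
    """
    locations, heights = peaks
    if locations.size < 1:
        raise ValueError("at least one density peak is required")
    if locations.size == 1:
        chosen = [0]
    else:
        chosen = [0, int(locations.size - 1)]
    out = []
    for i in chosen:
        width = _width_at_height(density, float(locations[i]), float(heights[i]))
        if width is None or width <= 0:
            out.append((float(locations[i]), density.bandwidth, True))
        else:
            out.append((float(locations[i]), width / 2.0, False))
    return out


def refine_population(
    amplitudes: np.ndarray,
    mu0: float,
    sigma0: float,
    min_members: int = MIN_MEMBERS,
) -> PopulationModel:
    """Three-iteration robust refinement of one population model.

    Each iteration selects the readings within ``mu +/- a*sigma`` and
    recomputes: median -> ``mu``, scaled MAD -> ``sigma``, Pearson kurtosis
    of the members -> ``k`` (floored at 1.05), and the bound multiplier
    ``a = 4.55 + 0.35*ln(k) + 0.045*ln(k)^2``.  Three iterations settle the
    estimates in the first decimal place.  Fewer than five members in the
    window sets the fallback flag and freezes the current estimates.
    """
    x = np.asarray(amplitudes, dtype=float)
    if not (np.isfinite(mu0) and np.isfinite(sigma0)) or sigma0 <= 0:
        raise ValueError("initial estimates must be finite with sigma0 > 0")
    mu, sigma, a = float(mu0), float(sigma0), INITIAL_A
    k = 3.0
    n_members = 0
    fallback = False
    for _ in range(N_REFINE_ITERATIONS):
        members = x[(x >= mu - a * sigma) & (x <= mu + a * sigma)]
        if members.size < min_members:
            fallback = True
            break
        n_members = int(members.size)
        mu = float(np.median(members))
        mad = float(np.median(np.abs(members - mu)))
        if mad > 0:
            sigma = MAD_SCALE * mad
        k = max(float(stats.kurtosis(members, fisher=False)), KURTOSIS_FLOOR)
        a = bound_multiplier(k)
    return PopulationModel(
        mu=mu, sigma=sigma, k=k, a=float(a), n_members=n_members, fallback=fallback
    )


def set_threshold(neg: PopulationModel) -> float:
    """Quantification threshold ``theta = mu_n + 1.5 * a_n * sigma_n``.

    Placed above the negative population's upper bound (1.5a > a) so that
    the probability of miscounting negative droplets as positive is
    minimized.
    """
    return neg.mu + THRESHOLD_FACTOR * neg.a * neg.sigma


def classify_droplets(
    amplitudes: np.ndarray | AmplitudeTable,
    min_droplets: int = MIN_DROPLETS,
    window_fraction: float = PEAK_WINDOW_FRACTION,
    prominence_floor: float = PEAK_PROMINENCE_FLOOR,
    bandwidth_floor: float = MIN_BANDWIDTH,
    min_members: int = MIN_MEMBERS,
    density_fallback: bool = True,
) -> ClassificationResult:
    """Run the full categorization pipeline on one well/channel.

    Returns per-droplet labels (``negative`` / ``positive`` / ``rain``),
    the threshold, the population models (negative first, positive last),
    and the count of density peaks as ``n_populations``.  Rain droplets are
    labelled separately for QC, but the quantification counts are set by
    the threshold alone (rain above ``theta`` — the bulk of it — counts
    positive, since rain droplets generally contain target), so
    ``n_neg + n_pos == n_total`` always.

    With no positive population (all-negative well), ``n_pos`` may be 0 and
    ``single_population`` is set; the threshold still sits above the
    negative cloud.
    """
    if isinstance(amplitudes, AmplitudeTable):
        amplitudes = amplitudes.amplitudes
    x = np.asarray(amplitudes, dtype=float)
    if x.size < min_droplets:
        raise ValueError(f"need at least {min_droplets} droplets, got {x.size}")

    density = estimate_density(x, bandwidth_floor=bandwidth_floor)
    peaks = find_density_peaks(density, window_fraction, prominence_floor)
    locations, _ = peaks
    n_populations = int(locations.size)
    seeds = initial_population_estimates(density, peaks)

    fallback_used = any(flag for _, _, flag in seeds)
    models = [
        refine_population(x, mu0, s0, min_members=min_members)
        for mu0, s0, flag in seeds
    ]
    fallback_used |= any(m.fallback for m in models)

    midpoint = 0.5 * (density.grid[0] + density.grid[-1])
    if len(models) == 1:
        single = True
        # A lone cloud with nothing else in range sits exactly at the
        # midpoint; bias the tie toward "negative" (one bandwidth of slack)
        # since an all-negative well is the common single-population case
        # and miscalling it positive would invert every count.
        if models[0].mu <= midpoint + density.bandwidth:
            neg, pos = models[0], None
        else:
            neg, pos = None, models[0]
    else:
        single = False
        neg, pos = models[0], models[-1]

    if neg is None:
        # no negative cloud at all: every droplet is positive, no threshold
        # can be estimated from a negative population; fall back to the
        # density minimum below the positive cloud (or the grid start).
        theta = _find_density_minimum(density, float(density.grid[0]), pos.lower)
        fallback_used = True
        rain_lo, rain_hi = theta, pos.lower
        populations = [pos]
    else:
        theta = set_threshold(neg)
        rain_lo, rain_hi = neg.upper, (pos.lower if pos is not None else np.inf)
        populations = [neg] if pos is None else [neg, pos]
        if pos is not None:
            overlap = neg.upper >= pos.lower
            theta_inside = theta >= pos.lower
            if overlap or theta_inside:
                fallback_used = True
                if density_fallback:
                    dmin = _find_density_minimum(density, neg.mu, pos.mu)
                    if overlap:
                        rain_lo = rain_hi = dmin
                    if theta_inside or not (rain_lo < theta < rain_hi):
                        theta = dmin

    labels = np.full(x.size, "negative", dtype=object)
    labels[x > theta] = "positive"
    if np.isfinite(rain_hi) and rain_hi > rain_lo:
        labels[(x > rain_lo) & (x < rain_hi)] = "rain"

    n_pos = int(np.count_nonzero(x > theta))
    n_neg = int(x.size - n_pos)
    n_rain = int(np.count_nonzero(labels == "rain"))
    return ClassificationResult(
        theta=float(theta),
        labels=labels,
        n_neg=n_neg,
        n_pos=n_pos,
        n_rain=n_rain,
        n_total=int(x.size),
        populations=populations,
        n_populations=n_populations,
        fallback_used=bool(fallback_used),
        single_population=single or (n_pos == 0),
    )
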