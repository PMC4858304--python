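"""Assay performance parameters and post-run acceptance checks.

Three run-validation criteria define a well-behaved droplet assay:

* **single amplification product** — exactly two fluorescence populations;
* **resolution** — the chromatography-style peak separation
  ``Rs = 2 * (t_p - t_n) / (w_p + w_n)`` must be at least 2.5, where ``t``
  is a population's peak fluorescence and ``w`` its base width (the span of
  the ``mu +/- a*sigma`` population range, i.e. ``2*a*sigma``);
* **rain** — at most 2.5% of droplets with intermediate fluorescence.

Validation runs are performed near lambda = 0.7 (about half the partitions
positive), where both rain and dispersion are visible without one
population dwarfing the other.

Post-run, two further checks guard the quantification itself: the measured
copy number must lie inside the platform's dynamic range, and the fraction
of the loaded volume actually analysed (compartmentalization) must reach
30% for quantification down to 1% analyte, or 50% down to 0.5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from dropstat.classify import ClassificationResult, PopulationModel
from dropstat.io import PlateConfig
from dropstat.quantify import PoissonEstimate

__all__ = [
    "ResolutionResult",
    "Verdict",
    "QCReport",
    "MIN_RESOLUTION",
    "MAX_RAIN_FRACTION",
    "VALIDATION_LAMBDA_WINDOW",
    "COMPARTMENTALIZATION_LIMITS",
    "DYNAMIC_RANGE_COPIES",
    "resolution",
    "rain_fraction",
    "compartmentalization_fraction",
    "evaluate_assay",
]

#: acceptance limits for the three run-validation criteria
EXPECTED_POPULATIONS = 2
MIN_RESOLUTION = 2.5
MAX_RAIN_FRACTION = 0.025

#: validation-condition window around lambda = 0.7 (declared tolerance)
VALIDATION_LAMBDA_WINDOW = (0.5, 0.9)

#: minimum compartmentalized fraction by quantification level (analyte share)
COMPARTMENTALIZATION_LIMITS = {0.01: 0.30, 0.005: 0.50}

#: default single-reaction dynamic range in copies per reaction, keyed by
#: platform partition count.  Derived with
#: :func:`dropstat.simulate.dynamic_range_bootstrap` at 2000 bootstraps
#: (95% of reactions under 25% relative error); recompute for other
#: platforms or repeat counts.
DYNAMIC_RANGE_COPIES = {20000: (61.0, 177000.0), 765: (59.0, 4200.0)}


@dataclass
class ResolutionResult:
    """Peak positions, base widths, and the resulting resolution."""

    t_n: float
    t_p: float
    w_n: float
    w_p: float
    r_s: float


@dataclass
class Verdict:
    """One pass/fail check with the measured value and the limit applied."""

    name: str
    passed: bool | None  # None = not evaluated
    value: float | None
    limit: str

    @property
    def evaluated(self) -> bool:
        return self.passed is not None


@dataclass
class QCReport:
    """Structured QC verdicts for one reaction."""

    n_populations: int | None = None
    r_s: float | None = None
    rain_fraction: float | None = None
    lambda_hat: float | None = None
    copies_per_reaction: float | None = None
    compartmentalization_fraction: float | None = None
    verdicts: list[Verdict] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        evaluated = [v for v in self.verdicts if v.evaluated]
        return bool(evaluated) and all(v.passed for v in evaluated)


def resolution(neg: PopulationModel, pos: PopulationModel) -> ResolutionResult:
    """Peak resolution ``Rs = 2 * (t_p - t_n) / (w_p + w_n)``.

    ``t`` is the population center and ``w`` the base width ``2*a*sigma``
    (the limits of the population range are its peak base).  ``Rs >= 2``
    means complete separation; the acceptance limit of 2.5 leaves headroom
    for degraded or inhibited samples.
    """
    if neg is None or pos is None:
        raise ValueError("resolution requires both populations")
    t_n, t_p = neg.mu, pos.mu
    if t_p <= t_n:
        raise ValueError("positive population must sit above the negative one")
    w_n = 2.0 * neg.a * neg.sigma
    w_p = 2.0 * pos.a * pos.sigma
    return ResolutionResult(
        t_n=t_n, t_p=t_p, w_n=w_n, w_p=w_p, r_s=2.0 * (t_p - t_n) / (w_p + w_n)
    )


def rain_fraction(result: ClassificationResult) -> float:
    """Share of droplets categorized as rain, ``n_rain / n_total``."""
    if result.n_total < 1:
        raise ValueError("classification result has no droplets")
    return result.n_rain / result.n_total


def compartmentalization_fraction(
    n_accepted: int, partition_volume_ul: float, loaded_volume_ul: float
) -> float:
    """Analysed volume over loaded volume, ``n * v_partition / v_loaded``.

    23530 accepted droplets of 0.85 nl from a 20 µl load give exactly 1.0.
    Values above 1 (volume bookkeeping noise) are reported as computed.
    """
    if n_accepted < 1:
        raise ValueError("n_accepted must be >= 1")
    if partition_volume_ul <= 0 or loaded_volume_ul <= 0:
        raise ValueError("volumes must be positive")
    return n_accepted * partition_volume_ul / loaded_volume_ul


def _compartmentalization_limit(quantification_level: float) -> float:
    """Limit for the declared quantification level: 30% down to 1%, 50% below."""
    if quantification_level < 0.01:
        return COMPARTMENTALIZATION_LIMITS[0.005]
    return COMPARTMENTALIZATION_LIMITS[0.01]


def evaluate_assay(
    classification: ClassificationResult | None = None,
    estimate: PoissonEstimate | None = None,
    config: PlateConfig | None = None,
    validation_run: bool = True,
    dynamic_range_copies: tuple[float, float] | None = None,
) -> QCReport:
    """Evaluate every applicable criterion and return a structured report.

    Missing inputs yield "not evaluated" verdicts rather than failures.
    ``validation_run`` additionally checks that the measured occupancy sits
    in the validation window around lambda = 0.7.  The dynamic-range check
    uses ``dynamic_range_copies`` when given, else the cached default for
    the platform's partition count (when known).
    """
    report = QCReport()
    verdicts = report.verdicts

    if classification is not None:
        report.n_populations = classification.n_populations
        verdicts.append(
            Verdict(
                name="single_amplification_product",
                passed=classification.n_populations == EXPECTED_POPULATIONS,
                value=float(classification.n_populations),
                limit=f"== {EXPECTED_POPULATIONS} populations",
            )
        )
        rain = rain_fraction(classification)
        report.rain_fraction = rain
        verdicts.append(
            Verdict(
                name="rain_fraction",
                passed=rain <= MAX_RAIN_FRACTION,
                value=rain,
                limit=f"<= {MAX_RAIN_FRACTION}",
            )
        )
        if classification.negative is not None and classification.positive is not None:
            r_s = resolution(classification.negative, classification.positive).r_s
            report.r_s = r_s
            verdicts.append(
                Verdict(
                    name="resolution",
                    passed=r_s >= MIN_RESOLUTION,
                    value=r_s,
                    limit=f">= {MIN_RESOLUTION}",
                )
            )
        else:
            verdicts.append(
                Verdict(name="resolution", passed=None, value=None, limit=f">= {MIN_RESOLUTION}")
            )
    else:
        for name in ("single_amplification_product", "rain_fraction", "resolution"):
            verdicts.append(Verdict(name=name, passed=None, value=None, limit=""))

    if estimate is not None:
        report.lambda_hat = estimate.lambda_hat
        report.copies_per_reaction = estimate.copies_per_reaction
        if validation_run:
            lo, hi = VALIDATION_LAMBDA_WINDOW
            verdicts.append(
                Verdict(
                    name="validation_lambda",
                    passed=lo <= estimate.lambda_hat <= hi,
                    value=estimate.lambda_hat,
                    limit=f"in [{lo}, {hi}] (target 0.7)",
                )
            )
        bounds = dynamic_range_copies
        if bounds is None and config is not None:
            bounds = DYNAMIC_RANGE_COPIES.get(config.max_partitions)
        if bounds is None:
            bounds = DYNAMIC_RANGE_COPIES.get(estimate.n_total)
        if bounds is not None:
            low, high = bounds
            copies = estimate.copies_per_reaction
            verdicts.append(
                Verdict(
                    name="dynamic_range",
                    passed=low <= copies <= high,
                    value=copies,
                    limit=f"copies in [{low:g}, {high:g}]",
                )
            )
        else:
            verdicts.append(
                Verdict(name="dynamic_range", passed=None, value=None, limit="")
            )
    else:
        names = ["dynamic_range"] + (["validation_lambda"] if validation_run else [])
        for name in names:
            verdicts.append(Verdict(name=name, passed=None, value=None, limit=""))

    if estimate is not None and config is not None:
        frac = compartmentalization_fraction(
            estimate.n_total, config.partition_volume_ul, config.loaded_volume_ul
        )
        report.compartmentalization_fraction = frac
        limit = _compartmentalization_limit(config.quantification_level)
        verdicts.append(
            Verdict(
                name="compartmentalization",
                passed=frac >= limit,
                value=frac,
                limit=f">= {limit} at level {config.quantification_level:g}",
            )
        )
    else:
        verdicts.append(
            Verdict(name="compartmentalization", passed=None, value=None, limit="")
        )
    return report
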