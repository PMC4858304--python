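"""Synthetic droplet reactions with known ground truth.

The generator emulates the statistical structure of end-point droplet
fluorescence in a dPCR run: target molecules are distributed over droplets
as a Poisson process with mean occupancy ``lambda_true``; empty droplets
emit from the negative fluorescence population and occupied droplets from
the positive one, except for a controllable share of "rain" — occupied
droplets whose amplification lagged, leaving them spread roughly uniformly
across the gap between the two clouds.  Each population is a two-component
normal scale mixture (a ``tail_weight`` share drawn at 3x scale) so that
kurtosis can be raised above the Gaussian value of 3, as is common in real
droplet data.

For confidence-interval coverage studies, :func:`generate_replicate_study`
adds between-dilution preparation noise: each dilution's true occupancy is
``lambda_true * (1 + eps)`` with ``eps ~ Normal(0, sigma_prep)``, shared by
all repeats of that dilution.

Not simulated: PCR kinetics, cycle-by-cycle fluorescence accumulation, and
droplet-volume variability (partition volume is treated as constant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dropstat.io import AmplitudeTable

__all__ = ["SyntheticSpec", "ReactionTruth", "generate_reaction", "generate_replicate_study"]

#: rain support sits between mu +/- 4 sigma edges of the two clouds
RAIN_EDGE_SIGMAS = 4.0
#: heavy-tail contamination component is drawn at this multiple of the scale
TAIL_SCALE_FACTOR = 3.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic droplet reaction.

    Attributes
    ----------
    n_droplets : int
        Accepted droplets in the reaction.
    lambda_true : float
        Mean target molecules per droplet (Poisson occupancy rate).
    neg_center, pos_center : float
        Fluorescence centers of the negative and positive clouds (a.u.).
    neg_scale, pos_scale : float
        Core scales of the two clouds (a.u.).
    tail_weight : float
        Share of each cloud drawn at ``TAIL_SCALE_FACTOR`` times its scale;
        0 gives Gaussian clouds (kurtosis 3), larger values raise kurtosis.
    rain_fraction : float
        Probability that an *occupied* droplet reads out as rain, uniform
        over the gap between the cloud edges.
    extra_population : tuple or None
        Optional ``(center, scale, weight)`` third population of occupied
        droplets (emulating a co-amplified product).
    sigma_prep : float
        Coefficient of variation of between-dilution preparation noise on
        ``lambda_true`` (used by :func:`generate_replicate_study`).
    seed : int
        Root seed; the same spec always yields bit-identical output.
    """

    n_droplets: int = 20000
    lambda_true: float = 0.7
    neg_center: float = 1000.0
    pos_center: float = 5000.0
    neg_scale: float = 100.0
    pos_scale: float = 150.0
    tail_weight: float = 0.0
    rain_fraction: float = 0.0
    extra_population: tuple[float, float, float] | None = None
    sigma_prep: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.lambda_true < 0:
            raise ValueError("lambda_true must be >= 0")
        if self.pos_center <= self.neg_center:
            raise ValueError("pos_center must exceed neg_center")
        if self.neg_scale <= 0 or self.pos_scale <= 0:
            raise ValueError("scales must be positive")
        if not 0 <= self.tail_weight < 1:
            raise ValueError("tail_weight must be in [0, 1)")
        if not 0 <= self.rain_fraction < 1:
            raise ValueError("rain_fraction must be in [0, 1)")
        extra_weight = self.extra_population[2] if self.extra_population else 0.0
        if extra_weight < 0 or self.rain_fraction + extra_weight >= 1:
            raise ValueError("rain_fraction + extra population weight must be < 1")
        if self.extra_population is not None and self.extra_population[1] <= 0:
            raise ValueError("extra population scale must be positive")
        if self.sigma_prep < 0:
            raise ValueError("sigma_prep must be >= 0")

    @property
    def rain_support(self) -> tuple[float, float]:
        lo = self.neg_center + RAIN_EDGE_SIGMAS * self.neg_scale
        hi = self.pos_center - RAIN_EDGE_SIGMAS * self.pos_scale
        if hi <= lo:
            raise ValueError("clouds too close for a rain gap (4-sigma edges overlap)")
        return lo, hi


@dataclass
class ReactionTruth:
    """Ground truth accompanying one synthetic reaction."""

    labels: np.ndarray  # per-droplet {"negative", "positive", "rain", "extra"}
    occupancy: np.ndarray  # per-droplet target molecule count
    lambda_true: float

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.occupancy))

    def counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def _draw_population(
    rng: np.random.Generator, n: int, center: float, scale: float, tail_weight: float
) -> np.ndarray:
    """Normal scale mixture: ``tail_weight`` share at 3x scale raises kurtosis."""
    scales = np.full(n, scale)
    if tail_weight > 0:
        heavy = rng.random(n) < tail_weight
        scales[heavy] *= TAIL_SCALE_FACTOR
    return center + scales * rng.standard_normal(n)


def generate_reaction(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[AmplitudeTable, ReactionTruth]:
    """Generate one reaction's amplitude table and its ground truth.

    Occupancy is ``Poisson(lambda_true)`` per droplet.  Occupied droplets
    read out as rain with probability ``rain_fraction`` (uniform over the
    gap between the cloud edges), as the extra population with its declared
    weight, and otherwise from the positive cloud.  Empty droplets read out
    from the negative cloud.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_droplets
    occupancy = rng.poisson(spec.lambda_true, size=n)
    occupied = occupancy > 0

    labels = np.full(n, "negative", dtype=object)
    amplitudes = np.empty(n)

    n_empty = int(n - occupied.sum())
    amplitudes[~occupied] = _draw_population(
        rng, n_empty, spec.neg_center, spec.neg_scale, spec.tail_weight
    )

    # fate of occupied droplets: rain / extra population / positive cloud
    n_occ = int(occupied.sum())
    fate = rng.random(n_occ)
    extra_weight = spec.extra_population[2] if spec.extra_population else 0.0
    is_rain = fate < spec.rain_fraction
    is_extra = (fate >= spec.rain_fraction) & (fate < spec.rain_fraction + extra_weight)
    is_pos = ~(is_rain | is_extra)

    occ_amp = np.empty(n_occ)
    if is_rain.any():
        lo, hi = spec.rain_support
        occ_amp[is_rain] = rng.uniform(lo, hi, size=int(is_rain.sum()))
    if is_extra.any():
        center, scale, _ = spec.extra_population
        occ_amp[is_extra] = _draw_population(
            rng, int(is_extra.sum()), center, scale, spec.tail_weight
        )
    if is_pos.any():
        occ_amp[is_pos] = _draw_population(
            rng, int(is_pos.sum()), spec.pos_center, spec.pos_scale, spec.tail_weight
        )
    amplitudes[occupied] = occ_amp

    occ_labels = np.full(n_occ, "positive", dtype=object)
    occ_labels[is_rain] = "rain"
    occ_labels[is_extra] = "extra"
    labels[occupied] = occ_labels

    table = AmplitudeTable(
        well_id=f"synth-{spec.seed}", channel="Ch1", amplitudes=amplitudes
    )
    truth = ReactionTruth(
        labels=np.asarray(labels), occupancy=occupancy, lambda_true=spec.lambda_true
    )
    return table, truth


@dataclass
class ReplicateStudy:
    """Nested dilution x repeat layout with per-dilution true occupancy."""

    reactions: list[list[tuple[AmplitudeTable, ReactionTruth]]]
    dilution_lambdas: np.ndarray
    base_spec: SyntheticSpec = field(repr=False, default=None)

    @property
    def n_dilutions(self) -> int:
        return len(self.reactions)

    @property
    def n_reactions(self) -> int:
        return sum(len(group) for group in self.reactions)


def generate_replicate_study(
    base_spec: SyntheticSpec,
    n_dilutions: int,
    repeats_per_dilution: int,
    seed: int | None = None,
) -> ReplicateStudy:
    """Generate a dilution-series study for CI-coverage work.

    Each dilution's occupancy is ``lambda_true * (1 + eps)`` with
    ``eps ~ Normal(0, sigma_prep)`` truncated at zero (a physical rate
    cannot be negative).  Each of the ``repeats_per_dilution`` reactions
    within a dilution is a separately pipetted reaction mix, so it carries
    one further independent ``(1 + eps)`` preparation factor on top of the
    dilution's occupancy — without it, repeat-to-repeat spread would
    reflect partition sampling alone and replicate-based intervals could
    never see the preparation variance they exist to capture.  A single
    root seed is expanded into
    independent per-reaction streams, so the study is reproducible and
    individual reactions can be regenerated in any order.
    """
    if n_dilutions < 1 or repeats_per_dilution < 1:
        raise ValueError("n_dilutions and repeats_per_dilution must be >= 1")
    root_seed = base_spec.seed if seed is None else seed
    root = np.random.SeedSequence(root_seed)
    noise_stream, reaction_stream = root.spawn(2)
    noise_rng = np.random.default_rng(noise_stream)
    eps = noise_rng.normal(0.0, base_spec.sigma_prep, size=n_dilutions)
    dilution_lambdas = np.maximum(base_spec.lambda_true * (1.0 + eps), 0.0)

    reaction_seeds = reaction_stream.spawn(n_dilutions * repeats_per_dilution)
    reactions: list[list[tuple[AmplitudeTable, ReactionTruth]]] = []
    for d in range(n_dilutions):
        group = []
        for r in range(repeats_per_dilution):
            rng = np.random.default_rng(reaction_seeds[d * repeats_per_dilution + r])
            lam_repeat = float(
                max(
                    dilution_lambdas[d]
                    * (1.0 + rng.normal(0.0, base_spec.sigma_prep)),
                    0.0,
                )
            )
            spec_d = SyntheticSpec(
                **{
                    **base_spec.__dict__,
                    "lambda_true": lam_repeat,
                }
            )
            table, truth = generate_reaction(spec_d, rng=rng)
            table.well_id = f"synth-d{d:02d}-r{r}"
            group.append((table, truth))
        reactions.append(group)
    return ReplicateStudy(
        reactions=reactions, dilution_lambdas=dilution_lambdas, base_spec=base_spec
    )
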