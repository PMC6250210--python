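"""Demographic model for the three-population admixture simulations.

The model describes two recently diverged ingroup populations (``I1``,
``I2``) and an outgroup (``O``) with topology ``((I1, I2), O)``.  All times
are expressed in coalescent units of 4N generations (ms convention: a pair
of lineages within a population of relative size 1 coalesces at rate 2 per
time unit).  Gene flow is modelled exclusively as instantaneous admixture
pulses: at a pulse time, looking backwards in time, each lineage currently
in the recipient population independently traces its ancestry to the donor
population with probability ``fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "AdmixturePulse",
    "DemographicModel",
    "ConfigurationError",
    "make_pulse_schedule",
    "SINGLE_PULSE_TIME",
    "FIVE_PULSE_TIMES",
]

#: Default pulse time for a single en-masse admixture event (4N units).
SINGLE_PULSE_TIME = 0.01

#: Pulse times used when total admixture is spread over five breakdowns in
#: assortative mating.
FIVE_PULSE_TIMES = (0.01, 0.008, 0.006, 0.004, 0.002)


class ConfigurationError(ValueError):
    """Raised when a demographic model or pulse schedule is inconsistent."""


@dataclass(frozen=True)
class AdmixturePulse:
    """One instantaneous admixture event.

    ``source_population`` is the donor and ``dest_population`` the recipient,
    both viewed forwards in time.  Backwards in time, each lineage in
    ``dest_population`` at ``time`` relabels to ``source_population`` with
    probability ``fraction``.
    """

    time: float
    source_population: str
    dest_population: str
    fraction: float

    def validate(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError(
                f"pulse fraction must be in [0, 1], got {self.fraction}"
            )
        if self.source_population == self.dest_population:
            raise ConfigurationError("pulse source and dest must differ")
        if self.time <= 0:
            raise ConfigurationError(f"pulse time must be > 0, got {self.time}")


@dataclass(frozen=True)
class DemographicModel:
    """Single source of truth for one simulation run.

    Parameters
    ----------
    population_labels
        Three labels with fixed roles ``(I1, I2, O)``.
    samples_per_population
        Haploid samples drawn from each population (default 8, 24 total).
    split_time_ingroups, split_time_root
        Divergence of (I1, I2) and of the root, in units of 4N generations.
    pulses
        Admixture pulses; all must pre-date the ingroup split.
    recombination_rate
        Population-scaled recombination rate 4Nr per base pair.
    chromosome_length
        Simulated chromosome length in base pairs.
    branch_scale
        Expected substitutions per site per coalescent time unit, the
        branch-scaling factor applied before sequence evolution.
    hky_kappa, base_frequencies
        HKY85 substitution-model parameters (frequencies in A, C, G, T
        order).
    """

    population_labels: tuple[str, str, str] = ("I1", "I2", "O")
    samples_per_population: int = 8
    split_time_ingroups: float = 0.4
    split_time_root: float = 1.5
    pulses: tuple[AdmixturePulse, ...] = ()
    recombination_rate: float = 0.001
    chromosome_length: int = 25_000_000
    branch_scale: float = 0.01
    hky_kappa: float = 2.0
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- roles ---------------------------------------------------------
    @property
    def ingroup1(self) -> str:
        return self.population_labels[0]

    @property
    def ingroup2(self) -> str:
        return self.population_labels[1]

    @property
    def outgroup(self) -> str:
        return self.population_labels[2]

    @property
    def n_samples(self) -> int:
        return 3 * self.samples_per_population

    def sample_names(self) -> list[str]:
        """Tip names ``<pop>_<index>``, grouped by population."""
        return [
            f"{pop}_{i}"
            for pop in self.population_labels
            for i in range(self.samples_per_population)
        ]

    def sample_populations(self) -> list[str]:
        return [
            pop
            for pop in self.population_labels
            for _ in range(self.samples_per_population)
        ]

    def validate(self) -> None:
        if len(set(self.population_labels)) != 3:
            raise ConfigurationError("three distinct population labels required")
        if self.samples_per_population < 1:
            raise ConfigurationError("samples_per_population must be >= 1")
        if not 0 < self.split_time_ingroups < self.split_time_root:
            raise ConfigurationError(
                "need 0 < split_time_ingroups < split_time_root, got "
                f"{self.split_time_ingroups} and {self.split_time_root}"
            )
        if self.recombination_rate < 0:
            raise ConfigurationError("recombination_rate must be >= 0")
        if self.chromosome_length < 1:
            raise ConfigurationError("chromosome_length must be >= 1")
        if self.branch_scale < 0:
            raise ConfigurationError("branch_scale must be >= 0")
        if self.hky_kappa <= 0:
            raise ConfigurationError("hky_kappa must be > 0")
        if len(self.base_frequencies) != 4 or any(
            f < 0 for f in self.base_frequencies
        ):
            raise ConfigurationError("base_frequencies must be four probabilities")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-12:
            raise ConfigurationError("base_frequencies must sum to 1 within 1e-12")
        labels = set(self.population_labels)
        for pulse in self.pulses:
            pulse.validate()
            if pulse.source_population not in labels or (
                pulse.dest_population not in labels
            ):
                raise ConfigurationError(
                    f"pulse references unknown population: {pulse}"
                )
            if pulse.time >= self.split_time_ingroups:
                raise ConfigurationError(
                    "pulse at time "
                    f"{pulse.time} is not before the ingroup split "
                    f"({self.split_time_ingroups}); the pulse populations do "
                    "not both exist at that time"
                )

    def with_pulses(self, pulses: Sequence[AdmixturePulse]) -> "DemographicModel":
        return replace(self, pulses=tuple(pulses))

    def with_seed(self, seed: int) -> "DemographicModel":
        return replace(self, seed=seed)


def make_pulse_schedule(
    total_fraction: float,
    mode: str = "single",
    *,
    source: str = "O",
    dest: str = "I2",
    split: str = "compound",
) -> list[AdmixturePulse]:
    """Build the admixture-pulse schedule for a given total admixed fraction.

    ``mode="single"`` places one en-masse pulse at 0.01 x 4N generations with
    the full ``total_fraction``.  ``mode="five_event"`` spreads the same
    cumulative ancestry over five pulses at 0.01, 0.008, 0.006, 0.004 and
    0.002; with ``split="compound"`` each pulse has per-event fraction
    ``q = 1 - (1 - total_fraction)**(1/5)`` so that the compounded admixed
    ancestry equals ``total_fraction`` exactly; ``split="equal"`` uses
    ``total_fraction / 5`` per event instead.
    """
    if not 0.0 <= total_fraction < 1.0:
        raise ConfigurationError(
            f"total_fraction must be in [0, 1), got {total_fraction}"
        )
    if mode == "single":
        return [
            AdmixturePulse(SINGLE_PULSE_TIME, source, dest, total_fraction)
        ]
    if mode == "five_event":
        if split == "compound":
            q = 1.0 - (1.0 - total_fraction) ** 0.2
        elif split == "equal":
            q = total_fraction / 5.0
        else:
            raise ConfigurationError(f"unknown split mode {split!r}")
        return [
            AdmixturePulse(t, source, dest, q) for t in FIVE_PULSE_TIMES
        ]
    raise ConfigurationError(f"unknown pulse schedule mode {mode!r}")
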