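"""Parameter bundles and validation.

All rates are per haploid genome per generation; map positions and the total
map length ``R`` are in Morgans; selective advantages are dimensionless
multiplicative effects (an allele with advantage ``s`` multiplies fitness by
``1 + s``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional


class ParameterError(ValueError):
    """Raised when a parameter bundle violates its invariants."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class SimParams:
    """Parameters of the individual-based sweep-interference simulator.

    Attributes
    ----------
    N : int
        Haploid population size (constant through time).
    U : float
        Genomic beneficial mutation rate per genome per generation; new
        mutations arrive as a Poisson(``N * U``) stream each generation.
    R : float
        Total genetic map length in Morgans; crossovers per meiosis are
        Poisson(``R``), uniform on ``[0, R)``.
    s : float, optional
        Selective advantage of every mutation (fixed-effects model).
    s_mean : float, optional
        Mean of an exponential distribution of selective advantages
        (set exactly one of ``s`` / ``s_mean``).
    generations : int
        Number of generations to simulate.
    seed : int
        Seed for the PCG64 generator; runs are bit-reproducible.
    fitness_noise_var : float
        Variance of optional non-heritable per-generation log-fitness noise
        (each individual's fitness is multiplied by ``exp(eps)`` with
        ``eps ~ Normal(0, fitness_noise_var)`` drawn fresh every generation).
    record_trajectories : bool
        Record per-generation copy numbers of every mutation.
    trajectory_stride : int
        Record every ``stride``-th generation to bound memory.
    burn_in : int, optional
        Generations to discard before measuring steady-state quantities.
        Defaults to ``max(1000, ceil(10 / s))``, reported in run metadata.
    marker_position : float, optional
        If set, a neutral multi-allelic marker locus is tracked at this map
        position (used by the painting experiment).
    """

    N: int
    U: float
    R: float
    s: Optional[float] = None
    s_mean: Optional[float] = None
    generations: int = 1000
    seed: int = 0
    fitness_noise_var: float = 0.0
    record_trajectories: bool = False
    trajectory_stride: int = 1
    burn_in: Optional[int] = None
    marker_position: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.N, (int,)) or self.N < 2:
            raise ParameterError("N", "sexual reproduction requires N >= 2")
        if self.U < 0:
            raise ParameterError("U", "mutation rate must be >= 0")
        if self.R <= 0:
            raise ParameterError("R", "map length must be > 0 Morgans")
        if (self.s is None) == (self.s_mean is None):
            raise ParameterError("s", "set exactly one of s (fixed) or s_mean (exponential)")
        if self.s is not None and self.s <= 0:
            raise ParameterError("s", "selective advantage must be > 0")
        if self.s_mean is not None and self.s_mean <= 0:
            raise ParameterError("s_mean", "mean selective advantage must be > 0")
        if self.generations < 1:
            raise ParameterError("generations", "must simulate at least one generation")
        if self.fitness_noise_var < 0:
            raise ParameterError("fitness_noise_var", "variance must be >= 0")
        if self.trajectory_stride < 1:
            raise ParameterError("trajectory_stride", "stride must be >= 1")
        if self.marker_position is not None and not (0 <= self.marker_position < self.R):
            raise ParameterError("marker_position", f"must lie in [0, {self.R})")
        if self.burn_in is not None and self.burn_in < 0:
            raise ParameterError("burn_in", "must be >= 0")

    @property
    def effect_scale(self) -> float:
        """Characteristic selective advantage (s, or the exponential mean)."""
        return self.s if self.s is not None else self.s_mean  # type: ignore[return-value]

    @property
    def default_burn_in(self) -> int:
        if self.burn_in is not None:
            return self.burn_in
        return max(1000, math.ceil(10.0 / self.effect_scale))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(sorted(unknown)[0], "unknown parameter key")
        return cls(**d)


@dataclass
class TheoryInputs:
    """Inputs to the analytic rate calculators.

    ``Z`` is the dimensionless interference constant of the additive
    approximation (1 by default; the kernel numerics give ~1.05).
    ``outcross_rate`` is the fraction of generations in which the population
    outcrosses (1 = obligate sex); ``mating`` selects the unlinked-variance
    reduction exponent.
    """

    N: int
    U: float
    R: float
    s: Optional[float] = None
    s_mean: Optional[float] = None
    Z: float = 1.0
    mating: str = "polygamy"
    outcross_rate: float = 1.0
    p0_convention: str = "diffusion"  # or "2s"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError("N", "need N >= 2")
        if self.U < 0:
            raise ParameterError("U", "mutation rate must be >= 0")
        if self.R <= 0:
            raise ParameterError("R", "map length must be > 0")
        if (self.s is None) == (self.s_mean is None):
            raise ParameterError("s", "set exactly one of s or s_mean")
        if (self.s is not None and self.s <= 0) or (self.s_mean is not None and self.s_mean <= 0):
            raise ParameterError("s", "selective advantage must be > 0")
        if self.Z <= 0:
            raise ParameterError("Z", "interference constant must be > 0")
        if self.mating not in ("polygamy", "monogamy"):
            raise ParameterError("mating", "must be 'polygamy' or 'monogamy'")
        if not (0 < self.outcross_rate <= 1):
            raise ParameterError("outcross_rate", "must be in (0, 1]")
        if self.p0_convention not in ("diffusion", "2s"):
            raise ParameterError("p0_convention", "must be 'diffusion' or '2s'")

    @property
    def effect_scale(self) -> float:
        return self.s if self.s is not None else self.s_mean  # type: ignore[return-value]

    def replace(self, **kw) -> "TheoryInputs":
        return dataclasses.replace(self, **kw)
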