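"""Summary statistics of simulation output.

The central quantity is the *density of sweeps* Lambda: adaptive
substitutions per Morgan per generation.  Its no-interference baseline is
``Lambda0 = N U p0 / R`` (p0 the single-locus fixation probability), and the
ratio ``Lambda / Lambda0`` measures the strength of Hill-Robertson
interference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tsa.stattools import acf

from .sim import MutationRecord, PopulationState, SimOutput

__all__ = [
    "SweepTrajectory",
    "RateSummary",
    "substitution_density",
    "fixation_probability",
    "log_fitness_stats",
    "sojourn_time",
    "rate_autocorrelation",
    "trajectories_from_output",
    "rate_summary",
]


@dataclass
class SweepTrajectory:
    """Per-generation frequency series of one mutation."""

    mutation_id: int
    generations: np.ndarray
    frequencies: np.ndarray
    s: float
    fate: str

    def __post_init__(self) -> None:
        f = self.frequencies
        assert np.all((f >= 0) & (f <= 1)), "frequencies must lie in [0, 1]"

    @property
    def resolved(self) -> bool:
        return self.fate in ("fixed", "lost")


@dataclass
class RateSummary:
    Lambda: float
    Lambda0: float
    p_fix: float
    p_fix_ci: Tuple[float, float]
    n_fixed: int
    n_mutations: int
    window: Tuple[int, int]
    sigma2: float


def substitution_density(
    fixations: Iterable[MutationRecord], window: Tuple[int, int], R: float
) -> float:
    """Substitutions per Morgan per generation in a generation window.

    ``window`` is half-open ``[t0, t1)`` in generations.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must be a non-empty generation span")
    if R <= 0:
        raise ValueError("map length must be positive")
    n = sum(1 for m in fixations if m.t_fate is not None and t0 <= m.t_fate < t1)
    return n / ((t1 - t0) * R)


def fixation_probability(
    n_fixed: int, n_mutations: int, alpha: float = 0.05
) -> Tuple[float, Tuple[float, float]]:
    """Fixation-probability estimate with an exact (Clopper-Pearson) CI."""
    if n_mutations <= 0:
        raise ValueError("need at least one resolved mutation")
    if n_fixed > n_mutations or n_fixed < 0:
        raise ValueError("fixed count must lie in [0, n_mutations]")
    lo, hi = proportion_confint(n_fixed, n_mutations, alpha=alpha, method="beta")
    return n_fixed / n_mutations, (float(lo), float(hi))


def log_fitness_stats(state: PopulationState) -> Tuple[float, float]:
    """Mean and heritable variance of log fitness (noise excluded)."""
    lw = state.heritable_log_fitness()
    return float(lw.mean()), float(lw.var())


def sojourn_time(traj: SweepTrajectory, f_lo: float = 0.1, f_hi: float = 0.9) -> Optional[float]:
    """Generations between the last up-crossing of ``f_lo`` and the first
    subsequent crossing of ``f_hi``.

    The last up-crossing ignores early stochastic dips below ``f_lo``; lost
    mutations return ``None``.
    """
    if not (0 <= f_lo < f_hi <= 1):
        raise ValueError("need 0 <= f_lo < f_hi <= 1")
    if not traj.resolved:
        raise ValueError("trajectory not resolved (mutation still segregating)")
    if traj.fate == "lost":
        return None
    f, g = traj.frequencies, traj.generations
    above_lo = f >= f_lo
    # last index where the series rises through f_lo
    rises = np.flatnonzero(above_lo[1:] & ~above_lo[:-1]) + 1
    if above_lo[0]:
        rises = np.concatenate([[0], rises])
    if rises.size == 0:
        raise ValueError("trajectory never crosses f_lo despite fixing; recording too sparse")
    t_lo = rises[-1]
    after = np.flatnonzero(f[t_lo:] >= f_hi)
    if after.size == 0:
        raise ValueError("trajectory never crosses f_hi despite fixing; recording too sparse")
    return float(g[t_lo + after[0]] - g[t_lo])


def rate_autocorrelation(series: Sequence[float], max_lag: int) -> np.ndarray:
    """Normalized autocorrelation of a per-generation series up to ``max_lag``.

    Used on the increments of mean log fitness: under strong interference the
    rate of adaptation is negatively autocorrelated on the timescale over
    which new alleles reach interfering frequencies.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= max_lag:
        raise ValueError("series shorter than max_lag")
    if x.var() == 0:
        raise ValueError("zero-variance series has no autocorrelation")
    return acf(x, nlags=max_lag, fft=True)


def trajectories_from_output(out: SimOutput) -> List[SweepTrajectory]:
    """Assemble :class:`SweepTrajectory` objects from a recorded run."""
    res: List[SweepTrajectory] = []
    N = out.params.N
    for mid, counts in out.trajectories.items():
        rec = out.final_state.registry[mid] if out.final_state is not None else None
        rec = rec or _find_record(out, mid)
        t0 = out.trajectory_t0[mid]
        gens = t0 + out.params.trajectory_stride * np.arange(len(counts))
        freqs = np.asarray(counts, dtype=float) / N
        fate = rec.fate if rec is not None else "segregating"
        if fate == "fixed" and freqs[-1] < 1.0:
            gens = np.append(gens, rec.t_fate)
            freqs = np.append(freqs, 1.0)
        s = rec.s if rec is not None else float("nan")
        res.append(SweepTrajectory(mid, gens, freqs, s, fate))
    return res


def _find_record(out: SimOutput, mid: int) -> Optional[MutationRecord]:
    for rec in out.fixations + out.losses:
        if rec.id == mid:
            return rec
    return None


def rate_summary(out: SimOutput, window: Optional[Tuple[int, int]] = None) -> RateSummary:
    """Steady-state rate summary of a run (post burn-in by default).

    The fixation-probability denominator counts only mutations that both
    originated in the window and were resolved by the end of the run
    (right-censoring of still-segregating mutations).
    """
    params = out.params
    if window is None:
        window = (out.burn_in, int(out.generations[-1]) + 1)
    Lam = substitution_density(out.fixations, window, params.R)
    t0, t1 = window
    in_win = [m for m in out.all_resolved if t0 <= m.t_origin < t1]
    n_fixed = sum(1 for m in in_win if m.fate == "fixed")
    n_tot = len(in_win)
    if n_tot > 0:
        p_fix, ci = fixation_probability(n_fixed, n_tot)
    else:
        p_fix, ci = float("nan"), (float("nan"), float("nan"))
    mask = (out.generations >= t0) & (out.generations < t1)
    sigma2 = float(out.var_log_fitness[mask].mean()) if mask.any() else float("nan")
    from .theory import pfix_diffusion

    p0 = pfix_diffusion(params.N, params.effect_scale)
    Lambda0 = params.N * params.U * p0 / params.R
    return RateSummary(
        Lambda=Lam,
        Lambda0=Lambda0,
        p_fix=p_fix,
        p_fix_ci=ci,
        n_fixed=n_fixed,
        n_mutations=n_tot,
        window=window,
        sigma2=sigma2,
    )
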