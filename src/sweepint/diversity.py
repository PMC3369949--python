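"""Neutral diversity under recurrent sweeps: the painting experiment.

Every individual is "painted" with a unique neutral marker allele at one map
position; the marker is inherited through recombination like any locus but
contributes nothing to fitness.  The decay of marker heterozygosity
``H_t = 1 - sum_i p_i(t)^2`` measures the pairwise rate of coalescence: under
pure drift ``H`` decays by a factor ``(1 - 1/N)`` per generation, while
linked sweeps (genetic draft) accelerate the long-term decay, so the fitted
late-time timescale ``T2`` falls below ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .params import SimParams
from .sim import PopulationState, SimOutput, init_population, run_simulation

__all__ = [
    "HeterozygosityTrace",
    "paint_markers",
    "heterozygosity",
    "estimate_T2",
    "T2Fit",
    "run_painting_experiment",
]


@dataclass
class HeterozygosityTrace:
    """Heterozygosity series from one painted replicate."""

    generations: np.ndarray
    H: np.ndarray
    paint_generation: int
    marker_position: float
    N: int

    def __post_init__(self) -> None:
        assert np.all((self.H >= 0) & (self.H <= 1 - 1 / self.N + 1e-12))


def paint_markers(state: PopulationState, position: float) -> PopulationState:
    """Give each of the N individuals a distinct neutral marker allele."""
    if not (0 <= position < state.params.R):
        raise ValueError(f"marker position must lie in [0, {state.params.R})")
    state.marker = np.arange(state.N, dtype=np.int64)
    state.marker_position = position
    return state


def heterozygosity(freqs: Sequence[float]) -> float:
    """H = 1 - sum p_i^2 for a normalized allele-frequency vector."""
    p = np.asarray(freqs, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("frequencies must be non-negative and sum to 1")
    return float(1.0 - np.sum(p**2))


@dataclass
class T2Fit:
    T2: float
    rate: float
    rate_se: float
    fit_start: int
    n_replicates: int


def _late_window_start(logH: np.ndarray, window: int, slope_tol: float) -> int:
    """First index where the rolling log-linear slope has stabilized.

    Slides a regression window along log H and returns the start of the first
    window whose slope differs from the next window's by less than
    ``slope_tol`` (relative).  Falls back to the midpoint of the series.
    """
    n = len(logH)
    if n < 3 * window:
        return n // 2
    t = np.arange(n)
    starts = range(0, n - 2 * window, max(window // 4, 1))
    prev = None
    for s0 in starts:
        sl = np.polyfit(t[s0 : s0 + window], logH[s0 : s0 + window], 1)[0]
        nxt = np.polyfit(t[s0 + window : s0 + 2 * window], logH[s0 + window : s0 + 2 * window], 1)[0]
        if prev is not None and sl < 0 and nxt < 0 and abs(nxt - sl) < slope_tol * abs(sl):
            return s0
        prev = sl
    return n // 2


def estimate_T2(
    traces: Sequence[HeterozygosityTrace],
    window: Optional[int] = None,
    slope_tol: float = 0.05,
    min_H: float = 1e-3,
    n_bootstrap: int = 200,
    bootstrap_seed: int = 0,
) -> T2Fit:
    """Pairwise coalescence time from the late-time decay of heterozygosity.

    Heterozygosity is first averaged over replicates at each generation
    (replicates whose diversity is already lost contribute zero), because
    the *expected* heterozygosity decays exactly at the pairwise coalescence
    rate, whereas the log of a single stochastic trace decays faster by a
    Jensen term of the same order.  ``log H-bar`` is then fitted on its
    late-time log-linear window, whose start is chosen where a rolling
    regression slope stabilizes (slope change below ``slope_tol``),
    accommodating the initial slower decay before draft takes over.  The
    standard error of the rate comes from bootstrap resampling of
    replicates.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    length = max(len(tr.H) for tr in traces)
    padded = np.zeros((len(traces), length))
    for i, tr in enumerate(traces):
        padded[i, : len(tr.H)] = tr.H  # after loss of diversity H stays 0
    gens = np.arange(1, length + 1)

    def fit_rate(H_mean: np.ndarray) -> Tuple[float, int]:
        keep = H_mean > min_H
        H, g = H_mean[keep], gens[keep]
        if len(H) < 10:
            raise ValueError(
                "trace too short for a stable fit (fewer than 10 usable points); "
                "run longer or lower min_H"
            )
        logH = np.log(H)
        w = window if window is not None else max(10, len(H) // 10)
        s0 = _late_window_start(logH, w, slope_tol)
        slope = np.polyfit(g[s0:], logH[s0:], 1)[0]
        if slope >= 0:
            raise ValueError("non-decaying heterozygosity in fit window; diagnostic: slope >= 0")
        return -slope, int(g[s0])

    rate, fit_start = fit_rate(padded.mean(axis=0))
    rng = np.random.default_rng(bootstrap_seed)
    boot = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(traces), size=len(traces))
        try:
            boot.append(fit_rate(padded[idx].mean(axis=0))[0])
        except ValueError:
            continue
    rate_se = float(np.std(boot)) if len(boot) > 10 else float("nan")
    return T2Fit(
        T2=float(1.0 / rate),
        rate=float(rate),
        rate_se=rate_se,
        fit_start=fit_start,
        n_replicates=len(traces),
    )


def run_painting_experiment(
    params: SimParams,
    n_replicates: int = 100,
    equilibration: int = 1000,
    horizon: Optional[int] = None,
    marker_position: Optional[float] = None,
) -> Tuple[List[HeterozygosityTrace], Optional[T2Fit]]:
    """Paint-and-decay experiment averaged over replicates.

    Each replicate evolves for ``equilibration`` generations to approach a
    steady rate of adaptation, is painted at a locus in the middle of the
    chromosome (default ``R/2``), and then runs until all marker diversity is
    lost (or ``horizon`` generations, default ``20 N``).
    """
    pos = marker_position if marker_position is not None else params.R / 2
    horizon = horizon if horizon is not None else 20 * params.N
    traces: List[HeterozygosityTrace] = []
    for rep in range(n_replicates):
        p_eq = SimParams(
            **{**params.to_dict(), "seed": params.seed + rep, "generations": max(equilibration, 1)}
        )
        state = init_population(p_eq)
        if equilibration > 0:
            run_simulation(p_eq, state=state, keep_state=True)
        paint_markers(state, pos)
        paint_gen = state.generation
        p_run = SimParams(**{**params.to_dict(), "seed": params.seed + rep, "generations": horizon})
        state.params = p_run
        H_list = []
        gens = []
        from .sim import step_generation

        for _ in range(horizon):
            step_generation(state)
            freqs = np.bincount(state.marker, minlength=state.N) / state.N
            H = 1.0 - float(np.sum(freqs**2))
            gens.append(state.generation - paint_gen)
            H_list.append(H)
            if H == 0.0:
                break
        traces.append(
            HeterozygosityTrace(
                generations=np.asarray(gens),
                H=np.asarray(H_list),
                paint_generation=paint_gen,
                marker_position=pos,
                N=params.N,
            )
        )
    try:
        fit = estimate_T2(traces)
    except ValueError:
        # horizon too short for a stable fit; traces are still useful
        fit = None
    return traces, fit
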