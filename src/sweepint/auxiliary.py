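"""Two simplified dynamics with closed-form counterparts.

*Complete recombination* ("mass meiosis"): every offspring draws each locus
independently from a fitness-weighted common pool, so linkage disequilibrium
is identically zero and the realized rate of adaptation solves
``v = v0 e^{-v}`` (product log).

*Infinitesimal model*: the focal mutation rides a quantitative background of
log fitness ``z`` with stationary variance ``sigma^2``; offspring are normal
about the mid-parent value with segregation variance ``sigma^2 / 2``.  The
branching simulation measures the fixation probability of a founder with
background ``z0`` under polygamous or monogamous mating; in both models
``p(z0)`` is proportional to the *square* of the founder's fitness, and the
``z0``-averaged probability is reduced by ``exp(-alpha sigma^2)`` relative to
``2s`` (``alpha = 4`` polygamy, ``alpha = 8`` monogamy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .params import ParameterError, SimParams
from .sim import PopulationState, SimOutput, DegenerateStateError, init_population

__all__ = [
    "InfinitesimalParams",
    "run_complete_recombination",
    "run_fluctuating_fitness",
    "infinitesimal_pfix",
    "single_locus_fixation_assay",
]


def _complete_recombination_step(state: PopulationState, resolved: Optional[list] = None) -> None:
    """One generation of the mass-meiosis model.

    Selection acts through fitness-weighted allele frequencies; every
    offspring then samples each locus independently at that frequency, so no
    linkage disequilibrium is ever generated.
    """
    params, rng = state.params, state.rng
    N, M = state.genotypes.shape
    G = state.genotypes
    logw = G @ np.log1p(state.s_values)
    if params.fitness_noise_var > 0:
        logw = logw + rng.normal(0.0, math.sqrt(params.fitness_noise_var), size=N)
    w = np.exp(logw - logw.max())
    if w.sum() <= 0 or not np.isfinite(w.sum()):
        raise DegenerateStateError("degenerate fitness distribution")
    if M > 0:
        pfreq = (w @ G) / w.sum()
        new_G = rng.random((N, M)) < pfreq
    else:
        new_G = np.zeros((N, 0), dtype=bool)

    n_new = rng.poisson(N * params.U)
    if n_new > 0:
        from .sim import MutationRecord, _draw_effects

        new_pos = rng.uniform(0.0, params.R, size=n_new)
        hosts = rng.integers(0, N, size=n_new)
        new_s = _draw_effects(params, rng, n_new)
        insert_at = np.searchsorted(state.positions, new_pos)
        order = np.argsort(new_pos)
        insert_at, new_pos, hosts, new_s = (
            insert_at[order], new_pos[order], hosts[order], new_s[order],
        )
        cols = np.zeros((N, n_new), dtype=bool)
        cols[hosts, np.arange(n_new)] = True
        new_ids = np.arange(state.next_id, state.next_id + n_new, dtype=np.int64)
        state.next_id += n_new
        new_G = np.insert(new_G, insert_at, cols, axis=1)
        state.positions = np.insert(state.positions, insert_at, new_pos)
        state.s_values = np.insert(state.s_values, insert_at, new_s)
        state.col_ids = np.insert(state.col_ids, insert_at, new_ids)
        for mid, p, sv in zip(new_ids, new_pos, new_s):
            state.registry[int(mid)] = MutationRecord(
                id=int(mid), position=float(p), s=float(sv), t_origin=state.generation + 1
            )

    state.generation += 1
    counts = new_G.sum(axis=0)
    fixed = counts == N
    lost = counts == 0
    for j in np.flatnonzero(fixed | lost):
        rec = state.registry[int(state.col_ids[j])]
        rec.count = int(counts[j])
        rec.fate = "fixed" if fixed[j] else "lost"
        rec.t_fate = state.generation
        if fixed[j]:
            state.fixed_log_fitness += np.log1p(rec.s)
        if resolved is not None:
            resolved.append(rec)
    keep = ~(fixed | lost)
    state.genotypes = new_G[:, keep]
    state.positions = state.positions[keep]
    state.s_values = state.s_values[keep]
    state.col_ids = state.col_ids[keep]
    counts = counts[keep]
    for j, mid in enumerate(state.col_ids):
        state.registry[int(mid)].count = int(counts[j])


def run_complete_recombination(params: SimParams) -> SimOutput:
    """Run the complete-recombination model; same outputs as the full sim."""
    state = init_population(params)
    resolved: list = []
    mean_lw = np.empty(params.generations)
    var_lw = np.empty(params.generations)
    n_seg = np.empty(params.generations, dtype=int)
    for t in range(params.generations):
        _complete_recombination_step(state, resolved)
        lw = state.heritable_log_fitness()
        mean_lw[t] = lw.mean()
        var_lw[t] = lw.var()
        n_seg[t] = state.n_segregating
    return SimOutput(
        params=params,
        burn_in=params.default_burn_in,
        fixations=[r for r in resolved if r.fate == "fixed"],
        losses=[r for r in resolved if r.fate == "lost"],
        generations=np.arange(1, params.generations + 1),
        mean_log_fitness=mean_lw,
        var_log_fitness=var_lw,
        n_segregating=n_seg,
        final_state=state,
    )


def run_fluctuating_fitness(params: SimParams) -> SimOutput:
    """Full linear-map dynamics with iid non-heritable log-fitness noise.

    Uncorrelated fitness fluctuations of variance ``v_n`` increase the
    variance in offspring number by a factor ``e^{v_n}`` and reduce every
    allele's fixation probability by the same factor.
    """
    if params.fitness_noise_var <= 0:
        raise ParameterError("fitness_noise_var", "must be > 0 for the fluctuating-fitness model")
    from .sim import run_simulation

    return run_simulation(params)


def single_locus_fixation_assay(
    base: SimParams, n_introductions: int, rng: Optional[np.random.Generator] = None
) -> Tuple[float, int]:
    """Monte-Carlo fixation probability of a lone beneficial allele.

    Repeatedly introduces a single copy into a wild-type population (U = 0)
    and iterates until it is lost or fixed.  Used as the offspring-number
    -variance oracle for the fluctuating-fitness model.
    """
    from .sim import step_generation

    params = SimParams(**{**base.to_dict(), "U": 0.0})
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n_fixed = 0
    for _ in range(n_introductions):
        state = init_population(params)
        state.rng = rng
        state.genotypes = np.zeros((params.N, 1), dtype=bool)
        state.genotypes[0, 0] = True
        state.positions = np.array([params.R / 2])
        state.s_values = np.array([params.effect_scale])
        state.col_ids = np.array([0], dtype=np.int64)
        from .sim import MutationRecord

        state.registry = {0: MutationRecord(id=0, position=params.R / 2, s=params.effect_scale, t_origin=0)}
        state.next_id = 1
        resolved: list = []
        while not resolved:
            step_generation(state, resolved)
        n_fixed += resolved[0].fate == "fixed"
    return n_fixed / n_introductions, n_fixed


@dataclass
class InfinitesimalParams:
    """Parameters of the infinitesimal-background branching simulation."""

    s: float
    sigma2: float
    mating: str = "polygamy"
    fix_threshold: int = 5000
    max_lineages: int = 10000
    min_fixed: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ParameterError("s", "focal advantage must be > 0")
        if self.sigma2 < 0:
            raise ParameterError("sigma2", "background variance must be >= 0")
        if self.mating not in ("polygamy", "monogamy"):
            raise ParameterError("mating", "must be 'polygamy' or 'monogamy'")
        if self.fix_threshold * self.s < 10:
            raise ParameterError(
                "fix_threshold",
                f"threshold {self.fix_threshold} too small relative to 1/s = {1/self.s:.0f}; "
                "lineages could still be lost after being declared fixed",
            )


def infinitesimal_pfix(
    z0: float | np.ndarray,
    params: InfinitesimalParams,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, float]:
    """Fixation probability of a focal mutation by branching simulation.

    The founder carries advantage ``s`` on background log fitness ``z0``
    (deviation from the population mean).  Each generation, every carrier
    with background ``z`` leaves a Poisson number of mutant offspring with
    mean ``(1+s) e^{z}`` normalized by the analytic lognormal mean
    ``e^{sigma^2/2}``; under polygamy each offspring has an independent
    fitness-biased mate (``z' ~ N(sigma^2, sigma^2)``), under monogamy a
    single random mate (``z' ~ N(0, sigma^2)``) is shared by all offspring
    and multiplies their number by ``e^{z'}`` (normalized).  Offspring
    backgrounds are mid-parent plus segregation noise ``N(0, sigma^2/2)``,
    measured relative to the advancing population mean (which moves by
    ``sigma^2`` per generation, keeping the process critical at ``s = 0``).

    A lineage is fixed when it reaches ``fix_threshold`` carriers and lost at
    zero.  Returns the estimate, a binomial standard error and diagnostics.
    """
    p = params
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    sigma = math.sqrt(p.sigma2)
    seg = math.sqrt(p.sigma2 / 2.0)
    z0 = np.atleast_1d(np.asarray(z0, dtype=float))
    n_lineages = p.max_lineages
    # members of all live lineages, concatenated
    founder_z = np.repeat(z0, math.ceil(n_lineages / len(z0)))[:n_lineages]
    lineage_of = np.arange(n_lineages)
    z = founder_z.copy()
    alive = np.ones(n_lineages, dtype=bool)
    fixed = np.zeros(n_lineages, dtype=bool)
    max_generations = 100000
    for _ in range(max_generations):
        if z.size == 0:
            break
        if p.mating == "polygamy":
            mean_off = (1.0 + p.s) * np.exp(z - p.sigma2 / 2.0)
            k = rng.poisson(mean_off)
            parent_idx = np.repeat(np.arange(z.size), k)
            mate = rng.normal(p.sigma2, sigma, size=parent_idx.size)
        else:
            mate_z = rng.normal(0.0, sigma, size=z.size)
            mean_off = (1.0 + p.s) * np.exp(z + mate_z - p.sigma2)
            k = rng.poisson(mean_off)
            parent_idx = np.repeat(np.arange(z.size), k)
            mate = np.repeat(mate_z, k)
        z_new = (z[parent_idx] + mate) / 2.0 + rng.normal(0.0, seg, size=parent_idx.size) - p.sigma2
        lin_new = lineage_of[parent_idx]
        sizes = np.bincount(lin_new, minlength=n_lineages)
        newly_fixed = (sizes >= p.fix_threshold) & alive
        newly_lost = (sizes == 0) & alive
        fixed |= newly_fixed
        alive &= ~(newly_fixed | newly_lost)
        keep = alive[lin_new]
        z, lineage_of = z_new[keep], lin_new[keep]
        if not alive.any():
            break
    n_fixed = int(fixed.sum())
    est = n_fixed / n_lineages
    if n_fixed < p.min_fixed:
        note = "below the requested number of fixed lineages; increase max_lineages"
    else:
        note = "ok"
    return {
        "p_fix": est,
        "se": math.sqrt(max(est * (1 - est), 1e-300) / n_lineages),
        "n_fixed": n_fixed,
        "n_lineages": n_lineages,
        "unresolved": int(alive.sum()),
        "note": note,
    }
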