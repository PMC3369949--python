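"""Individual-based forward simulator of recurrent selective sweeps.

The model: ``N`` haploid individuals, multiplicative beneficial mutations on a
continuous linear map of length ``R`` Morgans (infinite sites: every mutation
has a distinct real-valued position), fitness-proportional polygamous pairing
(both parents of each offspring drawn independently, so selfing is possible),
Poisson(``R``) crossovers per meiosis and a Poisson(``N*U``) stream of new
mutations.  Mutations are tracked as columns of an ``N x M`` presence matrix;
a mutation whose copy number hits ``N`` is folded into a fixed-background log
fitness and removed, one whose copy number hits 0 is discarded.

The same machinery optionally carries a selectively neutral, multi-allelic
marker locus used by the painting experiment (`sweepint.diversity`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .params import ParameterError, SimParams

__all__ = [
    "MutationRecord",
    "Genome",
    "PopulationState",
    "SimOutput",
    "init_population",
    "recombine",
    "crossover_pattern",
    "step_generation",
    "run_simulation",
    "DegenerateStateError",
]


class DegenerateStateError(RuntimeError):
    """All fitnesses are zero; parent sampling is undefined."""


@dataclass
class MutationRecord:
    """One beneficial mutation, shared by every individual that carries it."""

    id: int
    position: float
    s: float
    t_origin: int
    count: int = 1
    fate: str = "segregating"  # segregating | fixed | lost
    t_fate: Optional[int] = None


@dataclass
class Genome:
    """A haploid genome: mutation positions (sorted) and registry ids."""

    positions: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.positions) > 0), "positions must be strictly increasing"


def crossover_pattern(positions: np.ndarray, crossovers: np.ndarray, start: int) -> np.ndarray:
    """Which parent (0 or 1) contributes each locus, given crossover points.

    ``start`` is the parent contributing the leftmost segment; parity flips at
    every crossover.
    """
    flips = np.searchsorted(np.sort(crossovers), positions, side="right")
    return (flips + start) % 2


def recombine(parent_a: Genome, parent_b: Genome, R: float, rng: np.random.Generator) -> Genome:
    """Free meiosis between two genomes: Poisson(R) uniform crossovers.

    The offspring takes alternating parental segments between the sorted
    crossover points, starting from a fair-coin parent.
    """
    k = rng.poisson(R)
    xo = rng.uniform(0.0, R, size=k)
    start = int(rng.integers(0, 2))
    take_a = crossover_pattern(parent_a.positions, xo, start) == 0
    take_b = crossover_pattern(parent_b.positions, xo, start) == 1
    pos = np.concatenate([parent_a.positions[take_a], parent_b.positions[take_b]])
    ids = np.concatenate([parent_a.ids[take_a], parent_b.ids[take_b]])
    order = np.argsort(pos, kind="stable")
    pos, ids = pos[order], ids[order]
    # Infinite-sites continuum: a shared mutation appears in both parents at the
    # exact same position and must not be duplicated in the offspring.
    if pos.size > 1:
        keep = np.empty(pos.size, dtype=bool)
        keep[0] = True
        np.not_equal(ids[1:], ids[:-1], out=keep[1:])
        pos, ids = pos[keep], ids[keep]
    return Genome(pos, ids)


@dataclass
class PopulationState:
    """The population: presence matrix, mutation registry and bookkeeping.

    ``genotypes[i, j]`` is True when individual ``i`` carries the segregating
    mutation in column ``j``; ``positions``/``s_values``/``col_ids`` describe
    the columns (kept sorted by map position).  ``registry`` maps mutation id
    to its :class:`MutationRecord` (segregating, fixed and lost alike).
    """

    params: SimParams
    rng: np.random.Generator
    genotypes: np.ndarray  # (N, M) bool
    positions: np.ndarray  # (M,) float
    s_values: np.ndarray  # (M,) float
    col_ids: np.ndarray  # (M,) int
    registry: Dict[int, MutationRecord] = field(default_factory=dict)
    fixed_log_fitness: float = 0.0
    generation: int = 0
    next_id: int = 0
    marker: Optional[np.ndarray] = None  # (N,) int marker alleles
    marker_position: Optional[float] = None

    @property
    def N(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_segregating(self) -> int:
        return self.genotypes.shape[1]

    def genome(self, i: int) -> Genome:
        carried = self.genotypes[i]
        return Genome(self.positions[carried].copy(), self.col_ids[carried].copy())

    def heritable_log_fitness(self) -> np.ndarray:
        """Per-individual log fitness from segregating + fixed mutations."""
        return self.genotypes @ np.log1p(self.s_values) + self.fixed_log_fitness

    def counts(self) -> np.ndarray:
        return self.genotypes.sum(axis=0)

    def check_consistency(self) -> None:
        counts = self.counts()
        for j, mid in enumerate(self.col_ids):
            rec = self.registry[int(mid)]
            assert rec.fate == "segregating"
            assert rec.count == counts[j], (mid, rec.count, counts[j])
            assert 0 < rec.count < self.N


def init_population(params: SimParams) -> PopulationState:
    """A purely wild-type population of ``N`` empty genomes at generation 0."""
    rng = np.random.default_rng(params.seed)
    N = params.N
    state = PopulationState(
        params=params,
        rng=rng,
        genotypes=np.zeros((N, 0), dtype=bool),
        positions=np.zeros(0, dtype=float),
        s_values=np.zeros(0, dtype=float),
        col_ids=np.zeros(0, dtype=np.int64),
    )
    if params.marker_position is not None:
        from .diversity import paint_markers

        paint_markers(state, params.marker_position)
    return state


def _draw_effects(params: SimParams, rng: np.random.Generator, n: int) -> np.ndarray:
    if params.s is not None:
        return np.full(n, params.s)
    return rng.exponential(params.s_mean, size=n)


def step_generation(state: PopulationState, resolved: Optional[List[MutationRecord]] = None) -> None:
    """Advance the population by one generation, in place.

    Order of events: fitness evaluation (with optional non-heritable noise),
    independent fitness-proportional parent sampling, crossover inheritance,
    Poisson mutation into random newborns, then registry bookkeeping with
    fixed/lost columns removed at the end of the generation.  Resolved
    :class:`MutationRecord` objects are appended to ``resolved`` if given.
    """
    params, rng = state.params, state.rng
    N, M = state.genotypes.shape
    G = state.genotypes

    # (i) relative fitness; fixed factors are shared and cancel
    logw = G @ np.log1p(state.s_values)
    if params.fitness_noise_var > 0:
        logw = logw + rng.normal(0.0, np.sqrt(params.fitness_noise_var), size=N)
    w = np.exp(logw - logw.max())
    cdf = np.cumsum(w)
    if cdf[-1] <= 0 or not np.isfinite(cdf[-1]):
        raise DegenerateStateError("population fitness is degenerate (all zero or non-finite)")

    # (ii) N parent pairs, each parent independent (polygamy; selfing allowed)
    pa = np.searchsorted(cdf, rng.uniform(0.0, cdf[-1], size=N), side="right")
    pb = np.searchsorted(cdf, rng.uniform(0.0, cdf[-1], size=N), side="right")

    # (iii) one offspring per pair via Poisson crossovers
    k = rng.poisson(params.R, size=N)
    total = int(k.sum())
    xo_pos = rng.uniform(0.0, params.R, size=total)
    owner = np.repeat(np.arange(N), k)
    start = rng.integers(0, 2, size=N).astype(np.int64)
    if M > 0:
        flips = np.zeros((N, M + 1), dtype=np.int64)
        bucket = np.searchsorted(state.positions, xo_pos, side="right")
        np.add.at(flips, (owner, bucket), 1)
        parity = (np.cumsum(flips[:, :M], axis=1) + start[:, None]) % 2
        new_G = np.where(parity == 0, G[pa], G[pb])
    else:
        new_G = np.zeros((N, 0), dtype=bool)
    if state.marker is not None:
        below = xo_pos < state.marker_position
        mflips = np.bincount(owner[below], minlength=N)
        take_a = (mflips + start) % 2 == 0
        state.marker = np.where(take_a, state.marker[pa], state.marker[pb])

    # (iv) new mutations: Poisson(N*U), uniform position, random newborn host
    n_new = rng.poisson(N * params.U)
    if n_new > 0:
        new_pos = rng.uniform(0.0, params.R, size=n_new)
        hosts = rng.integers(0, N, size=n_new)
        new_s = _draw_effects(params, rng, n_new)
        assert np.unique(new_pos).size == n_new and not np.isin(new_pos, state.positions).any(), (
            "duplicate map position: probability-zero event on a continuum"
        )
        insert_at = np.searchsorted(state.positions, new_pos)
        order = np.argsort(new_pos)
        insert_at, new_pos, hosts, new_s = (
            insert_at[order],
            new_pos[order],
            hosts[order],
            new_s[order],
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

    # (v) bookkeeping: counts, fates, column removal at end of generation
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


@dataclass
class SimOutput:
    """Results of :func:`run_simulation`."""

    params: SimParams
    burn_in: int
    fixations: List[MutationRecord]
    losses: List[MutationRecord]
    generations: np.ndarray
    mean_log_fitness: np.ndarray
    var_log_fitness: np.ndarray
    n_segregating: np.ndarray
    trajectories: Dict[int, "np.ndarray"] = field(default_factory=dict)
    trajectory_t0: Dict[int, int] = field(default_factory=dict)
    heterozygosity: Optional[np.ndarray] = None
    final_state: Optional[PopulationState] = None

    @property
    def all_resolved(self) -> List[MutationRecord]:
        return self.fixations + self.losses


def run_simulation(params: SimParams, state: Optional[PopulationState] = None, keep_state: bool = False) -> SimOutput:
    """Run ``params.generations`` steps and collect per-generation summaries.

    An existing ``state`` (e.g. a painted population) may be passed to
    continue a run; otherwise a wild-type population is initialised.
    """
    if state is None:
        state = init_population(params)
    resolved: List[MutationRecord] = []
    gens = np.arange(state.generation + 1, state.generation + params.generations + 1)
    mean_lw = np.empty(params.generations)
    var_lw = np.empty(params.generations)
    n_seg = np.empty(params.generations, dtype=int)
    het = np.empty(params.generations) if state.marker is not None else None
    traj: Dict[int, list] = {}
    traj_t0: Dict[int, int] = {}
    for t in range(params.generations):
        step_generation(state, resolved)
        lw = state.heritable_log_fitness()
        mean_lw[t] = lw.mean()
        var_lw[t] = lw.var()
        n_seg[t] = state.n_segregating
        if het is not None:
            freqs = np.bincount(state.marker, minlength=state.N) / state.N
            het[t] = 1.0 - np.sum(freqs**2)
        if params.record_trajectories and state.generation % params.trajectory_stride == 0:
            counts = state.counts()
            for j, mid in enumerate(state.col_ids):
                key = int(mid)
                if key not in traj:
                    traj[key] = []
                    traj_t0[key] = state.generation
                traj[key].append(int(counts[j]))
    fixations = [r for r in resolved if r.fate == "fixed"]
    losses = [r for r in resolved if r.fate == "lost"]
    return SimOutput(
        params=params,
        burn_in=params.default_burn_in,
        fixations=fixations,
        losses=losses,
        generations=gens,
        mean_log_fitness=mean_lw,
        var_log_fitness=var_lw,
        n_segregating=n_seg,
        trajectories={k: np.asarray(v, dtype=float) for k, v in traj.items()},
        trajectory_t0=traj_t0,
        heterozygosity=het,
        final_state=state if keep_state else None,
    )
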