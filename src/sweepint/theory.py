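"""Closed-form and self-consistent rate calculators.

Notation (per haploid genome per generation unless stated):

* ``p0``        -- no-interference fixation probability of one new mutation.
* ``Lambda0``   -- baseline density of sweeps, ``N U p0 / R`` per Morgan.
* ``Lambda``    -- realized density of sweeps under interference.
* ``v0, v``     -- baseline / realized rate of increase of mean log fitness;
                   at steady state ``v`` equals the heritable variance in log
                   fitness ``sigma^2`` (Fisher's theorem) and
                   ``sigma^2 = Lambda R s``.
* ``Z``         -- dimensionless interference constant of the additive
                   approximation (kernel numerics give ~1.05; 1 by default).

The additive approximation for equal effects reads
``<p>/p0 = 1 - 2 Z Lambda`` which, combined with ``Lambda = Lambda0 <p>/p0``,
gives the explicit density ``Lambda = Lambda0 / (1 + 2 Z Lambda0)`` -- bounded
by ``1/(2Z)``, i.e. at ``Z = 1`` one substitution per centimorgan per 200
generations.  Heritable variance in log fitness at effectively unlinked loci
multiplies fixation probability by ``exp(-alpha sigma^2)``: ``alpha = 1``
for non-inherited (completely re-randomized) variance, ``alpha = 4`` under
polygamy and ``alpha = 8`` under monogamy (see `sweepint.auxiliary`; the
fixation probability of a mutation is proportional to the square of its
founder's fitness, so inherited variance enters through the square of the
cumulative transmission factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import lambertw

from .params import ParameterError, TheoryInputs

__all__ = [
    "TheoryResult",
    "ALPHA_COMPLETE_RECOMBINATION",
    "ALPHA_POLYGAMY",
    "ALPHA_MONOGAMY",
    "pfix_diffusion",
    "baseline",
    "lambertw_rate",
    "additive_density",
    "self_consistent_density",
    "coalescence_time",
    "exp_effects",
    "weak_selection_pfix",
    "facultative_rescale",
    "diffusion_sojourn_stats",
]

# Unlinked-variance reduction exponents: the z0-averaged fixation probability
# is 2s * exp(-alpha * sigma^2).  Complete recombination redraws the genetic
# background every generation (non-inherited variance, alpha = 1).  Under the
# infinitesimal model a founder's background is transmitted with cumulative
# exposure 2 (p(z0) proportional to e^{2 z0}), and second-order branching
# perturbation theory (left eigenvector N(0, sigma^2), eigenfunction e^{2z})
# gives <p> = 2s e^{-4 sigma^2} for polygamy and 2s e^{-8 sigma^2} for
# monogamy (the shared mate adds fully correlated offspring-number and
# offspring-type noise).  The package's branching simulation reproduces both,
# up to higher-order terms in sigma^2 (docs/methods.md).
ALPHA_COMPLETE_RECOMBINATION = 1.0
ALPHA_POLYGAMY = 4.0
ALPHA_MONOGAMY = 8.0


def _alpha(mating: str) -> float:
    return ALPHA_POLYGAMY if mating == "polygamy" else ALPHA_MONOGAMY


@dataclass
class TheoryResult:
    Lambda0: float
    Lambda: float
    p_fix: float
    p0: float
    sigma2: float
    T2: Optional[float] = None
    s_cutoff_strong: Optional[float] = None
    s_cutoff_neutral: Optional[float] = None
    diagnostics: Dict[str, float] = field(default_factory=dict)


def pfix_diffusion(N: int, s: float) -> float:
    """Diffusion fixation probability of a single new mutation.

    Haploid Wright-Fisher with genic selection: ``(1-e^{-2s})/(1-e^{-2Ns})``;
    tends to ``1/N`` as ``s -> 0`` and to ``~2s`` for ``Ns >> 1``, ``s`` small.
    """
    if N < 2:
        raise ParameterError("N", "need N >= 2")
    if s == 0:
        return 1.0 / N
    num = -math.expm1(-2.0 * s)
    den = -math.expm1(-2.0 * N * s) if 2.0 * N * s < 700 else 1.0
    return num / den


def _p0(inputs: TheoryInputs) -> float:
    s = inputs.effect_scale
    if inputs.p0_convention == "2s":
        return 2.0 * s
    return pfix_diffusion(inputs.N, s)


def baseline(inputs: TheoryInputs) -> Tuple[float, float, float]:
    """Baseline quantities ``(p0, Lambda0, v0)`` in the absence of interference.

    ``Lambda0 = N U p0 / R`` per Morgan per generation (the Abstract's
    ``2 N U s`` per genome with the weak-selection ``p0 = 2s``);
    ``v0 = N U p0 s`` per generation.
    """
    p0 = _p0(inputs)
    s = inputs.effect_scale
    Lambda0 = inputs.N * inputs.U * p0 / inputs.R
    v0 = inputs.N * inputs.U * p0 * s
    return p0, Lambda0, v0


def lambertw_rate(v0: float, alpha: float) -> float:
    """Solve the self-consistent rate ``v = v0 * exp(-alpha v)``.

    Closed form via the product log: ``v = W(alpha v0)/alpha``.  The rate
    grows without bound but only logarithmically in ``v0``.
    """
    if v0 < 0:
        raise ValueError("baseline rate must be >= 0")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if v0 == 0:
        return 0.0
    return float(np.real(lambertw(alpha * v0))) / alpha


def additive_density(Lambda0: float, Z: float = 1.0) -> float:
    """Explicit additive-approximation density ``Lambda0/(1 + 2 Z Lambda0)``.

    Monotone increasing in ``Lambda0`` and bounded by the ceiling ``1/(2Z)``
    (0.5 sweeps per Morgan per generation at ``Z = 1``).
    """
    if Lambda0 < 0:
        raise ValueError("baseline density must be >= 0")
    return Lambda0 / (1.0 + 2.0 * Z * Lambda0)


def self_consistent_density(inputs: TheoryInputs) -> TheoryResult:
    """Joint solve for the density of sweeps with linked and unlinked terms.

    Solves ``Lambda = Lambda0 (1 - 2 Z Lambda) exp(-alpha Lambda R s)`` where
    ``sigma^2 = Lambda R s`` is the steady-state variance in log fitness tied
    to the realized substitution rate.  Tight linkage dominates interference
    when ``alpha R s << 2 Z``.
    """
    p0, Lambda0, v0 = baseline(inputs)
    s, R, Z = inputs.effect_scale, inputs.R, inputs.Z
    al = _alpha(inputs.mating)
    if Lambda0 == 0:
        return TheoryResult(0.0, 0.0, p0, p0, 0.0, diagnostics={"residual": 0.0})

    def f(L: float) -> float:
        return Lambda0 * (1.0 - 2.0 * Z * L) * math.exp(-al * L * R * s) - L

    hi = min(Lambda0, 1.0 / (2.0 * Z))
    Lam = brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-12)
    sigma2 = Lam * R * s
    res = TheoryResult(
        Lambda0=Lambda0,
        Lambda=Lam,
        p_fix=p0 * Lam / Lambda0,
        p0=p0,
        sigma2=sigma2,
        diagnostics={
            "residual": f(Lam),
            "unlinked_over_linked": (al * R * s) / (2.0 * Z),
            "alpha": al,
            "Z": Z,
        },
    )
    return res


def coalescence_time(inputs: TheoryInputs, Lambda: float, sigma2: Optional[float] = None) -> float:
    """Expected pairwise coalescence time ``T2`` at a neutral locus.

    Drift contributes ``1/N`` per generation; a sweep of advantage ``s`` at
    map distance ``r`` forces coalescence with probability
    ``exp(-2 r ln(2Ns)/s)`` (both lineages must remain associated with the
    sweeping allele while it goes from one copy to near-fixation), which
    averaged over a linear map gives a rate ``Lambda s / ln(2Ns)``; unlinked
    sweeps multiply the total rate of coalescence by ``exp(alpha sigma^2)``.
    """
    if Lambda < 0:
        raise ValueError("Lambda must be >= 0")
    N, s = inputs.N, inputs.effect_scale
    if sigma2 is None:
        sigma2 = Lambda * inputs.R * s
    al = _alpha(inputs.mating)
    sweep_rate = Lambda * s / math.log(2.0 * N * s) if Lambda > 0 else 0.0
    return 1.0 / ((1.0 / N + sweep_rate) * math.exp(al * sigma2))


def exp_effects(inputs: TheoryInputs) -> TheoryResult:
    """Exponentially distributed advantages: cutoff profile and overall rate.

    With the crude interference coefficient ``c(zeta) = Z zeta`` and the
    baseline mean advantage of successful sweeps ``s_tilde = 2 s_mean``, the
    fixation-probability profile is ``p(s) = 2 (s - s_c)_+`` with cutoff
    ``s_c = 4 Z Lambda s_mean``, and the overall density solves
    ``Lambda = Lambda0 exp(-4 Z Lambda)`` -- an interference term exactly
    twice the fixed-effects one, solved as ``W(4 Z Lambda0)/(4 Z)``.
    """
    if inputs.s_mean is None:
        raise ParameterError("s_mean", "exponential-effects results need s_mean")
    sbar = inputs.s_mean
    Z = inputs.Z
    p0, Lambda0, _ = baseline(inputs)
    Lam = float(np.real(lambertw(4.0 * Z * Lambda0))) / (4.0 * Z) if Lambda0 > 0 else 0.0
    s_c = 4.0 * Z * Lam * sbar

    def profile(s_val: float) -> float:
        return max(2.0 * (s_val - s_c), 0.0)

    res = TheoryResult(
        Lambda0=Lambda0,
        Lambda=Lam,
        p_fix=Lam / Lambda0 * p0 if Lambda0 > 0 else p0,
        p0=p0,
        sigma2=Lam * inputs.R * 2.0 * sbar,
        s_cutoff_strong=s_c,
        diagnostics={
            "interference_term": 4.0 * Z * Lam,
            "fixed_effects_interference_term": 2.0 * Z * Lam,
            "s_tilde_baseline": 2.0 * sbar,
        },
    )
    res.diagnostics["profile"] = profile  # type: ignore[assignment]
    return res


def weak_selection_pfix(
    s: float, inputs: TheoryInputs, Lambda: float, s_mean_successful: float
) -> Tuple[float, bool]:
    """Fixation probability of a weakly selected allele among strong sweeps.

    ``p(s) = 2 s exp(-2 Z Lambda s_tilde / s)``, the resummed large-ratio
    limit of the interference coefficient.  Below the near-neutral scale the
    branching description breaks down; the value is floored at the neutral
    ``1/N`` and the second return value flags that regime.
    """
    if s <= 0:
        raise ValueError("s must be > 0")
    val = 2.0 * s * math.exp(-2.0 * inputs.Z * Lambda * s_mean_successful / s)
    neutral = 1.0 / inputs.N
    if val <= neutral:
        return neutral, True
    return val, False


def facultative_rescale(inputs: TheoryInputs, outcross_rate: Optional[float] = None) -> TheoryResult:
    """Density of sweeps for facultative sexuals outcrossing at rate ``psi``.

    A "generation" becomes the ``1/psi`` rounds of clonal reproduction
    between outcrossing events, with all selective coefficients scaled up
    accordingly (``s -> s/psi``).  The baseline per mutation is unchanged
    (drift accumulates over the same clonal rounds), but the interference
    terms rescale: per outcrossing cycle the density of sweeps is
    ``Lambda R / psi`` substitutions per map length, giving

        ``Lambda = Lambda0 (1 - 2 Z Lambda / psi) exp(-alpha Lambda R s / psi^2)``

    with ceiling ``psi / (2 Z)`` per Morgan per generation; linked loci
    dominate interference when ``R s << psi``.  ``psi = 1`` reproduces the
    obligate-sex solution exactly.
    """
    psi = inputs.outcross_rate if outcross_rate is None else outcross_rate
    if not (0 < psi <= 1):
        raise ParameterError("outcross_rate", "must be in (0, 1]")
    p0, Lambda0, _ = baseline(inputs)
    s, R, Z = inputs.effect_scale, inputs.R, inputs.Z
    al = _alpha(inputs.mating)
    if Lambda0 == 0:
        return TheoryResult(0.0, 0.0, p0, p0, 0.0, diagnostics={"outcross_rate": psi})

    def f(L: float) -> float:
        return Lambda0 * (1.0 - 2.0 * Z * L / psi) * math.exp(-al * L * R * s / psi**2) - L

    hi = min(Lambda0, psi / (2.0 * Z))
    Lam = brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-12)
    return TheoryResult(
        Lambda0=Lambda0,
        Lambda=Lam,
        p_fix=p0 * Lam / Lambda0,
        p0=p0,
        sigma2=Lam * R * s,
        diagnostics={
            "residual": f(Lam),
            "outcross_rate": psi,
            "ceiling": psi / (2.0 * Z),
            "linked_dominance_condition": R * s / psi,
            "alpha": al,
            "Z": Z,
        },
    )


# ---------------------------------------------------------------------------
# Diffusion sojourn times conditioned on fixation
# ---------------------------------------------------------------------------


def _sojourn_density(N: int, s: float) -> Callable[[float], float]:
    """Conditional mean sojourn density t*(x) for a new mutation destined to fix.

    For the haploid WF diffusion (drift ``s x (1-x)``, variance ``x(1-x)/N``),
    started from a single copy and conditioned on fixation:
    ``t*(x) = 2 N (1-e^{-a x})(1-e^{-a(1-x)}) / [a x(1-x)(1-e^{-a})]`` with
    ``a = 2 N s``; symmetric about ``x = 1/2`` (Maruyama), ``-> 2N`` as
    ``s -> 0``.
    """
    a = 2.0 * N * s

    def t_star(x: float) -> float:
        if x <= 0 or x >= 1:
            return 0.0
        if a == 0:
            return 2.0 * N
        num = (-math.expm1(-a * x)) * (-math.expm1(-a * (1.0 - x)))
        den = a * x * (1.0 - x) * (-math.expm1(-a))
        return 2.0 * N * num / den

    return t_star


def diffusion_sojourn_stats(
    N: int, s: float, bands: Tuple[Tuple[float, float], ...] = ((0.0, 0.5), (0.5, 1.0)), n_grid: int = 2001
) -> Dict[Tuple[float, float], Tuple[float, float]]:
    """Mean and standard deviation of sojourn times by frequency band.

    Diffusion approximation for an allele destined to fix, started from one
    copy.  The mean is the integral of the conditional sojourn density; the
    variance uses the Green function of the fixation-conditioned diffusion
    (drift ``M*(x) = M + V u'/u``), ``E[T^2] = 2 \\iint G(0,x) G(x,y)``.
    Returns ``{band: (mean, sd)}``.
    """
    if N < 2:
        raise ParameterError("N", "need N >= 2")
    if s < 0:
        raise ValueError("s must be >= 0")
    t_star = _sojourn_density(N, s)
    a = 2.0 * N * s
    eps = 1.0 / (4.0 * N)
    x = np.linspace(eps, 1.0 - eps, n_grid)

    def u(y):
        if a == 0:
            return y
        return -np.expm1(-a * y) / -np.expm1(-a)

    # conditioned-process scale density: psi*(y) = e^{-a y} / u(y)^2
    psi_star = np.exp(-a * x) / u(x) ** 2
    V = x * (1.0 - x) / N
    S_star = np.concatenate([[0.0], np.cumsum((psi_star[1:] + psi_star[:-1]) / 2 * np.diff(x))])
    S_inf = S_star[-1] + psi_star[-1] * eps  # upper boundary ~ absorbing at 1

    def G(ix: int, iy: int) -> float:
        # Green function of the conditioned diffusion, start x[ix]; entrance
        # boundary at 0, absorbing at 1: G = 2 (S*(1) - S*(max)) / (V psi*)
        im = max(ix, iy)
        return 2.0 * (S_inf - S_star[im]) / (V[iy] * psi_star[iy])

    out: Dict[Tuple[float, float], Tuple[float, float]] = {}
    dx = x[1] - x[0]
    G0 = np.array([2.0 * (S_inf - S_star[i]) / (V[i] * psi_star[i]) for i in range(n_grid)])
    for lo, hi in bands:
        sel = np.flatnonzero((x >= lo) & (x < hi))
        mean = float(sum(t_star(xx) for xx in x[sel]) * dx)
        # E[T^2] = 2 sum_x G(0,x) sum_y G(x,y), x,y in band
        Smax = np.maximum.outer(S_star[sel], S_star[sel])
        Gxy = 2.0 * (S_inf - Smax) / (V[sel] * psi_star[sel])[None, :]
        inner = Gxy.sum(axis=1) * dx
        second = 2.0 * float(np.sum(G0[sel] * inner) * dx)
        var = max(second - mean**2, 0.0)
        out[(lo, hi)] = (mean, math.sqrt(var))
    return out
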