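"""Fuzzy function space: protein triangles, phenotype, target and gap.

Cellular processes form the abstract interval Omega = [0,1].  Each protein
contributes a triangular possibility distribution (apex ``m``, half-width
``w``, height ``H = e*|h|``).  Activator triangles (h > 0) and inhibitor
triangles (h < 0) are combined with the Lukasiewicz bounded-sum /
bounded-difference operators:

    A(x) = min(sum_i f_i(x), 1)        (activators)
    I(x) = min(sum_j f_j(x), 1)        (inhibitors)
    f_P(x) = min(1, max(0, A(x) - I(x)))

The environmental target f_E is the clipped piecewise-linear sampling of a
sum of Gaussians whose means follow independent AR(1) fluctuations.
Adaptation is the gap g = int_0^1 |f_E - f_P| dx, and the (unnormalised)
selection weight of an individual is exp(-k*g).

All function arithmetic here is exact on piecewise-linear representations:
breakpoints are merged and clipping/crossing points inserted analytically,
so integrals are exact (not quadrature approximations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PiecewiseLinearFunction",
    "Triangle",
    "EnvironmentSpec",
    "EnvironmentState",
    "triangle_function",
    "combine_phenotype",
    "phenotype_from_proteome",
    "build_target",
    "initial_environment",
    "step_environment",
    "compute_gap",
    "selection_weight",
]


class PiecewiseLinearFunction:
    """Continuous piecewise-linear function on [0, 1].

    Stored as strictly increasing breakpoint abscissae ``xs`` (with
    xs[0] = 0 and xs[-1] = 1) and ordinates ``ys``; evaluation between
    breakpoints is linear interpolation.
    """

    __slots__ = ("xs", "ys")

    def __init__(self, xs, ys, _checked: bool = False):
        xs = np.asarray(xs, dtype=np.float64)
        ys = np.asarray(ys, dtype=np.float64)
        if not _checked:
            if xs.ndim != 1 or xs.shape != ys.shape or xs.size < 2:
                raise ValueError("need matching 1-d arrays with >= 2 points")
            if xs[0] != 0.0 or xs[-1] != 1.0 or np.any(np.diff(xs) <= 0):
                raise ValueError("xs must increase strictly from 0 to 1")
        self.xs = xs
        self.ys = ys

    @classmethod
    def zero(cls) -> "PiecewiseLinearFunction":
        return cls(np.array([0.0, 1.0]), np.array([0.0, 0.0]), _checked=True)

    def __call__(self, x):
        return np.interp(x, self.xs, self.ys)

    def integral(self) -> float:
        """Exact integral over [0, 1] (trapezoid rule is exact here)."""
        return float(np.trapezoid(self.ys, self.xs))

    def is_zero(self) -> bool:
        return bool(np.all(self.ys == 0.0))

    def __eq__(self, other) -> bool:
        if not isinstance(other, PiecewiseLinearFunction):
            return NotImplemented
        return (np.array_equal(self.xs, other.xs)
                and np.array_equal(self.ys, other.ys))

    def __hash__(self):
        return hash((self.xs.tobytes(), self.ys.tobytes()))

    def dump(self, path) -> None:
        """Two-column (x, y) text dump for plotting."""
        np.savetxt(path, np.column_stack([self.xs, self.ys]))


@dataclass(frozen=True)
class Triangle:
    """A protein's phenotypic contribution: apex m, half-width w, height H."""

    m: float
    w: float
    H: float

    def __call__(self, x):
        if self.w <= 0 or self.H <= 0:
            return np.zeros_like(np.asarray(x, dtype=float))
        return self.H * np.maximum(0.0, 1.0 - np.abs(np.asarray(x, float) - self.m) / self.w)


def triangle_function(protein_or_triangle) -> PiecewiseLinearFunction:
    """Piecewise-linear form of a triangle, clipped to the domain [0, 1].

    Accepts a :class:`Triangle` or any object with m/w/H attributes (e.g. a
    decoded protein).  Degenerate triangles (w = 0 or H = 0) give the zero
    function.
    """
    t = protein_or_triangle
    m, w, H = float(t.m), float(t.w), float(t.H)
    if w <= 0.0 or H <= 0.0:
        return PiecewiseLinearFunction.zero()
    xs = np.unique(np.clip([0.0, m - w, m, m + w, 1.0], 0.0, 1.0))
    tri = Triangle(m, w, H)
    return PiecewiseLinearFunction(xs, tri(xs), _checked=True)


# -- exact piecewise-linear algebra -----------------------------------------


def _merged_grid(functions: Sequence[PiecewiseLinearFunction]) -> np.ndarray:
    grids = [f.xs for f in functions]
    return grids[0] if len(grids) == 1 else np.unique(np.concatenate(grids))


def _insert_level_crossings(xs: np.ndarray, ys: np.ndarray,
                            level: float) -> Tuple[np.ndarray, np.ndarray]:
    """Insert breakpoints where the function crosses ``level`` strictly."""
    d = ys - level
    sign_change = d[:-1] * d[1:] < 0.0
    idx = np.nonzero(sign_change)[0]
    if idx.size == 0:
        return xs, ys
    x0, x1 = xs[idx], xs[idx + 1]
    y0, y1 = ys[idx], ys[idx + 1]
    xc = x0 + (level - y0) * (x1 - x0) / (y1 - y0)
    new_xs = np.insert(xs, idx + 1, xc)
    new_ys = np.insert(ys, idx + 1, np.full(idx.size, level))
    return new_xs, new_ys


def _clip(xs, ys, lo: Optional[float], hi: Optional[float]):
    if hi is not None:
        xs, ys = _insert_level_crossings(xs, ys, hi)
        ys = np.minimum(ys, hi)
    if lo is not None:
        xs, ys = _insert_level_crossings(xs, ys, lo)
        ys = np.maximum(ys, lo)
    return xs, ys


def _bounded_sum(triangles: Sequence[Triangle]) -> Tuple[np.ndarray, np.ndarray]:
    """min(sum of triangles, 1) on the union of their breakpoints."""
    if not triangles:
        return np.array([0.0, 1.0]), np.array([0.0, 0.0])
    pts = [0.0, 1.0]
    for t in triangles:
        pts.extend((t.m - t.w, t.m, t.m + t.w))
    xs = np.unique(np.clip(np.asarray(pts), 0.0, 1.0))
    ys = np.zeros_like(xs)
    for t in triangles:
        ys += t(xs)
    return _clip(xs, ys, None, 1.0)


def combine_phenotype(activators: Iterable, inhibitors: Iterable
                      ) -> PiecewiseLinearFunction:
    """Lukasiewicz combination of activator and inhibitor triangles.

    Inputs may be :class:`Triangle` objects or anything with m/w/H.
    """
    acts = [t if isinstance(t, Triangle) else Triangle(t.m, t.w, t.H)
            for t in activators]
    inhs = [t if isinstance(t, Triangle) else Triangle(t.m, t.w, t.H)
            for t in inhibitors]
    acts = [t for t in acts if t.w > 0 and t.H > 0]
    inhs = [t for t in inhs if t.w > 0 and t.H > 0]
    ax, ay = _bounded_sum(acts)
    if not inhs:
        xs, ys = _clip(ax, ay, 0.0, None)
        return PiecewiseLinearFunction(xs, ys, _checked=True)
    ix, iy = _bounded_sum(inhs)
    xs = np.unique(np.concatenate([ax, ix]))
    diff = np.interp(xs, ax, ay) - np.interp(xs, ix, iy)
    xs, ys = _clip(xs, diff, 0.0, 1.0)
    return PiecewiseLinearFunction(xs, ys, _checked=True)


def phenotype_from_proteome(proteome) -> PiecewiseLinearFunction:
    """Phenotype f_P from a decoded proteome (list of (rna, protein) pairs).

    Each protein instance contributes once per hosting RNA with that RNA's
    expression level (the concentration effect of shared/duplicated genes).
    """
    from collections import Counter

    acts: Counter = Counter()
    inhs: Counter = Counter()
    for _, p in proteome:
        if p.w <= 0 or p.H <= 0:
            continue
        (acts if p.h > 0 else inhs)[(p.m, p.w, p.H)] += 1
    # identical triangles add linearly, so k copies collapse to one
    # triangle of k-fold height before the bounded sum
    return combine_phenotype(
        [Triangle(m, w, H * n) for (m, w, H), n in acts.items()],
        [Triangle(m, w, H * n) for (m, w, H), n in inhs.items()])


# -- environmental target ----------------------------------------------------


@dataclass(frozen=True)
class EnvironmentSpec:
    """Fluctuating target: sum of Gaussians with AR(1)-wandering means.

    ``gaussians`` is a tuple of (height, mean, sd).  ``sigma`` is the
    stationary standard deviation of each mean's fluctuation, ``tau`` its
    characteristic return time (in generations), and ``resolution`` the
    number of uniform intervals used to linearise the Gaussian sum.
    """

    gaussians: Tuple[Tuple[float, float, float], ...] = (
        (1.2, 0.52, 0.12),
        (-1.4, 0.5, 0.07),
        (0.3, 0.8, 0.03),
    )
    sigma: float = 5e-3
    tau: float = 2500.0
    resolution: int = 1000

    def __post_init__(self):
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        if self.tau <= 1:
            raise ValueError("tau must be > 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class EnvironmentState:
    """Current deviations of the Gaussian means and the materialised target."""

    deviations: np.ndarray
    target: PiecewiseLinearFunction

    def means(self, spec: EnvironmentSpec) -> np.ndarray:
        base = np.array([g[1] for g in spec.gaussians])
        return base + self.deviations


def build_target(spec: EnvironmentSpec,
                 means: Optional[Sequence[float]] = None
                 ) -> PiecewiseLinearFunction:
    """Clipped piecewise-linear sampling of the Gaussian sum at D+1 points."""
    if means is None:
        means = [g[1] for g in spec.gaussians]
    xs = np.linspace(0.0, 1.0, spec.resolution + 1)
    ys = np.zeros_like(xs)
    for (height, _, sd), mu in zip(spec.gaussians, means):
        ys += height * np.exp(-((xs - mu) ** 2) / (2.0 * sd * sd))
    np.clip(ys, 0.0, 1.0, out=ys)
    return PiecewiseLinearFunction(xs, ys, _checked=True)


def initial_environment(spec: EnvironmentSpec) -> EnvironmentState:
    """Environment at t = 0: all deviations zero."""
    dev = np.zeros(len(spec.gaussians))
    return EnvironmentState(deviations=dev, target=build_target(spec))


def ar1_innovation_sd(spec: EnvironmentSpec) -> float:
    """Innovation scale (sigma/tau)*sqrt(2*tau - 1).

    Chosen so that the stationary standard deviation of the deviation
    process equals ``sigma`` exactly for the update
    ``dx' = dx*(1 - 1/tau) + innovation_sd * eps``.
    """
    return (spec.sigma / spec.tau) * math.sqrt(2.0 * spec.tau - 1.0)


def step_deviations(deviations: np.ndarray, spec: EnvironmentSpec,
                    eps: np.ndarray) -> np.ndarray:
    """One AR(1) update of the Gaussian-mean deviations."""
    return deviations * (1.0 - 1.0 / spec.tau) + ar1_innovation_sd(spec) * eps


def step_environment(state: EnvironmentState, spec: EnvironmentSpec,
                     rng: np.random.Generator) -> EnvironmentState:
    """Advance the fluctuating target by one generation.

    Each Gaussian mean receives an independent standard-normal innovation;
    the target is rebuilt at the new means.
    """
    eps = rng.standard_normal(len(spec.gaussians))
    dev = step_deviations(state.deviations, spec, eps)
    base = np.array([g[1] for g in spec.gaussians])
    return EnvironmentState(deviations=dev,
                            target=build_target(spec, base + dev))


# -- adaptation --------------------------------------------------------------


def compute_gap(f_p: PiecewiseLinearFunction,
                f_e: PiecewiseLinearFunction) -> float:
    """Gap with target: exact integral of |f_E - f_P| over [0, 1]."""
    xs = np.unique(np.concatenate([f_p.xs, f_e.xs]))
    diff = np.interp(xs, f_e.xs, f_e.ys) - np.interp(xs, f_p.xs, f_p.ys)
    xs, diff = _insert_level_crossings(xs, diff, 0.0)
    return float(np.trapezoid(np.abs(diff), xs))


def selection_weight(g: float, k: float) -> float:
    """Unnormalised reproduction weight exp(-k*g)."""
    return math.exp(-k * g)
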