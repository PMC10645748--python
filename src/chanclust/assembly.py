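"""Stochastic lattice model of channel-cluster self-assembly.

Channels nucleate, accrete onto existing clusters, and are removed from a
2D lattice representing the surface membrane.  At each synchronous step,
sampled from the occupancy at the start of the step:

* an empty site 4-adjacent to an occupied site becomes occupied with
  probability ``p_growth`` (growth takes precedence over nucleation);
* any other empty site becomes occupied with probability ``p_nucleation``;
* an occupied site is vacated with probability ``p_removal``.

The lattice is periodic.  Run to steady state, the connected-component
size distribution develops an exponential tail in the low-density regime,
the hallmark of stochastic self-assembly, and simulated distributions can
be matched to observed ones by a grid search over the three rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import SizeDistribution


@dataclass(frozen=True)
class AssemblyParams:
    """Nucleation / growth / removal probabilities per site per step."""

    p_nucleation: float
    p_growth: float
    p_removal: float
    grid_shape: tuple[int, int] = (256, 256)
    max_steps: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_nucleation", "p_growth", "p_removal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(d < 1 for d in self.grid_shape):
            raise ValueError("grid dimensions must be >= 1")


@dataclass
class LatticeState:
    """Binary occupancy grid plus the number of steps taken."""

    occupancy: np.ndarray
    step_index: int = 0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy)
        if not np.isin(self.occupancy, (0, 1)).all():
            raise ValueError("occupancy values must be 0 or 1")
        self.occupancy = self.occupancy.astype(np.uint8)

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "LatticeState":
        return cls(np.zeros(shape, dtype=np.uint8), 0)

    @property
    def occupancy_fraction(self) -> float:
        return float(self.occupancy.mean())


@dataclass
class SteadyStateResult:
    """Final lattice, size distribution, and convergence diagnostics."""

    state: LatticeState
    distribution: SizeDistribution
    converged: bool
    n_steps: int
    occupancy_history: np.ndarray


def synchronous_update(
    occ: np.ndarray,
    p_nucleation: float,
    p_growth: float,
    p_removal: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous update of one or many lattices.

    ``occ`` may carry leading batch dimensions; the last two axes are the
    (periodic) lattice.  All events are sampled from the state at step
    start, and each site sees exactly one event (removal if occupied,
    growth if empty and adjacent to an occupied site, else nucleation).
    """
    occ = np.asarray(occ, dtype=bool)
    nbr = (
        np.roll(occ, 1, axis=-1)
        | np.roll(occ, -1, axis=-1)
        | np.roll(occ, 1, axis=-2)
        | np.roll(occ, -1, axis=-2)
    )
    u = rng.random(occ.shape)
    new = np.where(
        occ,
        u >= p_removal,
        np.where(nbr, u < p_growth, u < p_nucleation),
    )
    return new.astype(np.uint8)


def step(state: LatticeState, params: AssemblyParams, rng: np.random.Generator) -> LatticeState:
    """Advance the lattice one synchronous step."""
    if state.occupancy.shape != tuple(params.grid_shape):
        raise ValueError(
            f"state shape {state.occupancy.shape} does not match "
            f"params.grid_shape {params.grid_shape}"
        )
    new = synchronous_update(
        state.occupancy, params.p_nucleation, params.p_growth, params.p_removal, rng
    )
    return LatticeState(new, state.step_index + 1)


def component_sizes(occ: np.ndarray) -> np.ndarray:
    """Sizes of 4-connected components on a periodic lattice."""
    from scipy import ndimage

    occ = np.asarray(occ, dtype=bool)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(occ, structure=structure)
    if n == 0:
        return np.array([], dtype=int)

    # merge labels that touch across the periodic boundary (union-find)
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    top, bottom = labels[0, :], labels[-1, :]
    for a, b in zip(top, bottom):
        if a and b:
            union(a, b)
    left, right = labels[:, 0], labels[:, -1]
    for a, b in zip(left, right):
        if a and b:
            union(a, b)

    roots = np.array([find(i) for i in range(n + 1)])
    merged = roots[labels]
    sizes = np.bincount(merged.ravel())[1:]
    return sizes[sizes > 0]


def size_distribution(occ: np.ndarray) -> SizeDistribution:
    """Connected-component size distribution of a lattice."""
    return SizeDistribution.from_sizes(component_sizes(occ))


def run_to_steady_state(
    params: AssemblyParams,
    initial: LatticeState | None = None,
    window: int = 500,
    rel_tol: float = 1e-3,
    n_windows: int = 5,
) -> SteadyStateResult:
    """Iterate until total occupancy is stationary or ``max_steps`` hit.

    Stationarity: the relative change between consecutive ``window``-step
    moving averages of the occupancy fraction stays below ``rel_tol`` for
    ``n_windows`` consecutive window comparisons.  Non-convergence within
    ``max_steps`` is flagged, not raised.
    """
    rng = np.random.default_rng(params.seed)
    state = initial if initial is not None else LatticeState.empty(params.grid_shape)
    if state.occupancy.shape != tuple(params.grid_shape):
        raise ValueError("initial state does not match params.grid_shape")

    history = []
    window_means: list[float] = []
    ok_streak = 0
    converged = False
    occ = state.occupancy
    steps_taken = 0
    for t in range(params.max_steps):
        occ = synchronous_update(
            occ, params.p_nucleation, params.p_growth, params.p_removal, rng
        )
        steps_taken = t + 1
        history.append(float(occ.mean()))
        if steps_taken % window == 0:
            m = float(np.mean(history[-window:]))
            if window_means:
                prev = window_means[-1]
                denom = max(abs(prev), 1e-12)
                if abs(m - prev) / denom < rel_tol:
                    ok_streak += 1
                else:
                    ok_streak = 0
            window_means.append(m)
            if ok_streak >= n_windows:
                converged = True
                break

    final = LatticeState(occ, state.step_index + steps_taken)
    dist = size_distribution(final.occupancy)
    return SteadyStateResult(
        state=final,
        distribution=dist,
        converged=converged,
        n_steps=steps_taken,
        occupancy_history=np.asarray(history),
    )


def exponential_tail_fit(dist: SizeDistribution, min_count: float = 1.0) -> tuple[float, float, float]:
    """Log-linear fit ``log(count) = a - size/tau`` on non-empty bins.

    Returns ``(amplitude, tau, r_squared)``.  Used to check that the
    steady-state size distribution is approximately exponential.
    """
    mask = dist.counts >= min_count
    if mask.sum() < 3:
        raise ValueError("need at least 3 non-empty bins for a log-linear fit")
    x = dist.sizes[mask]
    y = np.log(dist.counts[mask])
    slope, intercept = np.polyfit(x, y, 1)
    pred = intercept + slope * x
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    tau = -1.0 / slope if slope < 0 else float("inf")
    return float(np.exp(intercept)), float(tau), float(r2)


def _aligned_relative_frequencies(
    a: SizeDistribution, b: SizeDistribution
) -> tuple[np.ndarray, np.ndarray]:
    """Relative frequencies of both distributions on the union of sizes."""
    if a.sizes.size == 0 and b.sizes.size == 0:
        return np.array([]), np.array([])
    max_size = int(max(a.sizes.max(initial=0), b.sizes.max(initial=0)))
    fa = np.zeros(max_size + 1)
    fb = np.zeros(max_size + 1)
    fa[a.sizes.astype(int)] = a.relative_frequency
    fb[b.sizes.astype(int)] = b.relative_frequency
    return fa, fb


def distribution_distance(a: SizeDistribution, b: SizeDistribution) -> float:
    """Sum of squared differences of relative frequencies over shared bins."""
    fa, fb = _aligned_relative_frequencies(a, b)
    return float(np.sum((fa - fb) ** 2))


def fit_params(
    observed: SizeDistribution,
    search: list[AssemblyParams],
    n_replicates: int = 3,
    **steady_state_kwargs,
) -> tuple[AssemblyParams, float]:
    """Grid-search the rates minimizing the distance to an observed distribution.

    Each candidate is simulated to steady state with ``n_replicates``
    distinct seeds; the replicate relative-frequency distributions are
    averaged before computing the squared distance.  Returns the best
    candidate and its distance.
    """
    if not search:
        raise ValueError("search grid must not be empty")
    best: tuple[float, AssemblyParams] | None = None
    for candidate in search:
        dists = []
        for r in range(n_replicates):
            p = replace(candidate, seed=candidate.seed + 7919 * r)
            res = run_to_steady_state(p, **steady_state_kwargs)
            dists.append(res.distribution)
        # average relative frequencies on the union of sizes
        max_size = int(max((d.sizes.max(initial=0) for d in dists), default=0))
        avg = np.zeros(max_size + 1)
        for d in dists:
            f = np.zeros(max_size + 1)
            if d.sizes.size:
                f[d.sizes.astype(int)] = d.relative_frequency
            avg += f / n_replicates
        sizes = np.nonzero(avg)[0]
        mean_dist = SizeDistribution(sizes.astype(float), avg[sizes])
        d2 = distribution_distance(observed, mean_dist)
        if best is None or d2 < best[0]:
            best = (d2, candidate)
    return best[1], best[0]
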