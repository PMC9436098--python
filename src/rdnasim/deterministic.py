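"""Exact frequency recursions: Models A1 and A2.

Both models track the *relative frequency* of cells in each copy-number
state.  Every cell divides once per generation; the population doubles, so
absolute numbers are irrelevant and frequencies are renormalized each step
(10000 * 2^175 cells would overflow any counter, while every reported
statistic depends only on proportions).

Model A1: a division of a sub-cap cell yields one daughter with the parental
copy number and one amplified by the Delta split; cells at the cap divide
into two unchanged cells (the recombination circuit is off).

Model A2: Sir2 silencing rises continuously with copy number, so a growing
fraction of divisions amplify nothing.  The fraction is given by a
:class:`RampSpec` — zero at ``c_start``, 1 % one copy above it, rising
linearly to 100 % at the cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from rdnasim.core import (
    CopyNumberDistribution,
    ModelParams,
    NonConvergenceError,
    ParameterError,
    Trajectory,
    delta_split_weights,
)

__all__ = [
    "RampSpec",
    "noamp_probability",
    "advance_generation_a1",
    "advance_generation_a2",
    "run_to_saturation",
    "run_generations",
    "scan_delta",
    "fit_delta_a2",
    "DeltaFitResult",
]

StepFn = Callable[[CopyNumberDistribution], CopyNumberDistribution]


@dataclass(frozen=True)
class RampSpec:
    """Piecewise-linear probability that a division amplifies nothing.

    ``p_noamp`` is 0 at ``c_start`` (the founder state always amplifies),
    ``p_next`` one copy above it, and rises linearly to ``p_cap`` at
    ``c_max``; values outside the range clamp to [0, 1].
    """

    p_next: float = 0.01
    p_cap: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_next <= self.p_cap <= 1:
            raise ParameterError(
                "ramp must satisfy 0 <= p_next <= p_cap <= 1, got "
                f"p_next={self.p_next}, p_cap={self.p_cap}"
            )

    def probability(self, c: int, c_start: int, c_max: int) -> float:
        if c <= c_start:
            return 0.0
        if c >= c_max:
            return self.p_cap
        span = c_max - (c_start + 1)
        if span == 0:
            return self.p_cap
        return self.p_next + (self.p_cap - self.p_next) * (c - (c_start + 1)) / span


def noamp_probability(c: int, ramp: RampSpec, params: ModelParams) -> float:
    """No-amplification probability for a cell with ``c`` copies."""
    if c < params.c_start:
        raise ParameterError(f"copy number {c} below c_start ({params.c_start})")
    return ramp.probability(c, params.c_start, params.c_max)


def _split_matrix_row(params: ModelParams) -> list[tuple[int, float]]:
    return sorted(delta_split_weights(params.delta).items())


def advance_generation_a1(
    dist: CopyNumberDistribution, params: ModelParams
) -> CopyNumberDistribution:
    """One synchronous generation of the binary-switch recursion.

    Sub-cap mass splits half to its own state and half over the Delta jumps
    (clamped at the cap); mass at the cap is inert.  Total mass is conserved
    exactly (population doubling is absorbed by the renormalization).
    """
    dist.require_frequencies()
    n = params.n_states
    f = dist.weights
    out = np.zeros(n)
    out[n - 1] = f[n - 1]
    sub = f[: n - 1]
    out[: n - 1] += 0.5 * sub
    for inc, w in _split_matrix_row(params):
        if inc == 0:
            out[: n - 1] += 0.5 * w * sub
            continue
        shifted = np.minimum(np.arange(n - 1) + inc, n - 1)
        np.add.at(out, shifted, 0.5 * w * sub)
    return CopyNumberDistribution(params.c_start, params.c_max, out)


def advance_generation_a2(
    dist: CopyNumberDistribution,
    params: ModelParams,
    ramp: RampSpec | None = None,
) -> CopyNumberDistribution:
    """One generation of the linear-Sir2-ramp recursion.

    A fraction ``p_noamp(c)`` of each state's divisions produces two
    unamplified cells; the complement divides as in Model A1.  With the ramp
    forced to zero this reduces exactly to :func:`advance_generation_a1`.
    """
    if ramp is None:
        ramp = RampSpec()
    dist.require_frequencies()
    n = params.n_states
    f = dist.weights
    cs = np.arange(params.c_start, params.c_max + 1)
    p = np.array([ramp.probability(int(c), params.c_start, params.c_max) for c in cs])
    out = np.zeros(n)
    # each division yields two offspring; normalize by the doubling factor:
    # no-amp divisions leave both offspring at c, amplifying divisions leave
    # one at c and send one over the Delta jumps.
    out += f * (1.0 + p) / 2.0
    amp = 0.5 * (1.0 - p) * f
    for inc, w in _split_matrix_row(params):
        shifted = np.minimum(np.arange(n) + inc, n - 1)
        np.add.at(out, shifted, w * amp)
    return CopyNumberDistribution(params.c_start, params.c_max, out)


def run_to_saturation(
    step: StepFn,
    params: ModelParams,
    record_snapshots_every: int | None = None,
) -> Trajectory:
    """Iterate a generation-advance rule from the founder point mass.

    Stops after the first generation at which the fraction of cells at the
    cap reaches ``params.saturation_frac`` (evaluated after completing each
    generation's update); the trajectory's final generation index is the
    generations-to-saturation.  Raises :class:`NonConvergenceError` if the
    run does not saturate within ``params.max_generations``.
    """
    dist = CopyNumberDistribution.point_mass(params.c_start, params)
    traj = Trajectory()

    def record(g: int, d: CopyNumberDistribution) -> None:
        snap = None
        if record_snapshots_every and g % record_snapshots_every == 0:
            snap = d
        traj.append(g, g * params.t0, d.mean(), d.frac_at_cap(), snap)

    g = 0
    record(g, dist)
    while dist.frac_at_cap() < params.saturation_frac:
        if g >= params.max_generations:
            raise NonConvergenceError(
                f"no saturation within {params.max_generations} generations "
                f"(frac at cap {dist.frac_at_cap():.4f})"
            )
        dist = step(dist)
        g += 1
        record(g, dist)
    return traj


def run_generations(
    step: StepFn, params: ModelParams, n_generations: int
) -> Trajectory:
    """Iterate a fixed number of generations (no stopping condition)."""
    dist = CopyNumberDistribution.point_mass(params.c_start, params)
    traj = Trajectory()
    traj.append(0, 0.0, dist.mean(), dist.frac_at_cap(), dist)
    for g in range(1, n_generations + 1):
        dist = step(dist)
        traj.append(g, g * params.t0, dist.mean(), dist.frac_at_cap(), dist)
    return traj


def scan_delta(
    deltas: Iterable[float],
    params: ModelParams,
    step_factory: Callable[[ModelParams], StepFn] | None = None,
) -> pd.DataFrame:
    """Generations-to-saturation for a grid of Delta values.

    Returns a table with one row per Delta (columns ``delta``,
    ``generations``, ``elapsed_time_s``); rows that fail to converge carry
    NaN.  Under Model A1 the generation count is strictly decreasing in
    Delta; under the A2 ramp the integer-jump lattice interacts with the
    near-cap silencing and the count need not be monotone, so monotonicity
    is reported (column attribute) rather than enforced.
    """
    if step_factory is None:
        step_factory = lambda p: (lambda d: advance_generation_a1(d, p))
    rows = []
    for delta in deltas:
        p = params.with_(delta=float(delta))
        step = step_factory(p)
        try:
            traj = run_to_saturation(step, p)
            g: float = traj.final_generation
            t = g * p.t0
        except NonConvergenceError:
            g, t = float("nan"), float("nan")
        rows.append({"delta": float(delta), "generations": g, "elapsed_time_s": t})
    df = pd.DataFrame(rows, columns=["delta", "generations", "elapsed_time_s"])
    gens = df["generations"].to_numpy(dtype=float)
    df.attrs["monotone_decreasing"] = bool(
        np.all(np.diff(gens[np.isfinite(gens)]) <= 0)
    )
    return df


@dataclass
class DeltaFitResult:
    """Outcome of the integral-Delta search for the ramp model."""

    delta: int | None
    window: tuple[float, float]
    table: pd.DataFrame

    @property
    def fitted(self) -> bool:
        return self.delta is not None


def fit_delta_a2(
    candidates: Sequence[int],
    window: tuple[float, float],
    params: ModelParams,
    ramp: RampSpec | None = None,
) -> DeltaFitResult:
    """Smallest integral Delta whose A2 saturation time falls in ``window``.

    The full candidate table is always returned alongside the fit: the
    generation count is not monotone in Delta under the ramp model, so the
    table, not the single fitted value, is the meaningful result.
    """
    if not candidates:
        raise ParameterError("candidate list must be non-empty")
    lo, hi = window
    if lo > hi:
        raise ParameterError(f"window low {lo} exceeds high {hi}")
    if ramp is None:
        ramp = RampSpec()
    table = scan_delta(
        [float(c) for c in candidates],
        params,
        step_factory=lambda p: (lambda d: advance_generation_a2(d, p, ramp)),
    )
    fit: int | None = None
    for cand, gens in zip(candidates, table["generations"]):
        if np.isfinite(gens) and lo <= gens <= hi:
            fit = int(cand)
            break
    return DeltaFitResult(delta=fit, window=(lo, hi), table=table)
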