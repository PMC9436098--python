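"""Shared domain types and elementary operations.

Copy-number states live on the integer interval ``[c_start, c_max]``.  A
population is described either by relative frequencies (deterministic
recursions) or by integer cell counts (stochastic engines).  The per-division
amplification increment Delta, the copy-number-dependent generation time, and
the mortality-corrected growth-rate arithmetic used to calibrate the models
all live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ModelParams",
    "CopyNumberDistribution",
    "Trajectory",
    "GrowthMeasurement",
    "ParameterError",
    "NonConvergenceError",
    "delta_split_weights",
    "generation_time",
    "actual_growth_rate",
    "summarize",
]


class ParameterError(ValueError):
    """A model parameter violates its invariant."""


class NonConvergenceError(RuntimeError):
    """A run failed to reach saturation within the generation budget."""


@dataclass(frozen=True)
class ModelParams:
    """Complete parameterization of a simulation run.

    Defaults are the parameters of the *cln3* evolution experiment: a
    population founded at 125 rDNA copies amplifying toward a 220-copy cap,
    with an average gain of 1.3 copies per amplifying division, a 10000-cell
    inoculum re-seeded every 12 generations, and a 97-minute (5820 s) base
    division time.

    Parameters
    ----------
    c_start
        Initial copy number (every founder cell starts here).
    c_max
        Copy-number cap; recombination is silenced at the cap, so it is an
        absorbing boundary for the asymmetric models.
    delta
        Average copy-number increment of the amplified daughter per division
        (copies/division, > 0).  Non-integral values are realized as a
        floor/ceil mixture, see :func:`delta_split_weights`.
    saturation_frac
        Fraction of cells that must sit at ``c_max`` for the run to count as
        saturated (0 < f <= 1).
    n0
        Bottleneck/inoculum size in cells.
    reseed_interval
        Generations between bottlenecks in Models A3/B.
    t0
        Base generation time in seconds, anchored at ``c_start``.
    gti
        Generation-time increment in seconds per extra copy above
        ``c_start``; negative values make high-copy cells divide faster.
    aging_cap
        Maximum number of divisions a mother cell may perform, or ``None``
        for no replicative-aging limit.
    max_generations
        Safety cap; runs that do not saturate by then raise
        :class:`NonConvergenceError`.
    """

    c_start: int = 125
    c_max: int = 220
    delta: float = 1.3
    saturation_frac: float = 0.98
    n0: int = 10000
    reseed_interval: int = 12
    t0: float = 5820.0
    gti: float = 0.0
    aging_cap: int | None = None
    max_generations: int = 10000

    def __post_init__(self) -> None:
        if self.c_start > self.c_max:
            raise ParameterError(
                f"c_start ({self.c_start}) must not exceed c_max ({self.c_max})"
            )
        if not self.delta > 0:
            raise ParameterError(f"delta must be > 0, got {self.delta}")
        if not 0 < self.saturation_frac <= 1:
            raise ParameterError(
                f"saturation_frac must lie in (0, 1], got {self.saturation_frac}"
            )
        if self.n0 < 1:
            raise ParameterError(f"n0 must be >= 1, got {self.n0}")
        if self.reseed_interval < 1:
            raise ParameterError(
                f"reseed_interval must be >= 1, got {self.reseed_interval}"
            )
        if not self.t0 > 0:
            raise ParameterError(f"t0 must be > 0, got {self.t0}")
        # generation time must stay positive across the whole state range
        t_end = self.t0 + self.gti * (self.c_max - self.c_start)
        if not t_end > 0:
            raise ParameterError(
                f"t0 + gti*(c_max - c_start) = {t_end} s; generation time "
                "must stay positive over the full copy-number range"
            )
        if self.aging_cap is not None and self.aging_cap < 1:
            raise ParameterError(f"aging_cap must be >= 1, got {self.aging_cap}")
        if self.max_generations < 1:
            raise ParameterError("max_generations must be >= 1")

    @property
    def n_states(self) -> int:
        return self.c_max - self.c_start + 1

    def with_(self, **overrides) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **overrides)


def delta_split_weights(delta: float) -> dict[int, float]:
    """Split a (possibly non-integral) mean increment into integer jumps.

    The amplified daughter gains ``floor(delta)`` copies with probability
    ``1 - frac`` and ``ceil(delta)`` copies with probability ``frac``, where
    ``frac`` is the fractional part of ``delta``; the expected gain is then
    exactly ``delta``.  For Delta = 1.3 this is the canonical 70 % / 30 %
    split between +1 and +2.  A gain of 0 can only arise for ``delta < 1``.
    """
    if not delta > 0:
        raise ParameterError(f"delta must be > 0, got {delta}")
    lo = math.floor(delta)
    frac = delta - lo
    if frac < 1e-12:
        return {lo: 1.0}
    if frac > 1 - 1e-12:
        return {lo + 1: 1.0}
    return {lo: 1.0 - frac, lo + 1: frac}


def generation_time(c: int, params: ModelParams) -> float:
    """Division time in seconds for a cell with ``c`` copies.

    Affine in copy number: ``t0 + gti * (c - c_start)``.
    """
    if not params.c_start <= c <= params.c_max:
        raise ParameterError(
            f"copy number {c} outside [{params.c_start}, {params.c_max}]"
        )
    return params.t0 + params.gti * (c - params.c_start)


@dataclass(frozen=True)
class GrowthMeasurement:
    """Mortality-corrected growth-rate arithmetic for one strain.

    From an apparent (OD-based) growth rate and the dead-cell fraction F the
    death rate is ``DR = F * GR_app``, the actual growth rate is
    ``GR_actual = GR_app - DR`` and the generation time is ``ln 2 / GR``.
    """

    gr_apparent: float
    dead_fraction: float
    dr: float
    gr_actual: float
    generation_time_h: float

    @property
    def gr_actual_2dp(self) -> float:
        """Actual growth rate rounded half-up to 2 decimals (as printed)."""
        return float(
            Decimal(repr(self.gr_actual)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )


def actual_growth_rate(gr_apparent: float, dead_fraction: float) -> GrowthMeasurement:
    """Correct an apparent growth rate for cell mortality."""
    if not gr_apparent > 0:
        raise ParameterError(f"gr_apparent must be > 0, got {gr_apparent}")
    if not 0 <= dead_fraction <= 1:
        raise ParameterError(
            f"dead_fraction must lie in [0, 1], got {dead_fraction}"
        )
    dr = dead_fraction * gr_apparent
    gr_actual = gr_apparent - dr
    return GrowthMeasurement(
        gr_apparent=gr_apparent,
        dead_fraction=dead_fraction,
        dr=dr,
        gr_actual=gr_actual,
        generation_time_h=math.log(2) / gr_actual,
    )


class CopyNumberDistribution:
    """Weights of cells over the copy-number states ``[c_start, c_max]``.

    Stored as a dense vector over the (small) state range.  Weights are
    either relative frequencies (summing to 1) or integer counts; mass
    assigned beyond ``c_max`` must be clamped by the caller before insertion.
    """

    __slots__ = ("c_start", "c_max", "weights")

    def __init__(self, c_start: int, c_max: int, weights: np.ndarray):
        weights = np.asarray(weights)
        if weights.shape != (c_max - c_start + 1,):
            raise ParameterError(
                f"weights shape {weights.shape} does not match state range "
                f"[{c_start}, {c_max}]"
            )
        if np.any(weights < 0):
            raise ParameterError("weights must be non-negative")
        self.c_start = c_start
        self.c_max = c_max
        self.weights = weights

    # -- constructors -----------------------------------------------------
    @classmethod
    def point_mass(cls, c: int, params: ModelParams) -> "CopyNumberDistribution":
        w = np.zeros(params.n_states)
        w[c - params.c_start] = 1.0
        return cls(params.c_start, params.c_max, w)

    @classmethod
    def from_dict(
        cls, d: dict[int, float], c_start: int, c_max: int
    ) -> "CopyNumberDistribution":
        w = np.zeros(c_max - c_start + 1)
        for c, v in d.items():
            if not c_start <= c <= c_max:
                raise ParameterError(f"state {c} outside [{c_start}, {c_max}]")
            w[c - c_start] = v
        return cls(c_start, c_max, w)

    # -- views ------------------------------------------------------------
    @property
    def support(self) -> np.ndarray:
        return np.arange(self.c_start, self.c_max + 1)

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def as_dict(self) -> dict[int, float]:
        """Sparse view: only states with non-zero weight."""
        nz = np.nonzero(self.weights)[0]
        return {int(self.c_start + i): float(self.weights[i]) for i in nz}

    # -- statistics -------------------------------------------------------
    def mean(self) -> float:
        tot = self.total
        if tot == 0:
            raise ParameterError("empty distribution")
        return float((self.support * self.weights).sum() / tot)

    def frac_at_cap(self) -> float:
        tot = self.total
        if tot == 0:
            raise ParameterError("empty distribution")
        return float(self.weights[-1] / tot)

    def variance(self) -> float:
        m = self.mean()
        return float((self.weights * (self.support - m) ** 2).sum() / self.total)

    def normalized(self) -> "CopyNumberDistribution":
        tot = self.total
        if tot == 0:
            raise ParameterError("empty distribution")
        return CopyNumberDistribution(
            self.c_start, self.c_max, self.weights / tot
        )

    def require_frequencies(self, tol: float = 1e-9) -> None:
        if abs(self.total - 1.0) > tol:
            raise ParameterError(
                f"frequencies sum to {self.total}, expected 1 within {tol}"
            )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CopyNumberDistribution([{self.c_start}, {self.c_max}], "
            f"total={self.total:.6g}, mean={self.mean():.3f})"
        )


def summarize(dist: CopyNumberDistribution) -> tuple[float, float]:
    """Return (mean copy number, fraction of cells at the cap)."""
    return dist.mean(), dist.frac_at_cap()


@dataclass
class Trajectory:
    """Per-generation record of a run.

    ``times_s`` holds elapsed simulated seconds (only meaningful for the
    asynchronous Model B; synchronous models advance by one generation time
    per step).  ``snapshots`` optionally maps generation index to the full
    distribution at that generation.
    """

    generations: list[int] = field(default_factory=list)
    times_s: list[float] = field(default_factory=list)
    mean_copies: list[float] = field(default_factory=list)
    frac_at_cap: list[float] = field(default_factory=list)
    snapshots: dict[int, CopyNumberDistribution] = field(default_factory=dict)

    def append(
        self,
        generation: int,
        time_s: float,
        mean: float,
        frac: float,
        snapshot: CopyNumberDistribution | None = None,
    ) -> None:
        if self.generations and generation <= self.generations[-1]:
            raise ParameterError("generation indices must be strictly increasing")
        self.generations.append(generation)
        self.times_s.append(time_s)
        self.mean_copies.append(mean)
        self.frac_at_cap.append(frac)
        if snapshot is not None:
            self.snapshots[generation] = snapshot

    @property
    def final_generation(self) -> int:
        if not self.generations:
            raise ParameterError("empty trajectory")
        return self.generations[-1]

    def __len__(self) -> int:
        return len(self.generations)

    def to_frame(self):
        """Long-format pandas DataFrame (generation, time_s, mean, frac)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": self.generations,
                "time_s": self.times_s,
                "mean_copies": self.mean_copies,
                "frac_at_cap": self.frac_at_cap,
            }
        )
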