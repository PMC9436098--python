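"""Stochastic engines: Model A3 (bottlenecked) and Model B (asynchronous).

Model A3 plays the same division rules as the deterministic recursions but
with integer cell counts and a serial-passage bottleneck: every
``reseed_interval`` generations the population is resampled down to ``n0``
cells, mimicking the daily re-inoculation of the evolution experiment.

Model B drops the assumption of synchronous division.  Every cell divides
after its own generation time, affine in copy number (``t0 + gti * extra
copies``), so lineages that amplify faster also replicate faster (or slower,
for positive ``gti``) — a growth-rate selection coupled to the amplification
process.  The engine is a discrete-event simulation over cohorts: cells
sharing (copy number, lineage division count, next division time) are
processed as one block, which keeps the event queue small even for
multi-million-cell populations.

All engines are exactly reproducible from (params, seed).
"""

from __future__ import annotations

import heapq
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from rdnasim.core import (
    CopyNumberDistribution,
    ModelParams,
    NonConvergenceError,
    ParameterError,
    Trajectory,
    delta_split_weights,
)
from rdnasim.deterministic import RampSpec

__all__ = [
    "reseed",
    "run_model_a3",
    "run_model_b",
    "run_replicates",
    "ModelA3Result",
    "ModelBResult",
    "ReplicateSummary",
    "POPULATION_CAP",
]

# populations above this size are multinomially thinned back to it; with the
# default 12-generation bottleneck (10000 * 2^12 ~ 4.1e7) it never triggers,
# it only guards degenerate settings such as reseed_interval -> infinity
POPULATION_CAP = 10**8


def reseed(
    dist: CopyNumberDistribution, n0: int, rng: np.random.Generator
) -> CopyNumberDistribution:
    """Sample a bottleneck of ``n0`` cells from a population.

    Cells are chosen multinomially from the normalized weights (sampling
    with replacement; the source population after 12 doublings is ~4000x
    larger than the inoculum, so the hypergeometric correction is
    negligible).  The result is in count mode and sums to exactly ``n0``.
    """
    if n0 < 1:
        raise ParameterError(f"n0 must be >= 1, got {n0}")
    tot = dist.total
    if tot == 0:
        raise ParameterError("cannot reseed from an empty distribution")
    counts = rng.multinomial(n0, dist.weights / tot)
    return CopyNumberDistribution(dist.c_start, dist.c_max, counts)


# ---------------------------------------------------------------------------
# Model A3: synchronous generations, integer counts, periodic bottleneck
# ---------------------------------------------------------------------------


@dataclass
class ModelA3Result:
    generations: int
    trajectory: Trajectory
    seed: int
    final: CopyNumberDistribution


def _a3_advance(
    counts: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    noamp_p: np.ndarray | None,
) -> np.ndarray:
    """One synchronous generation on an (ages, states) count array.

    Rows are mother ages (a single row when no aging cap is set; with a cap
    of K there are K+1 rows and row K holds retired cells that no longer
    divide but stay in the population).  The offspring with the parental
    copy number is the continuing mother (age + 1); the amplified offspring
    is a newborn daughter (age 0).
    """
    n_ages, n = counts.shape
    aged = params.aging_cap is not None
    w = delta_split_weights(params.delta)
    incs = sorted(w.items())
    new = np.zeros_like(counts)
    idx = np.arange(n - 1)
    for a in range(n_ages):
        row = counts[a]
        if aged and a == n_ages - 1:
            new[a] += row  # retired cells persist without dividing
            continue
        mother_row = min(a + 1, n_ages - 1) if aged else 0
        daughter_row = 0
        sub = row[:-1]
        # cap-state cells divide into two unamplified cells
        new[mother_row][n - 1] += row[n - 1]
        new[daughter_row][n - 1] += row[n - 1]
        # sub-cap: one offspring keeps the parental copy number
        new[mother_row][:-1] += sub
        if noamp_p is None:
            amp = sub
        else:
            namp = rng.binomial(sub, 1.0 - noamp_p[:-1])
            new[daughter_row][:-1] += sub - namp  # unamplified daughters
            amp = namp
        # split the amplified daughters over the Delta jumps
        remaining = amp
        for k, (inc, _weight) in enumerate(incs):
            if k < len(incs) - 1:
                frac = w[inc] / sum(w[i] for i, _ in incs[k:])
                take = rng.binomial(remaining, frac)
            else:
                take = remaining
            remaining = remaining - take
            np.add.at(new[daughter_row], np.minimum(idx + inc, n - 1), take)
    return new


def run_model_a3(
    params: ModelParams,
    seed: int,
    ramp: RampSpec | None = None,
    record_snapshots_every: int | None = None,
) -> ModelA3Result:
    """Bottlenecked stochastic run of Model A1 (or A2 when a ramp is given).

    Starts from ``n0`` cells at ``c_start``; every ``reseed_interval``
    generations the population is resampled down to ``n0`` cells.  Stops at
    the first generation where the fraction of cells at the cap reaches
    ``saturation_frac``.
    """
    rng = np.random.default_rng(seed)
    n = params.n_states
    n_ages = (params.aging_cap + 1) if params.aging_cap is not None else 1
    counts = np.zeros((n_ages, n), dtype=np.int64)
    counts[0][0] = params.n0
    noamp_p = None
    if ramp is not None:
        noamp_p = np.array(
            [
                ramp.probability(c, params.c_start, params.c_max)
                for c in range(params.c_start, params.c_max + 1)
            ]
        )
    traj = Trajectory()

    def state_dist() -> CopyNumberDistribution:
        return CopyNumberDistribution(
            params.c_start, params.c_max, counts.sum(axis=0)
        )

    def record(g: int) -> None:
        d = state_dist()
        snap = None
        if record_snapshots_every and g % record_snapshots_every == 0:
            snap = d
        traj.append(g, g * params.t0, d.mean(), d.frac_at_cap(), snap)

    g = 0
    record(g)
    while True:
        d = state_dist()
        if d.frac_at_cap() >= params.saturation_frac:
            return ModelA3Result(
                generations=g, trajectory=traj, seed=seed, final=d
            )
        if g >= params.max_generations:
            raise NonConvergenceError(
                f"Model A3 did not saturate within {params.max_generations} "
                f"generations (seed {seed})"
            )
        counts = _a3_advance(counts, params, rng, noamp_p)
        g += 1
        total = int(counts.sum())
        if g % params.reseed_interval == 0:
            flat = rng.multinomial(params.n0, counts.ravel() / total)
            counts = flat.reshape(counts.shape)
        elif total > POPULATION_CAP:
            flat = rng.multinomial(POPULATION_CAP, counts.ravel() / total)
            counts = flat.reshape(counts.shape)
        record(g)


# ---------------------------------------------------------------------------
# Model B: asynchronous discrete-event engine over cohorts
# ---------------------------------------------------------------------------

_TIME_QUANTUM = 10**6  # event times keyed in integer microseconds


@dataclass
class ModelBResult:
    """Outcome of an asynchronous run.

    ``generations`` is elapsed simulated time divided by the base generation
    time ``t0`` — the number of base division periods, which is how serial
    dilution experiments count generations and which coincides exactly with
    the synchronous generation counter when ``gti`` is zero.
    ``mean_divisions`` is the population-mean lineage division count at the
    stopping point, an alternative generation metric also reported.
    """

    generations: float
    mean_divisions: float
    elapsed_s: float
    trajectory: Trajectory
    seed: int
    saturated: bool
    final: CopyNumberDistribution | None = None


def run_model_b(
    params: ModelParams,
    seed: int,
    symmetric: bool = False,
    c_floor: int | None = None,
    stop_at_mean_divisions: float | None = None,
    reset_clocks_on_reseed: bool = False,
) -> ModelBResult:
    """Discrete-event simulation with copy-number-dependent division times.

    Every division of a sub-cap cell produces one offspring with the
    parental copy number and one amplified over the Delta split (cap cells
    produce two unamplified offspring); each offspring schedules its next
    division ``generation_time(copies)`` after birth.  The population is
    bottlenecked to ``n0`` cells whenever the population-mean division count
    crosses a multiple of ``reseed_interval`` — the reading that degenerates
    exactly to Model A3 when ``gti`` is zero.  Sampled cells keep their
    division phase by default (``reset_clocks_on_reseed=True`` instead
    restarts every sampled cell's clock, which barely changes predictions).

    With ``symmetric=True`` the division rule is the symmetric-exchange
    counterfactual: one daughter gains and the other loses the Delta
    increment, clamped to ``[c_floor, c_max]``; there is no absorbing cap,
    so such runs should use ``stop_at_mean_divisions``.
    """
    rng = np.random.default_rng(seed)
    w = delta_split_weights(params.delta)
    (lo, w_lo), *rest = sorted(w.items())
    hi, w_hi = rest[0] if rest else (lo, 0.0)
    n = params.n_states
    cap_idx = n - 1
    floor_idx = 0
    if symmetric:
        if c_floor is None:
            c_floor = params.c_start  # callers normally pass a viability floor
        if c_floor > params.c_start:
            raise ParameterError("c_floor must not exceed c_start")
        floor_idx = 0
        offset = params.c_start - c_floor
    else:
        offset = 0
    n_total_states = n + offset  # states c_floor .. c_max
    aging = params.aging_cap is not None
    if symmetric and aging:
        raise ParameterError(
            "the aging cap is not supported with the symmetric division rule"
        )

    def gt(ci: int) -> float:
        c = c_floor + ci if symmetric else params.c_start + ci
        # generation time extrapolates linearly below c_start for the
        # symmetric counterfactual's reduced-copy cells
        return params.t0 + params.gti * (c - params.c_start)

    if symmetric and gt(0) <= 0:
        raise ParameterError("generation time not positive at the copy floor")

    def tkey(t: float) -> int:
        return int(round(t * _TIME_QUANTUM))

    start_idx = offset if symmetric else 0
    cap_state = n_total_states - 1

    events: dict[int, dict[tuple, int]] = defaultdict(lambda: defaultdict(int))
    heap: list[int] = []

    def schedule(tk: int, key: tuple, m: int) -> None:
        if tk not in events:
            heapq.heappush(heap, tk)
        events[tk][key] += m

    def initial_key(ci: int, d: int) -> tuple:
        return (ci, d, 0) if aging else (ci, d)

    first = tkey(gt(start_idx))
    schedule(first, initial_key(start_idx, 0), params.n0)

    total = params.n0
    sum_d = 0
    at_cap = 0
    retired: dict[tuple, int] = defaultdict(int)  # aged-out cells, still counted
    next_reseed = float(params.reseed_interval)
    traj = Trajectory()
    tnow = 0.0
    traj.append(0, 0.0, float(params.c_start), 0.0)
    next_record = 1

    def record_if_due(mean_d: float) -> None:
        nonlocal next_record
        while mean_d >= next_record:
            mean_c = _mean_copies()
            traj.append(
                next_record, tnow, mean_c, at_cap / total if total else 0.0
            )
            next_record += 1

    def _state_counts() -> CopyNumberDistribution:
        w = np.zeros(n_total_states, dtype=np.int64)
        for tk2 in events:
            for key, m in events[tk2].items():
                w[key[0]] += m
        for key, m in retired.items():
            w[key[0]] += m
        low = c_floor if symmetric else params.c_start
        return CopyNumberDistribution(low, params.c_max, w)

    def _mean_copies() -> float:
        s = 0
        for tk2 in events:
            for key, m in events[tk2].items():
                s += (c_floor + key[0] if symmetric else params.c_start + key[0]) * m
        for key, m in retired.items():
            s += (c_floor + key[0] if symmetric else params.c_start + key[0]) * m
        return s / total

    def offspring_states(ci: int, m: int) -> list[tuple[int, int]]:
        """Copy-number states of the amplified offspring of m divisions."""
        k = rng.binomial(m, w_hi) if w_hi > 0 else 0
        out = []
        for cnt, inc in ((m - k, lo), (k, hi)):
            if cnt:
                out.append((min(ci + inc, cap_state), cnt))
        return out

    def symmetric_offspring(ci: int, m: int) -> list[tuple[int, int]]:
        """Both daughters of m symmetric-exchange divisions.

        Each division misaligns the sisters by one increment drawn from the
        Delta split: one daughter gains it, the other loses the same amount,
        clamped to the state range.
        """
        k = rng.binomial(m, w_hi) if w_hi > 0 else 0
        out = []
        for cnt, inc in ((m - k, lo), (k, hi)):
            if cnt:
                out.append((min(ci + inc, cap_state), cnt))
                out.append((max(ci - inc, floor_idx), cnt))
        return out

    while heap:
        tk = heapq.heappop(heap)
        batch = events.pop(tk)
        tnow = tk / _TIME_QUANTUM
        for key, m in sorted(batch.items()):
            ci, d = key[0], key[1]
            age = key[2] if aging else 0
            d2 = d + 1
            # dividers leave the population...
            total -= m
            sum_d -= d * m
            if ci == cap_state and not symmetric:
                at_cap -= m
            # ...and are replaced by their offspring
            if symmetric:
                for cj, cnt in symmetric_offspring(ci, m):
                    schedule(tkey(tnow + gt(cj)), initial_key(cj, d2), cnt)
                    total += cnt
                    sum_d += d2 * cnt
            else:
                mother_age = age + 1
                mother_key = (ci, d2, mother_age) if aging else (ci, d2)
                if aging and mother_age >= params.aging_cap:
                    retired[(ci, d2)] += m  # mother retires, stays counted
                    total += m
                    sum_d += d2 * m
                    if ci == cap_state:
                        at_cap += m
                else:
                    schedule(tkey(tnow + gt(ci)), mother_key, m)
                    total += m
                    sum_d += d2 * m
                    if ci == cap_state:
                        at_cap += m
                if ci == cap_state:
                    # recombination is off: the daughter is unamplified
                    schedule(
                        tkey(tnow + gt(ci)), initial_key(ci, d2), m
                    )
                    total += m
                    sum_d += d2 * m
                    at_cap += m
                else:
                    for cj, cnt in offspring_states(ci, m):
                        schedule(
                            tkey(tnow + gt(cj)), initial_key(cj, d2), cnt
                        )
                        total += cnt
                        sum_d += d2 * cnt
                        if cj == cap_state:
                            at_cap += cnt
        mean_d = sum_d / total
        record_if_due(mean_d)
        if not symmetric and at_cap >= params.saturation_frac * total:
            return ModelBResult(
                generations=tnow / params.t0,
                mean_divisions=mean_d,
                elapsed_s=tnow,
                trajectory=traj,
                seed=seed,
                saturated=True,
                final=_state_counts(),
            )
        if stop_at_mean_divisions is not None and mean_d >= stop_at_mean_divisions:
            return ModelBResult(
                generations=tnow / params.t0,
                mean_divisions=mean_d,
                elapsed_s=tnow,
                trajectory=traj,
                seed=seed,
                saturated=False,
                final=_state_counts(),
            )
        if mean_d > params.max_generations:
            raise NonConvergenceError(
                f"Model B exceeded {params.max_generations} mean divisions "
                f"without saturating (seed {seed})"
            )
        if mean_d >= next_reseed or total > POPULATION_CAP:
            is_reseed = mean_d >= next_reseed
            if is_reseed:
                next_reseed += params.reseed_interval
            target = params.n0 if is_reseed else POPULATION_CAP
            keys: list[tuple[int | None, tuple]] = []
            counts: list[int] = []
            for tk2 in list(events.keys()):
                for key, m in events[tk2].items():
                    keys.append((tk2, key))
                    counts.append(m)
            for key, m in retired.items():
                keys.append((None, key))
                counts.append(m)
            arr = np.array(counts, dtype=np.int64)
            sample = rng.multinomial(target, arr / arr.sum())
            events.clear()
            heap.clear()
            retired = defaultdict(int)
            total = 0
            sum_d = 0
            at_cap = 0
            for (tk2, key), m in zip(keys, sample):
                if m == 0:
                    continue
                ci, d = key[0], key[1]
                total += m
                sum_d += d * m
                if ci == cap_state and not symmetric:
                    at_cap += m
                if tk2 is None:
                    retired[key] += m
                elif is_reseed and reset_clocks_on_reseed:
                    schedule(tkey(tnow + gt(ci)), key, m)
                else:
                    schedule(tk2, key, m)
            if total == 0:
                break
        if not heap and retired:
            # everyone has aged out: the population can no longer divide
            raise NonConvergenceError(
                f"population stalled: all cells reached the aging cap "
                f"(seed {seed})"
            )
    raise NonConvergenceError(f"event queue exhausted before stopping (seed {seed})")


# ---------------------------------------------------------------------------
# replicate runner
# ---------------------------------------------------------------------------


@dataclass
class ReplicateSummary:
    """Per-seed outcomes of repeated stochastic runs.

    ``sd`` is the sample standard deviation (n-1 denominator); it is NaN for
    a single run and 0 for a deterministic runner.  Failed runs are recorded
    in ``failures`` rather than silently dropped.
    """

    values: list[float] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        if not self.values:
            raise ParameterError("no successful runs")
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        if len(self.values) < 2:
            return float("nan")
        return float(np.std(self.values, ddof=1))


def run_replicates(
    runner: Callable[[int], float],
    n_runs: int,
    base_seed: int,
) -> ReplicateSummary:
    """Run ``runner(seed)`` for seeds ``base_seed .. base_seed + n_runs - 1``."""
    if n_runs < 1:
        raise ParameterError(f"n_runs must be >= 1, got {n_runs}")
    summary = ReplicateSummary()
    for i in range(n_runs):
        seed = base_seed + i
        try:
            summary.values.append(float(runner(seed)))
            summary.seeds.append(seed)
        except NonConvergenceError as exc:
            summary.failures[seed] = str(exc)
    return summary
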