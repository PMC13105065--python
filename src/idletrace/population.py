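"""Stochastic multi-state birth-death-transition simulation of clonal populations.

Drug-tolerant persister (DTP) populations in the "idling" regime are modelled
as collections of clonal lineages whose cells occupy discrete phenotypic
states. Each state has its own division and death rate, and cells switch
between states with first-order transition rates. Idling corresponds to a
landscape whose aggregate net growth rate is near zero while division and
death individually remain non-zero.

Two solvers are provided: an exact event-driven (Gillespie direct method)
simulator, and a deterministic mean-field solution of the expected per-state
counts via the matrix exponential, which serves as an analytic oracle for the
stochastic one. A treatment protocol helper simulates a pre-treatment
landscape, remaps every surviving cell onto a drug-modified landscape through
a configurable state map, and continues the simulation, preserving lineage
identity throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PhenotypeState",
    "PhenotypeLandscape",
    "LineagePopulation",
    "SimTrajectory",
    "simulate",
    "mean_field_solution",
    "run_treatment_protocol",
]


@dataclass(frozen=True)
class PhenotypeState:
    """A phenotypic state with division and death rates (events/cell/hour)."""

    name: str
    division_rate: float
    death_rate: float

    def __post_init__(self) -> None:
        for label, rate in (("division_rate", self.division_rate),
                            ("death_rate", self.death_rate)):
            if not np.isfinite(rate) or rate < 0:
                raise ValueError(
                    f"{label} of state {self.name!r} must be finite and >= 0, "
                    f"got {rate}"
                )

    @property
    def net_rate(self) -> float:
        return self.division_rate - self.death_rate


@dataclass(frozen=True)
class PhenotypeLandscape:
    """An ordered set of phenotypic states plus an inter-state transition matrix.

    ``transition_rates[i, j]`` is the per-cell rate (per hour) of switching
    from state ``i`` to state ``j``. The diagonal must be zero: only switch
    events are encoded, residence is implicit.
    """

    states: tuple[PhenotypeState, ...]
    transition_rates: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        k = np.asarray(self.transition_rates, dtype=float)
        n = len(states)
        if n == 0:
            raise ValueError("landscape needs at least one state")
        if k.shape != (n, n):
            raise ValueError(
                f"transition matrix shape {k.shape} does not match "
                f"{n} states"
            )
        if not np.all(np.isfinite(k)):
            raise ValueError("transition rates must be finite")
        if np.any(k < 0):
            raise ValueError("off-diagonal transition rates must be >= 0")
        if np.any(np.diag(k) != 0):
            raise ValueError("transition-matrix diagonal must be zero")
        k = k.copy()
        k.setflags(write=False)
        object.__setattr__(self, "transition_rates", k)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    def division_rates(self) -> np.ndarray:
        return np.array([s.division_rate for s in self.states])

    def death_rates(self) -> np.ndarray:
        return np.array([s.death_rate for s in self.states])

    def rate_matrix(self) -> np.ndarray:
        """Mean-field generator A with A[i,i] = b_i - d_i - sum_j k_ij and
        A[j,i] = k_ij, so that d/dt n = A n for the expected state counts."""
        k = self.transition_rates
        a = k.T.astype(float).copy()
        np.fill_diagonal(
            a, self.division_rates() - self.death_rates() - k.sum(axis=1)
        )
        return a


@dataclass
class LineagePopulation:
    """Cell counts per (lineage, state): ``counts[lineage]`` is an int vector
    over the landscape's states."""

    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for lineage, vec in self.counts.items():
            v = np.asarray(vec, dtype=np.int64)
            if np.any(v < 0):
                raise ValueError(f"negative count for lineage {lineage!r}")
            clean[str(lineage)] = v
        self.counts = clean

    @classmethod
    def uniform(cls, lineages: list[str], n_states: int,
                cells_per_lineage: int, state: int = 0) -> "LineagePopulation":
        """All lineages start with the same size, all cells in one state."""
        counts = {}
        for lin in lineages:
            v = np.zeros(n_states, dtype=np.int64)
            v[state] = cells_per_lineage
            counts[lin] = v
        return cls(counts)

    @property
    def lineages(self) -> list[str]:
        return list(self.counts)

    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    def lineage_totals(self) -> dict[str, int]:
        return {lin: int(v.sum()) for lin, v in self.counts.items()}

    def state_totals(self) -> np.ndarray:
        return np.sum(list(self.counts.values()), axis=0)

    def as_matrix(self) -> tuple[list[str], np.ndarray]:
        lins = self.lineages
        return lins, np.array([self.counts[l] for l in lins], dtype=np.int64)


@dataclass
class SimTrajectory:
    """Recorded snapshots of a simulation, plus provenance.

    ``landscape_schedule`` lists ``(switch_time, landscape_label, record)``
    tuples; ``record`` documents any state remapping applied at the switch.
    """

    times: np.ndarray
    snapshots: list[LineagePopulation]
    seed: int
    landscape_schedule: list[tuple[float, str, dict]] = field(default_factory=list)
    state_names: tuple[str, ...] = ()
    empty_start: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.snapshots):
            raise ValueError("snapshot count must equal time count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def snapshot_at(self, t: float) -> LineagePopulation:
        idx = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[idx], t):
            raise KeyError(f"no snapshot recorded at t={t}")
        return self.snapshots[idx]

    def totals(self) -> np.ndarray:
        return np.array([s.total() for s in self.snapshots], dtype=float)

    def to_frame(self):
        """Long-format table (time, lineage, state, count)."""
        import pandas as pd

        rows = []
        for t, snap in zip(self.times, self.snapshots):
            for lin, vec in snap.counts.items():
                for si, c in enumerate(vec):
                    name = (self.state_names[si]
                            if self.state_names else str(si))
                    rows.append((t, lin, name, int(c)))
        return pd.DataFrame(rows, columns=["time", "lineage", "state", "count"])


def _validate_record_times(record_times, t_max: float) -> np.ndarray:
    rt = np.asarray(sorted(set(float(t) for t in record_times)), dtype=float)
    if rt.size == 0:
        raise ValueError("record_times must be non-empty")
    if rt[0] < 0 or rt[-1] > t_max + 1e-12:
        raise ValueError("record_times must lie within [0, t_max]")
    return rt


def simulate(
    landscape: PhenotypeLandscape,
    init: LineagePopulation,
    t_max: float,
    record_times,
    seed: int,
    method: str = "direct",
    tau: float = 0.5,
) -> SimTrajectory:
    """Simulate division/death/transition events for every lineage.

    ``method="direct"`` is the exact Gillespie direct method (default).
    ``method="tau"`` is approximate fixed-step tau-leaping with step ``tau``
    hours, intended for large populations; event counts per step are Poisson
    and removals are clamped to the available cells.

    Lineage identity is heritable and never changes. The same ``seed`` gives
    a bit-identical trajectory.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rt = _validate_record_times(record_times, t_max)
    rng = np.random.default_rng(seed)

    lins, counts = init.as_matrix()
    if counts.size == 0 or counts.shape[1] != landscape.n_states:
        if counts.size == 0:
            counts = np.zeros((0, landscape.n_states), dtype=np.int64)
        else:
            raise ValueError(
                "initial population state dimension does not match landscape"
            )
    empty_start = counts.sum() == 0
    if empty_start:
        warnings.warn("initial population is empty; all snapshots are zero")

    div = landscape.division_rates()
    dea = landscape.death_rates()
    k = landscape.transition_rates
    kout = k.sum(axis=1)
    rtot = div + dea + kout  # per-cell total event rate by state

    snapshots: list[LineagePopulation] = []

    def record() -> None:
        snapshots.append(
            LineagePopulation({l: counts[i].copy() for i, l in enumerate(lins)})
        )

    if method == "direct":
        t = 0.0
        next_rec = 0
        while next_rec < rt.size:
            a_ls = counts * rtot  # (L, S) propensities
            a0 = float(a_ls.sum())
            if a0 <= 0:
                break
            t_next = t + rng.exponential(1.0 / a0)
            while next_rec < rt.size and rt[next_rec] <= t_next:
                record()
                next_rec += 1
            if next_rec >= rt.size or t_next > t_max:
                t = t_next
                break
            t = t_next
            # choose the (lineage, state) cell class, then the event type
            flat = a_ls.ravel().cumsum()
            idx = int(np.searchsorted(flat, rng.random() * flat[-1], side="right"))
            li, si = divmod(idx, landscape.n_states)
            u = rng.random() * rtot[si]
            if u < div[si]:
                counts[li, si] += 1
            elif u < div[si] + dea[si]:
                counts[li, si] -= 1
            else:
                krow = k[si].cumsum()
                sj = int(np.searchsorted(krow, u - div[si] - dea[si],
                                         side="right"))
                counts[li, si] -= 1
                counts[li, sj] += 1
        while next_rec < rt.size:  # absorbed or ran past t_max: freeze state
            record()
            next_rec += 1
    elif method == "tau":
        t = 0.0
        next_rec = 0
        while next_rec < rt.size and rt[next_rec] <= t:
            record()
            next_rec += 1
        while next_rec < rt.size:
            step = min(tau, rt[next_rec] - t)
            births = rng.poisson(counts * div * step)
            deaths = rng.poisson(counts * dea * step)
            moves = rng.poisson(counts[:, :, None] * k[None] * step)
            removals = deaths + moves.sum(axis=2)
            # clamp removals so counts stay non-negative
            over = removals > counts
            if np.any(over):
                scale = np.where(removals > 0, counts / np.maximum(removals, 1), 0)
                deaths = np.where(over, np.floor(deaths * scale).astype(np.int64),
                                  deaths)
                moves = np.where(over[:, :, None],
                                 np.floor(moves * scale[:, :, None]).astype(np.int64),
                                 moves)
                removals = deaths + moves.sum(axis=2)
            counts = counts + births - removals + moves.sum(axis=1)
            t += step
            while next_rec < rt.size and rt[next_rec] <= t + 1e-12:
                record()
                next_rec += 1
    else:
        raise ValueError(f"unknown method {method!r}")

    return SimTrajectory(
        times=rt,
        snapshots=snapshots,
        seed=int(seed),
        landscape_schedule=[(0.0, landscape.label, {})],
        state_names=landscape.state_names,
        empty_start=bool(empty_start),
    )


def mean_field_solution(
    landscape: PhenotypeLandscape, init_by_state, times
) -> np.ndarray:
    """Expected per-state counts exp(t*A) @ n0, as a (n_states, n_times) matrix.

    A is the branching-process generator from
    :meth:`PhenotypeLandscape.rate_matrix`; this is the deterministic oracle
    for the stochastic simulator's ensemble mean.
    """
    n0 = np.asarray(init_by_state, dtype=float)
    if n0.shape != (landscape.n_states,):
        raise ValueError("init_by_state length must equal number of states")
    ts = np.asarray(times, dtype=float)
    if np.any(ts < 0):
        raise ValueError("times must be >= 0")
    a = landscape.rate_matrix()
    out = np.empty((landscape.n_states, ts.size))
    for j, t in enumerate(ts):
        out[:, j] = expm(a * t) @ n0
    return out


def run_treatment_protocol(
    untreated: PhenotypeLandscape,
    drugged: PhenotypeLandscape,
    state_map: np.ndarray,
    init: LineagePopulation,
    t_pre: float,
    t_post: float,
    record_times,
    seed: int,
) -> SimTrajectory:
    """Simulate t_pre hours untreated, remap surviving cells onto the drugged
    landscape via ``state_map`` (rows: untreated states; columns: probability
    over drugged states), then simulate t_post hours drugged.

    The remap is instantaneous at the switch and multinomial per cell;
    lineage identities are preserved. ``record_times`` are absolute hours in
    [0, t_pre + t_post].
    """
    sm = np.asarray(state_map, dtype=float)
    if sm.shape != (untreated.n_states, drugged.n_states):
        raise ValueError("state_map shape must be (n_untreated, n_drugged)")
    if np.any(sm < 0) or np.any(np.abs(sm.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("state_map rows must be probability distributions")
    if t_pre < 0 or t_post <= 0:
        raise ValueError("t_pre must be >= 0 and t_post > 0")
    rt = _validate_record_times(record_times, t_pre + t_post)

    ss = np.random.SeedSequence(seed)
    seed_pre, seed_map, seed_post = (int(s.generate_state(1)[0] % (2**31))
                                     for s in ss.spawn(3))

    pre_times = [t for t in rt if t <= t_pre]
    if t_pre > 0:
        traj_pre = simulate(untreated, init,
                            t_max=t_pre,
                            record_times=sorted(set(pre_times + [t_pre])),
                            seed=seed_pre)
        at_switch = traj_pre.snapshot_at(t_pre)
        pre_snaps = [traj_pre.snapshot_at(t) for t in pre_times]
    else:
        at_switch = init
        pre_snaps = []

    rng = np.random.default_rng(seed_map)
    remapped: dict[str, np.ndarray] = {}
    for lin, vec in at_switch.counts.items():
        new = np.zeros(drugged.n_states, dtype=np.int64)
        for si, n in enumerate(vec):
            if n > 0:
                new += rng.multinomial(int(n), sm[si])
        remapped[lin] = new

    post_times = sorted(t - t_pre for t in rt if t > t_pre)
    if not post_times:
        post_times = [t_post]
        keep_post = False
    else:
        keep_post = True
    traj_post = simulate(drugged, LineagePopulation(remapped),
                         t_max=t_post, record_times=post_times,
                         seed=seed_post)

    times = list(pre_times) + ([t + t_pre for t in post_times] if keep_post else [])
    snaps = pre_snaps + (traj_post.snapshots if keep_post else [])
    record = {
        "state_map": sm.tolist(),
        "untreated_states": untreated.state_names,
        "drugged_states": drugged.state_names,
    }
    return SimTrajectory(
        times=np.asarray(times),
        snapshots=snaps,
        seed=int(seed),
        landscape_schedule=[
            (0.0, untreated.label, {}),
            (float(t_pre), drugged.label, record),
        ],
        state_names=drugged.state_names,
    )
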