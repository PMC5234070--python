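"""Kinetic Monte Carlo (Gillespie) simulation of stochastic networks.

Direct-method continuous-time simulation: exponential waiting times with the
total exit rate, next state proportional to the outgoing rates.  Empirical
occupancies and integrated currents cross-validate the linear-algebra
steady states and mean currents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import StochasticNetwork

__all__ = ["Trajectory", "OccupancyEstimate", "gillespie_run", "occupancy"]

#: number of equal time batches used for batch-mean standard errors
N_BATCHES = 10

#: fraction of the trajectory discarded before estimation
BURN_IN_FRACTION = 0.1


@dataclass
class Trajectory:
    """A single continuous-time realisation.

    ``times[i]`` is the time of the i-th jump, ``states[i]`` the state index
    occupied after it; ``states[0]`` at implicit time 0 is the initial
    state and ``times[0]`` the first jump time.  ``disps`` holds the
    horizontal displacement of each jump.
    """

    times: np.ndarray = field(repr=False)
    states: np.ndarray = field(repr=False)
    disps: np.ndarray = field(repr=False)
    initial: int
    t_max: float
    seed: int
    node_ids: tuple[str, ...] = field(repr=False, default=())

    @property
    def n_jumps(self) -> int:
        return len(self.times)


@dataclass
class OccupancyEstimate:
    """Time-weighted occupancies and empirical current with batch errors."""

    occupancy: np.ndarray
    occupancy_se: np.ndarray = field(repr=False)
    current: float = 0.0
    current_se: float = 0.0
    t_effective: float = 0.0
    node_ids: tuple[str, ...] = field(repr=False, default=())


def gillespie_run(net: StochasticNetwork, t_max: float, start: str,
                  seed: int) -> Trajectory:
    """Simulate ``net`` for total time ``t_max`` from node ``start``.

    Reproducible: a given (network, t_max, start, seed) always yields the
    same trajectory.
    """
    if not t_max > 0:
        raise ValueError("t_max must be positive")
    n = net.n_states
    start_idx = net.index(start)
    targets: list[list[int]] = [[] for _ in range(n)]
    rates: list[list[float]] = [[] for _ in range(n)]
    disps: list[list[int]] = [[] for _ in range(n)]
    for e in net.edges:
        j = net.index(e.src)
        targets[j].append(net.index(e.dst))
        rates[j].append(e.rate)
        disps[j].append(e.disp)
    exit_rate = np.array([sum(r) for r in rates])
    if np.any(exit_rate <= 0):
        dead = net.nodes[int(np.argmin(exit_rate))].id
        raise ValueError(f"absorbing state {dead!r}: zero exit rate")
    cum = [np.cumsum(r) for r in rates]
    tgt = [np.asarray(t, dtype=np.int64) for t in targets]
    dsp = [np.asarray(d, dtype=np.int64) for d in disps]

    rng = np.random.default_rng(seed)
    t = 0.0
    state = start_idx
    times: list[float] = []
    visited: list[int] = [start_idx]
    jumps: list[int] = []
    while True:
        t += rng.exponential(1.0 / exit_rate[state])
        if t > t_max:
            break
        c = cum[state]
        k = int(np.searchsorted(c, rng.random() * c[-1], side="right"))
        k = min(k, len(c) - 1)
        times.append(t)
        jumps.append(int(dsp[state][k]))
        state = int(tgt[state][k])
        visited.append(state)
    return Trajectory(
        np.asarray(times), np.asarray(visited, dtype=np.int64),
        np.asarray(jumps, dtype=np.int64), start_idx, float(t_max),
        int(seed), tuple(nd.id for nd in net.nodes),
    )


def occupancy(traj: Trajectory, burn_in: float = BURN_IN_FRACTION
              ) -> OccupancyEstimate:
    """Time-weighted occupancy and empirical current from a trajectory.

    The first ``burn_in`` fraction of the run is discarded; errors are
    batch-mean standard errors over ten equal time batches.
    """
    if traj.t_max <= 0:
        raise ValueError("trajectory has no duration")
    n = len(traj.node_ids) if traj.node_ids else int(traj.states.max()) + 1
    t0 = burn_in * traj.t_max
    # dwell intervals: state[i] is occupied on [start_i, end_i)
    starts = np.concatenate(([0.0], traj.times))
    ends = np.concatenate((traj.times, [traj.t_max]))
    states = traj.states

    batch_edges = np.linspace(t0, traj.t_max, N_BATCHES + 1)
    occ_batches = np.zeros((N_BATCHES, n))
    cur_batches = np.zeros(N_BATCHES)
    for b in range(N_BATCHES):
        lo, hi = batch_edges[b], batch_edges[b + 1]
        overlap = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0.0, None)
        occ = np.bincount(states, weights=overlap, minlength=n)
        occ_batches[b] = occ / (hi - lo)
        in_batch = (traj.times >= lo) & (traj.times < hi)
        cur_batches[b] = traj.disps[in_batch].sum() / (hi - lo)
    occ_mean = occ_batches.mean(axis=0)
    total = occ_mean.sum()
    occ_mean = occ_mean / total
    occ_se = occ_batches.std(axis=0, ddof=1) / np.sqrt(N_BATCHES) / total
    cur_mean = float(cur_batches.mean())
    cur_se = float(cur_batches.std(ddof=1) / np.sqrt(N_BATCHES))
    return OccupancyEstimate(occ_mean, occ_se, cur_mean, cur_se,
                             float(traj.t_max - t0), traj.node_ids)
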