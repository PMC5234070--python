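"""Builders for the canonical networks: two-bulk ladders, the chemosensory
adaptation lattice, kinetic proofreading chains, and quenched disorder.

Adaptation model
----------------
A receptor complex is described by activity ``a in {0, 1}`` and methylation
level ``m in 0..M-1``.  Activity flips are governed by the free-energy
landscape ``f(a, m) = a * E * (S - m)`` through Glauber (sigmoid) rates

    rate(a=0 -> 1) = omega_a * sigma(E * (m - S)),
    rate(a=1 -> 0) = omega_a * sigma(E * (S - m)),

with ``sigma(x) = 1 / (1 + exp(-x))``, so the crossover sits at ``m = S``
(the log chemoattractant concentration).  Methylation kinetics implement the
adaptation feedback and are independent of ``m`` and ``S``: the inactive row
methylates (m -> m+1 at ``omega_m``, reverse suppressed by ``exp(-G)``) and
the active row demethylates (m -> m-1 at ``omega_m``, reverse suppressed by
``exp(-G)``), with reflecting ends.  Each elementary plaquette then carries
a cycle affinity of ``E + 2G``: the model is a genuinely driven (futile)
cycle, reaching detailed balance only at ``G = -E/2`` (or for ``E = 0`` at
``G = 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bulk import BulkUnitCell
from .generator import build_generator, steady_state
from .modes import column_marginals, fit_decay, region_from_columns, RegionProjector
from .network import RateEdge, StateNode, StochasticNetwork

__all__ = [
    "LadderSpec",
    "AdaptationSpec",
    "ProofreadingSpec",
    "DisorderSpec",
    "ModelError",
    "build_two_bulk_ladder",
    "build_adaptation_network",
    "bulk_limits",
    "adaptation_sweep",
    "build_proofreading_chain",
    "proofreading_cell",
    "apply_disorder",
    "cycle_affinity",
    "interface_region",
]


class ModelError(ValueError):
    """Raised for invalid model specifications."""


def sigmoid(x: float) -> float:
    # guard against overflow for strongly saturated arguments
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


# ---------------------------------------------------------------------------
# two-bulk ladder (the reference geometry)
# ---------------------------------------------------------------------------


@dataclass
class LadderSpec:
    """Two translationally invariant bulks joined by interpolating interfaces.

    ``interface_rule`` is one of ``linear``, ``sigmoid`` or ``explicit`` (the
    latter takes mixing weights in ``interface_table``, one per interface
    column).  The periodic variant contains a second interface at the seam.
    """

    rows: int
    columns_per_bulk: int
    left_cell: BulkUnitCell
    right_cell: BulkUnitCell
    interface_columns: int = 1
    interface_rule: str = "sigmoid"
    interface_table: Sequence[float] | None = None
    boundary: str = "open"

    def __post_init__(self) -> None:
        if self.columns_per_bulk < 4:
            raise ModelError("columns_per_bulk must be at least 4")
        if self.interface_columns < 1:
            raise ModelError("interface width must be at least 1")
        if self.left_cell.n_internal != self.rows or self.right_cell.n_internal != self.rows:
            raise ModelError(
                f"cells must have {self.rows} internal states to match rows"
            )
        if self.interface_rule not in ("linear", "sigmoid", "explicit"):
            raise ModelError(f"unknown interface rule {self.interface_rule!r}")
        if self.interface_rule == "explicit":
            if (self.interface_table is None
                    or len(self.interface_table) != self.interface_columns):
                raise ModelError(
                    "explicit interface rule needs one mixing weight per "
                    "interface column"
                )


def _interface_mix(spec: LadderSpec) -> list[float]:
    w = spec.interface_columns
    if spec.interface_rule == "explicit":
        return [float(s) for s in spec.interface_table]
    if spec.interface_rule == "linear":
        return [(i + 1.0) / (w + 1.0) for i in range(w)]
    centre = (w - 1) / 2.0
    return [sigmoid(8.0 * (i - centre) / w) for i in range(w)]


def _mix_cell(left: BulkUnitCell, right: BulkUnitCell, s: float
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        (1 - s) * left.intra + s * right.intra,
        (1 - s) * left.hop_plus + s * right.hop_plus,
        (1 - s) * left.hop_minus + s * right.hop_minus,
    )


def build_two_bulk_ladder(spec: LadderSpec) -> StochasticNetwork:
    """Assemble the two-bulk network of the reference geometry.

    Columns are laid out left bulk | interface A | right bulk (| interface B
    wrapping to the left bulk when periodic).  A hop edge takes its rate
    from its source column's (interpolated) cell.  Interface column lists
    are recorded in the metadata for region construction.
    """
    n = spec.columns_per_bulk
    w = spec.interface_columns
    mix_a = _interface_mix(spec)
    # per-column mixing weight s in [0, 1]; 0 = left cell, 1 = right cell
    s_cols: list[float] = [0.0] * n + mix_a + [1.0] * n
    iface_a = list(range(n, n + w))
    iface_b: list[int] = []
    if spec.boundary == "periodic":
        s_cols += [1.0 - s for s in mix_a]
        iface_b = list(range(2 * n + w, 2 * n + 2 * w))
    c_tot = len(s_cols)

    def tag_of(c: int) -> str:
        if c in iface_a or c in iface_b:
            return "interface"
        return "bulk_L" if c < n else ("bulk_R" if c < 2 * n + w else "interface")

    nodes = [
        StateNode(f"c{c}r{r}", x=c, row=r, tag=tag_of(c))
        for c in range(c_tot)
        for r in range(spec.rows)
    ]
    edges: list[RateEdge] = []
    for c, s in enumerate(s_cols):
        intra, hp, hm = _mix_cell(spec.left_cell, spec.right_cell, s)
        for i in range(spec.rows):
            for j in range(spec.rows):
                if i != j and intra[i, j] > 0:
                    edges.append(RateEdge(f"c{c}r{j}", f"c{c}r{i}", intra[i, j], 0))
        right_nb = c + 1 if c + 1 < c_tot else (0 if spec.boundary == "periodic" else None)
        left_nb = c - 1 if c - 1 >= 0 else (c_tot - 1 if spec.boundary == "periodic" else None)
        if right_nb is not None:
            for i in range(spec.rows):
                for j in range(spec.rows):
                    if hp[i, j] > 0:
                        edges.append(
                            RateEdge(f"c{c}r{j}", f"c{right_nb}r{i}", hp[i, j], +1)
                        )
        if left_nb is not None:
            for i in range(spec.rows):
                for j in range(spec.rows):
                    if hm[i, j] > 0:
                        edges.append(
                            RateEdge(f"c{c}r{j}", f"c{left_nb}r{i}", hm[i, j], -1)
                        )
    meta = {
        "builder": "two_bulk_ladder",
        "rows": spec.rows,
        "columns_per_bulk": n,
        "n_columns": c_tot,
        "interface_columns": w,
        "interface_rule": spec.interface_rule,
        "interface_A_cols": iface_a,
        "interface_B_cols": iface_b,
    }
    return StochasticNetwork(nodes, edges, spec.boundary, meta)


def interface_region(net: StochasticNetwork, which: str = "A", pad: int = 3
                     ) -> RegionProjector:
    """Region projector around a ladder interface, padded by ``pad`` columns.

    The interface column lists come from the builder metadata; periodic
    networks wrap the padding around the seam.
    """
    key = f"interface_{which}_cols"
    cols = net.metadata.get(key)
    if not cols:
        raise ModelError(f"network metadata has no {key}")
    c_tot = net.metadata["n_columns"]
    padded: set[int] = set()
    for c in range(min(cols) - pad, max(cols) + pad + 1):
        padded.add(c % c_tot if net.boundary == "periodic" else c)
    padded = {c for c in padded if 0 <= c < c_tot}
    return region_from_columns(net, padded)


# ---------------------------------------------------------------------------
# chemosensory adaptation
# ---------------------------------------------------------------------------


@dataclass
class AdaptationSpec:
    """Parameters of the two-row adaptation lattice (see module docstring).

    ``a0_bias`` multiplies the activation rate by ``exp(a0_bias)``, shifting
    the activity set point away from 1/2 without touching the topology.
    """

    M: int
    E: float
    S: float
    G: float
    omega_a: float = 1.0
    omega_m: float = 1.0
    a0_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.M < 4:
            raise ModelError("need at least 4 methylation levels")
        if not (self.omega_a > 0 and self.omega_m > 0):
            raise ModelError("omega_a and omega_m must be positive")
        if not (0 < self.S < self.M):
            raise ModelError(
                f"S = {self.S} must lie inside (0, {self.M}) for an interior interface"
            )


def _flip_rates(spec: AdaptationSpec, m: int) -> tuple[float, float]:
    up = spec.omega_a * math.exp(spec.a0_bias) * sigmoid(spec.E * (m - spec.S))
    down = spec.omega_a * sigmoid(spec.E * (spec.S - m))
    return up, down


def build_adaptation_network(spec: AdaptationSpec) -> StochasticNetwork:
    """2 x M lattice of activity (rows) and methylation (columns)."""
    nodes = []
    for m in range(spec.M):
        near = abs(m - spec.S) <= 2
        tag = "interface" if near else ("bulk_L" if m < spec.S else "bulk_R")
        nodes.append(StateNode(f"m{m}a0", x=m, row=0, tag=tag))
        nodes.append(StateNode(f"m{m}a1", x=m, row=1, tag=tag))
    edges: list[RateEdge] = []
    eg = math.exp(-spec.G)
    for m in range(spec.M):
        up, down = _flip_rates(spec, m)
        if up > 0:
            edges.append(RateEdge(f"m{m}a0", f"m{m}a1", up, 0))
        if down > 0:
            edges.append(RateEdge(f"m{m}a1", f"m{m}a0", down, 0))
        if m + 1 < spec.M:
            # inactive row methylates, active row demethylates
            edges.append(RateEdge(f"m{m}a0", f"m{m + 1}a0", spec.omega_m, +1))
            edges.append(RateEdge(f"m{m + 1}a0", f"m{m}a0", spec.omega_m * eg, -1))
            edges.append(RateEdge(f"m{m + 1}a1", f"m{m}a1", spec.omega_m, -1))
            edges.append(RateEdge(f"m{m}a1", f"m{m + 1}a1", spec.omega_m * eg, +1))
    meta = {
        "builder": "adaptation",
        "M": spec.M, "E": spec.E, "S": spec.S, "G": spec.G,
        "omega_a": spec.omega_a, "omega_m": spec.omega_m,
        "a0_bias": spec.a0_bias,
    }
    return StochasticNetwork(nodes, edges, "open", meta)


def bulk_limits(spec: AdaptationSpec, floor_distance: float = 10.0,
                sat_tol: float = 1e-6) -> tuple[BulkUnitCell, BulkUnitCell]:
    """Saturated unit cells of the adaptation lattice far from the interface.

    The left (m << S) and right (m >> S) limits replace the sigmoids by 0/1;
    strictly vanishing flip rates are floored at
    ``omega_a * exp(-|E| * floor_distance)`` to keep the cells irreducible.
    Raises :class:`ModelError` when the sigmoids do not saturate to
    ``sat_tol`` within the lattice (|E| too small for M).
    """
    d_left = spec.S            # distance from m = 0 to the crossover
    d_right = spec.M - 1 - spec.S
    worst = sigmoid(-abs(spec.E) * min(d_left, d_right))
    if worst > sat_tol:
        raise ModelError(
            f"sigmoids saturate only to {worst:.2e} (> {sat_tol:g}) at the "
            f"lattice ends; increase E or M"
        )
    floor = spec.omega_a * math.exp(-abs(spec.E) * floor_distance)
    bias = math.exp(spec.a0_bias)
    eg = math.exp(-spec.G)
    hop_plus = np.diag([spec.omega_m, spec.omega_m * eg])   # rows: a=0, a=1
    hop_minus = np.diag([spec.omega_m * eg, spec.omega_m])

    def cell(up: float, down: float) -> BulkUnitCell:
        intra = np.array([[0.0, down], [up, 0.0]])  # intra[i, j] = rate j -> i
        return BulkUnitCell(2, intra, hop_plus.copy(), hop_minus.copy())

    left = cell(up=floor * bias, down=spec.omega_a)
    right = cell(up=spec.omega_a * bias, down=floor)
    return left, right


def adaptation_sweep(spec: AdaptationSpec, s_values: Iterable[float],
                     fit_margin: int = 5) -> pd.DataFrame:
    """Exact steady-state observables across chemoattractant levels.

    For each ``S`` the stationary distribution is solved exactly and reduced
    to the mean activity, the mean methylation level and exponential-decay
    fits of the methylation marginal on both sides of the interface
    (``fit_margin`` columns away from the crossover and the reflecting
    ends).  Columns: S, mean_activity, mean_methylation, kappa_left,
    kappa_right, r2.
    """
    rows = []
    for s in s_values:
        sp = AdaptationSpec(spec.M, spec.E, float(s), spec.G,
                            spec.omega_a, spec.omega_m, spec.a0_bias)
        net = build_adaptation_network(sp)
        p = steady_state(build_generator(net))
        act = sum(p[net.index(f"m{m}a1")] for m in range(sp.M))
        marg = column_marginals(net, p)
        mean_m = sum(m * q for m, q in marg.items())
        s0 = int(round(s))
        left_cols = range(2, s0 - fit_margin + 1)
        right_cols = range(s0 + fit_margin, sp.M - 2)
        kl, r2l = fit_decay(marg, list(left_cols)) if len(left_cols) >= 4 else (float("nan"), float("nan"))
        kr, r2r = fit_decay(marg, list(right_cols)) if len(right_cols) >= 4 else (float("nan"), float("nan"))
        rows.append((float(s), float(act), float(mean_m), kl, kr,
                     min(r2l, r2r)))
    return pd.DataFrame(rows, columns=[
        "S", "mean_activity", "mean_methylation",
        "kappa_left", "kappa_right", "r2",
    ])


# ---------------------------------------------------------------------------
# kinetic proofreading
# ---------------------------------------------------------------------------


@dataclass
class ProofreadingSpec:
    """Uniform birth-death chain from reactants (column 0) to products."""

    n_stages: int
    forward: float
    backward: float
    substrate_label: str = "R"

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ModelError("need at least 2 stages")
        if not (self.forward > 0 and self.backward > 0):
            raise ModelError("rates must be positive")
        if self.substrate_label not in ("R", "W"):
            raise ModelError("substrate_label must be 'R' or 'W'")


def build_proofreading_chain(spec: ProofreadingSpec) -> StochasticNetwork:
    """Open chain of ``n_stages + 1`` states with uniform rates."""
    n = spec.n_stages
    nodes = [
        StateNode(f"s{i}", x=i, row=0,
                  tag="vacuum_boundary" if i in (0, n) else "bulk_L")
        for i in range(n + 1)
    ]
    edges = []
    for i in range(n):
        edges.append(RateEdge(f"s{i}", f"s{i + 1}", spec.forward, +1))
        edges.append(RateEdge(f"s{i + 1}", f"s{i}", spec.backward, -1))
    meta = {"builder": "proofreading", "n_stages": n,
            "forward": spec.forward, "backward": spec.backward,
            "substrate": spec.substrate_label}
    return StochasticNetwork(nodes, edges, "open", meta)


def proofreading_cell(spec: ProofreadingSpec) -> BulkUnitCell:
    """The B = 1 bulk unit cell of the proofreading chain."""
    return BulkUnitCell(1, np.zeros((1, 1)),
                        np.array([[spec.forward]]),
                        np.array([[spec.backward]]))


# ---------------------------------------------------------------------------
# quenched disorder and cycle diagnostics
# ---------------------------------------------------------------------------


@dataclass
class DisorderSpec:
    """Multiplicative log-uniform quenched disorder of strength ``delta``."""

    strength: float
    law: str = "log_uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ModelError("disorder strength must be non-negative")
        if self.strength >= 5:
            raise ModelError("disorder strength >= 5 would swamp the log-rates")
        if self.law != "log_uniform":
            raise ModelError(f"unknown disorder law {self.law!r}")


def apply_disorder(net: StochasticNetwork, d: DisorderSpec) -> StochasticNetwork:
    """Multiply each edge rate by ``exp(u)``, u ~ U(-delta, delta).

    Draws follow the network's edge order from a generator seeded with
    ``d.seed``, so a given (network, spec) pair always yields the same
    disordered network; ``delta = 0`` returns a bit-identical copy.
    """
    rng = np.random.default_rng(d.seed)
    u = rng.uniform(-d.strength, d.strength, len(net.edges))
    rates = [e.rate * math.exp(ui) for e, ui in zip(net.edges, u)]
    return net.with_rates(rates, {"disorder_strength": d.strength,
                                  "disorder_seed": d.seed})


def cycle_affinity(net: StochasticNetwork, cycle: Sequence[str]) -> float:
    """ln of the forward/backward rate product around a closed node cycle.

    Zero on every cycle iff the network satisfies detailed balance
    (Kolmogorov's criterion).  ``cycle`` lists node ids; the closing edge
    back to the first node is implied.
    """
    rate = {(e.src, e.dst): e.rate for e in net.edges}
    total = 0.0
    nodes = list(cycle)
    for a, b in zip(nodes, nodes[1:] + nodes[:1]):
        if (a, b) not in rate or (b, a) not in rate:
            raise ModelError(f"cycle edge {a!r}<->{b!r} missing from network")
        total += math.log(rate[(a, b)]) - math.log(rate[(b, a)])
    return total
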