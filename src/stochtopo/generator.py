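"""Master-equation generators, tilted generators and their spectra.

Convention (fixed once, inherited by every other module): the master equation
is ``dp/dt = W p`` with ``W[i, j] = rate(j -> i)`` for ``i != j`` and
``W[j, j] = -sum_i rate(j -> i)``, so every column of ``W`` sums to zero.

Tilting by the current-counting field ``lam`` multiplies each off-diagonal
entry by ``exp(lam * disp)`` where ``disp`` is the horizontal displacement of
the jump; the diagonal is never tilted.  The largest eigenvalue of the tilted
generator is the scaled cumulant generating function (SCGF) ``e(lam)`` of the
time-integrated horizontal current, with ``e(0) = 0`` and ``e'(0) = J`` the
mean current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import NetworkError, StochasticNetwork

__all__ = [
    "GeneratorMatrix",
    "TiltedGenerator",
    "SpectralResult",
    "build_generator",
    "tilt_generator",
    "steady_state",
    "scgf",
    "mean_current",
    "spectral_gap",
]

#: above this size the leading eigenpair is obtained iteratively (ARPACK)
DENSE_CUTOFF = 500

#: absolute tolerance for exact zero modes (lam = 0)
ZERO_TOL = 1e-10


@dataclass
class GeneratorMatrix:
    """Dense generator ``W`` with the node order it was built in."""

    entries: np.ndarray
    node_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass
class TiltedGenerator:
    """Tilted current matrix ``W(lam)``; equals the generator at lam = 0."""

    entries: np.ndarray
    node_ids: tuple[str, ...]
    lam: float

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass
class SpectralResult:
    """Leading spectral data of ``W(lam)``.

    ``e_lam`` is the eigenvalue of largest real part (the SCGF),
    ``leading_right`` the matching right eigenvector normalised to unit sum,
    ``leading_left`` the left eigenvector normalised so that
    ``leading_left @ leading_right = 1``, and ``gap`` the distance between the
    real parts of the two leading eigenvalues.
    """

    e_lam: float
    leading_right: np.ndarray
    leading_left: np.ndarray
    gap: float
    lam: float


def build_generator(net: StochasticNetwork) -> GeneratorMatrix:
    """Assemble the master-equation generator of ``net``.

    Columns sum to zero by construction; the off-diagonal entry ``(i, j)``
    equals the rate of the edge ``j -> i`` (zero if absent).
    """
    n = net.n_states
    w = np.zeros((n, n))
    for e in net.edges:
        j = net.index(e.src)
        i = net.index(e.dst)
        w[i, j] = e.rate
        w[j, j] -= e.rate
    return GeneratorMatrix(w, tuple(nd.id for nd in net.nodes))


def tilt_generator(gen: GeneratorMatrix, net: StochasticNetwork, lam: float
                   ) -> TiltedGenerator:
    """Tilt ``gen`` by the current field ``lam``.

    Off-diagonals are scaled by ``exp(lam * disp)``; the diagonal stays the
    untilted outflow, so ``lam = 0`` reproduces the generator exactly.
    """
    w = gen.entries.copy()
    if lam != 0.0:
        for e in net.edges:
            if e.disp != 0:
                j = net.index(e.src)
                i = net.index(e.dst)
                w[i, j] = e.rate * np.exp(lam * e.disp)
    return TiltedGenerator(w, gen.node_ids, float(lam))


def steady_state(gen: GeneratorMatrix, tol: float = ZERO_TOL) -> np.ndarray:
    """Stationary distribution: the unique probability vector with ``W p = 0``.

    Uses the subtraction-free GTH (Grassmann-Taksar-Heyman) state
    elimination, which stays entrywise accurate even for metastable chains
    whose wells are coupled through exponentially small rates (where an
    SVD null space would appear degenerate).  Raises :class:`NetworkError`
    if elimination stalls, which happens exactly when the chain is
    reducible (null space dimension != 1).
    """
    # row convention internally: a[i, j] = rate i -> j
    a = gen.entries.T.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    if n == 1:
        return np.ones(1)
    scale = np.max(a) if np.max(a) > 0 else 1.0
    s = np.empty(n)
    for m in range(n - 1, 0, -1):
        s[m] = a[m, :m].sum()
        if s[m] <= 0:
            raise NetworkError(
                "generator null space has dimension != 1: state "
                f"{gen.node_ids[m]!r} unreachable-from below during GTH "
                "elimination (reducible network)"
            )
        f = a[:m, m] / s[m]
        a[:m, :m] += np.outer(f, a[m, :m])
        np.fill_diagonal(a[:m, :m], 0.0)
    p = np.zeros(n)
    p[0] = 1.0
    for m in range(1, n):
        p[m] = (p[:m] @ a[:m, m]) / s[m]
    p /= p.sum()
    resid = np.max(np.abs(gen.entries @ p))
    if resid > 1e-10 * max(1.0, scale):
        raise NetworkError(f"steady-state residual too large: {resid:g}")
    return p


def _leading_pair_dense(w: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, float]:
    vals, vecs = np.linalg.eig(w)
    order = np.argsort(vals.real)[::-1]
    lead = order[0]
    e_lam = vals[lead].real
    right = vecs[:, lead].real
    lvals, lvecs = np.linalg.eig(w.T)
    li = int(np.argmin(np.abs(lvals - vals[lead])))
    left = lvecs[:, li].real
    # gap: skip eigenvalues degenerate with the leader (complex pairs share
    # a real part)
    reals = np.sort(vals.real)[::-1]
    rest = reals[reals < e_lam - 1e-13 * max(1.0, abs(e_lam))]
    gap = float(e_lam - rest[0]) if rest.size else 0.0
    return float(e_lam), right, left, gap


def _leading_pair_sparse(w: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, float]:
    ws = sp.csr_matrix(w)
    try:
        vals, vecs = spla.eigs(ws, k=2, which="LR", tol=1e-12, maxiter=5000)
        lvals, lvecs = spla.eigs(ws.T.tocsr(), k=1, which="LR", tol=1e-12,
                                 maxiter=5000)
    except spla.ArpackNoConvergence as exc:  # pragma: no cover - rare
        raise NetworkError(
            f"eigensolver failed to converge: {exc} "
            f"(converged {len(exc.eigenvalues)} eigenvalues)"
        ) from exc
    order = np.argsort(vals.real)[::-1]
    e_lam = float(vals[order[0]].real)
    right = vecs[:, order[0]].real
    left = lvecs[:, 0].real
    gap = float(e_lam - vals[order[1]].real)
    return e_lam, right, left, gap


def scgf(net: StochasticNetwork, lam: float) -> SpectralResult:
    """Scaled cumulant generating function ``e(lam)`` and leading eigenpair.

    On an open network a nonzero ``lam`` still tilts the seam-free edges; a
    warning flags that the current field is then not conjugate to a winding
    current.
    """
    if lam != 0.0 and net.boundary == "open":
        warnings.warn(
            "tilting an open network: lam is not conjugate to a periodic "
            "winding current",
            stacklevel=2,
        )
    gen = build_generator(net)
    tilted = tilt_generator(gen, net, lam)
    if tilted.n <= DENSE_CUTOFF:
        e_lam, right, left, gap = _leading_pair_dense(tilted.entries)
    else:
        e_lam, right, left, gap = _leading_pair_sparse(tilted.entries)
    # orient and normalise: the leading right vector of a tilted Metzler
    # matrix is positive (Perron-Frobenius)
    if right.sum() < 0:
        right = -right
    right = np.abs(right) if lam == 0.0 else right
    right = right / right.sum()
    denom = left @ right
    if abs(denom) < 1e-300:
        raise NetworkError("left/right leading eigenvectors are orthogonal")
    left = left / denom
    return SpectralResult(e_lam, right, left, gap, float(lam))


def mean_current(net: StochasticNetwork, p: np.ndarray) -> float:
    """Mean horizontal current ``J = sum_edges rate * p(src) * disp``.

    ``p`` must be the steady state of ``net``; then ``J`` equals ``e'(0)``.
    """
    j = 0.0
    for e in net.edges:
        if e.disp != 0:
            j += e.rate * p[net.index(e.src)] * e.disp
    return float(j)


def spectral_gap(net: StochasticNetwork) -> float:
    """Gap between the real parts of the two slowest relaxation eigenvalues.

    For the untilted generator the leading eigenvalue is 0; the gap is the
    slowest nonzero relaxation rate and bounds the time to reach the steady
    state.
    """
    res = scgf(net, 0.0)
    return float(res.gap)
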