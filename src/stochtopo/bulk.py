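"""Topology of translationally invariant bulk unit cells.

A bulk is a column of ``B`` internal states replicated along the horizontal
axis, with within-column rates ``intra``, rightward hopping rates
``hop_plus`` (column c -> c+1) and leftward rates ``hop_minus``.  Its tilted
Bloch matrix is

    W(k, lam) = intra + hop_plus * e^{ik + lam} + hop_minus * e^{-ik - lam} + D,

with ``D`` the diagonal of total untilted outflow.  The winding number of the
phase of ``det W(k, lam)`` over one Brillouin zone is the bulk topological
invariant; a mismatch of windings across an interface forces zero modes of
the tilted generator localized there.

Orientation: the winding is taken along increasing ``k``, so that a
rightward-biased single-row bulk has w = +1 for lam > 0.  Equivalently, with
``z = e^{ik}``, w equals the number of roots of ``P(z) = z^B det W(z, lam)``
inside the unit circle minus ``B`` (argument principle) — implemented
independently in :func:`winding_oracle_roots`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BulkUnitCell",
    "BlochMatrix",
    "WindingResult",
    "TopologicalWindow",
    "BulkTopologyError",
    "BandTouchingError",
    "MarginalBulkWarning",
    "bloch_matrix",
    "winding_number",
    "winding_oracle_roots",
    "topological_charge",
    "lambda_window",
    "bulk_decay_rates",
]

#: relative threshold below which |det| is treated as a band touching
BAND_TOUCH_RTOL = 1e-10

#: default number of k-points for the phase integral
DEFAULT_N_K = 512

#: default lambda offset at which single-side windings are probed
DEFAULT_EPS = 0.05

#: default bisection tolerance for window endpoints
WINDOW_TOL = 1e-6


class BulkTopologyError(ValueError):
    """Raised for invalid unit cells or degenerate winding evaluations."""


class BandTouchingError(BulkTopologyError):
    """det W(k, lam) vanishes on the k-circle: the winding is undefined."""


class MarginalBulkWarning(UserWarning):
    """All determinant roots sit on the unit circle (diffusive bulk)."""


@dataclass(frozen=True)
class BulkUnitCell:
    """Repeating unit of a translationally invariant bulk.

    ``intra[i, j]`` is the within-column rate j -> i (zero diagonal);
    ``hop_plus[i, j]`` the rate from state j in column c to state i in
    column c+1; ``hop_minus[i, j]`` the corresponding leftward rate.
    """

    n_internal: int
    intra: np.ndarray
    hop_plus: np.ndarray
    hop_minus: np.ndarray

    def __post_init__(self) -> None:
        b = self.n_internal
        for name in ("intra", "hop_plus", "hop_minus"):
            m = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, m)
            if m.shape != (b, b):
                raise BulkTopologyError(f"{name} must be {b}x{b}, got {m.shape}")
            if np.any(m < 0):
                raise BulkTopologyError(f"{name} has negative entries")
        if np.any(np.diag(self.intra) != 0):
            raise BulkTopologyError("intra must have zero diagonal")
        if not np.any(self.hop_plus > 0):
            raise BulkTopologyError("hop_plus has no positive entry (bulk disconnected)")
        if not np.any(self.hop_minus > 0):
            raise BulkTopologyError("hop_minus has no positive entry (bulk disconnected)")

    @property
    def outflow_diag(self) -> np.ndarray:
        """Diagonal D of total untilted outflow per internal state."""
        total = self.intra + self.hop_plus + self.hop_minus
        return -np.diag(total.sum(axis=0))

    def mirror(self) -> "BulkUnitCell":
        """Left-right mirror image (hop_plus and hop_minus exchanged)."""
        return BulkUnitCell(self.n_internal, self.intra.copy(),
                            self.hop_minus.copy(), self.hop_plus.copy())


@dataclass
class BlochMatrix:
    entries: np.ndarray
    k: float
    lam: float


@dataclass
class WindingResult:
    """Winding number with the phase trajectory that produced it."""

    w: int
    lam: float
    min_abs_det: float
    theta_trajectory: np.ndarray = field(repr=False)


@dataclass
class TopologicalWindow:
    """Protected interval (lam_minus, lam_plus) with winding mismatch dw.

    ``eta_left`` / ``eta_right`` are the bulk localization lengths (inverse
    of the smallest decay rate of each cell's determinant roots at lam = 0);
    ``inf`` for a marginal bulk, ``nan`` for an empty window.
    """

    lam_minus: float
    lam_plus: float
    dw: int
    eta_left: float
    eta_right: float

    @property
    def is_empty(self) -> bool:
        return self.dw == 0

    @classmethod
    def empty(cls) -> "TopologicalWindow":
        return cls(0.0, 0.0, 0, float("nan"), float("nan"))


def bloch_matrix(cell: BulkUnitCell, k: float, lam: float) -> BlochMatrix:
    """Fourier-transformed tilted bulk generator at wave vector ``k``."""
    entries = (
        cell.intra.astype(complex)
        + cell.hop_plus * np.exp(1j * k + lam)
        + cell.hop_minus * np.exp(-1j * k - lam)
        + cell.outflow_diag
    )
    return BlochMatrix(entries, float(k), float(lam))


def _det_on_grid(cell: BulkUnitCell, lam: float, n_k: int) -> tuple[np.ndarray, np.ndarray]:
    k = np.linspace(0.0, 2.0 * np.pi, n_k + 1)
    base = (cell.intra + cell.outflow_diag).astype(complex)
    zp = np.exp(1j * k + lam)
    zm = np.exp(-1j * k - lam)
    mats = (
        base[None, :, :]
        + cell.hop_plus[None, :, :] * zp[:, None, None]
        + cell.hop_minus[None, :, :] * zm[:, None, None]
    )
    return k, np.linalg.det(mats)


def winding_number(cell: BulkUnitCell, lam: float, n_k: int = DEFAULT_N_K
                   ) -> WindingResult:
    """Winding number of the Bloch determinant phase over one Brillouin zone.

    The phase is unwrapped along a uniform k-grid of ``n_k`` intervals; the
    result is ``(theta(2*pi) - theta(0)) / (2*pi)`` rounded to the nearest
    integer.  Raises :class:`BandTouchingError` if ``|det|`` dips below
    ``1e-10`` of its maximum (including the mandatory zero at lam = 0).
    """
    if lam == 0.0:
        raise BulkTopologyError(
            "winding number is undefined at lam = 0 (det vanishes at k = 0); "
            "evaluate at a small offset instead"
        )
    k, dets = _det_on_grid(cell, lam, n_k)
    abs_det = np.abs(dets)
    max_det = abs_det.max()
    min_det = abs_det.min()
    if min_det <= BAND_TOUCH_RTOL * max_det:
        k_bad = k[int(np.argmin(abs_det))]
        raise BandTouchingError(
            f"|det W(k, lam)| ~ {min_det:.3e} at k = {k_bad:.6f} "
            f"(lam = {lam:g}): band touching, winding undefined"
        )
    theta = np.unwrap(np.angle(dets))
    steps = np.abs(np.diff(theta))
    if np.any(steps > 0.9 * np.pi):
        raise BulkTopologyError(
            f"phase step of {steps.max():.3f} rad exceeds the unwrap safety "
            f"margin at n_k = {n_k}; refine the k-grid"
        )
    w_raw = (theta[-1] - theta[0]) / (2.0 * np.pi)
    w = int(round(w_raw))
    if abs(w - w_raw) > 1e-6:
        raise BulkTopologyError(
            f"winding integral {w_raw:.8f} is not an integer; refine the grid"
        )
    return WindingResult(w, float(lam), float(min_det), theta)


def _det_poly_coeffs(cell: BulkUnitCell, lam: float) -> np.ndarray:
    """Coefficients (ascending) of P(z) = z^B det W(z, lam).

    Each entry of ``z * W(z)`` is a quadratic in z, so P has degree at most
    2B; its coefficients are recovered exactly by sampling det on 2B + 1
    roots of unity and taking a DFT.
    """
    b = cell.n_internal
    n = 2 * b + 1
    zs = np.exp(2j * np.pi * np.arange(n) / n)
    base = (cell.intra + cell.outflow_diag).astype(complex)
    vals = np.empty(n, dtype=complex)
    for j, z in enumerate(zs):
        m = base + cell.hop_plus * (z * np.exp(lam)) + cell.hop_minus * (np.exp(-lam) / z)
        vals[j] = np.linalg.det(m) * z**b
    coeffs = np.fft.fft(vals) / n
    if np.max(np.abs(coeffs.imag)) > 1e-9 * max(1.0, np.max(np.abs(coeffs))):
        raise BulkTopologyError("determinant polynomial has non-real coefficients")
    return coeffs.real


def winding_oracle_roots(cell: BulkUnitCell, lam: float
                         ) -> tuple[int, np.ndarray]:
    """Winding number via the argument principle on determinant roots.

    Expresses ``det W(z, lam)`` (z = e^{ik}) as a Laurent polynomial, counts
    the roots of ``P(z) = z^B det W(z, lam)`` strictly inside the unit circle
    and subtracts the pole order ``B``.  Independent of the phase-integral
    route in :func:`winding_number` and must agree with it on every valid
    input.
    """
    if lam == 0.0:
        raise BulkTopologyError("winding oracle is undefined at lam = 0")
    b = cell.n_internal
    coeffs = _det_poly_coeffs(cell, lam)
    scale = np.max(np.abs(coeffs))
    # trim vanishing leading coefficients (degree may be below 2B)
    top = len(coeffs)
    while top > 1 and abs(coeffs[top - 1]) <= 1e-12 * scale:
        top -= 1
    poly = coeffs[:top]
    roots = np.roots(poly[::-1])
    on_circle = np.abs(np.abs(roots) - 1.0) < 1e-8
    if np.any(on_circle):
        raise BandTouchingError(
            f"determinant root on the unit circle at lam = {lam:g}: "
            f"{roots[on_circle]}"
        )
    # degree deficit relative to 2B means roots at infinity, which are
    # outside the unit circle and do not contribute
    inside = int(np.sum(np.abs(roots) < 1.0))
    charge = inside - b
    return charge, roots


def topological_charge(cell: BulkUnitCell, eps: float = DEFAULT_EPS) -> int:
    """Single winding label for a bulk terminating on vacuum at both ends.

    Returns ``w(+eps) + w(-eps)``: +1 for a rightward-biased bulk (density
    pushed to the right edge), -1 for leftward, 0 for an axis-unbiased bulk.
    """
    if not eps > 0:
        raise BulkTopologyError("eps must be positive")
    wp = winding_number(cell, +eps).w
    wm = winding_number(cell, -eps).w
    return wp + wm


def bulk_decay_rates(cell: BulkUnitCell, circle_tol: float = 1e-6
                     ) -> list[float]:
    """Exponential rates available to steady-state profiles in this bulk.

    Roots ``z*`` of ``det W(z, lam=0) = 0`` off the unit circle give decay
    rates ``|ln|z*||``; any exponentially localized steady-state profile in
    the bulk interior decays at one of these rates.  Warns with
    :class:`MarginalBulkWarning` if every root is on the circle.
    """
    b = cell.n_internal
    coeffs = _det_poly_coeffs(cell, 0.0)
    scale = np.max(np.abs(coeffs))
    top = len(coeffs)
    while top > 1 and abs(coeffs[top - 1]) <= 1e-12 * scale:
        top -= 1
    roots = np.roots(coeffs[:top][::-1])
    rates = [
        float(abs(np.log(abs(z)))) for z in roots
        if abs(z) > 0 and abs(abs(z) - 1.0) > circle_tol
    ]
    if not rates:
        warnings.warn(
            "all determinant roots lie on the unit circle: marginal "
            "(diffusive) bulk with no exponential localization",
            MarginalBulkWarning,
            stacklevel=2,
        )
    return sorted(rates)


def _winding_pair(left: BulkUnitCell, right: BulkUnitCell, lam: float,
                  n_k: int) -> tuple[int, int]:
    return winding_number(left, lam, n_k).w, winding_number(right, lam, n_k).w


def _first_transition(left: BulkUnitCell, right: BulkUnitCell,
                      ref: tuple[int, int], start: float, stop: float,
                      tol: float, n_k: int, n_scan: int = 200) -> float | None:
    """Smallest |lam| in (start, stop] where either bulk winding changes.

    ``start``/``stop`` share a sign; scans a uniform grid to bracket the
    first change, then bisects to ``tol``.  A band touching encountered
    during the scan is itself a transition point.
    """

    def changed(lam: float) -> bool:
        try:
            return _winding_pair(left, right, lam, n_k) != ref
        except BandTouchingError:
            return True

    grid = np.linspace(start, stop, n_scan + 1)
    lo = grid[0]
    hi = None
    for lam in grid[1:]:
        if changed(lam):
            hi = lam
            break
        lo = lam
    if hi is None:
        return None
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        if changed(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def lambda_window(left: BulkUnitCell, right: BulkUnitCell,
                  search_range: float = 5.0, tol: float = WINDOW_TOL,
                  n_k: int = DEFAULT_N_K) -> TopologicalWindow:
    """Protected window (lam_minus, lam_plus) of nonzero winding mismatch.

    The mismatch ``dw = w_L - w_R`` is evaluated just off lam = 0 on both
    sides; if it vanishes there, an empty-window marker is returned.  The
    endpoints are the nearest winding transitions of either bulk, located by
    bisection to ``tol``.  Localization lengths ``eta`` are taken from each
    bulk's determinant-root decay rates at lam = 0.
    """
    probe = min(DEFAULT_EPS, search_range / 10.0)
    ref_p = _winding_pair(left, right, +probe, n_k)
    ref_m = _winding_pair(left, right, -probe, n_k)
    dw_p = ref_p[0] - ref_p[1]
    dw_m = ref_m[0] - ref_m[1]
    if dw_p == 0 and dw_m == 0:
        return TopologicalWindow.empty()
    lam_plus = _first_transition(left, right, ref_p, probe, search_range, tol, n_k)
    lam_minus = _first_transition(left, right, ref_m, -probe, -search_range, tol, n_k)
    if lam_plus is None or lam_minus is None:
        raise BulkTopologyError(
            f"no winding transition found within |lam| <= {search_range}; "
            "increase search_range"
        )
    # report dw at an offset safely inside the window
    off = min(DEFAULT_EPS, abs(lam_plus) / 2.0)
    wl, wr = _winding_pair(left, right, +off, n_k)
    dw = wl - wr

    def eta(cell: BulkUnitCell) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", MarginalBulkWarning)
            rates = bulk_decay_rates(cell)
        return 1.0 / min(rates) if rates else float("inf")

    return TopologicalWindow(float(lam_minus), float(lam_plus), int(dw),
                             eta(left), eta(right))
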