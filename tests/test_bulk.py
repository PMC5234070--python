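"""Bloch matrices, winding numbers, the argument-principle oracle and the
protected lambda window."""

import numpy as np
import pytest

from stochtopo import (
    BandTouchingError,
    BulkTopologyError,
    BulkUnitCell,
    bloch_matrix,
    bulk_decay_rates,
    lambda_window,
    topological_charge,
    winding_number,
    winding_oracle_roots,
)
from stochtopo.bulk import MarginalBulkWarning

from conftest import random_cell

LN2 = np.log(2.0)


def scalar_cell(p: float, q: float) -> BulkUnitCell:
    return BulkUnitCell(1, np.zeros((1, 1)), np.array([[p]]), np.array([[q]]))


# -- bloch matrix -----------------------------------------------------------


def test_scalar_bloch_formula():
    cell = scalar_cell(2.0, 1.0)
    k, lam = 0.7, 0.3
    b = bloch_matrix(cell, k, lam)
    expect = 2.0 * np.exp(1j * k + lam) + 1.0 * np.exp(-1j * k - lam) - 3.0
    assert b.entries[0, 0] == pytest.approx(expect, abs=1e-14)


def test_det_vanishes_at_origin_of_k_lam():
    rng = np.random.default_rng(3)
    cell = random_cell(rng, 3)
    assert abs(np.linalg.det(bloch_matrix(cell, 0.0, 0.0).entries)) < 1e-12


def test_bloch_periodic_in_k():
    cell = scalar_cell(1.5, 0.5)
    b1 = bloch_matrix(cell, 1.1, 0.2).entries
    b2 = bloch_matrix(cell, 1.1 + 2 * np.pi, 0.2).entries
    assert np.allclose(b1, b2, atol=1e-12)


def test_invalid_cells_rejected():
    with pytest.raises(BulkTopologyError, match="negative"):
        BulkUnitCell(1, np.zeros((1, 1)), np.array([[-1.0]]), np.array([[1.0]]))
    with pytest.raises(BulkTopologyError, match="hop_minus"):
        BulkUnitCell(1, np.zeros((1, 1)), np.array([[1.0]]), np.array([[0.0]]))
    with pytest.raises(BulkTopologyError, match="diagonal"):
        BulkUnitCell(1, np.ones((1, 1)), np.array([[1.0]]), np.array([[1.0]]))


# -- winding numbers --------------------------------------------------------


@pytest.mark.parametrize(
    "p, q, lam, expected",
    [
        (2.0, 1.0, +0.1, 1),
        (2.0, 1.0, -0.1, 0),
        (1.0, 2.0, -0.05, -1),
        (1.0, 2.0, +0.05, 0),
    ],
)
def test_scalar_winding_examples(p, q, lam, expected):
    assert winding_number(scalar_cell(p, q), lam).w == expected


def test_winding_rejects_zero_tilt():
    with pytest.raises(BulkTopologyError, match="lam = 0"):
        winding_number(scalar_cell(2.0, 1.0), 0.0)


def test_oracle_root_values():
    charge, roots = winding_oracle_roots(scalar_cell(2.0, 1.0), 0.1)
    assert charge == 1
    assert sorted(np.round(np.abs(roots), 3)) == [0.452, 0.905]
    charge, roots = winding_oracle_roots(scalar_cell(1.0, 1.0), 0.2)
    assert charge == 1
    assert np.allclose(np.abs(roots), np.exp(-0.2), atol=1e-6)


def test_winding_matches_oracle_on_random_cells():
    """Argument principle: the phase integral and the determinant-root count
    agree on 100 seeded random cells with B <= 3."""
    rng = np.random.default_rng(12345)
    checked = 0
    for _ in range(100):
        cell = random_cell(rng, int(rng.integers(1, 4)))
        for lam in (-0.3, -0.05, 0.05, 0.3):
            try:
                w = winding_number(cell, lam).w
                charge, _ = winding_oracle_roots(cell, lam)
            except BandTouchingError:
                continue
            assert w == charge, f"disagreement at lam={lam}"
            checked += 1
    assert checked >= 350


def test_winding_grid_independent():
    rng = np.random.default_rng(999)
    for _ in range(25):
        cell = random_cell(rng, int(rng.integers(1, 4)))
        for lam in (-0.3, 0.05):
            try:
                w_coarse = winding_number(cell, lam, n_k=512).w
                w_fine = winding_number(cell, lam, n_k=4096).w
            except BandTouchingError:
                continue
            assert w_coarse == w_fine


def test_winding_saturates_at_large_tilt():
    rng = np.random.default_rng(7)
    for _ in range(10):
        cell = random_cell(rng, 2)
        for sign in (+1, -1):
            assert (winding_number(cell, sign * 10.0).w
                    == winding_number(cell, sign * 20.0).w)


def test_mirror_antisymmetry():
    """A left-right mirrored cell satisfies w'(lam) = -w(-lam)."""
    rng = np.random.default_rng(11)
    for _ in range(10):
        cell = random_cell(rng, 2)
        mirrored = cell.mirror()
        for lam in (0.05, 0.4, -0.25):
            assert winding_number(mirrored, lam).w == -winding_number(cell, -lam).w


def test_rightward_bias_gives_positive_winding():
    assert winding_number(scalar_cell(2.0, 1.0), 0.05).w == +1


def test_transition_coincides_with_unit_circle_crossing():
    """The winding step at lam = ln 2 is where a determinant root crosses
    |z| = 1 (solvable cell: roots e^-lam and e^-lam / 2)."""
    cell = scalar_cell(2.0, 1.0)
    eps = 1e-4
    below = winding_oracle_roots(cell, -LN2 + eps)[1]
    above = winding_oracle_roots(cell, -LN2 - eps)[1]
    assert (np.abs(below).min() - 1.0) < 0 < (np.abs(above).min() - 1.0)
    assert winding_number(cell, -LN2 + eps).w != winding_number(cell, -LN2 - eps).w


# -- topological charge -----------------------------------------------------


@pytest.mark.parametrize(
    "p, q, expected",
    [(2.0, 1.0, +1), (1.0, 2.0, -1), (1.0, 1.0, 0)],
)
def test_topological_charge(p, q, expected):
    assert topological_charge(scalar_cell(p, q)) == expected


# -- lambda window and decay rates ------------------------------------------


def test_solvable_window_is_log_two(cell_rightward, cell_leftward):
    win = lambda_window(cell_rightward, cell_leftward)
    assert win.lam_plus == pytest.approx(LN2, abs=1e-6)
    assert win.lam_minus == pytest.approx(-LN2, abs=1e-6)
    assert win.dw == 1
    assert win.eta_left == pytest.approx(1.0 / LN2, rel=1e-9)


def test_identical_bulks_give_empty_window(cell_rightward):
    win = lambda_window(cell_rightward, cell_rightward)
    assert win.is_empty
    assert win.dw == 0


def test_swapped_bulks_reverse_mismatch(cell_rightward, cell_leftward):
    win = lambda_window(cell_leftward, cell_rightward)
    assert win.dw == -1
    assert win.lam_plus == pytest.approx(LN2, abs=1e-6)


def test_decay_rates_solvable(cell_rightward):
    rates = bulk_decay_rates(cell_rightward)
    assert len(rates) == 1
    assert rates[0] == pytest.approx(LN2, abs=1e-9)


def test_unbiased_bulk_is_marginal():
    with pytest.warns(MarginalBulkWarning):
        rates = bulk_decay_rates(scalar_cell(1.0, 1.0))
    assert rates == []


def test_window_endpoints_equal_decay_rates(cell_rightward, cell_leftward):
    """Localization-length relation on the solvable model: |lam +-| equals
    the bulk decay rate ln 2 on both sides."""
    win = lambda_window(cell_rightward, cell_leftward)
    kappa = bulk_decay_rates(cell_rightward)[0]
    assert abs(win.lam_plus) == pytest.approx(kappa, abs=1e-6)
    assert abs(win.lam_minus) == pytest.approx(kappa, abs=1e-6)
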