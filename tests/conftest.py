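"""Shared fixtures: the exactly solvable two-bulk geometry and friends.

The solvable pair is a single-row left bulk hopping right at rate 2 and
left at rate 1, joined to its mirror image.  Its protected window is
(-ln 2, +ln 2) with winding mismatch 1, and its steady state decays away
from the inner interface at exactly ln 2 per column.
"""

from functools import lru_cache

import numpy as np
import pytest

from stochtopo import (
    BulkUnitCell,
    LadderSpec,
    build_two_bulk_ladder,
)


def _cell(p: float, q: float) -> BulkUnitCell:
    return BulkUnitCell(1, np.zeros((1, 1)), np.array([[p]]), np.array([[q]]))


@pytest.fixture(scope="session")
def cell_rightward() -> BulkUnitCell:
    return _cell(2.0, 1.0)


@pytest.fixture(scope="session")
def cell_leftward() -> BulkUnitCell:
    return _cell(1.0, 2.0)


@lru_cache(maxsize=None)
def _ring(n: int, identical: bool = False):
    left = _cell(2.0, 1.0)
    right = _cell(2.0, 1.0) if identical else _cell(1.0, 2.0)
    return build_two_bulk_ladder(
        LadderSpec(1, n, left, right, boundary="periodic"))


@lru_cache(maxsize=None)
def _chain(n: int):
    return build_two_bulk_ladder(
        LadderSpec(1, n, _cell(2.0, 1.0), _cell(1.0, 2.0), boundary="open"))


@pytest.fixture(scope="session")
def ring40():
    """Periodic solvable two-bulk network, 40 columns per bulk."""
    return _ring(40)


@pytest.fixture(scope="session")
def chain40():
    """Open solvable two-bulk chain, 40 columns per bulk."""
    return _chain(40)


@pytest.fixture(scope="session")
def chain10():
    return _chain(10)


@pytest.fixture(scope="session")
def control_ring40():
    """Identical bulks on both sides: no winding mismatch, no protection."""
    return _ring(40, identical=True)


@pytest.fixture(scope="session")
def ring_of_size():
    """Factory: solvable periodic ring with n columns per bulk (cached)."""
    return _ring


def random_cell(rng: np.random.Generator, b: int) -> BulkUnitCell:
    """Random strictly positive unit cell with log-uniform rates."""

    def mat() -> np.ndarray:
        return np.exp(rng.uniform(np.log(0.1), np.log(10.0), (b, b)))

    intra = mat()
    np.fill_diagonal(intra, 0.0)
    return BulkUnitCell(b, intra, mat(), mat())
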