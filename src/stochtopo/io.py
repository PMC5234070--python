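"""Canonical JSON readers/writers and the fixture generator.

The network and unit-cell formats are small JSON schemas with a canonical
serialization: keys in a fixed order, floats printed with 17 significant
digits, so write -> read -> write is byte-identical.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import numpy as np

from . import models
from .bulk import BulkUnitCell, bulk_decay_rates, lambda_window
from .network import ALLOWED_DISPS, RateEdge, StateNode, StochasticNetwork

__all__ = [
    "SchemaError",
    "read_network",
    "write_network",
    "network_to_dict",
    "read_cell",
    "write_cell",
    "make_fixtures",
]


class SchemaError(ValueError):
    """Raised when a JSON file violates the network or cell schema."""


# ---------------------------------------------------------------------------
# canonical serialization
# ---------------------------------------------------------------------------


def _fmt(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        v = float(value)
        if math.isnan(v) or math.isinf(v):
            raise SchemaError(f"cannot serialize non-finite number {v}")
        return format(v, ".17g")
    if isinstance(value, str):
        return json.dumps(value)
    if value is None:
        return "null"
    raise SchemaError(f"cannot serialize {type(value).__name__}")


def _canonical(obj: Any, indent: int = 0) -> str:
    pad = " " * indent
    pad2 = " " * (indent + 2)
    if isinstance(obj, dict):
        if not obj:
            return "{}"
        items = [
            f"{pad2}{json.dumps(str(k))}: {_canonical(v, indent + 2)}"
            for k, v in sorted(obj.items())
        ]
        return "{\n" + ",\n".join(items) + "\n" + pad + "}"
    if isinstance(obj, (list, tuple)):
        if not obj:
            return "[]"
        items = [f"{pad2}{_canonical(v, indent + 2)}" for v in obj]
        return "[\n" + ",\n".join(items) + "\n" + pad + "]"
    return _fmt(obj)


def _dump_canonical(obj: dict, path: str | Path) -> None:
    Path(path).write_text(_canonical(obj) + "\n")


# ---------------------------------------------------------------------------
# network format
# ---------------------------------------------------------------------------


def network_to_dict(net: StochasticNetwork) -> dict:
    return {
        "boundary": net.boundary,
        "metadata": _jsonable(net.metadata),
        "nodes": [
            {"id": n.id, "row": n.row, "tag": n.tag, "x": n.x} for n in net.nodes
        ],
        "edges": [
            {"disp": e.disp, "dst": e.dst, "rate": e.rate, "src": e.src}
            for e in net.edges
        ],
    }


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_network(net: StochasticNetwork, path: str | Path) -> None:
    """Write a network in the canonical JSON format."""
    _dump_canonical(network_to_dict(net), path)


def read_network(path: str | Path) -> StochasticNetwork:
    """Read and validate a network JSON file.

    Raises :class:`SchemaError` naming the offending field on any
    violation (missing key, negative rate, reserved displacement...).
    """
    data = json.loads(Path(path).read_text())
    for key in ("nodes", "edges", "boundary"):
        if key not in data:
            raise SchemaError(f"missing top-level key {key!r}")
    nodes = []
    for k, nd in enumerate(data["nodes"]):
        for key in ("id", "x"):
            if key not in nd:
                raise SchemaError(f"node #{k}: missing field {key!r}")
        if not isinstance(nd["x"], int):
            raise SchemaError(f"node {nd['id']!r}: x must be an integer")
        nodes.append(StateNode(str(nd["id"]), nd["x"], int(nd.get("row", 0)),
                               str(nd.get("tag", "bulk_L"))))
    edges = []
    for k, ed in enumerate(data["edges"]):
        for key in ("src", "dst", "rate"):
            if key not in ed:
                raise SchemaError(f"edge #{k}: missing field {key!r}")
        rate = ed["rate"]
        if not isinstance(rate, (int, float)) or not rate > 0:
            raise SchemaError(
                f"edge {ed['src']!r}->{ed['dst']!r}: rate must be a positive "
                f"number, got {rate!r}"
            )
        disp = ed.get("disp", 0)
        if disp not in ALLOWED_DISPS:
            raise SchemaError(
                f"edge {ed['src']!r}->{ed['dst']!r}: disp = {disp!r} is "
                "reserved/unimplemented (allowed: -1, 0, +1)"
            )
        edges.append(RateEdge(str(ed["src"]), str(ed["dst"]), float(rate), disp))
    return StochasticNetwork(nodes, edges, data["boundary"],
                             data.get("metadata") or {})


# ---------------------------------------------------------------------------
# unit cell format
# ---------------------------------------------------------------------------


def write_cell(cell: BulkUnitCell, path: str | Path) -> None:
    _dump_canonical(
        {
            "n_internal": cell.n_internal,
            "intra": cell.intra.tolist(),
            "hop_plus": cell.hop_plus.tolist(),
            "hop_minus": cell.hop_minus.tolist(),
        },
        path,
    )


def read_cell(path: str | Path) -> BulkUnitCell:
    data = json.loads(Path(path).read_text())
    for key in ("n_internal", "intra", "hop_plus", "hop_minus"):
        if key not in data:
            raise SchemaError(f"missing cell key {key!r}")
    return BulkUnitCell(
        int(data["n_internal"]),
        np.asarray(data["intra"], dtype=float),
        np.asarray(data["hop_plus"], dtype=float),
        np.asarray(data["hop_minus"], dtype=float),
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _solvable_cells() -> tuple[BulkUnitCell, BulkUnitCell]:
    inward = BulkUnitCell(1, np.zeros((1, 1)), np.array([[2.0]]), np.array([[1.0]]))
    outward = BulkUnitCell(1, np.zeros((1, 1)), np.array([[1.0]]), np.array([[2.0]]))
    return inward, outward


def make_fixtures(out_dir: str | Path, seed: int = 0,
                  columns_per_bulk: int = 40) -> list[Path]:
    """Emit the canonical test networks plus a manifest of derived values.

    Written files: the solvable single-row two-bulk geometry (open and
    periodic), the identical-bulk control, a two-row ladder, adaptation
    networks for G in {-2, 0, 2} (M = 48, E = 6), and proofreading chains
    for the correct (R) and wrong (W) substrates.  The manifest records the
    analytically known window, mismatch and decay rates for each.
    Deterministic: two calls with the same seed produce identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    right_cell, left_cell = _solvable_cells()
    written: list[Path] = []

    def emit(name: str, net: StochasticNetwork) -> None:
        path = out / f"{name}.json"
        write_network(net, path)
        written.append(path)

    n = columns_per_bulk
    emit("two_bulk_open", models.build_two_bulk_ladder(
        models.LadderSpec(1, n, right_cell, left_cell, boundary="open")))
    emit("two_bulk_ring", models.build_two_bulk_ladder(
        models.LadderSpec(1, n, right_cell, left_cell, boundary="periodic")))
    emit("identical_bulk_ring", models.build_two_bulk_ladder(
        models.LadderSpec(1, n, right_cell, right_cell, boundary="periodic")))
    two_row_left = BulkUnitCell(
        2, np.array([[0.0, 1.0], [1.0, 0.0]]),
        np.diag([2.0, 2.0]), np.diag([1.0, 1.0]))
    two_row_right = BulkUnitCell(
        2, np.array([[0.0, 1.0], [1.0, 0.0]]),
        np.diag([1.0, 1.0]), np.diag([2.0, 2.0]))
    emit("two_row_ladder_ring", models.build_two_bulk_ladder(
        models.LadderSpec(2, n, two_row_left, two_row_right, boundary="periodic")))
    for g in (-2.0, 0.0, 2.0):
        tag = f"G{g:+.0f}".replace("+", "p").replace("-", "m")
        emit(f"adaptation_{tag}", models.build_adaptation_network(
            models.AdaptationSpec(M=48, E=6.0, S=24.0, G=g)))
    emit("proofreading_R", models.build_proofreading_chain(
        models.ProofreadingSpec(5, 2.0, 1.0, "R")))
    emit("proofreading_W", models.build_proofreading_chain(
        models.ProofreadingSpec(5, 1.0, 2.0, "W")))
    emit("two_bulk_ring_disordered", models.apply_disorder(
        models.build_two_bulk_ladder(
            models.LadderSpec(1, n, right_cell, left_cell, boundary="periodic")),
        models.DisorderSpec(0.3, seed=seed)))

    win = lambda_window(right_cell, left_cell)
    manifest = {
        "seed": seed,
        "columns_per_bulk": n,
        "lam_minus": win.lam_minus,
        "lam_plus": win.lam_plus,
        "lam_plus_exact": math.log(2.0),
        "dw_two_bulk_ring": 1,
        "dw_identical_bulk_ring": 0,
        "dw_adaptation_Gp2": 1,
        "dw_adaptation_Gm2": -1,
        "charge_proofreading_R": 1,
        "charge_proofreading_W": -1,
        "decay_rates_left_bulk": bulk_decay_rates(right_cell),
        "provenance": "stochtopo.io.make_fixtures",
    }
    path = out / "manifest.json"
    _dump_canonical(manifest, path)
    written.append(path)
    return written
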