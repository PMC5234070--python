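"""Model builders: ladders, adaptation lattices, proofreading chains,
quenched disorder, and their cycle/topology diagnostics."""

import numpy as np
import pytest

from stochtopo import (
    AdaptationSpec,
    DisorderSpec,
    LadderSpec,
    ModelError,
    ProofreadingSpec,
    adaptation_sweep,
    apply_disorder,
    build_adaptation_network,
    build_generator,
    build_proofreading_chain,
    build_two_bulk_ladder,
    bulk_limits,
    column_marginals,
    cycle_affinity,
    proofreading_cell,
    steady_state,
    topological_charge,
    winding_number,
)


# -- two-bulk ladder --------------------------------------------------------


def test_bulk_columns_are_translationally_invariant(ring40):
    """Any two interior bulk columns carry identical incident rate patterns."""
    by_src = {}
    for e in ring40.edges:
        c = ring40.node(e.src).x
        by_src.setdefault(c, []).append((e.disp, ring40.node(e.dst).x - 0, e.rate))
    sig = lambda c: sorted((d, r) for d, _, r in by_src[c])
    assert sig(5) == sig(20)          # left bulk interior
    assert sig(45) == sig(70)         # right bulk interior
    assert sig(5) != sig(45)


def test_open_chain_peaks_at_interface(chain40):
    p = steady_state(build_generator(chain40))
    marg = column_marginals(chain40, p)
    peak = max(marg, key=marg.get)
    assert peak in chain40.metadata["interface_A_cols"]


def test_identical_cells_give_flat_ring(control_ring40):
    p = steady_state(build_generator(control_ring40))
    marg = column_marginals(control_ring40, p)
    vals = np.array(list(marg.values()))
    assert vals.std() / vals.mean() < 1e-10


def test_periodic_variant_has_two_interfaces(ring40):
    assert ring40.metadata["interface_A_cols"]
    assert ring40.metadata["interface_B_cols"]
    assert ring40.boundary == "periodic"


def test_ladder_spec_validation(cell_rightward, cell_leftward):
    with pytest.raises(ModelError, match="columns_per_bulk"):
        LadderSpec(1, 3, cell_rightward, cell_leftward)
    with pytest.raises(ModelError, match="internal states"):
        LadderSpec(2, 10, cell_rightward, cell_leftward)
    with pytest.raises(ModelError, match="mixing weight"):
        LadderSpec(1, 10, cell_rightward, cell_leftward,
                   interface_rule="explicit")


def test_explicit_interface_table(cell_rightward, cell_leftward):
    net = build_two_bulk_ladder(LadderSpec(
        1, 5, cell_rightward, cell_leftward, interface_columns=2,
        interface_rule="explicit", interface_table=[0.25, 0.75]))
    c = net.metadata["interface_A_cols"][0]
    hop = {(net.node(e.src).x, e.disp): e.rate for e in net.edges}
    assert hop[(c, +1)] == pytest.approx(0.75 * 2.0 + 0.25 * 1.0)


# -- adaptation -------------------------------------------------------------


def test_adaptation_spec_validation():
    with pytest.raises(ModelError):
        AdaptationSpec(M=3, E=6.0, S=1.0, G=2.0)
    with pytest.raises(ModelError, match="S"):
        AdaptationSpec(M=48, E=6.0, S=60.0, G=2.0)


def test_plaquette_affinity_is_E_plus_2G():
    """Each elementary methylation/activity cycle dissipates E + 2G."""
    spec = AdaptationSpec(M=12, E=6.0, S=6.0, G=2.0)
    net = build_adaptation_network(spec)
    affs = [
        cycle_affinity(net, [f"m{m}a0", f"m{m + 1}a0", f"m{m + 1}a1", f"m{m}a1"])
        for m in range(spec.M - 1)
    ]
    assert np.allclose(affs, spec.E + 2 * spec.G, atol=1e-9)


def test_detailed_balance_at_compensating_drive():
    """Kolmogorov's criterion holds on every plaquette when G = -E/2."""
    spec = AdaptationSpec(M=12, E=6.0, S=6.0, G=-3.0)
    net = build_adaptation_network(spec)
    for m in range(spec.M - 1):
        cyc = [f"m{m}a0", f"m{m + 1}a0", f"m{m + 1}a1", f"m{m}a1"]
        assert cycle_affinity(net, cyc) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("g, expected_dw", [(2.0, +1), (-2.0, -1)])
def test_bulk_limit_winding_mismatch(g, expected_dw):
    left, right = bulk_limits(AdaptationSpec(M=48, E=6.0, S=24.0, G=g))
    dw = winding_number(left, 0.05).w - winding_number(right, 0.05).w
    assert dw == expected_dw


def test_bulk_limits_mirror_symmetry():
    """Left and right saturated cells are images under (m -> -m, a -> 1-a)."""
    left, right = bulk_limits(AdaptationSpec(M=48, E=6.0, S=24.0, G=2.0))
    perm = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert np.allclose(perm @ left.hop_minus @ perm, right.hop_plus)
    assert np.allclose(perm @ left.hop_plus @ perm, right.hop_minus)
    assert np.allclose(perm @ left.intra @ perm, right.intra)


def test_bulk_limits_require_saturation():
    with pytest.raises(ModelError, match="saturate"):
        bulk_limits(AdaptationSpec(M=8, E=0.5, S=4.0, G=2.0))


def test_adaptive_sweep_is_flat_and_tracks_ligand():
    """dw=+1 regime: activity pinned at the set point, <m> tracks S."""
    sweep = adaptation_sweep(AdaptationSpec(M=48, E=6.0, S=24.0, G=2.0),
                             np.arange(12.0, 37.0, 2.0))
    act = sweep.mean_activity
    assert (act.max() - act.min()) / act.mean() < 0.02
    offset = sweep.mean_methylation - sweep.S
    assert offset.max() - offset.min() < 0.5


def test_reversed_drive_destroys_adaptation():
    """dw=-1 regime: the activity is strongly ligand dependent."""
    sweep = adaptation_sweep(AdaptationSpec(M=48, E=6.0, S=24.0, G=-2.0),
                             np.arange(12.0, 37.0, 2.0))
    act = sweep.mean_activity
    assert (act.max() - act.min()) / act.mean() > 0.20


def _mean_activity(net) -> float:
    p = steady_state(build_generator(net))
    return sum(p[net.index(f"m{m}a1")] for m in range(net.metadata["M"]))


def test_adaptation_robust_to_disorder():
    """Protected regime: the activity set point barely moves under rate
    disorder of strength 0.2; the unprotected regime swings wildly."""
    protected_dev = 0.0
    for s in (14.0, 24.0, 34.0):
        net = build_adaptation_network(AdaptationSpec(M=48, E=6.0, S=s, G=2.0))
        clean = _mean_activity(net)
        for seed in range(10):
            act = _mean_activity(apply_disorder(net, DisorderSpec(0.2, seed=seed)))
            protected_dev = max(protected_dev, abs(act - clean))
    assert protected_dev < 0.05 * 1.0   # within 5 points of the 0.5 set point
    rev = build_adaptation_network(AdaptationSpec(M=48, E=6.0, S=24.0, G=-2.0))
    clean = _mean_activity(rev)
    rev_dev = max(
        abs(_mean_activity(apply_disorder(rev, DisorderSpec(0.2, seed=seed))) - clean)
        for seed in range(10))
    assert rev_dev > 3 * protected_dev


# -- proofreading -----------------------------------------------------------


def test_proofreading_discrimination_ratio():
    r_net = build_proofreading_chain(ProofreadingSpec(5, 2.0, 1.0, "R"))
    w_net = build_proofreading_chain(ProofreadingSpec(5, 1.0, 2.0, "W"))
    p_r = steady_state(build_generator(r_net))
    p_w = steady_state(build_generator(w_net))
    ratio_r = p_r[r_net.index("s5")] / p_r[r_net.index("s0")]
    ratio_w = p_w[w_net.index("s5")] / p_w[w_net.index("s0")]
    assert ratio_r == pytest.approx(32.0, rel=1e-12)
    assert ratio_w == pytest.approx(1.0 / 32.0, rel=1e-12)
    # discrimination between substrates is (f_R b_W / b_R f_W)^n
    assert ratio_r / ratio_w == pytest.approx(4.0 ** 5, rel=1e-12)


def test_proofreading_charges():
    assert topological_charge(proofreading_cell(ProofreadingSpec(5, 2.0, 1.0))) == +1
    assert topological_charge(proofreading_cell(ProofreadingSpec(5, 1.0, 2.0))) == -1


# -- disorder ---------------------------------------------------------------


def test_zero_disorder_is_identity(ring40):
    same = apply_disorder(ring40, DisorderSpec(0.0, seed=3))
    assert all(a.rate == b.rate for a, b in zip(same.edges, ring40.edges))


def test_disorder_is_deterministic(ring40):
    a = apply_disorder(ring40, DisorderSpec(0.3, seed=5))
    b = apply_disorder(ring40, DisorderSpec(0.3, seed=5))
    assert all(x.rate == y.rate for x, y in zip(a.edges, b.edges))
    c = apply_disorder(ring40, DisorderSpec(0.3, seed=6))
    assert any(x.rate != y.rate for x, y in zip(a.edges, c.edges))


def test_disorder_keeps_rates_positive_and_bounded(ring40):
    d = apply_disorder(ring40, DisorderSpec(0.3, seed=1))
    for clean, noisy in zip(ring40.edges, d.edges):
        assert 0 < noisy.rate
        assert abs(np.log(noisy.rate / clean.rate)) <= 0.3


def test_disorder_spec_validation():
    with pytest.raises(ModelError):
        DisorderSpec(-0.1)
    with pytest.raises(ModelError):
        DisorderSpec(6.0)
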