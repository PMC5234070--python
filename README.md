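# stochtopo

Topologically protected steady states of non-equilibrium Markov state
networks.

Many biophysical processes — chemosensory adaptation, kinetic proofreading,
cell signalling — are modelled as continuous-time Markov chains whose rates
break detailed balance. When such a network decomposes into translationally
invariant "bulk" regions joined at interfaces, each bulk can be assigned an
integer topological invariant, and a mismatch of invariants across an
interface forces the steady state to localize there, robustly against
disorder in the kinetic rates. `stochtopo` implements this analysis end to
end for researchers in stochastic thermodynamics and systems biology.

## The framework

A network with states carrying an integer horizontal coordinate evolves by
the master equation dp/dt = W p (columns of W sum to zero). Tilting the
off-diagonal entries by the current-counting field λ,

    W(λ)_ij = W_ij e^{λ (i_x − j_x)}   (i ≠ j),

gives the tilted current matrix whose largest eigenvalue e(λ) is the scaled
cumulant generating function of the horizontal current, with e′(0) = J the
mean current. For a translationally invariant bulk with B states per
column, the Bloch matrix

    W(k, λ) = intra + hop₊ e^{ik+λ} + hop₋ e^{−ik−λ} + D

has determinant D(k, λ) = |D| e^{iθ(k, λ)}, and the winding number

    w = (1/2π) ∮ dθ(k, λ)

is an integer invariant of the bulk (equivalently, the number of roots of
z^B det W(z, λ) inside the unit circle minus B). When the left and right
bulks around an interface satisfy δw = w_L − w_R ≠ 0 throughout a window
λ⁻ < 0 < λ⁺, the tilted generator is pinned at e(λ) = 0 across that window,
the steady state is exponentially localized at the interface with a decay
rate tied to |λ±|, and a local index counting zero modes of W(λ) and
W(λ)ᵀ in the interface region equals δw — a stochastic bulk–boundary
correspondence.

The package provides:

- `network` / `generator` — network containers, generators, tilting, exact
  steady states (subtraction-free GTH elimination, stable even for
  metastable chains), e(λ), mean currents, spectral gaps;
- `bulk` — Bloch matrices, phase-integral winding numbers, an independent
  argument-principle oracle, the protected (λ⁻, λ⁺) window and bulk
  localization lengths;
- `modes` — zero modes, localization fractions, the local interface index,
  exponential-decay fits, s_min(W(λ))² scans;
- `models` — two-bulk ladders, the chemosensory adaptation lattice,
  kinetic proofreading chains, quenched disorder;
- `kmc` — Gillespie simulation with batch-mean error bars;
- `io` / `cli` — canonical JSON/CSV formats and the `stochtopo` command.

## Worked example

Two single-row bulks, the left hopping right at rate 2 and left at rate 1,
the right bulk mirrored, joined into a ring. The flows converge on the
inner interface:

```python
import numpy as np
from stochtopo import (BulkUnitCell, LadderSpec, build_two_bulk_ladder,
                       build_generator, steady_state, lambda_window,
                       winding_number, local_index, interface_region)

right = BulkUnitCell(1, np.zeros((1, 1)), [[2.0]], [[1.0]])
left_mirror = BulkUnitCell(1, np.zeros((1, 1)), [[1.0]], [[2.0]])

print(winding_number(right, 0.05).w)        # 1
print(winding_number(left_mirror, 0.05).w)  # 0  -> mismatch dw = 1

win = lambda_window(right, left_mirror)
print(win.lam_minus, win.lam_plus, win.dw)
# -0.6931468925476074 0.6931468925476074 1   (the exact window is +-ln 2)

ring = build_two_bulk_ladder(LadderSpec(1, 40, right, left_mirror,
                                        boundary="periodic"))
p = steady_state(build_generator(ring))
region = interface_region(ring, "A", pad=3)
print(local_index(ring, 0.05, region))      # 1  == dw, the index theorem
print(round(p[ring.index("c39r0")] / p[ring.index("c34r0")], 3))
# 32.0 = 2**5: the steady state grows by 2 per column toward the interface
```

The window endpoints ±ln 2 equal the bulk decay rate: the steady state
decays away from the interface at exactly κ = ln 2 per column, and the
localization length η = 1/κ matches 1/|λ±|.

The same machinery classifies the biophysical models: the adaptation
lattice at driving G = +2 has δw = +1 (activity pinned at its set point,
mean methylation tracking the ligand parameter S), and the proofreading
bulk has charge +1 for the correct substrate (product-localized) and −1
for the wrong one (reactant-localized).

## Command line

```sh
stochtopo fixtures --out-dir fixtures --seed 0
stochtopo winding --cell fixtures/../cell.json --lam 0.05
stochtopo window --left left.json --right right.json
stochtopo index --net net.json --lam 0.05 --region cols:37-43
stochtopo scan --net net.json --lam-min -1 --lam-max 1 --steps 81 --out scan.csv
stochtopo simulate --net net.json --tmax 1e5 --seed 11 --out occ.csv
stochtopo adapt-sweep --spec adapt.json --s-min 12 --s-max 36 --steps 13 --out sweep.csv
```

See `docs/methods.md` for the model conventions, numerical choices and
known limitations.
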