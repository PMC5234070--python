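# Methods

## Model and conventions

The master equation is dp/dt = W p with W[i, j] = rate(j → i) for i ≠ j and
zero column sums. This column convention is fixed once in `generator` and
inherited everywhere. Tilting multiplies each off-diagonal entry by
e^{λ·disp}; the diagonal is never tilted, so W(0) = W exactly. The per-edge
displacement `disp ∈ {−1, 0, +1}` is stored explicitly rather than derived
from coordinates so that a hop across a periodic seam counts ±1 and the
tilt is conjugate to the true winding current.

Bloch matrices use W(k, λ) = intra + hop₊ e^{ik+λ} + hop₋ e^{−ik−λ} + D,
with D the diagonal of total untilted outflow, and the winding number is
(θ(2π) − θ(0))/2π along increasing k. With this orientation a
rightward-biased single-row bulk has w = +1 for λ > 0, which makes the
proofreading labels come out as "+1 localizes at products, −1 at
reactants". The opposite orientation is equally consistent; only
differences and signs of mismatches matter, and the choice is fixed
package-wide. λ = 0 is excluded from winding evaluation because det W(0, 0)
= 0 identically (probability conservation); windows are probed on both
sides of zero.

Equivalently, with z = e^{ik}, w equals the number of roots of
P(z) = z^B det W(z, λ) inside the unit circle minus B. `winding_oracle_roots`
implements this argument-principle route independently (P's coefficients
are recovered exactly by a DFT over 2B + 1 roots of unity, then `np.roots`);
the two routes are cross-checked on hundreds of random cells in the suite
and must agree wherever neither detects a band touching.

## Numerical choices

- Winding phase integral: 512 k-points by default; per-step unwrapped phase
  jumps above 0.9π raise an error suggesting grid refinement; |det| below
  1e−10 of its maximum raises a band-touching error naming the offending k.
- Window search: the mismatch is evaluated at λ = ±0.05 (or half the window
  if smaller); endpoints are bracketed on a 200-point scan of the search
  range and bisected to 1e−6. A band touching encountered mid-scan is
  itself treated as the transition point.
- Steady states use GTH (Grassmann–Taksar–Heyman) state elimination, which
  is subtraction-free and therefore entrywise accurate even when two
  metastable wells are coupled through rates of order e^{−50} — the regime
  of the reversed-drive adaptation model, where any null-space method based
  on floating-point cancellation sees a spuriously two-dimensional kernel.
  Elimination stalling (a zero pivot) is exactly reducibility and raises an
  error.
- Zero modes are the singular vectors of W(λ) whose singular values are at
  most `tol` times the largest, with `tol = 1e−6` by default. The
  tolerance is relative because finite bulks split the topological zero
  mode by ~e^{−N/η}; the default presumes at least ~30 columns per bulk at
  decay rates around ln 2. Smaller systems or λ close to the window edge
  need a looser tolerance.
- The leading eigenpair for e(λ) is computed densely below 500 states and
  with ARPACK (largest real part) above.
- Exact-zero thresholds are 1e−10 absolute (λ = 0 modes, window band-touch
  test); exponentially split modes at λ ≠ 0 use the configurable relative
  tolerance above.

## The local index and region sizes

`local_index` counts right zero modes minus left zero modes carrying a
majority (> frac, default 0.5, ties conservatively "out") of their 1-norm
mass in the region. The composed-matrix kernel dim ker(ρW(λ)) is exposed
as a diagnostic (`rho_kernel_dim`) but not used for the index: it
over-counts by the dimension of the projector's own null space.

A practical subtlety governs region sizes. Any seamless single-row network
has the exact left null vector u_x = e^{−λx} (and the open chain the exact
right null vector e^{+λx}), so on a two-interface ring the conjugate (left)
zero mode consists of a sharply localized side (decay rate of order the
bulk rates) and a slow side decaying at exactly λ per column. Its
localization length is therefore max(1/λ, bulk decay length), and the
interface region must cover that tail for majority-mass counting: at
λ = 0.05 on 40-column bulks a ±3-column region captures only ~17% of the
left mode. The steady-state-like (right) mode at the converging interface
is tight at any λ in the window, so ±3 columns suffice there. The suite
probes the δw = +1 seam at λ = 0.05 with pad 3 and the δw = −1 seam at
λ = 0.3 with pad 10, both robust across 20 disorder realisations at
strength 0.3.

`fit_decay` returns κ = |slope| of the log-marginal regression; interior
fit ranges (≥ 5 columns from interfaces and ends) recover the bulk
determinant-root rate to machine precision on the solvable chain.

## Synthetic models and what they do (not) show

The two-bulk ladder, adaptation lattice and proofreading chains are the
study systems, generated by code, not stored. Defaults follow the regime
the analysis targets: 40 columns per bulk for localization claims (10/20/40
for size series), the solvable rate pair 2/1 vs 1/2 (window exactly ±ln 2),
adaptation at M = 48, E = 6, ω_a = ω_m = 1, G = ±2, S swept over [12, 36],
proofreading with 5 stages at forward/backward 2/1 (R) and 1/2 (W), and
log-uniform multiplicative disorder of strength 0.2–0.3.

The adaptation lattice uses f(a, m) = a·E·(S − m) with Glauber flip rates
ω_a σ(±E(m − S)) and m-independent methylation kinetics: methylate when
inactive, demethylate when active, reverse hops suppressed by e^{−G};
reflecting boundaries at m = 0 and M − 1. This is the standard futile-cycle
architecture of adaptation models: because the methylation kinetics ignore
the activity free energy, every elementary plaquette carries cycle affinity
E + 2G (not 2G), so the lattice is driven even at G = 0 and reaches
detailed balance only at G = −E/2 — the suite asserts exactly this. The
saturated bulk limits floor strictly-zero flip rates at ω_a e^{−|E|·10} to
preserve irreducibility; this changes windings by nothing measurable
(off-diagonal products are ~e^{−60}).

These generators emulate the topology and drive structure of real
biochemical networks but not their kinetic detail: no ligand-binding
kinetics beyond the lumped S parameter, no receptor-cluster cooperativity,
single-loop proofreading only (multi-loop ladders are an extension point),
and hops are nearest-column only (the JSON format reserves larger `disp`
values but they are unimplemented). Passing tests demonstrate the
topological mechanism and its disorder robustness in these idealized
geometries, not quantitative agreement with measured rate constants.

## Design choices that were genuinely open

- Interface interpolation defaults to a sigmoid mix of the two cells'
  rates over the interface columns (same σ as the adaptation flips); a
  linear rule and an explicit per-column table are available because the
  localized modes are insensitive to interface detail.
- Bulk-vs-vacuum geometries (proofreading) use the single label
  w(+ε) + w(−ε) (`topological_charge`), a reduction justified on the
  solvable cell: +1 rightward-biased, −1 leftward, 0 unbiased.
- Localization lengths η are reported as 1/κ_min from the determinant
  roots at λ = 0 of each bulk separately, and the identity |λ±| = κ is
  asserted only on the solvable model where it is exact.
- The Gillespie sampler is the direct method with a single RNG stream per
  run, 10% burn-in and ten-batch standard errors; the default start state
  in the CLI is node 0, while tests start from the steady-state mode to
  shorten equilibration.
- Windows with unequal mismatch on the two sides of λ = 0 report the
  positive-side value; all shipped models have equal mismatches.

## Known limitations

- Winding evaluation very close to a transition (|det| near zero on the
  grid) errors rather than guessing; the window search treats such points
  as the transition itself, which biases endpoints by at most the
  bisection tolerance.
- The s_min² plateau edge detected at threshold 1e−8 sits ~ln(1e4)/N
  inside the true λ± at N columns per bulk; it converges as sizes double
  but should not be read as λ± at small N.
- No Legendre transform to rate functions, no time-dependent driving, no
  higher-dimensional lattices.
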