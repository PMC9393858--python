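# Methods

All quantities are in reduced Lennard-Jones units (ε = σ = k_B = 1).

## Model and ensembles

The pair potential is the untruncated 12-6 LJ form for clusters ("all
interactions included", no periodic box) and a spherically truncated form
with analytical mean-field tail corrections for bulk boxes (minimum-image
convention; the box must satisfy L ≥ 2 r_c, violation aborts the run).
Cluster simulations use a grand-canonical setup: the cluster exchanges
particles with an implicit ideal-gas reservoir of number density n_v at
temperature T. The chemical-potential convention is βμ_gas = ln(n_v σ³),
so n_v = 1 means μ_gas = 0 with the kinetic (de Broglie) term excluded;
the same convention is used when CNT intercepts are converted to bulk
chemical potentials, so the kinetic term cancels throughout.

## Cluster definitions

*Liquid*: Stillinger criterion — the graph with edges between pairs closer
than R must be connected; R is also the AVBMC insertion radius (one
parameter, R = 1.5 by default). Edges use strict `< R`; the boundary has
measure zero, the convention is fixed for determinism.

*Solid*: every particle is assigned to a distinct FCC site; (a) each
particle must lie within r of its site (`≤ r`), and (b) the occupied-site
graph (edges between nearest-neighbor sites) must be connected. FCC sites
are the even-parity integer triples of a half-cell grid with cell edge
a = a_nn·√2; a site id is its triple packed into one integer, which makes
ids stable under lattice growth by construction. The lattice frame is
fixed in space: the site constraint itself pins the cluster, and no
lattice translation/rotation moves are attempted.

## Move set and acceptance rules

Move mix is 50/50 between swap moves and local moves (intrasite jumps for
solid, translations capped at 0.2 for liquid). Insertion points are drawn
uniformly in a sphere via radius-cubed inversion, so V_in is exactly
(4/3)π·radius³.

The swap acceptance probabilities are per-path (super-detailed-balance)
Metropolis forms, with all counts evaluated in the pre-move state and
bias differences folded into ΔE:

*Lattice AVBMC* (target particle j, N particles):

    insert: min{1, n_v V_in e^(−βΔE′) · N·N_vac(j) / [(N+1)(N_in(j)+1)]}
    delete: min{1, e^(−βΔE′)/(n_v V_in) · N·N_in(j) / [(N−1)(N_vac(j)+1)]}

where N_vac(j)/N_in(j) are the vacant/occupied neighbors among the 12
sites adjacent to j's site. Insertions with N_vac = 0, deletions of the
last neighbor, deletions that disconnect the occupied-site graph, and
moves crossing the size window are rejected outright (they still count as
attempts).

*Original AVBMC*:

    insert: min{1, n_v V_in e^(−βΔE′) · N / [(N+1)(N_in(j)+1)]}
    delete: min{1, e^(−βΔE′) · N·N_in(j) / [n_v V_in (N−1)]}

The deletion form follows from the reverse insertion targeting j among the
N−1 survivors; forward and reverse arguments multiply to exactly one.

These rules make the chain sample π(x, N) ∝ n_v^N e^(−β[U + η(N)]). For
the liquid cluster this is the standard indistinguishable-particle
convention, P(N) ∝ n_v^N Z_N/N! with Z_N the labeled configuration
integral — the factorial is what makes the CNT intercept equal the bulk
chemical potential. For the lattice cluster the occupied-site pattern
labels the particles and no factorial appears. Both conventions are
certified against exact references (below), not assumed.

## Validation oracles

For lattice models restricted to an enumerable sub-lattice (≤ 12 sites)
the grand-canonical distribution is summed exactly over all nonempty
connected occupancy patterns; each occupied site contributes an activity
factor n_v·V_in, and in "frozen" mode a Boltzmann factor of the
site-center pair energies (positions still integrate freely over the
insertion spheres, separating entropic from energetic factors so rule
errors are attributable). The engine, run on the same model with thinned
sampling (every 50 moves, so the chi-square reference distribution
applies), matches the enumeration with p ≈ 0.3–0.5; deliberately dropping
the N_vac proposal factor (negative control) gives p < 10⁻¹⁰⁰. For the
liquid engine the references are quadrature (dimer) and brute-force
Monte Carlo integration (trimer) of the connectivity-constrained
configuration integrals.

## Umbrella sampling

Sampling is restricted to hard size windows [n_min, n_max] (minimum
cluster size 1); δΔG needs only adjacent-size ratios, which windows
preserve, so sparse window campaigns suffice and global stitching (least
squares on ≥ 2 shared sizes) is optional. Histograms are unbiased via
βΔG(n) = −ln H(n) − βη(n) + C, the constant fixed by an anchor
(ΔG at the lowest window size = 0 by default; every downstream quantity
uses differences only, and anchor independence of δΔG is tested exactly).
Errors come from 5 equal blocks; δΔG errors use the block scatter of the
per-block *increments*, because adjacent ΔG values from one run are
strongly correlated and quadrature of their separate errors would
overstate the uncertainty. A size unvisited in any block raises an
"insufficient sampling" error naming the size.

The self-adaptive bias iterates η ← −ΔG_est until the max/min visited
count ratio is below 10 (cap 20 iterations). During adaptation, sizes
not yet visited get ΔG estimates by interpolating between visited sizes
and continuing the mean visited slope outward, which steers the next
iteration into unexplored sizes; the strict unbiasing contract is not
relaxed for production analysis. For larger clusters the bias is
extended along the fitted CNT line: η(n) = −[ΔG(n_ref) + Σ (b + s·x_m)].

## Bulk NPT

864 particles (4·6³; any 4k³ works) with r_c = 4.75 and tail corrections.
One sweep = N single-particle translations plus 4 volume moves uniform in
ln V with the standard (N+1) ln V Jacobian term. A constant-volume
warm-up (a tenth of the equilibration) precedes volume moves: a perfect
cold lattice at the target density is under static tension and would
otherwise transiently collapse the box below 2 r_c. The running pair
energy is resynchronized against a full recompute every 20 sweeps.
Liquid runs start from random sequential insertion with a 0.85σ minimum
distance; solid runs start from a perfect FCC lattice at ρ = 0.985.
Densities are reported as the sample mean of N/V (for the ideal-gas
check note N/⟨V⟩ = (P/T)·N/(N+1) instead); enthalpy per particle is
⟨U + PV⟩/N; the virial pressure (with its tail correction) is sampled
alongside as a consistency check — for crystals the mean-field tail makes
it systematically approximate, so the quantitative check is run on the
liquid. Saturation pressures are not an output of this package; a
Clausius-type correlation ln p = A + B/T + C/T² fit to published
reduced-LJ coexistence data supplies them, and the resulting densities
are insensitive to pressure across [0, 0.01].

## CNT analysis and phase diagram

δΔG series are fit by weighted least squares (weights 1/σ², unweighted
fallback when errors are absent) against x = n^(2/3) − (n−1)^(2/3);
parameter errors use the known-σ covariance. Surface tension
γ = s/(36π/ρ²)^(1/3) and chemical potential μ = b + T ln n_v with errors
propagated in quadrature.

Chemical potentials propagate in temperature by βμ(β) = β₀μ₀ + ∫ h dβ′
with h interpolated linearly in β and trapezoidal quadrature at β-step
≤ 0.001 (round-trip reversible to 10⁻⁹). The melting point is the brentq
root of Δ(βμ)(T) to |ΔT| < 10⁻⁶, with uncertainty from ≥ 1000 Gaussian
resamples of the input chemical potentials (and optional common enthalpy
offsets). The solid–liquid curve integrates dP/dT = Δh/(TΔv) by RK4 at
ΔT ≤ 0.0005; by default Δh and Δv are held at their melting-point values
(the traced interval is hundredths wide), with callables accepted for
re-simulated values. The triple point is the bracketed intersection with
a liquid–vapor (T, P) table — user-supplied TSV or the built-in
correlation.

## Structure diagnostics

Neighbor definition everywhere: pair distance < 1.5σ (near the first
minimum of the liquid pair correlation); the cutoff is a named knob in
every report since no single convention is canonical. Q6 is the global
Steinhardt parameter — the ℓ = 6 spherical-harmonic average over **all**
neighbor bonds, not the per-particle average; the two differ numerically.
A perfect FCC nearest-neighbor bond set gives Q6 = 0.57452 (the test
reference), random bonds decay like N_b^(−1/2). Surface particles are
those with coordination < 9; their count scales as n^(2/3) for filled
FCC balls. Site-displacement histograms use 0.005σ bins normalized to
unit area.

## Problem sizes used in the shipped checks

The published protocol samples each cluster ≥ 10¹⁰ times and reaches
n = 8000; the package's own checks are chosen at desk scale: exact
enumeration at 10⁶ moves, NPT boxes of 864 particles (256 in the unit
tests, with r_c ≈ 3.2 and correspondingly looser tolerances), cluster
windows of width ~10 around n = 100 with ~10⁶ swap attempts after
self-adaptive flattening. At these sizes the bulk densities carry
statistical errors of a few 10⁻³ and the acceptance rates a systematic
uncertainty of order one percentage point (they depend mildly on how flat
the adapted bias is), which the test tolerances reflect.

## What the synthetic generators do and do not emulate

Tiny enumerable models (≤ 12 sites, ≤ 3 liquid particles), multinomial
size samplers with prescribed βΔG, and exact-CNT δΔG series exercise the
acceptance rules, the unbiasing algebra, and the fitting machinery with
known ground truth. They do not emulate the slow collective dynamics of
large clusters (window diffusion, bias-convergence stalls) or interface
fluctuations of real droplets; passing them certifies correctness of the
machinery, while accuracy on real systems is governed by sampling length
and the δΔG linearity assumption of CNT.

## Known limitations

- Lattice-AVBMC clusters are FCC-only; other lattices (HCP, BCC) are not
  implemented.
- The solid-cluster surface is constrained by r: small r over-orders the
  interface, so extrapolated solid *surface* quantities depend on r far
  more than the intercept (bulk chemical potential) does.
- The mean-field tail correction assumes g(r) = 1 beyond the cutoff; for
  crystals this is approximate, which shifts the virial pressure by
  O(10⁻²) even when sampling is exact.
- No explicit vapor box: the reservoir is strictly ideal.
- Incremental connectivity is recomputed by BFS on every deletion rather
  than maintained by a dynamic-connectivity structure; fine at n ≲ 10³.
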