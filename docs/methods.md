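# Methods

This note documents the models implemented in `oxyphase`, the choices made
where the physics or the numerics left freedom, and what the test suite
does and does not demonstrate.

## Units

The lattice model works in dimensionless units: length in lattice spacings
b̄ (one cell diameter, 10 μm by default), energy in k_BT, concentration in
units of the saturation concentration c_s.  The film height is carried in
millimetres because the dimensionless field amplitude factorises as
κ·h[mm], with κ = q/(b̄²c_s D)·10⁻³ evaluated in SI units (κ = 0.84 with
the default constants D = 2×10⁻⁵ cm²/s, c_s = 250 μM, q = 4.2×10⁻¹⁷
mol/s, b̄ = 10 μm).  The simulator's default is κ = 0.85/1.2: the rounded
bare value reduced by 1.2, compensating the two-dimensional treatment of
multilayer aggregates, which overestimates the oxygen available to buried
cells.

## Oxygen field

The film is a slab 0 < z < h with c = c_s at the air interface (z = h),
a consumption flux at the substrate (z = 0), and periodic lateral
boundaries (implied by the spectral treatment).  For the shifted
concentration f = 1 − c/c_s, each lateral Fourier mode obeys an
independent two-point boundary-value problem, giving the substrate kernel

    f(k, 0) = 𝒥(k) · tanh(h̃k)/(h̃k) · κ·h[mm],       K(0) = κ·h[mm],

with h̃ the height in lattice units and 𝒥 = η·q the per-site consumption
map.  Gradients are obtained spectrally (ik multipliers, the unpaired
Nyquist column zeroed so the gradient of a real field stays real).  The
kernel at arbitrary depth sinh(h̃k(1−z̃))/(h̃k·cosh h̃k) is evaluated in an
overflow-safe exponential form.

### Consumption fixed point

Each cell consumes at q = tanh(c/c_csm) (c_csm = 0.02): nearly constant
above c_csm, linear below.  Cells sharing a site share one concentration
and hence one q; the q grid is defined on every site (an empty site
carries the value a cell arriving there would adopt), which keeps warm
starts continuous across moves.  Field and consumption are solved jointly
to max|Δq| < 10⁻⁸ (at most 200 iterations):

* **Fast path** — Anderson-accelerated fixed-point iteration (depth 3,
  regularised least squares, iterates clipped to [0,1]).  Warm-started
  sweeps converge in 2–6 steps whenever consumption is mostly saturated.
* **Stiff path** — in strongly anoxic states (c of order c_csm over large
  regions, e.g. deprived atmospheres or thick films) the bare Picard map
  is expansive: its Jacobian W·K∗(η·), W = tanh′(c/c_csm)/c_csm, has
  collective long-wavelength modes with gain well above unity, and
  accelerated fixed-point iteration stalls.  Those states are solved by an
  inexact Newton method whose Jacobian-vector products are applied
  analytically in Fourier space, with an LGMRES inner solve, a mean-field
  Fourier preconditioner and a backtracking line search on the residual
  max-norm.  A state that needed Newton is marked stiff and subsequent
  solves skip the fast path, re-probing it every 64 solves.

During iteration the concentration is floored at zero when evaluating
tanh; the accepted solution must imply strictly positive concentrations,
otherwise an unphysical-regime error is raised.  Concentrations down to a
few percent of c_s occur in practice and remain positive.

## Lattice Monte Carlo

A site holds at most η_max = 4 cells (an effective cap encoding the
~40 μm maximum aggregate thickness).  Two cells in contact — same site or
8-neighbour (Moore) sites — contribute −ε (ε = 0.15); contacts are counted
once per pair, so the move energetics derive from a consistent Hamiltonian
(this makes the adhesion-only dynamics a genuine equilibrium sampler,
verified against exact Boltzmann enumeration).  A proposed move from m to
m′ carries

    ΔE = ΔE_adh + ΔE_aer + ΔE_occ,

with ΔE_occ infinite (an unconditional rejection) if the target is full,
and the aerotactic term −χ·H[c_aer − c_m]·(∇c·Δr)/c_m implementing
logarithmic gradient sensing below the onset c_aer = 0.1 (χ = 2).  Design
choices the model statement leaves open, fixed here once:

* proposals are uniform over the 8 Moore neighbours, and the directional
  gradient is the spectral gradient at the source dotted with the
  displacement vector (diagonal moves weight it geometrically);
* the onset step is smoothed as H(x) = (1 + tanh(x/w))/2 with w = 0.01 in
  c_s units — an artifact parameter giving a ~1%-of-saturation soft onset;
* within a sweep every cell receives exactly one proposal, in a fresh
  random permutation (avoids lattice-scan artifacts); the field is frozen
  during the sweep and the fixed point re-solved once afterwards, the
  standard particle–field decoupling for local moves;
* acceptance is Metropolis at unit temperature, p = min[1, e^(−ΔE)].

Initial conditions: uniform random placement under the capacity cap, or a
centred disk at η = η_max.  Cell number is conserved exactly (no
division).  One seeded generator drives a run; the sweep kernel is
numba-jitted with the per-sweep random draws supplied by that generator.

A run records the typical aggregate radius a(t); the plateau criterion
compares the means of the last two quarters of the series (difference
below 5%), and steady-state radii are reported as means over the trailing
quarter, over ≥3 seeds where a comparison is printed.

## Continuum model

The aggregate is a disk of radius a and projected density ρ_a = 2×10⁶
cm⁻² at the bottom of a cylindrical Wigner–Seitz-like cell of radius
b = a/√φ with no lateral flux; the background gas of cells covers the
whole substrate, including under the aggregate, at density
ρ_b = ρ̄ − φ·ρ_a.  With this convention φ_max = ρ̄/ρ_a corresponds exactly
to an empty background, and the bottom flux is j(r) = q(ρ_b + ρ_a·1_{r<a}).
The alternative convention — background confined to the annulus r > a with
ρ̄ = φρ_a + (1−φ)ρ_b — is inconsistent with the anchoring worked example
(it gives c(0,0) = 0.078·c_s instead of 0.01·c_s at a = 130 μm, ρ̄ = 10⁶
cm⁻², h = 1 mm, φ = 0.16·φ_max), so the additive convention is used
throughout.

Separating variables with radial modes J0(μ_n r/b), J1(μ_n) = 0, the
minimal (centre) concentration is

    1 − c(0,0)/c_s = (q/(Dc_s)) [ ρ̄h + ρ_a·a·S(√φ, h/b) ],
    S(u, v) = Σ_{n≥1} 2 J1(μ_n u) tanh(μ_n v) / (μ_n² J0(μ_n)²).

The series is summed over 4000 modes with the oscillating tail averaged
over the last two partial sums (tail below 10⁻⁴; verified against an
axisymmetric finite-difference solve to better than 0.5%).  The shape
factor exposed as ψ(√φ, (h/a)√φ) is the rearrangement of the size
condition, ψ = ρ_a·S/(ρ_a − ρ̄); it requires the density pair (ρ̄, ρ_a) as
parameters because no strictly two-argument form is consistent with this
boundary-value problem.

The preferred size solves c(0,0) = ĉ (ĉ/c_s = 0.01, ξ ≡ 1 − ĉ/c_s) by
bracketing and Brent root finding in a (relative tolerance 10⁻⁴).  Finite
aggregates exist for h between h_min = ξDc_s/(qρ_a) and h_max = ξDc_s/(qρ̄)
(0.589 and 1.179 mm at ρ̄ = 10⁶ cm⁻²); at or below the continuous-covering
threshold the solver reports "continuous", at or above h_max "none".  In
the additive-background geometry the a → ∞ limit consumes at ρ_a + ρ_b, so
the actual continuous threshold sits slightly below the closed-form h_min
except at φ = φ_max where they coincide.

Coupling the density to the height through the growth law
ρ̄_exp(h) = ξ_div·Dc_s/(qh) (ξ_div = 0.95, division assumed to stop below
c_div) collapses the size condition to a·S(√φ, h/b) = (Δξ/ξ)·h_min
(Δξ = ξ − ξ_div = 0.04) at every height — consistent with the thick-film
limit a ≈ h_min·Δξ/ξ since S → 1 as φ → 0.  At h = 1 mm this machinery
predicts a ≈ 35.5 μm for φ = 0.16·φ_max and a ≈ 112.5 μm for φ = φ_max.
The spread between the two φ choices (a factor ≈3 at 1 mm, shrinking with
h) is larger than in the original closed-form treatment, whose exact shape
function is not available; the implementation resolves any mismatch in
favour of the boundary-value problem anchored by the 130 μm fixed-density
example, and the tests record the bracket honestly.

## Aggregate statistics

Lattice aggregates are connected components (8-connectivity, matching the
Moore dynamics; periodic wrap) of the η ≥ 3 mask, sorted by decreasing
area.  The representative set adds components largest-first until the
cumulative area first strictly exceeds 90% of the total (the crossing
component is included); the typical radius is a = √(⟨A⟩/π)·b̄ over that
set.  Image domains are segmented by thresholding inverted intensity
(inter-class-variance/Otsu threshold by default; a fixed threshold is
accepted), hole filling and a 20 px minimum-area filter — a documented
reconstruction of an under-specified detector, asserted in tests only on
the robust population of large dark domains.  Mode and FWHM of P(a′) and
P(d′) use Freedman–Diaconis binning with a floor of 8 bins, the mode being
the centre of the maximal bin and the FWHM interpolated linearly between
bin centres; nearest-neighbour distances use the periodic metric for
lattice states and the bounded metric for images.

## Synthetic data

The image generator renders dark disks (log-normal radii, median 100 μm
and shape 0.15, echoing the experimentally observed unimodal distribution)
on a lighter background, placed by dart throwing with a minimum centre
spacing (radius draws truncated at 0.48× the spacing so domains never
overlap) or on a square grid, with optional additive Gaussian noise; the
truth table carries exact centres and radii and everything is
bit-reproducible under a fixed seed.  It emulates only the geometry and
contrast of a large-field brightfield view — no optics, shading or
texture — so detection tests certify the segmentation and statistics
pipeline, not performance on real micrographs.  Lattice generators produce
the canonical uniform, single-disk (η = η_max), random, and
diagonally-touching-blocks states.

## Atmosphere changes

A change of atmospheric oxygen rescales the saturation concentration
c_s → c_s′.  Following the equivalent-height argument this is implemented
as a multiplicative change of the dimensionless field amplitude
(κ·h → κ·h·c_s/c_s′) with the geometric tanh kernel unchanged, applied
mid-run without touching the cell configuration; thresholds c_aer and
c_csm keep their numeric values in the rescaled units.  The alternative
convention (thresholds fixed in absolute concentration) would rescale
both thresholds by c_s/c_s′; it is not selected because the depletion
field itself, not the physiological thresholds, is what the atmosphere
modifies in the equivalent-height picture.

## Problem sizes used in the tests

Full-scale runs (L = 100, 10⁴ cells, 10⁶–10⁷ sweeps) reproduce steady
sizes quantitatively but take hours.  The suite instead runs reduced
surrogates, chosen once: L = 50 with 2×10⁵ sweeps for the height-ordering
and saturation-versus-coarsening checks (h = 1.15 vs 1.30 mm; χ = 2 vs
χ = 0), 6×10⁴ sweeps for the coupled-density rank ordering, and a
172 000-sweep five-phase schedule for the atmosphere step (enrich, return,
deprive, return).  At this scale the absolute steady sizes are distorted
by the small box (a single large aggregate can span an appreciable
fraction of a 500 μm box), so the tests assert orderings, saturation
behaviour and reversibility rather than absolute micrometre values; the
equilibrium sampler itself is validated exactly against Boltzmann
enumeration on small lattices, and the field solver against an
independent 3D finite-difference oracle (band-limited random consumption
maps; agreement to ~0.1%, well within the 1% bound asserted).  A
single-site point source is *not* expected to agree with a lateral
grid-step finite-difference solve at the 1% level — the lattice spectral
solution and the FD discretisation disagree by construction at the
highest wavenumbers (≈9% at the source site) — which is a statement about
the oracle's dispersion, not an error in either solver.

## Known limitations

* No cell division: the cell number is fixed, so density–height coupling
  enters only through initial conditions or the growth-law substitution.
* The 2D lattice with η_max occupancy is an effective description of
  multilayer aggregates; κ carries an empirical 1/1.2 correction.
* Periodic lateral boundaries: meniscus-gradient (laterally varying h)
  experiments are out of reach of the spectral solver.
* The continuum model treats a single disk in a flux-free cylinder;
  interacting aggregates, non-circular shapes and formation kinetics are
  outside its scope.
* Image analysis assumes dark-on-light grayscale input with uniform
  illumination; no artifact correction or tracking.
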