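# Methods

## Model

The package simulates consecutive two-species reaction–diffusion systems
with Schnakenberg kinetics f(u,v) = a − u + u²v, g(u,v) = b − u²v on a
rectangular tissue patch, periodic in y (top/bottom) and zero-flux in x
(left/right); the rectangle stands for a small window of a much larger skin
field, which is why one axis is periodic. The kinetics of system i are
multiplied by a binary competence indicator S_i(x,y); diffusion is never
gated. The model is phenomenological: "competence" is purely geometric
(tissue once patterned stops reacting), with no mechanics, growth, or
cross-system chemistry. Each system starts from its own independently
perturbed homogeneous steady state — the five morphogen pairs are treated
as distinct species coupled only through the geometry of the competent
region.

Assumptions worth keeping in mind:

- The homogeneous steady state (u*, v*) = (a+b, b/(a+b)²) must be stable
  without diffusion (trace of the Jacobian negative) and Turing-unstable
  with it; the analysis module checks both and flags the contrary case.
- Gating only the kinetics means morphogens still diffuse through patterned
  tissue. An optional factor reducing diffusion inside patterned regions is
  deliberately **not** used by the canonical scenarios, which implement the
  equations exactly as written above.
- "Reached stability" is operationalized as the fixed schedule (500 time
  units for system 1, 1,000 for each later system); the convergence flag is
  logged but never gates the sequence. At the default parameters all runs
  are stationary well before the scheduled end.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| a, b | 0.3, 0.8 | – | canonical spot-forming Schnakenberg constants |
| D_u, D_v | 1, 40 | length²/time | ratio 40 is comfortably above the critical ratio d_crit ≈ 28.5 for these kinetics, and k_crit ≈ 0.42 makes the wavelength (~15) comparable to the domain width, so system 1 yields the large primary spots |
| domain | 15 × 25 | length | the tissue patch |
| schedule | 500 + 4 × 1000 | time | per-system durations |
| perturbation amplitude | 0.01 | fraction of (u*, v*) | small enough for the linear theory to pick the pattern, large enough to leave the unstable manifold quickly |
| threshold_fraction | 0.5 | – | a condensation is tissue above half-maximum activator excess over u*; scale-free in overall amplitude |
| min condensation area | 4 cells | – | suppresses single-cell speckle |
| min amplitude | 0.05 · u* | – | a field whose excess over u* is below this everywhere is treated as unpatterned, so relaxed/stable systems yield no spurious spots |
| exclusion margin | 0.5 | length | patterned regions visibly exceed the bright spot cores; dilating condensations by a disc of this radius reproduces that halo |
| per-system seeds | hash(seed, i) | – | independent noise per system, reproducible overall |

All five systems share one parameter set by default; the configuration
accepts a per-system list (the model text indexes D per system but gives no
values, so identical values are the minimal choice).

Diffusion coefficients are exposed per system; whether the original study
varied them is unknown, so the default keeps them equal.

## Linear stability analysis

Eigenvalues of J − k² diag(D_u, D_v) are evaluated from the closed-form 2×2
characteristic polynomial (exact and cheap, no general eigensolver). The
critical diffusion ratio solves the marginal condition
(d f_u + g_v)² = 4 d det J as a quadratic in d = D_v/D_u, taking the root
with d f_u + g_v > 0. The dispersion relation is sampled on a uniform
k-grid augmented with the rectangle's admissible modes
(k_x = πn/15 cosines for zero-flux, k_y = 2πm/25 for periodicity); the
continuous maximizer is refined by bounded scalar minimization and reported
alongside the nearest admissible mode.

## Numerical scheme

Fields live on a uniform cell-centered grid, default 120×200 (spacing
0.125) with dt = 0.05; tests and the acceptance script use 60×100 with
dt = 0.1, which still resolves the wavelength by ~60 cells and is checked
against the finer resolution explicitly. Time stepping is semi-implicit
(IMEX): the 5-point Laplacian is treated implicitly through the transforms
that diagonalize it exactly — DCT-II along x (the mirror-ghost zero-flux
stencil) and a real FFT along y (the wrap) — while the gated kinetics are
explicit. The implicit solve is a per-mode division, so a step costs a few
FFTs; the scheme is unconditionally stable in the diffusion term. An
explicit Euler scheme (with the dt ≤ spacing²/(4 max D) guard enforced) is
provided as an internal cross-check and agrees with IMEX at matched small
dt.

Numerical details and degenerate cases:

- The IMEX fixed points satisfy the dt-independent discrete stationarity
  equation D ∇²u + f·S = 0 exactly, which the refinement tests exploit.
  Halving dt can still shift the final pattern by a fraction of a cell:
  spot patterns are quasi-degenerate under y-translation and the transient
  selects the phase. Pattern-level quantities (spot count, centroids) are
  the stable observables.
- Concentrations may transiently undershoot zero by rounding; values below
  −10⁻⁹, or any NaN/Inf, abort integration with the offending time and
  cell.
- A zero-duration run returns its inputs and evaluates only the
  instantaneous change rate.
- Refinement studies share one noise realization by drawing the initial
  perturbation on a coarse reference grid and block-replicating it
  (`make_initial_condition(..., noise_grid=...)`).

## Competence masks

Condensations are connected components (4-connectivity, wrapping across the
periodic y seam via a union-find merge on top of `scipy.ndimage.label`) of
cells above the half-maximum threshold. Components are restricted to the
system's own competence region: a condensation is patterned tissue, which
in this model can only arise where the kinetics were active — this makes
"condensations never overlap excluded tissue" hold by construction rather
than by numerical accident. Centroids use the circular mean in y. Masks
shrink by removing condensations dilated with a physical-radius disc
(elliptical in cell units if dx ≠ dy, periodic in y), so the sequence of
masks is monotone by construction.

The horseshoe scenario builds an annulus around the system-1 primary spot
(largest area): inner radius 1.2× the primary's equivalent radius, width
2.5 length units, with a 60° half-angle opening facing posterior (+y) —
the sector where no ectopic buds are observed immediately behind the
primary bud. These are package choices; the original figures do not state
the geometry. The ring must not exceed half the periodic extent (it would
overlap itself through the wrap).

## Scenarios

- `full`: mask_{i} = mask_{i−1} minus system-(i−1) condensations.
- `remove_bud2`: system 2 is still simulated, but from system 3 on the mask
  is rebuilt from the condensations of systems 1, 3, …, i−1 only — its
  *influence* is removed, not its pattern.
- `horseshoe`: from system 3 on, the mask is the intersection of
  "not patterned by system 1" with the ring; system 2's placement is
  irrelevant to it.

## Pattern metrics

The primary bud is the largest-area system-1 spot. Every other spot is
classified by (distance, bearing) from it; bearing 0° is anterior (−y),
positive toward +x (the right). Distance beyond the interbud radius gives
class 2 regardless of bearing; otherwise half-open sectors apply: anterior
[−30°, 30°) → 3, lateral ±[30°, 90°) → 4/4′ (right/left by the sign of the
x-offset), posterior-lateral ±[90°, 150°) → 5/5′, and the remaining 60°
posterior wedge is left unclassified (no buds are expected there). The
interbud radius defaults to 0.6× the system-1 nearest-neighbor spacing
(0.6× half the smaller domain extent if system 1 made a single spot);
sector angles and the radius are configurable. Spacing statistics use the
periodic-y metric throughout. Because the anterior direction is part of the
coordinate convention, the symmetry test for the classifier is the
left–right mirror (x → −x), which swaps 4↔4′ and 5↔5′ and fixes 2 and 3.

## Synthetic fixtures

The generator produces the four field families every stage needs:
perturbed homogeneous states (the Turing initial condition), planted
Gaussian condensations with known centers (truncated at 4σ so geometry is
exact), commensurate hexagonal spot lattices (row count quantized to the
period, in-row spacing re-derived to stay equilateral, adjustment
reported), and single Laplacian eigenmodes of the mixed
periodic/zero-flux rectangle. All fixtures are bit-reproducible from their
spec and seed and carry machine-readable ground truth. They emulate
geometry, not biology: no microscopy noise, no tissue curvature, no growth
— so passing detection/classification tests establishes correctness of the
measurement code, not realism of the images it would face in experiments.

## Problem sizes

Sequential runs in the test suite and in `scripts/acceptance.py` use the
60×100 grid at dt = 0.1 (five systems ≈ 10 s); the refinement check runs
the same seed at 120×200 / dt = 0.05 and the symmetry check runs twenty
two-system seeds. The full suite completes in a few minutes on one CPU.

## Limitations

- Exactly two species per system; no amplitude equations, no growing or
  curved domains, no unstructured meshes.
- Competence is geometric; the model cannot speak to mechanics, cell
  movement or proliferation.
- With the default wavelength (~15) the 15×25 patch holds few spots, so
  spot counts are small and mode quantization is strong; wavelength-spacing
  comparisons are made with smaller-wavelength parameters on the same
  patch.
- Animation output is a PNG frame sequence, not an encoded video.
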