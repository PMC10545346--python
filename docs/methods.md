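# Methods

This note documents the models, estimators and numerical choices behind
`germorder`, and what the synthetic data do and do not establish.

## Bond-orientational order

Cell–cell connectivity is approximated by a Voronoi tessellation of the
cell centroids. The n-fold order parameter of cell *j* is

    psi_n(j) = sum_{k in N(j)} l_jk^2 exp(i n theta_jk) / sum_k l_jk^2,

with `l_jk` the length of the shared Voronoi edge and `theta_jk` the angle
of the separation vector from the anterior–posterior (+x) axis
(counterclockwise positive). The edge-length-squared weights make short,
degenerate contacts irrelevant: bonds with `l < 1e-6` of the mean
nearest-neighbour spacing are dropped outright, and exactly degenerate
point sets (perfect lattices, co-circular quadruples) are jittered by
`1e-9` of the spacing before tessellation so the solver's output is well
defined while every jitter-scale edge still falls below the drop
threshold.

**Boundary rule.** A cell is excluded from all statistics when its Voronoi
region is unbounded *or pokes outside the convex hull of the point set*
(hull vertices included). The second clause matters in practice: the
polygons of the first interior ring extend far beyond the data and would
otherwise bias polygon-area-based quantities such as the mean cell length
`l_bar = sqrt(mean Voronoi polygon area)`.

The global order parameter is `|<psi_n>|` over valid cells; its standard
error propagates the component covariance of the complex mean along the
direction of the mean.

## Correlation functions

`C_n(r)` is the mean of `Re[psi_n(x1) psi_n*(x2)]` over unordered pairs
binned by separation (the imaginary parts cancel pairwise, so the curve is
real by construction). Distances are Euclidean in the plane and geodesic
on meshes, in units of the mean cell length. Default bin widths: 0.5 cell
lengths for `C_n`, 0.1 for the high-resolution `g(r)`; both configurable.
Empty bins are reported as NaN (undefined), never zero. `C_n` is reported
unnormalized.

`g(r)` is normalized per centre cell with the effective-volume method:
`g(r) = (1/N) sum_i n_i(r) / (rho dV_i)` with `dV_i` the annular shell
clipped to the measurement rectangle. The clipped area is computed in
closed form (signed corner decomposition of the disc–rectangle
intersection), exact to floating point; a 10^6-sample Monte Carlo oracle
checks it in the tests. For the axis-restricted `g_AP`/`g_DV` (default
wedge half-width 15°) the wedge fraction of the clipped shell approximates
the wedge–rectangle intersection; this is exact for interior cells and a
mild approximation within a shell-width of the boundary. Pairs are counted
once per ordered centre. The reported quantity is `g(r) - 1`.

## Circular statistics for divisions

Division axes are nematic (theta and theta+pi are the same axis); all
statistics live in doubled-angle space. The modified circular mean is
`theta_bar = 1/2 arg(sum exp(2 i theta))`, mapped to [-pi/2, pi/2); it is
undefined (NaN) when the doubled resultant vanishes. The angular
dispersion is `s = sqrt(2 (1 - R2))` with `R2` the doubled-angle mean
resultant length, ranging from 0 (perfect alignment) to sqrt(2)
(isotropy); the unrooted variant `2 (1 - R2)` is available behind a flag.
Von Mises fits are maximum likelihood on the doubled angles with the
location fixed at the circular mean; a resultant within 1e-12 of unity
saturates the concentration at a documented cap (1e4) with a flag.

Wave speeds are ordinary least-squares slopes of division position vs.
division time: absolute time and A–P position across rows; distance from
the ventral midline `|y|` vs. time relative to the first event of the wave
in each parasegment for the D–V direction, pooling the two sides (per-side
fits available). Doubling times come from least squares on
`log2 N(t) = log2 N0 + t / tau`; constant counts give `tau = inf` with a
flag. Pre-division reorientation flags an event whose presumptive axis at
(t_div - 5 min) differs nematically from the final axis by more than 45°;
events whose angle track does not cover the window are excluded from the
denominator and reported.

## Division-driven flow

Tissue velocity solves `lap(v) + 1/(1-2 nu) grad(div v) = 0` with
`nu = 1/3` throughout (the dimensional shear/bulk viscosities are absorbed
by the renormalization and never appear individually). Each division is a
circular Eshelby inclusion of radius set so the hole area equals the
dividing cell's Voronoi polygon area, with eigenstrain
`eps* = (M/2) I + q (2 n n^T - I)` along the measured division axis.

The exterior displacement was derived from Muskhelishvili complex
potentials by matching displacement and traction across the interface
(kappa = 3 - 4 nu):

    u(z) = a^2/(4(1-nu)) [ M/conj(z) + q (kappa/z + z/conj(z)^2 - a^2/conj(z)^3) ]

for the axis along +x, rotated for general axes; the interior strain is
uniform with components `(M +/- q kappa)/(kappa + 1)`, consistent with the
2D Eshelby tensor. Two independent oracles validate the constants: an
axisymmetric finite-difference solve of the radial Navier ODE for the
dilatational part (agreement < 1% on r in [1.5a, 10a]) and the FEM solver
itself on an annulus (relative L2 < 2% — in practice ~0.3% — on [2a, 5a]).

The FEM is a vectorized P1 Galerkin discretization of
`integral(grad u : grad v + 1/(1-2 nu) div u div v)` with Dirichlet data
everywhere: measured velocities on the exterior boundary, own-inclusion
analytic displacement plus a uniform advection velocity on each hole rim
(per-inclusion advection behind a flag). Meshes are Delaunay
triangulations of a structured grid plus hole-rim rings (rim edge length
at most a/4), holes excised by centroid tests, orphan nodes compacted;
overlapping holes or holes touching the exterior boundary fail loudly.
Direct sparse solves. Dividing cells' velocities are the displacements of
the deformed-inclusion ellipse foci; non-dividing cells average the nodal
solution over their Voronoi polygons.

Because the solution is affine in (M, q), the amplitude fit performs three
FEM solves and minimizes the mean velocity residual over the affine family
by Nelder–Mead from a fixed 5x5 start grid (ties broken by smallest |q|) —
deterministic given the inputs. The residual is

    R(x) = |<v> u(x) - <u> v(x)|^2 / (2 <u>^2 <v>^2),

with `<.>` the root-mean-square field magnitude: zero for fields equal up
to positive scale, one for typical-magnitude orthogonal fields, symmetric
and pointwise non-negative. A measured field that is identically zero
admits any parallel prediction under this scale-invariant residual; the
fit returns the zero-residual solution (0, 0) in that case.

Patch averaging for the mean division flow maps each division's
neighbourhood rigidly (daughter centre of mass to the origin, axis to +y),
co-rotates velocities, and averages linear interpolants on a common polar
grid. Any interpolant satisfying the rigid-equivariance contract is
acceptable; piecewise-linear interpolation is used.

## Vertex model

Cells are simple polygons with shared vertices; the energy is
`e = sum_c (A_c - A0)^2 + k_P (P_c - P0)^2` with `k_P = 1`, per-cell
targets `A0 = 1`, `P0 = p0 sqrt(A0)` and `p0 = 4` (perfect square). A
division event proceeds as mitotic elongation followed by cleavage: the
mother's targets swell to a 2:1 rectangle of twice its area oriented along
the division axis and the tissue relaxes; the cell is then cut through its
centroid perpendicular to the axis, and the daughters inherit the mother's
original square targets, so the tissue doubles its area over a round while
growth pushes only along division axes. Cut endpoints within
`0.12 sqrt(A)` of an existing vertex reuse it — without this snapping,
consecutive divisions of neighbouring cells deposit near-duplicate
vertices whose tiny edges trigger T1 churn and destroy the lattice.

Relaxation is damped gradient descent with backtracking line search for a
fixed effort (150 iterations) per division event — overdamped dynamics
with a finite mechanical-remodelling time rather than full quasi-static
equilibration — followed by T1 swaps of interior edges shorter than
`0.05 sqrt(A0)` (new edge 1.5x threshold; swaps producing non-simple
polygons are rejected). The boundary is free. Wave ordering sorts cells by
row (anterior to posterior) and then by distance from the horizontal
midline outward; random ordering permutes all cells.

A caveat worth knowing: at `p0 = 4` the square lattice is marginally
floppy — every shape with P = 4 and A = 1 has zero energy — so relaxation
heals perturbations back to the energy floor but not to exact coordinates,
and residual displacements of order 1e-2 can persist along ~1e-7-energy
directions. The order-parameter contrasts are insensitive to this.

At these defaults a 12x12 starting grid gives, after one full round,
global `|psi4|` of ~1.0 for a perfectly oriented wave, ~0.95 for perfectly
oriented but randomly timed divisions (timing barely matters), and ~0.2
for uniformly random axes.

## Synthetic germband

The generator emulates the study conditions at the track level: parasegment
rows assembled anterior to posterior; wave w of row r starting at
`r * stagger + w * tau` (stagger defaults to row spacing / A–P speed, so
division events advance across rows at exactly the configured A–P speed);
within-row divisions delayed by `|y| / v_DV` from the ventral midline;
axes von Mises about the A–P axis in doubled angles; Gaussian timing
jitter and positional jitter; a planted fraction of >45° late
reorientations; optional differential cleavage near the midline.
Defaults: 8 rows x 8 cells, 10 um spacing, doubling time 10 h, A–P speed
7.5 um/h, D–V speed 19.2 um/h, concentration kappa = 20, timing jitter
0.1 h, positional jitter 0.3 um, reorientation fraction 7.4%.

Rows are static and daughters are placed symmetrically at
`+/- d / 2^(g+2)` about the mother along the division axis (g = parent
generation), so each completed wave refines the tissue into a finer
rectangular lattice without any advection map. This keeps division-event
positions exactly on the configured wave lines (wave-speed fits recover
the inputs) and keeps snapshots plausibly ordered, at the cost of a rising
cell density: the real tissue instead elongates at constant density during
row insertion. Consequently the generator supports order, choreography and
kinetics analyses, but not density- or area-time-course studies, and the
flow module's measured-velocity inputs must come from elsewhere (the
pipeline's flow stage demonstrates the forward prediction only). Passing
tests on this generator shows the estimators recover known choreography
parameters under realistic noise — not that segmentation, tracking or
surface-extraction errors of real imaging are handled.

Null models: Bridson blue-noise sampling thinned to the exact target count
(min spacing defaulting to the value that lands Bridson ~12% above target;
infeasible density/spacing combinations fail before sampling), and square
lattices with isotropic Gaussian noise of SD = lattice constant / SNR
(SNR = 5 default; the "signal" is the lattice constant). The two-sample
Kolmogorov–Smirnov test uses the exact ECDF supremum and the asymptotic
Kolmogorov tail with the standard finite-sample effective-size correction
`lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) D`; a permutation oracle
bounds it within a factor of two at n = m = 8.

## Mesh geometry

Gaussian curvature is the barycentric-area-normalized angle deficit
(boundary vertices NaN — the 2 pi deficit does not apply); discrete
Gauss–Bonnet `sum K A = 2 pi chi` holds to 1e-9 on closed meshes. Mean
curvature projects the cotangent Laplacian of position onto angle-weighted
vertex normals; with counterclockwise faces and outward normals, convex
surfaces carry H < 0 under this convention (only |H| is geometric).
Geodesics use the heat method (`t = mean edge length squared`); planar
meshes short-circuit to exact Euclidean distances through the same entry
point, and source/target points snap to the nearest vertex within a
relative tolerance (0.1% of the bounding-box diagonal) or fail. Accuracy
on a subdivision-4 icosphere is ~1% against great-circle arcs, adequate
for correlation binning.

## Problem sizes and reproducibility

All simulations and replicate studies are sized for a laptop-class single
core: 12x12 vertex-model rounds with 5 seeds per condition, 100-replicate
wave-speed recoveries, 20-replicate doubling-time recoveries,
10^6-sample Monte Carlo shell-area checks. Every stochastic component
draws from `numpy.random.default_rng` seeded explicitly from configs or
function arguments; pipeline runs record the config hash, seed and package
version in a manifest, and rerunning a config reproduces deterministic
outputs bit-identically.
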