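# Methods

This note describes the models implemented in `kfibers`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real spindles.

## The director field and streamlines

Spindle microtubules align locally with their neighbours. In the
one-elastic-constant active-liquid-crystal description, with no
hydrodynamic flows, the steady-state headless orientation field n(x)
(n ≡ −n) satisfies the Laplace equation ∇²n = 0 inside the spindle, with
*tangential anchoring* on the elliptical spindle boundary and *radial
anchoring* on two +1 aster disks representing the poles. The solution
depends only on the geometry — the ellipse semi-axes a, b, the two defect
centers on the long axis, and the defect radius — and on no material
parameter.

**Discretization.** The 2D solve works in the doubled-angle representation
(cos 2θ, sin 2θ), which is single-valued for a headless field: each bulk
cell is relaxed to the normalized average of its four neighbours
(harmonic-map relaxation), with boundary and defect cells re-imposed every
sweep. Sweeps are red–black Gauss–Seidel: plain Jacobi leaves the period-2
checkerboard mode neutrally stable (eigenvalue −1 of the 4-neighbour
average) and can oscillate indefinitely in strongly frustrated
configurations. The residual is the largest torque on any bulk cell — the
component of the neighbour average perpendicular to the cell director —
which vanishes at the harmonic-map fixed point; the default tolerance is
10⁻⁶.

**Initialization and continuation.** A uniform initial field cannot build
the winding-2 doubled-angle topology the boundary data demand, and
relaxation from it pins spurious lattice defects. The solver therefore
starts from a bipolar-aster ansatz — the direction field whose integral
curves are circles through both defect centers, which is radial at each
defect and near-tangential at a spindle-shaped boundary — and runs
coarse-to-fine continuation (4×, 2×, then the target spacing), since angle
domain walls depin far more easily on coarse grids. *Known limitation:* in
a maximally frustrated geometry (a concentric radial defect inside a
tangentially anchored circle, where the two anchorings disagree by exactly
π/2 along the whole boundary) a lattice-pinned π wall in the doubled angle
can survive next to the boundary; the elongated geometries with near-pole
defects that the package targets do not excite this mode, as the
grid-refinement tests verify (interior bulk angles change < 0.01 rad when
the spacing is halved).

**Axisymmetric (3D) solves.** `solve_director(..., axisymmetric=True)`
relaxes the meridional (x, ρ) half-plane with the cylindrical stencil
(∂xx + ∂ρρ + ρ⁻¹∂ρ, with the symmetry condition 2∂ρρ on the axis row).
For the rotationally symmetric spindle this yields the 3D field in any
plane containing the axis at 2D cost, and 3D streamlines remain in
meridional planes, so the planar tracer applies unchanged.

**Streamlines.** Curves tangent to the director are integrated with a
fixed-step midpoint (RK2) scheme, step = half the grid spacing, the
headless sign chosen each step to reduce the distance to the target pole.
Integration stops on entering the defect disk (the radial continuation to
the defect center supplies the remaining arc length, so s = 0 exactly at
the pole center) or on entering the polar cap behind the defect, where
edge streamlines funnel around the defect rim. Trajectory points that
overshoot the discrete boundary by less than one step are projected back
inside; larger exits raise an error, flagging inconsistent geometry.
Seeds sit on the equatorial midplane every 0.5 µm, symmetric about the
axis, with edge seeds nudged half a grid cell inward.

## Minus-end flux balance

Along a streamline with arc length s from the pole, the steady-state
density n(s) of KMT minus ends obeys

    j(s) + v(s) dn/ds + n(s) dv/ds − r n(s) = 0,

with j the recruitment rate density, v ≥ 0 the poleward minus-end speed
and r the (position-independent) kinetochore detachment rate, default
0.4 min⁻¹ from the measured bulk KMT lifetime. The solver uses the
conservative flux form d(nv)/ds = r n − j, integrating from the pole with
zero poleward minus-end flux at s = 0:

    v(s) = [∫₀ˢ (r n − j) ds′] / n(s).

This avoids differentiating a noisy density and makes the kinetochore-end
flux automatically equal the per-streamline nucleation rate. Regions where
n falls below 10⁻⁴ of its maximum are masked. For the *nucleate* model
(j = 0 in the bulk) a flat bulk density forces dv/ds = r exactly; for the
*capture* model, j(s) ∝ n_nonKMT(s)·P_reach(s) with
P_reach = exp(−(s_kin−s)/L) the probability a non-KMT grows the remaining
distance to the kinetochore before catastrophe (L configurable, default
2 µm = the mean non-KMT length; L = ∞ gives P ≡ 1). The capture channel is
normalized so total recruitment balances total detachment; with
n_nonKMT ≈ n_KMT and P ≡ 1 this recapitulates the standing distribution
and v ≡ 0 — the near-zero-speed capture prediction. Hybrids carry a
fraction f of recruitment through the capture channel and 1 − f through
the kinetochore point source.

The measured minus-end density is a pooled histogram across streamlines
(per-streamline-µm convention), counting minus ends whose plus end lies
upstream, fit to a Gaussian-plus-constant by least squares. The Gaussian's
center and width are bounded to the pole half / quarter of the domain:
without this constraint the decomposition is unidentifiable on nearly
flat data (a domain-wide Gaussian mimics the constant), and the bound
encodes the physical reading of the component as a pole peak.

Near the pole (s ≤ s_p = 1.5 µm) minus-end depolymerases chew pinned
minus ends, so tubulin treadmills through KMTs at
v_tread = [v(s_p) − v(s)]·θ(s_p − s); the tubulin speed v_tub = v + v_tread
is continuous and equals v(s_p) throughout the pole region.

## The stochastic KMT lifecycle simulation

Each kinetochore anchors one streamline at coordinate s_kin. Per time step
(dt = 0.01 min): Poisson births per kinetochore; nucleated KMTs start at
zero length (minus end at s_kin), captured ones draw their initial minus
end from j(s); minus ends advect by explicit Euler ds/dt = −v(s) (v is
smooth and ≲ µm/min, so Euler at this dt is far below the discretization
error of anything measured); ends reaching the pole pin at the defect
edge; each KMT detaches after an exponential lifetime with rate r. KMTs
never leave their streamline. Burn-in is 10 min = 4/r before any
measurement; fixed seeds give identical trajectories. The completed
lifetime log stores birth times as well: the raw log is right-censored by
the end of the run, which a KS test at n = 10⁴ resolves, so distributional
tests use the cohort born ≥ 10/r before the end.

By construction, the nucleate-model flux solution drives the simulated
minus-end distribution back to the n(s) it was derived from; the
simulator tests verify this closure (KS p > 0.01 at 10⁴ pooled samples),
the exponentiality of detachment times, and the steady-state count
(nucleation rate / r within Poisson bands).

## Photoconversion: simulation and analysis

**Forward model.** A line at a chosen spindle-axis position marks tubulin
on every live KMT with a modified-Cauchy profile
(1 + (x/γ)²)^(−p), γ = 1.0 µm, p = 1 by default — the measured activation
width scale (the axial width of the two-photon line is σ_z = 1.0 ± 0.1 µm);
the tail exponent is exposed because the exact profile shape is an
empirical fit. All marks on one KMT move rigidly at the tubulin speed
v_tub(s_minus) of that KMT's minus end; marks crossing the (depolymerizing)
minus end vanish, and a KMT's detachment removes its marks. Frames are
rendered at 0.1 µm/px by bilinear deposition of mark weights plus a 1 px
optical blur; an optional immobile fast pool (rate 1/0.26 min⁻¹) stands in
for the non-KMT background.

**Analysis.** Mirrors the experimental chain: band-average 15 px either
side of the pole–pole axis (map_coordinates sampling; an optional narrow
central sub-band reproduces the thin-section control); per frame, Gaussian
fit over the central 5 px of the candidate local maximum nearest the
previous frame's peak; background = Gaussian height at the mirror position
on the opposite half-spindle; heights corrected as
(main − opposite)/bleach with a dark-corrected bleaching reference;
speed = −slope of center vs time (poleward positive, ≥ 5 valid frames);
turnover = dual-exponential fit seeded by a log-linear fit of the late
tail (slow) and the early residual (fast), with flags for
identifiability (k_fast < 2 k_slow), short records (< 2 slow lifetimes)
and boundary-stuck parameters.

On synthetic movies at the experimental conditions (slow fraction 0.26,
lifetimes 2.8 and 0.26 min, 5 s frames, 2.5 min records, SNR ≈ 10) the
chain recovers slow fraction, both lifetimes and the line speed within a
few percent; the 2.5 min record is shorter than two slow lifetimes, so
fits carry the short-record flag exactly as the experimental ones would.

**What the measured line speed is.** The activated line contains marked
tubulin from *every* KMT spanning it, so the measured line speed is the
minus-end-density-weighted mixture of tubulin speeds, not v_tub at the
line position. Its gradient with line position is

    d⟨v⟩/ds = r − n(s)·⟨v⟩(s)/N(s),    N(s) = ∫₀ˢ n ds′,

strictly below the minus-end relation dv/ds = r whenever the bulk density
is nonzero. With the default study conditions the pipeline measures a
slope ≈ 0.25 (µm/min)/µm against r = 0.4 min⁻¹ — the same ratio the
experimental measurement reports. The end-to-end test therefore asserts
the qualitative dichotomy (nucleate: speeds rise away from the pole;
capture: near-zero speeds) and documents that the measured slope sits
below r for this structural reason. Lines are placed in the bulk of one
half-spindle (1.5–4.0 µm from the pole): equator-adjacent lines pick up
marks from the opposite half-spindle whose anti-poleward motion makes the
tracked center there unstable. Each position is averaged over replicate
simulated populations, mirroring the per-bin averaging of the
experimental dataset.

## Orientation statistics

All circular statistics run in the doubled-angle representation:
⟨θ⟩ = arg⟨e^{2iθ}⟩/2 and the scalar nematic order parameter
S = ⟨(3 cos²(θ − ⟨θ⟩) − 1)/2⟩, which is 1 for perfect alignment, 0 for 3D
isotropy and −0.5 for perpendicular alignment. This uniaxial convention is
the default even for in-plane projected angles (matching how the
experimental values were computed); the 2D estimator ⟨cos 2Δ⟩ — whose
isotropic in-plane expectation is 0 — is available via `estimator="2d"`.
Binned fields accumulate 0.1 µm microtubule segments into 0.1 µm bins,
weighted by segment length; rotational averaging rotates the 3D segment
cloud about the spindle axis in π/10 increments before projection.
Registration rescales each spindle's axis by the pole–pole distance and
its radial direction by the width of an ellipse fitted to the density
(threshold at a configurable quantile, ellipse from the second moments of
the mask — a robust equivalent of perimeter least squares), then averages
in the doubled-angle representation.

Geometry fitting is staged: first the elliptical boundary (center,
height, width) with the defects pinned at the ellipse vertices, then,
with the boundary frozen, the defect positions along the axis and the
defect radius, both by Nelder–Mead on a density-weighted χ² over occupied
bins between measured and model angles. Empty bins are excluded.
Displacing the fitted defects to the spindle interior or periphery
degrades χ² several-fold.

## Synthetic data: what it emulates and what it does not

The generators provide closed-loop ground truth, not realism:

* **Spindle reconstructions** lay KMTs along streamlines of the solved
  field with per-segment von-Mises angular noise drawn in the doubled
  angle (respecting headless symmetry; concentration κ maps to a local 2D
  order parameter I₁(κ)/I₀(κ)); minus-end positions are drawn from the
  configured n(s); non-KMTs get exponential lengths (mean 2 µm). Defaults:
  HeLa-like geometry (a = 6, b = 3.5 µm, defects at ±5 µm, radius 0.5 µm),
  κ = 50, and n(s) = Gaussian(center 1 µm, σ 0.6 µm) + constant with a
  peak/bulk amplitude ratio of 2 (≈ 25% of minus-end mass in the pole
  peak). The pooled per-µm density along streamlines is deliberately less
  pole-concentrated than the 3D-distance histogram (which puts ~half the
  minus ends within 1.7 µm of the pole — the generated spindles reproduce
  that statistic through the arc-length/3D-distance geometry), because
  only a modest pooled peak is simultaneously consistent with measured
  line speeds of 0.2–1.2 µm/min through v = r·N(s)/n(s). Real features
  *not* emulated: K-Fiber bundling, MT curvature fluctuations beyond the
  angular-noise walk, chromosome bodies, z-anisotropy of the
  reconstruction volume.
* **Photoconversion movies** render an advecting, decaying, bleaching
  modified-Cauchy line with Gaussian (optionally shot) noise and perfect
  pole markers; no point-spread function, drift or marker-localization
  error. Parameter-recovery results on these movies bound estimator bias
  and variance under ideal imaging, not robustness to tracking failures.
* **Orientation maps** sample the model field with wrapped Gaussian noise
  and a flat density weight; retardance physics (per-MT birefringence) is
  out of scope.

One measurement subtlety: resampling a noisy polyline into chords
vector-averages adjacent (sign-aligned) steps, which slightly inflates
alignment measured on resampled segments; tests of the angular-noise
mechanism therefore read the raw polyline edges.

## Model comparison

Hybrid predictions share one minus-end profile and one capture shape; for
each capture fraction f on a 0.05 grid the flux solve plus treadmilling
yields a speed curve, evaluated at the dataset's position bins (a full
photoconversion-simulation round trip can be substituted through the
`simulate` hook). The likelihood is independent Gaussian per bin with the
bin SEM (optionally inflated by Monte-Carlo prediction noise), under a
uniform prior; the posterior is normalized on the grid. Calibration:
with data generated at a known f*, the posterior mode lands in the
generating grid cell in ≳ 95% of replicates at experiment-like SEMs.

## Problem sizes

Default test and acceptance workloads are sized for a single CPU: director
grids of 0.05–0.25 µm spacing on ~10 µm domains, 30 streamlines, simulated
populations of a few hundred KMTs (10⁴ pooled minus-end samples for
distributional tests), 100–200 movie replicates for recovery statistics,
and 8 replicate populations × 6 line positions for the end-to-end speed
curves.
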