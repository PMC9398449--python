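# kfibers

Quantitative machinery for studying how kinetochore-fibers self-organize
in metaphase mitotic spindles.

During cell division, each chromosome is held by a bundle of kinetochore
microtubules (KMTs) whose plus ends are embedded in the kinetochore and
whose minus ends point toward a spindle pole. Electron-tomography
reconstructions of human (HeLa) metaphase spindles show that roughly half
of all KMT minus ends never reach the pole. `kfibers` implements the
modeling and analysis stack needed to ask why: where are new KMTs
recruited (nucleated de novo at the kinetochore vs captured from the
non-KMT pool), along what trajectories do they grow, how fast do their
minus ends move, and how do they detach?

The package answers these questions with four connected components:

* **Nematic director field.** Spindle microtubules behave as an active
  liquid crystal; at steady state, with a single elastic constant and no
  flows, the headless orientation field obeys the Laplace equation
  ∇²**n** = 0 inside an elliptical spindle with tangential boundary
  anchoring and two +1 aster defects at the poles. The finite-difference
  solver works in the doubled-angle representation (cos 2θ, sin 2θ) and
  its streamlines — curves tangent to **n** — are the tracks KMTs follow.
  The solution depends only on geometry, not on any material parameter.
* **Minus-end flux balance.** Along a streamline with arc length *s* from
  the pole, the steady-state minus-end density n(s) satisfies
  j(s) + v dn/ds + n dv/ds − r·n = 0 (recruitment, advection,
  detachment). Given a measured n(s) and a recruitment hypothesis j(s),
  the solver returns the minus-end speed profile v(s). Nucleation at the
  kinetochore (j = 0 in the bulk) forces dv/ds = r where n is flat —
  speeds grow linearly away from the pole; capture from the spindle
  (j ≈ r·n) predicts near-zero speeds. Minus-end depolymerization at the
  pole (s ≤ s_p = 1.5 µm) makes tubulin treadmill at
  v_tread = [v(s_p) − v(s)]·θ(s_p − s).
* **Stochastic KMT lifecycle simulation.** Poisson recruitment at each
  kinetochore, advection of minus ends along streamlines at v(s),
  pole-region treadmilling, and exponential detachment at r = 0.4 min⁻¹,
  in a 2D central slice or the axisymmetric 3D field.
* **Photoconversion.** Both directions of the marking experiment:
  simulate a photoconverted line of tubulin (modified-Cauchy profile) in
  the model spindle, and analyze movies — line profiles band-averaged
  about the pole–pole axis, Gaussian peak tracking, bleaching and
  background corrections, dual-exponential turnover
  (A_s e^{−k_s t} + A_f e^{−k_f t}, slow = KMT, fast = non-KMT) and linear
  speed fits — plus a Bayesian comparison of hybrid recruitment models
  against speed-vs-position data.

A synthetic-data module generates spindle reconstructions, photoconversion
movies and orientation maps with known ground truth, so every analysis
stage is tested closed-loop without downloads.

## Worked example

```python
import numpy as np
from kfibers import flux_balance as fb, nematic_field as nf
from kfibers import photoconversion as pc, synthetic_data as sd

# solve the director field for a HeLa-like spindle and trace a streamline
geom = sd.default_geometry()                       # 12 x 7 um ellipse, poles at +-5 um
field = nf.solve_director(geom, spacing=0.15, tol=1e-5)
sl = nf.trace_streamline(field, start=np.array([0.0, 2.0]), target_pole=0)
print(f"streamline arc length to the pole: {sl.s_max:.2f} um")

# infer the minus-end speed profile under kinetochore nucleation
n_of_s = sd.SyntheticSpindleConfig().minus_end_density
speed = fb.treadmill_profile(
    fb.solve_speed(n_of_s, fb.nucleate_model(), r=0.4, s_max=sl.s_max)
)
print(f"v(1.5 um) = {speed.v_at(1.5):.2f} um/min, v(4.5 um) = {speed.v_at(4.5):.2f} um/min")

# generate a photoconversion movie at experimental conditions and analyze it
cfg = sd.SyntheticMovieConfig(speed=1.2, activation_x0=3.5, noise_sd=0.5, seed=7)
movie, truth = sd.generate_movie(cfg)
result = pc.analyze_movie(movie, bleach=sd.bleach_curve(cfg))
print(f"line speed: {result.speed.speed_um_per_min:.2f} um/min (true 1.20)")
print(f"slow fraction: {result.turnover.slow_fraction:.3f} (true 0.260)")
print(f"KMT lifetime: {result.turnover.lifetime_slow_min:.2f} min (true 2.80)")
print(f"non-KMT lifetime: {result.turnover.lifetime_fast_min:.3f} min (true 0.260)")
```

Output:

```
streamline arc length to the pole: 5.75 um
v(1.5 um) = 0.62 um/min, v(4.5 um) = 2.95 um/min
line speed: 1.20 um/min (true 1.20)
slow fraction: 0.267 (true 0.260)
KMT lifetime: 2.86 min (true 2.80)
non-KMT lifetime: 0.263 min (true 0.260)
```

The streamline from the equator at 2 µm off-axis curves into the pole
after 5.75 µm of arc. Under kinetochore nucleation the inferred minus-end
speed rises from 0.62 µm/min near the pole region boundary to ~3 µm/min in
the outer bulk — longer KMTs grow more slowly. The analysis chain recovers
the generating turnover parameters of the movie (26% slow-turnover
tubulin with a 2.8 min KMT lifetime against a 0.26 min non-KMT
background) to within a few percent.

A thin CLI mirrors the library: `kfibers synth spindle|movie|map`,
`kfibers field solve`, `kfibers orient analyze`, `kfibers flux solve`,
`kfibers simulate run`, `kfibers photo analyze|simulate`,
`kfibers compare run`, `kfibers io validate`. See `kfibers --help`.

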