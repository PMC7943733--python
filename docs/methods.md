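# Methods

## Physical model

A phase-only spatial light modulator (SLM) sits in a pupil plane of a
multiphoton excitation path. Displaying a phase mask Φ(x′, y′) over the round
aperture Ω redistributes the focal field into a set of N diffraction-limited
spots at sample coordinates Xₙ = (xₙ, yₙ, zₙ). The ideal wavefront for a
single spot is a tilt plus a quadratic defocus,

    φₙ(x′, y′) = (2π/λf)(xₙx′ + yₙy′) + (2π/λf²)(x′² + y′²) zₙ ,

and a multi-spot hologram is the phase of the coherent superposition

    Φ = arg( Σₙ aₙ e^{i(φₙ + θₙ)} ) .

The field each spot receives back from a displayed mask is the conjugated
pupil sum Eₙ = Σ_Ω A e^{−i(Φ − φₙ)}, where A(x′, y′) is the illumination
amplitude. Everything in the package — the three synthesis algorithms and
all quality metrics — is built from these three primitives.

Conventions the formulas do not fix, chosen here once:

- Pixel centres at (i + 0.5 − D/2)·pitch, so the aperture centre falls
  between pixels and the active set Ω is exactly the centres inside the
  circle (fill factor → π/4).
- A is normalised to unit power, Σ_Ω A² = 1. The intensity fraction of a
  spot is Iₙ = ‖Eₙ‖²/(Σ_Ω A)², which makes a perfectly conjugated single
  spot score exactly 1 and bounds Σₙ Iₙ by 1 for resolved spots.
- Phase wraps to [0, 2π); arg(0) := 0 at exactly-cancelled pixels.
- Target amplitudes are normalised to Σ‖aₙ⁰‖² = 1; any positive rescale
  leaves every hologram iterate unchanged (asserted as a property test).

## Reference geometry and its parameters

| parameter | default | meaning |
| --- | --- | --- |
| aperture | 1,152 px | diameter of the round active region |
| pitch | 9.2 µm | SLM pixel pitch |
| wavelength | 800 nm | excitation wavelength |
| effective focal f | 5.4 mm | compound system focal length seen from the SLM |
| illumination | Gaussian, 6 mm amplitude waist | truncated by the aperture |

The effective focal length is derived, not measured: a 9 mm objective focal
length demagnified by the 5:3 pupil relay that matches the 10.6 mm SLM short
side to the 18 mm objective back aperture. It is exposed in the geometry
config because any error in it only rescales the sample coordinates. With
these constants the aliasing-free lateral field of view is ±λf/(2·pitch) ≈
±234 µm, consistent with the benchmark patterns (300 µm cubes, 200 µm grids).

Both Gaussian and uniform illumination are implemented; Gaussian is the
default since that is the physical beam. The simulated metrics are nearly
insensitive to the choice (the normalisation of Iₙ absorbs the profile).

`PupilModel.scaled(D)` produces desk-scale pupils for fast runs. It scales
the Gaussian waist with the aperture so the beam truncation ratio — the only
dimensionless parameter of the illumination — matches the reference
geometry. Wavelength, pitch and f are kept, so sample coordinates keep their
meaning at proportionally reduced numerical aperture.

## Algorithms

**RS (random superposition).** Draw θₙ i.i.d. uniform on [0, 2π) and
superpose once. Cost: M·N pixel evaluations (M = |Ω|).

**WGS (weighted Gerchberg-Saxton).** Iteration 0 is RS. Each iteration
computes the spot fields, locks θₙ = arg Eₙ, and multiplies per-spot weights
by ⟨dₙ⟩/dₙ where dₙ is the drive; amplitudes aₙ = wₙaₙ⁰ feed the next
superposition. Two weight modes:

- `target_normalized` (default): dₙ = ‖Eₙ‖/aₙ⁰, whose fixed point is power
  shares proportional to the targets (Fₙ → 1 for arbitrary targets);
- `literal`: dₙ = ‖Eₙ‖, whose fixed point is equal magnitudes — correct for
  uniform targets only, kept for parity with the classical formulation.

Weights are clamped at 10⁶ if a spot field collapses to zero (degenerate
early iterates on symmetric grids); a warning is emitted. Cost: M·N·I per
projection direction.

**CS-WGS.** Identical to WGS, but both projections run on a random pixel
subset of size ⌈c·M⌉ for all but the last `terminal_full` iterations
(default 2), which run at full sampling and produce the phase on every
pixel. The subset is a prefix of one seeded permutation drawn at start
(`fixed` mode, default); a `redraw` mode draws a fresh subset per iteration.
Compressed spot-field estimates have arbitrary scale, so quality metrics are
only ever computed from full-sampling fields. Cost per direction:
2·M·N + c·M·N·(I − 2).

One scheduling subtlety: with alternating projections, a literal "both
projections full for the last two iterations" is impossible — the forward
projection of the first full iteration consumes a phase that exists only on
the subset. The schedule used is: backward (superposition) full on the last
two iterations; forward full on the last iteration plus the final quality
evaluation. Counting that final evaluation as the last forward pass makes
the measured counters of both directions equal the cost formula exactly,
which the tests assert.

At c = 1 the subset is all of Ω and the implementation routes through the
identical full-sampling code path, so CS-WGS(c=1) is bit-identical to WGS
under equal seeds.

## Quality metrics

From full-sampling intensity fractions Iₙ and targets aₙ⁰:

- efficiency e = Σₙ Iₙ;
- power ratios Fₙ = (Iₙ/ΣI) / (‖aₙ⁰‖²/Σ‖a⁰‖²);
- uniformity u = 1 − (max F − min F)/(max F + min F);
- variance v = ⟨(Fₙ − 1)²⟩.

All three are invariant under rescaling intensities or targets. For N = 1,
F₁ = 1 by self-normalisation, hence u = 1 and v = 0. Near convergence WGS's
u can limit-cycle at the 10⁻⁴ level; the monotonicity property asserted in
the tests is relaxed accordingly.

## Benchmark protocols

Wall-clock time is replaced everywhere by pixel-evaluation counts, the unit
the algorithms' own scaling laws are written in and the only one that is
hardware-independent. Measured counters are asserted against the predicted
formulas exactly, so a budget in "full-iteration equivalents" is well
defined.

- *Convergence-to-target*: the smallest iteration count whose final
  uniformity reaches a fraction (default 92%) of a 200-iteration WGS
  reference. For WGS one long run suffices because the per-iteration trace
  quality equals the final quality of a shorter run; CS-WGS is rescanned per
  candidate count because its terminal full iterations depend on the total.
- *Fixed budget*: the largest iteration count whose predicted cost fits a
  given evaluation budget, emulating a fixed SLM refresh window. The default
  budget in the sweeps is three full-iteration equivalents — a compute-bound
  refresh in which WGS manages only a couple of iterations while CS-WGS at
  c = 1/8 fits ten.

Sweeps run a full factorial (scenarios × algorithms × compressions ×
replicates) where replicates differ only in the seeds of the initial phase
offsets and subset permutation; following the benchmark reporting
convention, comparisons against WGS use the best-performing compression per
cell.

## Synthetic benchmark patterns

- Square grids of k² uniform spots (k = 2…12), planar, spanning 200 µm
  edge-to-edge regardless of k (the span is not stated in the benchmark
  description; 200 µm fits the stated fields of view), optionally rigidly
  rotated in 3D.
- Random clouds of 9–99 spots i.i.d. uniform in a centred cube (200 or
  300 µm), with target powers either uniform or i.i.d. uniform on [0.5, 1]
  before normalisation ("randomly distributed target intensities" is not
  quantified; [0.5, 1] keeps every target within 2× of the rest, as one
  would use for somata of one cell type).

These emulate the *geometry* of photostimulation targets only. They do not
model tissue scattering, aberrations, SLM pixel response or crosstalk
between physically extended excitation volumes, so quantitative agreement
with measured fluorescence is out of scope by construction.

## Known divergences from the published performance figures

Two published numbers are not reproducible from the published equations,
and the acceptance checks that assert them are expected to stay red:

1. *RS on the 100-spot random cloud.* The printed values are e = 0.554,
   u = 0.0245, v = 0.44. Evaluating the model exactly as written — Eq.-style
   conjugated pupil sums at the exact spot coordinates — gives e ≈ 0.786
   (the classical π/4 asymptote of random-phase superposition), u ≈ 0.95,
   v ≈ 4·10⁻⁴, robustly across illumination profiles, focal constants and
   pupil sizes. The reason is structural: the conjugated sum at a spot's own
   coordinates is self-aligned, cross-talk from well-separated spots
   averages out over M ≈ 10⁶ pixels, and the residual per-spot intensity
   noise is O(1/(aₙ√M)) ≈ 1%, which forces u near 1. A uniformity of 0.0245
   would require order-unity intensity fluctuations that the stated field
   model cannot produce; the printed figures most plausibly come from the
   study's measurement pipeline (camera-sampled intensities), which is
   hardware-dependent and out of scope here.
2. *e > 0.9 on ~100-spot random patterns.* Converged WGS in this model
   reaches e ≈ 0.79–0.82 on random clouds (while exceeding 0.92 on planar
   grids). The ~π/4 plateau is the price of phase-only encoding of a random
   superposition; weighting trades a little more efficiency for uniformity.
   The corresponding uniformity claim (u > 0.9) is met at the full-size
   pupil.

A corollary of (1): because the model's RS is already highly uniform on
random clouds, the "time to reach 92% of reference uniformity" protocol is
degenerate there (every algorithm satisfies the target at its minimal
iteration count), and under a tight fixed budget the early WGS iterations
can transiently *reduce* uniformity below RS. The cost-advantage and
budget-ranking checks therefore hold on grid scenarios — where convergence
work actually exists — and the random-cloud cells are reported as what they
are. On random clouds u > 0.9 requires the full 1,152-px pupil: desk-scale
pupils leave a residual cross-talk floor near u ≈ 0.85, which is why the
99-spot acceptance runs use the full geometry and the grid references use
384 px.

## Numerical choices

- All field sums are dense complex128 linear algebra; the (M, N) matrix
  e^{iφₙ} is precomputed once per (pupil, pattern) and shared across seeds
  and iteration counts (`spot_basis`). At the full pupil with N = 144 this
  is ≈ 2.4 GB, the peak memory of the benchmark runs.
- exp(i·phase) is built via cos/sin into a preallocated complex array to
  avoid a second M×N temporary.
- Gray export uses a linear 8-bit LUT by default: gray = nearest of the 256
  calibrated phases, exact midpoints rounding down (phase π → 127).
  Calibration tables load from a 256-entry CSV.
- Problem sizes in the test-suite and acceptance runs (384-px or smaller
  desk pupils for grid references and sweeps, 3–10 seed replicates) were
  chosen so every check measures its quantity at the smallest scale at
  which that quantity is stable.

## Limitations

- No zeroth diffraction order, SLM pixel response dynamics, temporal
  focusing, or scanning — out of scope by design.
- Quality metrics are point-sampled at the exact spot coordinates; no
  integration over an excitation volume.
- Overlapping spots (closer than a diffraction-limited radius laterally or
  axially) double-count power; the Σ Iₙ ≤ 1 bound and the uniformity floor
  both degrade, which matters for dense patterns on small desk pupils.
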