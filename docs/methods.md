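# Methods

## Scope and assumptions

`ringflow` models steady creeping flow of water along the tracheids of one
annual conifer ring, represented — as is standard in dendroanatomy — by a
single representative radial file (tracheidogram) running pith to bark.
The physical assumptions, inherited from the partial models the package
composes:

* **Parallel ring.** Tracheids exchange water chiefly with their
  tangential neighbours, so the cells of the radial file are isolated
  parallel resistors: `K_ring = Σ K_i`. No radial/tangential network
  topology, no sapwood- or tree-level upscaling.
* **Series tracheid.** Each cell is a rectangular Hagen–Poiseuille lumen
  (hydraulic diameter `D_h = 2LT/(L+T)`) in series with its wall. Water
  travels a fraction β = 0.5 of the tracheid length before crossing a
  wall, and crosses two walls per cell (entry and exit), giving
  `R_wall = 2 R_pit / N_pit`.
* **Uniform pits.** All pits of a cell are identical and evenly split
  between the two radial walls; `N_pit = α·L·l` is kept real-valued in
  every formula (integer rounding is display-only, because the count is a
  density × area product, not an observed integer). Tangential-wall pits
  (latewood) are outside the axial-flow model.
* **Isometric pit geometry.** `D_m = c_Dm·L` up to the cap `max_Dm`, then
  constant; torus, aperture and margo-pore diameters are fixed fractions
  of `D_m`; canal length equals the wall thickness. Margo pores are equal
  sized, counted as `N_po = D_mc²/(0.63·D_po + t_f)²` where `D_mc` is the
  diameter of the margo annulus (membrane minus torus area).
* **Constant tracheid length** `l` within a run.

Two points in the pit model are genuinely open and are implemented as
pluggable hooks with documented defaults:

* The **equivalent margo-pore diameter** `D_pe` entering the margo term
  has no independent defining relation; the default is `D_pe = D_po`
  (override via `derive_pit_geometry(..., dpe_fn=...)`).
* The **pore-interaction correction** `f(ε)` for streams merging through
  neighbouring margo pores has no closed form here; the default is
  `f = 1` (no interaction), with ε carried in the parameters and any
  substitute required to be monotone with `f(0) = 1`
  (`pit_resistance(..., pore_interaction=...)`). Under these defaults the
  package reproduces the published single-cell and ring benchmarks within
  a few percent; the residual gap is consistent with an unreported
  `f(ε) < 1`.

## Parameters

All parameters live in `ModelParams` (flat-JSON serialisable); defaults
are central literature values for the Pinaceae.

| name | meaning | unit | default |
|---|---|---|---|
| `mu` | dynamic viscosity of water, 20 °C | MPa·s | 1.002e-9 |
| `t_f` | margo strand thickness | µm | 0.140 |
| `l` | axial tracheid length | mm | 2.2 |
| `TD` | outer tangential tracheid diameter | µm | 30 |
| `alpha` | pit density on radial walls | m⁻² | 6.5e8 |
| `beta` | tracheid overlap factor | — | 0.5 |
| `max_Dm` | membrane-diameter cap | µm | 25 (`larix_25`) / 22 (`pinaceae_22`) |
| `c_Dm, c_Dt, c_Da, c_Dpo` | isometric ratios | — | 0.70, 0.50, 0.25, 0.03030 |
| `epsilon` | margo pore-area fraction | — | 0 (unused by default `f`) |

Validation enforces positive lengths, `0 < β ≤ 1`, `0 ≤ ε < 1` and the
anatomical ordering `c_Da < c_Dt < 1`. The isometry coefficients are
parameters rather than literals so other Pinaceae calibrations (the
literature reports ± ranges) can be explored; the membrane cap is a
per-run parameter because published calibrations themselves use both 22
and 25 µm depending on the material.

## Units and numerical choices

* Internal computation is entirely in MPa, s, mm; `mu` is therefore
  1.002e-9 MPa·s. `ringflow.units` provides the only conversions
  (mm³↔m³ bases differ by 10⁹ — the classic error in this literature —
  so ring outputs carry both bases explicitly).
* Per-cell report resistances are written on the 10⁻³ MPa s mm⁻³
  (kPa s mm⁻³) scale with documented per-column rounding; inputs can be
  re-emitted at full precision (`write_tracheidograms`), making
  write→read lossless.
* Mork's rule ties (`L = 2·WT` exactly) classify as latewood; earlywood
  requires strict `L > 2·WT`.
* The wall/lumen crossover diameter is found by scanning L at ≤0.1 µm
  steps and linearly interpolating the sign change of `R_wall − R_lum`;
  a 0.001 µm brute-force scan agrees to <0.01 µm (test-verified). No
  sign change raises a diagnostic error rather than extrapolating.
* Degenerate geometry (zero aperture, zero pore count) and non-physical
  inputs (`L ≤ 0`, `WT ≤ 0`, `WT ≥ TD/2`) raise typed errors carrying the
  field, cell position and file/line context.

## Synthetic tracheidograms

The generator (`SyntheticSpec`, `generate_tracheidogram`) emulates the
canonical shape of a conifer tracheidogram: an earlywood plateau of wide
cells (`L_max`, default 40 µm over 35% of positions), a half-cosine
decline to the final latewood cell (`L_min`, default 4 µm), and a linear
wall-thickness law (default `WT = −8/70·L + 10` µm, i.e. thin-walled wide
cells grading to thick-walled narrow ones). Multiplicative lognormal
noise with configurable CV acts on the lumen profile only; WT derives
from the noiseless profile so that low noise cannot flip the Mork
classification. Seeding uses one master seed with per-ring child streams
`SeedSequence(master, spawn_key=(ring_index,))`, so batches are
reproducible cell-for-cell in any generation order.

What the generator does *not* emulate — and hence what passing synthetic
tests cannot show about real data: multi-file averaging noise, missing or
collapsed cells, intra-annual density fluctuations (multiple plateaus),
between-ring correlation of structure, or any cambial-dynamics process
model. It supports structural experiments (equal-width rings of different
anatomy, width–conductance sweeps), not inference about measured wood.

## Design choices

* The ring is one representative radial file; averaging multiple files
  into it is upstream of this package. Ring width is reported only as the
  context proxy `Σ(L + 2·WT)`.
* Profiles are named by calibration (`pinaceae_22`, `larix_25`) and
  resolve to exact parameter sets; every CLI run writes a manifest
  (version, profile, parameters, input hashes, seed) sufficient to
  reproduce it byte-identically.
* The bundled worked example uses two measured *Larix sibirica*
  tracheidograms (21 and 15 cells) transcribed once into versioned data
  files with provenance headers; tests compare against those files, never
  against literals scattered through test code.
* Acceptance-style checks run the same code paths as users: single-cell
  benchmarks at L = 10 and 20 µm, ring conductance/pit-partition for the
  two bundled rings, the ~18 µm crossover diameter, and exactness/oracle
  properties (series-sum identities, parallel additivity under
  tracheidogram splits, term-by-term formula transcriptions at 1e-12
  relative). Problem sizes are tiny by construction — two measured rings,
  a 361-point scan, a 200-ring synthetic ensemble — and run in seconds.

## Known limitations

* Accuracy inherits the isometric coefficients' scatter (±0.07 on
  `c_Dm`, ±0.11 on `c_Dt`, ±0.04 on `c_Da`); the package treats them as
  exact per run.
* No vulnerability-to-embolism, air-seeding or torus-aspiration
  mechanics; the pit is a fixed geometric resistor.
* No within-ring tracheid-length variation, no tangential-pit radial
  flow, no mechanical-property outputs.
* Published whole-dataset summaries (multi-tree, multi-decade
  pit-contribution distributions) depend on measurement sets not bundled
  here and are deliberately not reproduced; the model behaviour they
  summarise is covered by the synthetic sweep properties instead.
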