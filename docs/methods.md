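# Methods

## Scope and data model

morphoscape analyses a time series of categorical land-use rasters sharing
one extent and cell size. Cell values 1–9 encode the land-use nomenclature
(built-up, urban green, arable, crop mosaic, vineyards, olive groves,
woodland, pastures, wetlands); 0 is nodata and "outside the study area",
always treated as background. The default cell size of 100 m makes one
pixel one hectare, matching the 1-ha minimum mapping unit customary for
regional land-use maps; it is overridable everywhere. Supported formats
are the ESRI ASCII grid (whitespace-separated, row-major from the north,
`NODATA_value` honoured) and single-band TIFF via tifffile, with cell size
and year carried in the image-description tag. Values outside 0–9 are
remapped to nodata with a logged warning rather than failing the read.

## Morphological segmentation

For one class mask, the seven types are derived in a fixed order:

1. **Core** — foreground whose Chebyshev distance to the nearest background
   pixel exceeds the edge width `w` (default 1 pixel; equivalent to `w`
   8-neighbour erosions). The lattice border counts as background by
   default (`border_condition="background"`), i.e. the map edge is treated
   as leaving the study area; with `"foreground"` the mask continues
   virtually past the border and an all-foreground mask is all core. The
   default follows the fixed-study-area reading; both behaviours are
   contract-tested.
2. **Holes** — 4-connected background components with no background path to
   the border. Foreground connectivity is 8 throughout; the 8/4 pairing is
   the standard digital-topology choice that avoids paradoxical crossings.
3. **Boundary zone** — non-core foreground within Chebyshev distance `w` of
   a core pixel; each such pixel is a **perforation** when its nearest
   background pixel lies in a hole and an **edge** otherwise. Ties
   (nearest hole and nearest outer background at equal distance) go to
   edge: deterministic, and it favours the commoner class.
4. **Connectors** — the remaining foreground is split into 8-connected
   components, each typed whole: K is the number of distinct core patches
   the component touches directly or through a boundary pixel lying within
   `w` of that core. K=0 → **islet**; K≥2 → **bridge**; K=1 → **loop** if
   the component's contact pixels with that core's region form ≥2 separate
   8-connected clusters, else **branch**.

Component-wise connector typing is a deliberate simplification of the
skeleton-based, per-pixel machinery of GuidosToolbox; bit-compatibility
with Guidos outputs is not promised and not attempted. The segmentation is
a partition by construction (asserted on every call), monotone in `w`
(larger edge width never increases core), and mirror-equivariant; all
three properties are tested, and the whole classifier is checked for exact
agreement against an independent brute-force reimplementation (pure
Python, BFS + pairwise distances) on exhaustive 3×3 masks, thousands of
seeded random 4×4–6×6 masks and 1000 random 12×12 masks.

## Patch metrics and change conventions

Per (year, class, type), patches are 8-connected components; areas are in
hectares via the cell area. The 9×7 mean-patch-size table per year is the
factor-analysis input. Two change-rate conventions coexist in the
reference tables and are implemented separately:

* per cent per year, linear relative to the initial value,
  100·(v₁−v₀)/(v₀·Δt) — used for core-area shares (verified cell-by-cell
  against the printed rates, e.g. arable 61.6→50.4 over 25 yr → −0.73). A
  compound (geometric) mode exists but is not the default.
* hectares per year, (v₁−v₀)/Δt — used for mean patch size. The published
  change table is headed "per cent annual change", but its cells equal the
  plain ha/yr difference (all 189 cells reproduce to ≤0.009); the absolute
  convention is therefore implemented and the header treated as a
  misprint.

One printed core-share rate (olive groves, 1.7→3.1 over the third stage,
printed 5.15) is consistent with the linear convention only at Δt=16
although the window is 17 years; the implementation keeps Δt=17 and does
not match that single cell. Stage lengths are fixed at 25, 25 and 17 years
(1949–1974–1999–2016).

## Multi-way factor analysis

Each year table is column-standardised with the population (n) divisor —
a deterministic contract; constant columns become zeros. The default
variant weights each table by α_k = 1/σ₁², scales blocks by √α_k,
concatenates columns (9×28 for four years) and takes the SVD. Eigenvalues
are the squared singular values of the weighted concatenation — on this
scale the conventional eigenvalue-greater-than-1 retention reproduces the
three-axis solution of the reference study (3.57, 1.27, 1.09, then 0.66);
a 1/n covariance scaling would make the rule degenerate. Retention has a
floor of one axis for weakly structured data. Axis signs are canonicalised
(largest-magnitude loading positive); an optional alignment step greedily
permutes/flips retained axes against a reference coordinate table for
side-by-side reading — downstream displacement statistics are invariant to
it. Partial loadings are singular-value-scaled block rows of V; partial
row scores are K·X_k√α_k·V_k so their average over tables equals the
global score. The STATIS variant draws table weights from the leading
eigenvector of the RV matrix (scaled to sum 1) instead.

On the shipped year tables, the default variant yields a first-axis share
of 49.4% and RV(1999, 2016) = 0.978 versus the published 46.6% and 0.935.
The original standardisation and variant are not stated in the source, so
exact reproduction is not expected; both implemented variants are within a
few points, the default (classical) variant is the closer and each result
records its variant. The RV coefficient is non-negative by construction;
the source text's "ranging from 1 to −1" is treated as a slip.

## Rapidity of change

R′ divides the Euclidean displacement over the retained axes by the window
length; the division sits **outside** the radical. The typeset source
formula places /t under the root, but only √(Σ)/t reproduces all six
printed per-dimension stage averages (0.018/0.083, 0.024/0.089,
0.012/0.046) from the printed coordinates, so that reading is implemented.
Long-cycle values use Δt = 67 on the 1949/2016 coordinates; this
recomputes the printed loop (0.010), branch (0.007) and woodland (0.041),
while the printed islet (0.002), bridge (0.005), olive-grove (0.043) and
wetland (0.035) long-term values are not recoverable from the coordinate
table under any convention tried (√(Σ)/t, √(Σ/t), stage averaging); the
package reports its own computed values. A related consequence: computed
from the coordinates, the fast long-cycle structures are edge, loop and
bridge — edge has the largest R′ (0.0125) and branch (0.0068) is exactly
the median, hence slow under the tie rule — whereas the source narrative
names loop/branch/bridge from its non-recomputable printed values.
Fast/slow uses the strict above-median rule with ties to slow,
per dimension and window.

## Synthetic landscape generator

The generator emulates the study conditions the pipeline assumes, not any
specific city. Defaults (chosen once): 256×256 grid at 100 m; initial
class proportions arable-dominant with 7% built-up (built-up 0.07, urban
green 0.02, arable 0.35, crop mosaic 0.08, vineyards 0.07, olive groves
0.04, woodland 0.20, pastures 0.15, wetlands 0.02); stage pixel budgets
6000 / 6500 / 1100 scaled from the reference built-up trajectory
(6.6→15.9→25.9→27.6% of the study area); smoothing scale 4 px; seed 0.
`SynthConfig.scaled()` rescales the budgets by grid area for smaller runs.

t0 is a central Euclidean-disk nucleus plus a neutral rural mosaic:
independent uniform-noise fields smoothed with a Gaussian kernel
(wrap-around boundary), each class greedily claiming its target count by
field rank. Densification converts the rural pixels nearest the urban mass
(ties row-major). Dispersed growth plants seeds in a Chebyshev ring
[r+2, 2.5r] around the urban centroid (r from the urban pixel count) and
grows each into a ragged cluster — the seed plus a random subset of its
1–2-pixel neighbourhood, kept below the full neighbourhood so the patches
are typically coreless (islets), the morphological signature of
discontinuous medium-density expansion. Sprinkle adds isolated single
urban pixels with no 8-adjacency to existing settlement. All randomness
flows from one `numpy` generator keyed by the seed.

What the generator does *not* emulate: real class geometry (roads, rivers,
terrain), vector-derived patch shapes, rural-to-rural transitions,
multi-nucleus systems, and any calibration to a real city's class mix.
Passing pipeline tests on synthetic series therefore demonstrates the
machinery (segmentation → tables → factor analysis → rapidity) and the
qualitative stage signatures, not predictive validity for any real map.

## Numerical choices and degenerate inputs

Population-variance z-scores; deterministic row-major relabelling of
components; edge/perforation ties to edge; fast/slow ties to slow; axis
signs canonicalised as above. Empty masks segment to all-none; core share
of an empty class raises; a zero table has no MFA weight and raises;
missing window endpoints raise naming the year. Pipeline runs are
bit-reproducible for a fixed configuration, and every artifact directory
carries the config hash and package version.

## Problem sizes

The test suite runs the full pipeline at 256×256 over four dates (a few
seconds), plus quarter- and eighth-scale runs for the orchestration tests;
oracle-equivalence sweeps use exhaustive 3×3, a 3000-mask seeded subset of
the 4×4 space, 400-mask samples at 5×5/6×6 and 1000 random 12×12 masks.
These sizes keep the whole suite under a minute while exercising every
code path; the statistics modules operate on fixed 9×7 tables where size
is not a factor.

## Known limitations

* Connector typing is component-wise; corridors that a per-pixel skeleton
  analysis would split into mixed types get a single label.
* Only Chebyshev distances are supported for the morphology (no Euclidean
  edge widths, no multi-scale analysis).
* The MFA does not provide bootstrap ellipses, supplementary elements or
  DISTATIS.
* Published long-term rapidity values that do not recompute from the
  published coordinates (see above) are reported as computed, not matched.
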