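# morphoscape

Quantifies long-term metropolitan landscape change from multi-temporal
categorical land-use rasters, for landscape ecologists and spatial planners
studying urban growth stages (compact urbanisation → suburbanisation →
counter-urbanisation).

The package combines three pieces:

1. **Morphological spatial pattern analysis (MSPA).** The binary mask of each
   land-use class is partitioned into seven mutually exclusive structural
   types with mathematical morphology: *core* (foreground farther than the
   edge width `w` from any background pixel, Chebyshev metric, 8-connected
   foreground / 4-connected background), *islet* (component with no core),
   *perforation* / *edge* (core boundary facing an enclosed hole / the outer
   background), and the connector types *bridge*, *loop*, *branch*
   (components touching ≥2 cores, the same core twice, or one core once).

2. **Multi-way factor analysis (MFA).** For each observation year, the
   9 (land-use functions) × 7 (structural types) table of mean patch size
   (ha) is column-standardised, weighted by α_k = 1/σ₁²(X_k) so no year
   dominates, column-concatenated and decomposed by SVD. Axes with
   eigenvalue > 1 are retained; each year gets partial loadings
   (structures) and partial scores (functions) in the common compromise
   space, and the RV coefficient
   RV = tr(S₁S₂)/√(tr(S₁²)·tr(S₂²)), S = XXᵀ, measures between-year
   configuration similarity. A STATIS weighting variant (RV-eigenvector
   weights) is available.

3. **Rapidity of change.** Each entity's speed in factor space over a stage
   window [t₀, t₁] is

   R′ = √( Σₐ (x_{a,t₁} − x_{a,t₀})² ) / (t₁ − t₀)

   over the n retained axes. Entities strictly above their dimension's
   median R′ are *fast* variables, the rest *slow*; per-dimension means
   summarise each stage's dynamism.

A synthetic-landscape generator (`morphoscape.synthlandscape`) produces
reproducible four-date series — compact nucleus, autocorrelated rural
mosaic, then densification, dispersed fringe growth and diffuse sprinkle —
so the full pipeline is testable without external data. The printed
reference tables of a 1949–2016 study of metropolitan Rome ship as CSV
fixtures (`morphoscape.datasets`) and drive the numeric regression tests.

## Worked example

```python
from morphoscape import analyse, datasets

coords = datasets.load_axis_coordinates()   # printed axis coordinates
result = analyse(coords)
print(result.averages.round(3).to_string(index=False))
```

prints

```
dimension               window  mean_rprime
 function         urbanisation        0.083
structure         urbanisation        0.018
 function      suburbanisation        0.089
structure      suburbanisation        0.024
 function counter_urbanisation        0.046
structure counter_urbanisation        0.012
 function            long_term        0.038
structure            long_term        0.007
```

Functional attributes move faster than structural ones in every window, and
both dimensions peak during suburbanisation (1974–1999): dispersed fringe
growth reorganises the form–function relationship faster than either
compact densification or late sprawl. The `examples/` directory holds one
short script per capability (segmentation, patch metrics and change rates,
MFA, rapidity, synthetic end-to-end run); each prints the numbers it
computes and a line on what they mean. A thin CLI wraps the pipeline:

```sh
morphoscape synth --seed 0 --grid-size 128 --out grids/
morphoscape run --config cfg.yaml
morphoscape rapidity --coords <coordinates.csv> --windows long
```

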