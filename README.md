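# migsurf

Penalized-likelihood estimation of **effective migration surfaces** from
geo-referenced SNP genotypes.

Spatial population-genetic structure is often summarized as isolation by
distance: genetic similarity decays with geographic distance. Real
landscapes are not uniform — mountain ranges, water bodies and habitat
boundaries locally restrict or enhance gene flow. `migsurf` is for
population geneticists and landscape ecologists who want to map that
heterogeneity: it discretizes the habitat as a triangular lattice of demes
and estimates a relative gene-flow rate for **every lattice edge** from a
genotype matrix and sample coordinates, producing a surface in which
low-weight regions mark barriers to migration and high-weight regions mark
corridors.

## Model

Latent allele frequencies on the d lattice nodes follow a Gaussian Markov
random field whose precision is the weighted graph Laplacian
L(w) = diag(W1) − W:

    f_j ~ N_d( μ_j 1, μ_j(1 − μ_j) L† ),

so that the expected rescaled squared frequency difference between demes
equals the **resistance distance** of the weighted graph. Observed node
frequencies add binomial sampling noise, approximated by a residual
variance σ². After projecting out per-SNP means with an orthonormal
contrast matrix C, the rescaled sample covariance Σ̂ enters a Wishart
likelihood, and edge weights are estimated by box-constrained L-BFGS on

    ŵ = argmin_{l ≤ w ≤ u}  p·[ tr(M⁻¹S) + log det M ]  +  (λ/2)‖Δ log(e^{αw} − 1)‖²,

with M = C(A L† Aᵀ + σ² diag(n⁻¹))Cᵀ and S = C Σ̂ Cᵀ. The penalty smooths
adjacent edges — on a log scale where migration is weak and a linear scale
where it is strong (α = 1/ŵ0 from a constant-weight null fit). The penalty
strength λ is chosen by leave-one-node-out cross-validation with
warm-started regularization paths. See `docs/methods.md` for the full
account.

## Worked example

Simulate genotypes under a 10-fold migration barrier in the centre of an
8×12 lattice habitat, then fit the surface:

```python
import migsurf as ms

graph = ms.build_rectangle_lattice(8, 12, spacing_km=50.0)
scenario = ms.Scenario(name="barrier", sampling="dense", seed=1)
sim = ms.simulate_dataset(graph, scenario, p=1000, n_per_node=10)

model = ms.SpatialMigrationModel.from_genotypes(
    sim.genotypes, sim.sample_coords, graph=graph
)
print(model.fit_null().summary())
fit = model.fit(lam=10.0)
print(fit.summary())
```

```
Homogeneous isolation-by-distance fit
============================================
edge weight w0                       4.34333
residual variance sigma^2           0.528791
negative log-likelihood              -109405
iterations                                61
converged                               True

Effective migration surface fit
====================================================
edges (m)                                      249
nodes (d)                                       96
penalty strength lambda                         10
penalty scale alpha                       0.230238
scale w0 (null fit)                        4.34333
residual variance sigma^2                 0.528791
objective                                  -121570
projected-gradient norm                  1.666e-02
iterations                                      22
initialized from                              null
converged                                     True
----------------------------------------------------
log10(w / w0) quantiles
  min                                      -0.5443
  25%                                      -0.3403
  median                                    0.2992
  75%                                       0.4260
  max                                       0.4877
```

Reading the output: the null stage estimates the overall migration scale
ŵ0 ≈ 4.3 and the residual variance σ̂² ≈ 0.53 (ten diploids per node of
binomial sampling noise). The fitted surface is reported as log10(w/ŵ0):
the lower quartile (−0.34, i.e. weights ~2× below the homogeneous scale)
is carried by the down-weighted barrier edges in the habitat centre, while
background edges sit around +0.3 to +0.5. `fit.to_dataframe()` gives the
per-edge table, `fit.plot()` draws the surface, and
`model.loocv(...)` selects λ by cross-validation
(`cv.summary()` prints the error curve and the selected value).

The same pipeline is available from the shell:

```bash
migsurf simulate --scenario barrier --rows 8 --cols 12 --seed 1 --out sim/
migsurf cv  --genotypes sim/genotypes.tsv --coords sim/coords.csv \
            --polygon sim/polygon.txt --resolution 50 --out cv/
migsurf fit --genotypes sim/genotypes.tsv --coords sim/coords.csv \
            --polygon sim/polygon.txt --resolution 50 \
            --cv-summary cv/cv_summary.json --out fit/
```

Inputs are plain text: a delimited genotype matrix (0/1/2, `NA` or `-9`
missing) or a PLINK bed/bim/fam triple, a coordinate CSV with a mandatory
`lon,lat` header, and a habitat polygon (`lon lat` per line, or GeoJSON).

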