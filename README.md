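# seedmorph

Outline-based geometric morphometrics for seed identification, built for
archaeobotanical use cases: discriminating closely related taxa (the
motivating system is the poppy genus *Papaver*, where the domesticated
opium poppy *P. somniferum* and its wild relative *P. setigerum* overlap
strongly in seed form) and assigning archaeological seeds of unknown
identity to a reference collection of modern material.

The package covers the full analysis chain:

1. **Outline extraction** — sub-pixel tracing of binary seed masks
   (marching squares at the 0.5 iso-level), bounding-box length/width,
   ingestion of landmark files (CSV or TPS; five landmarks per seed:
   three on the hilum arch, two at the length extremes).
2. **Normalization** — full generalized Procrustes alignment driven by
   the landmark configurations (translation, scaling to unit centroid
   size, iterative least-squares rotation to the consensus), with the
   outline start point anchored at landmark 2.
3. **Elliptic Fourier transform** — the closed outline (x(t), y(t)),
   parameterized by arc length t ∈ [0, T), is decomposed as

   x(t) = a₀ + Σₙ aₙ cos(2πnt/T) + bₙ sin(2πnt/T)
   y(t) = c₀ + Σₙ cₙ cos(2πnt/T) + dₙ sin(2πnt/T)

   using the piecewise-linear chain-sum formulation (exact for polygons).
   Per-harmonic power is (aₙ² + bₙ² + cₙ² + dₙ²)/2; the number of retained
   harmonics H\* is the smallest H whose mean cumulative power reaches 95%.
4. **Statistics** — measurement-error percentage (%ME, the
   within-measurement variance component over the within + among sum, from
   a repeated-measures ANOVA), Kruskal–Wallis and pairwise Wilcoxon tests
   on log sizes and cell counts, PCA with supplementary projection of
   unknowns, permutational MANOVA on the coefficient matrix, per-taxon
   mean-shape reconstruction, and a UPGMA tree on Euclidean distances
   between taxon mean coefficients (Newick output).
5. **Classification** — linear discriminant analysis with leave-one-out
   cross-validation, benchmarked per descriptor family (cell count, size,
   shape, and their combination) on class-balanced resamples (classes
   subsampled to 30), with a shuffled-label chance ceiling; unknown seeds
   are assigned by majority vote of per-permutation LDA predictions.
6. **Synthetic seeds** — a generative model (Fourier-coefficient shape
   families, log-normal sizes, negative-binomial cell counts, controllable
   positioning/cleaning/landmarking noise) that emulates the reference
   design: 7 taxa × 30 seeds, two extra accessions of the two closest
   taxa, 33 unknowns, and 5 seeds × 3 taxa × 3 repeated acquisitions for
   the reproducibility tests. Every downstream stage is testable against
   known ground truth.

## Worked example

Run the full synthetic experiment (seven reference taxa, two extra
accessions, 33 unknown seeds drawn half-and-half from the two closest
taxa) and print the headline statistics:

```python
from seedmorph.pipeline import RunConfig, run_pipeline

cfg = RunConfig(rng_seed=42, outdir="runs/demo",
                n_perm_benchmark=100, n_perm_assign=100,
                feature_sets=("cells", "size", "shape", "all"))
summary = run_pipeline(cfg)
print(summary["h_star"])
print(summary["permanova"])
print(summary["benchmark"]["all"])
print(summary["assignment_composition"]["all"])
```

Output (abridged):

```
5
{'F': 48.799, 'r2': 0.527, 'adj_r2': 0.516, 'p': 0.001, 'df_between': 6}
{'P_argemone': 0.964, 'P_dubium': 0.933, 'P_hybridum': 0.998,
 'P_nigrum': 0.892, 'P_rhoeas': 0.959, 'P_setigerum': 0.915,
 'P_somniferum': 0.899}
{'P_nigrum': 1, 'P_setigerum': 15, 'P_somniferum': 17}
```

Reading this: the 95%-power rule retains 5 harmonics (20 shape
variables); the permutational MANOVA rejects shape homogeneity across the
seven taxa (pseudo-F = 48.8, p = 0.001, the permutation floor at 999
permutations); combining all descriptors yields per-class leave-one-out
accuracies of 89–100%; and the 33 unknown seeds — a simulated mixed
assemblage — come back split 15/17 between the two closest taxa, with one
seed straying to the third member of their species group.

The same run writes `analysis_table.csv`, `benchmark.csv`,
`assignments.csv`, `pca_scores.csv`, `stat_tests.csv`, `upgma_tree.nwk`
and a machine-readable `summary.json` under `runs/demo/`. The equivalent
shell invocation is:

```sh
seedmorph run --seed 42 --out runs/demo --n-perm-benchmark 100
```

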