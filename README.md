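# ensembleproj

Cross-validated low-dimensional projections of protein conformational
ensembles.

Crystallographic ensembles are *degenerate* datasets: a few dozen structures
described by thousands of coordinate degrees of freedom (3 × Cα count), so
the empirical correlation matrix is hopelessly rank-deficient. `ensembleproj`
embeds such ensembles in 2-D with two independent methods and only trusts
cluster structure that both methods reproduce:

1. **PCA via truncated SVD** of the column-standardized coordinate matrix
   (equivalent to diagonalizing the correlation matrix, without ever forming
   it).
2. **Random projection**: the correlation matrix is replaced by a symmetric
   Gaussian random matrix of the same dimension; the data are projected onto
   the eigenvectors of its largest eigenvalues. Because the Gaussian
   symmetric ensemble is rotation-invariant, this is a uniformly random
   orthonormal 2-frame — an unbiased low-dimensional shadow of the cloud.

If both embeddings show the same clusters (chance-corrected agreement ≥ 0.9
and equal cluster counts), the verdict is `validated`; clusters seen by PCA
alone are flagged `unvalidated`. Chi-square confidence ellipses and
Mahalanobis outlier flags annotate the embeddings. A single random 2-frame
can lie nearly orthogonal to a real separation direction, so validation runs
support `replicates`: the random projection is redrawn with consecutive
seeds and a split counts as confirmed if any replicate reproduces it.

## Layout

| module | contents |
| --- | --- |
| `ensembleproj.structures` | PDB Cα extraction (altloc policies), shared-atom intersection, Kabsch superposition (iterative-mean reference, gauge-fixed), coordinate-matrix construction and TSV round-trip |
| `ensembleproj.projection` | standardization (divisor-N), covariance/correlation, eigendecomposition, truncated-SVD PCA, seeded symmetric random matrices, random projection |
| `ensembleproj.validation` | density and k-means/silhouette cluster detectors, adjusted-Rand agreement + verdict, replicate handling, confidence ellipses, outlier flags |
| `ensembleproj.synthetic` | synthetic helical ensembles with known cluster structure, thermal noise, rigid-body jitter; PDB writer |
| `ensembleproj.pipeline` | simulate/load → superpose → matrix → project ×2 → validate → plot, with a reproducibility manifest |
| `ensembleproj.cli` | `ensembleproj` command-line entry point |

## CLI

```sh
# synthetic two-cluster ensemble, 58 entries of 565 Cα
ensembleproj simulate --atoms 565 --clusters 2 --count 29,29 \
    --displacement 5 --noise 0.3 --jitter --seed 7 --out-dir fixtures/

ensembleproj build-matrix --pdb-dir fixtures/ --altloc occupancy \
    --reference mean --out matrix.tsv

ensembleproj project --matrix matrix.tsv --method pca --out scores_pca.tsv
ensembleproj project --matrix matrix.tsv --method random --seed 1234 \
    --out scores_rand.tsv

ensembleproj validate --scores-pca scores_pca.tsv \
    --scores-random scores_rand.tsv --detector kmeans --out report.json

ensembleproj plot --scores-pca scores_pca.tsv \
    --scores-random scores_rand.tsv --out projections.png
```

Exit codes: `0` success, `1` validation failure (clusters not confirmed by
the random projection), `2` error.

The whole chain also runs from one YAML config:

```sh
ensembleproj run --config config.yaml
```

```yaml
seed: 7
output_dir: run/
simulate:
  chain_sizes: [565]
  n_clusters: 2
  per_cluster_counts: [29, 29]
  displacement_magnitude: 5.0
  noise_sigma: 0.3
  rigid_jitter: true
project: {k: 2, replicates: 16}
validate: {detector: kmeans_silhouette, threshold: 0.9}
```

Every run writes `manifest.json` (config snapshot, seeds, matrix shape,
spectra, verdict); re-running from the same config reproduces all scores
bit-identically.

Real PDB ensembles are analyzed the same way: point `build-matrix` (or the
`input.pdb_dir` config section) at a directory of PDB files of the same
protein. Only ATOM records are read; Cα atoms are matched across entries by
(chain, residue number, insertion code) and the intersection defines the
matrix columns.

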