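"""From a count matrix to a pseudotime-targeted feature selection.

Simulates a tiny gene-by-cell count matrix whose expression drifts along a
latent trajectory, then runs the full single-cell front end: QC filtering,
Pearson-residual normalization, principal-curve pseudotime from a 2-D
embedding, LOESS expression profiles, and finally QUBO selection of the
genes most informative about pseudotime.
"""

import numpy as np
import scipy.sparse as sp

from qubofs import (ContinuousDataset, CountMatrix, fit_pseudotime,
                    pearson_residual_transform, qc_filter, select_features,
                    smoothed_profiles)

rng = np.random.default_rng(7)
n_genes, n_cells = 200, 150
t_true = np.sort(rng.uniform(0, 1, n_cells))        # latent trajectory

base = rng.gamma(2.0, 20.0, n_genes)
slope = np.zeros(n_genes)
slope[:20] = rng.normal(0, 2.0, 20)                 # 20 trajectory genes
mu = np.exp(np.log(base)[:, None] + slope[:, None] * t_true[None, :])
counts = rng.poisson(mu)
genes = np.array([f"GENE{i}" for i in range(n_genes)], dtype=object)
cells = np.array([f"CELL{i:03d}" for i in range(n_cells)], dtype=object)

m = CountMatrix(sp.csr_matrix(counts), genes, cells)
filtered, report = qc_filter(m, min_libsize=100, min_genes_per_cell=50,
                             min_cells_per_gene=5)
print(f"QC: {report['cells_in']} -> {report['cells_out']} cells, "
      f"{report['genes_in']} -> {report['genes_out']} genes")

residuals = pearson_residual_transform(filtered)

# embedding: the top two principal components of the residuals
centered = (residuals - residuals.mean(axis=1, keepdims=True)).T
_, _, Vt = np.linalg.svd(centered, full_matrices=False)
embedding = centered @ Vt[:2].T
pt = fit_pseudotime(embedding)
corr = abs(np.corrcoef(pt.values, t_true)[0, 1])
print(f"pseudotime vs latent trajectory: |r| = {corr:.3f}")

# select the genes most informative about pseudotime
data = ContinuousDataset(residuals.T, pt.values,
                         feature_names=[str(g) for g in filtered.gene_names])
selection = select_features(data, k=5, seed=1)
print(f"top pseudotime genes: {selection.names}")

grid, curves = smoothed_profiles(residuals, pt, selection.indices)
print(f"LOESS profiles on a {grid.size}-point grid; first gene spans "
      f"[{curves[0].min():.2f}, {curves[0].max():.2f}] residual units")
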