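import gzip
import shutil

import numpy as np
import pytest
import scipy.io
import scipy.sparse as sp

from qubofs.scrna import (CountMatrix, PseudotimeVector, fit_pseudotime,
                          pearson_residual_transform, qc_filter, read_counts,
                          smoothed_profiles)


def _toy_mtx_dir(tmp_path, gz=False):
    # 3 genes x 2 cells, 4 stored entries
    M = sp.coo_matrix(np.array([[5, 0], [0, 3], [2, 7]]))
    d = tmp_path / "counts"
    d.mkdir(parents=True)
    scipy.io.mmwrite(d / "matrix.mtx", M)
    (d / "features.tsv").write_text(
        "ENSG1\tGeneA\tGene Expression\nENSG2\tGeneB\tGene Expression\n"
        "ENSG3\tGeneC\tGene Expression\n")
    (d / "barcodes.tsv").write_text("AAAC-1\nAAAG-1\n")
    if gz:
        for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
            with open(d / name, "rb") as src, \
                    gzip.open(d / (name + ".gz"), "wb") as dst:
                shutil.copyfileobj(src, dst)
            (d / name).unlink()
    return d


class TestReadCounts:
    def test_mtx_round_trip(self, tmp_path):
        m = read_counts(_toy_mtx_dir(tmp_path))
        assert m.counts.nnz == 4
        assert m.counts.shape == (3, 2)
        assert list(m.gene_names) == ["GeneA", "GeneB", "GeneC"]
        assert list(m.cell_barcodes) == ["AAAC-1", "AAAG-1"]
        assert m.counts[2, 1] == 7

    def test_gzipped_identical_to_plain(self, tmp_path):
        plain = read_counts(_toy_mtx_dir(tmp_path / "a"))
        (tmp_path / "a").mkdir(exist_ok=True)
        zipped = read_counts(_toy_mtx_dir(tmp_path / "b", gz=True))
        assert (plain.counts != zipped.counts).nnz == 0
        assert list(plain.gene_names) == list(zipped.gene_names)

    def test_csv_cells_in_rows_transposed(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text("cell,GeneA,GeneB\nc1,1,2\nc2,3,4\nc3,5,6\n")
        m = read_counts(f, format="csv", orientation="cells_by_genes")
        assert m.counts.shape == (2, 3)  # genes x cells
        assert list(m.gene_names) == ["GeneA", "GeneB"]
        assert m.counts[1, 2] == 6

    def test_missing_path(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_counts(tmp_path / "nope")

    def test_sidecar_mismatch_error(self, tmp_path):
        d = _toy_mtx_dir(tmp_path)
        (d / "barcodes.tsv").write_text("A\nB\nC\nD\n")
        with pytest.raises(ValueError, match="neither"):
            read_counts(d)

    def test_duplicate_gene_names_suffixed(self, tmp_path):
        d = _toy_mtx_dir(tmp_path)
        (d / "features.tsv").write_text(
            "E1\tDup\tx\nE2\tDup\tx\nE3\tOther\tx\n")
        m = read_counts(d)
        assert list(m.gene_names) == ["Dup", "Dup.1", "Other"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            CountMatrix(sp.csr_matrix(np.array([[1, -2]])),
                        np.array(["g"]), np.array(["c1", "c2"]))


def _qc_matrix(rng, n_genes=40, n_cells=25):
    counts = rng.poisson(6.0, size=(n_genes, n_cells))
    counts[counts < 1] = 1  # every gene seen in every cell
    genes = [f"G{i}" for i in range(n_genes - 1)] + ["MT-ND1"]
    cells = [f"C{i}" for i in range(n_cells)]
    return counts.astype(float), genes, cells


class TestQcFilter:
    def test_libsize_threshold(self, ):
        rng = np.random.default_rng(0)
        counts, genes, cells = _qc_matrix(rng)
        counts[:, 0] *= 0
        counts[0, 0] = 999          # total 999 -> removed at the 1000 floor
        counts[:, 1:] += 100        # others comfortably above
        m = CountMatrix(sp.csr_matrix(counts), genes, cells)
        out, report = qc_filter(m, min_genes_per_cell=1, min_cells_per_gene=1)
        assert report["cells_fail_libsize"] == 1
        assert "C0" not in out.cell_barcodes

    def test_mito_fraction_threshold(self):
        rng = np.random.default_rng(1)
        counts, genes, cells = _qc_matrix(rng)
        counts += 50
        lib = counts[:, 0].sum() - counts[-1, 0]
        counts[-1, 0] = lib / 3     # MT share 25% > 15% -> removed
        m = CountMatrix(sp.csr_matrix(counts), genes, cells)
        out, report = qc_filter(m, min_libsize=1, min_genes_per_cell=1,
                                min_cells_per_gene=1)
        assert report["cells_fail_mito"] == 1
        assert "C0" not in out.cell_barcodes

    def test_gene_min_cells_threshold(self):
        rng = np.random.default_rng(2)
        counts, genes, cells = _qc_matrix(rng, n_genes=30, n_cells=20)
        counts += 10
        counts[3, :] = 0
        counts[3, :14] = 1          # nonzero in 14 < 15 cells -> removed
        m = CountMatrix(sp.csr_matrix(counts), genes, cells)
        out, report = qc_filter(m, min_libsize=1, min_genes_per_cell=1)
        assert report["genes_fail_min_cells"] == 1
        assert "G3" not in out.gene_names

    def test_all_cells_removed_reports_attrition(self):
        rng = np.random.default_rng(3)
        counts, genes, cells = _qc_matrix(rng)
        m = CountMatrix(sp.csr_matrix(counts), genes, cells)
        with pytest.raises(ValueError, match="cells_fail_libsize"):
            qc_filter(m)  # default 1000-read floor removes every toy cell

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        counts, genes, cells = _qc_matrix(rng, n_genes=60, n_cells=30)
        counts += rng.integers(0, 200, size=counts.shape)
        m = CountMatrix(sp.csr_matrix(counts), genes, cells)
        kw = dict(min_libsize=100, min_genes_per_cell=10, min_cells_per_gene=5)
        once, _ = qc_filter(m, **kw)
        twice, report = qc_filter(once, **kw)
        assert (once.counts != twice.counts).nnz == 0
        assert report["cells_in"] == report["cells_out"]
        assert report["genes_in"] == report["genes_out"]


class TestPearsonResiduals:
    def test_uniform_matrix_all_zero(self):
        m = CountMatrix(sp.csr_matrix(np.full((4, 6), 3.0)),
                        [f"g{i}" for i in range(4)],
                        [f"c{i}" for i in range(6)])
        assert np.allclose(pearson_residual_transform(m), 0.0, atol=1e-12)

    def test_poisson_limit_hand_case(self):
        X = np.array([[4.0, 0.0], [2.0, 6.0]])
        m = CountMatrix(sp.csr_matrix(X), ["g1", "g2"], ["c1", "c2"])
        mu = np.outer(X.sum(1), X.sum(0)) / X.sum()
        want = (X - mu) / np.sqrt(mu)
        got = pearson_residual_transform(m, theta=1e12, clip=None)
        assert np.allclose(got, want, atol=1e-6)

    def test_zero_count_negative_residual(self):
        X = np.array([[4.0, 0.0], [2.0, 6.0]])
        m = CountMatrix(sp.csr_matrix(X), ["g1", "g2"], ["c1", "c2"])
        assert pearson_residual_transform(m)[0, 1] < 0

    def test_auto_clip_bound(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(2.0, size=(30, 25)).astype(float)
        X[0, 0] = 5000.0
        m = CountMatrix(sp.csr_matrix(X), [f"g{i}" for i in range(30)],
                        [f"c{i}" for i in range(25)])
        res = pearson_residual_transform(m)
        assert np.abs(res).max() <= np.sqrt(25) + 1e-12

    def test_gene_variance_near_one_under_null(self):
        # independent Poisson product structure -> residual variance ~ 1
        rng = np.random.default_rng(6)
        gene_rates = rng.gamma(3, 2, 200)
        cell_depth = rng.uniform(0.5, 2.0, 500)
        mu = np.outer(gene_rates, cell_depth)
        X = rng.poisson(mu).astype(float)
        m = CountMatrix(sp.csr_matrix(X), [f"g{i}" for i in range(200)],
                        [f"c{i}" for i in range(500)])
        res = pearson_residual_transform(m, theta=1e12, clip=None)
        assert abs(res.var(axis=1).mean() - 1.0) < 0.2

    def test_matches_scanpy_reference(self):
        import anndata
        import scanpy as sc

        rng = np.random.default_rng(7)
        X = rng.poisson(3.0, size=(40, 60)).astype(np.float32)  # genes x cells
        adata = anndata.AnnData(X.T.copy())
        out = sc.experimental.pp.normalize_pearson_residuals(
            adata, theta=100, inplace=False)
        want = np.asarray(out["X"]).T
        m = CountMatrix(sp.csr_matrix(X), [f"g{i}" for i in range(40)],
                        [f"c{i}" for i in range(60)])
        got = pearson_residual_transform(m, theta=100)
        assert np.allclose(got, want, atol=1e-4)

    def test_zero_grand_total_error(self):
        m = CountMatrix(sp.csr_matrix(np.zeros((3, 3))),
                        ["a", "b", "c"], ["x", "y", "z"])
        with pytest.raises(ValueError, match="grand total"):
            pearson_residual_transform(m)


def _segment_embedding(n=100):
    t = np.linspace(0, 1, n)
    return t, np.column_stack([t, np.zeros(n)])


class TestPseudotime:
    def test_straight_segment_recovers_position(self):
        t, emb = _segment_embedding()
        pt = fit_pseudotime(emb)
        aligned = pt.values if pt.values[0] < pt.values[-1] else 1 - pt.values
        assert np.allclose(aligned, t, atol=1e-6)

    def test_rotation_invariance_up_to_reversal(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 1, 150))
        emb = np.column_stack([t, 0.3 * np.sin(3 * t)]) \
            + 0.01 * rng.normal(size=(150, 2))
        theta = np.pi / 2
        Rm = np.array([[np.cos(theta), -np.sin(theta)],
                       [np.sin(theta), np.cos(theta)]])
        a = fit_pseudotime(emb).values
        b = fit_pseudotime(emb @ Rm.T + np.array([5.0, -2.0])).values
        err = min(np.abs(a - b).max(), np.abs(a - (1 - b)).max())
        assert err < 1e-8

    def test_uniform_scaling_invariance(self):
        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(0, 1, 120))
        emb = np.column_stack([np.cos(2 * t), np.sin(2 * t)]) \
            + 0.01 * rng.normal(size=(120, 2))
        a = fit_pseudotime(emb).values
        b = fit_pseudotime(7.5 * emb).values
        err = min(np.abs(a - b).max(), np.abs(a - (1 - b)).max())
        assert err < 1e-8

    def test_noisy_s_curve_spearman(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(10)
        t = np.sort(rng.uniform(0, 1, 300))
        emb = np.column_stack([t, 0.2 * np.sin(2 * np.pi * t)]) \
            + 0.02 * rng.normal(size=(300, 2))
        pt = fit_pseudotime(emb)
        assert abs(spearmanr(pt.values, t).statistic) >= 0.95

    def test_degenerate_embedding_error(self):
        with pytest.raises(ValueError, match="coincident"):
            fit_pseudotime(np.zeros((50, 2)))

    def test_too_few_cells_error(self):
        with pytest.raises(ValueError, match="10 cells"):
            fit_pseudotime(np.random.default_rng(0).normal(size=(5, 2)))

    def test_flip_reverses(self):
        _, emb = _segment_embedding()
        a = fit_pseudotime(emb).values
        b = fit_pseudotime(emb, flip=True).values
        assert np.allclose(a, 1 - b, atol=1e-10)

    def test_normalized_range(self):
        _, emb = _segment_embedding()
        pt = fit_pseudotime(emb)
        assert pt.values.min() == 0.0 and pt.values.max() == 1.0


class TestSmoothedProfiles:
    def test_constant_gene_flat_line(self):
        pt = PseudotimeVector(np.linspace(0, 1, 80))
        expr = np.vstack([np.full(80, 2.5), np.linspace(0, 1, 80)])
        grid, curves = smoothed_profiles(expr, pt, [0])
        assert np.allclose(curves[0], 2.5, atol=1e-9)
        assert grid.size == 100

    def test_identity_gene_tracks_pseudotime(self):
        t = np.linspace(0, 1, 200)
        pt = PseudotimeVector(t)
        _, curves = smoothed_profiles(t[None, :], pt, [0])
        interior = slice(10, 90)
        grid = np.linspace(0, 1, 100)
        assert np.allclose(curves[0][interior], grid[interior], atol=1e-3)

    def test_reversed_pseudotime_mirrors_curve(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 1, 150)
        expr = (np.sin(3 * t) + 0.05 * rng.normal(size=150))[None, :]
        _, c1 = smoothed_profiles(expr, PseudotimeVector(t), [0])
        _, c2 = smoothed_profiles(expr, PseudotimeVector(1 - t), [0])
        assert np.allclose(c1[0], c2[0][::-1], atol=1e-8)

    def test_empty_gene_list_error(self):
        with pytest.raises(ValueError, match="empty"):
            smoothed_profiles(np.zeros((2, 10)),
                              PseudotimeVector(np.linspace(0, 1, 10)), [])
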