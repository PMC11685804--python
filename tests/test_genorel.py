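"""Marker QC and relationship-matrix construction."""

import numpy as np
import pytest

from canegps.genorel import (
    EmptyPanelError,
    amatrix,
    build_grm,
    dedup_complete_ld,
    filter_markers,
    hadamard_kernels,
    heterozygosity,
    hmatrix,
    impute_mean,
    ld_prune,
    pairwise_r2,
    read_dosage_tsv,
    read_pedigree_csv,
    write_dosage_tsv,
    write_pedigree_csv,
)
from canegps.simdata import SimConfig, simulate_genotypes, simulate_pedigree

from conftest import make_genotype_matrix, make_pedigree


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


class TestFilterMarkers:
    def test_missing_and_maf_thresholds(self):
        d = np.zeros((10, 3))
        d[:3, 0] = np.nan          # 30% missing → dropped at 0.2
        d[0, 1] = 1.0              # MAF 0.05 → dropped at 0.1
        d[:5, 2] = 2.0             # MAF 0.5, complete → kept
        G = make_genotype_matrix(d)
        out = filter_markers(G, max_missing=0.2, min_maf=0.1)
        assert list(out.marker_ids) == ["m2"]

    def test_all_passing_is_identity(self):
        rng = np.random.default_rng(0)
        G = make_genotype_matrix(rng.integers(0, 3, (20, 8)).astype(float))
        out = filter_markers(G, max_missing=0.2, min_maf=0.05)
        assert np.array_equal(out.dosages, G.dosages)
        assert list(out.marker_ids) == list(G.marker_ids)

    def test_empty_panel_raises(self):
        G = make_genotype_matrix(np.zeros((6, 2)))  # all monomorphic
        with pytest.raises(EmptyPanelError):
            filter_markers(G, min_maf=0.1)


class TestLdOperations:
    def test_dedup_identical_and_reflected_columns(self):
        x = np.array([0, 1, 2, 1, 0, 2, 1, 0], dtype=float)
        d = np.column_stack([x, x, 2 - x, 1.0 + 0 * x])
        d[:, 3] = [0, 2, 0, 2, 0, 2, 0, 2]
        G = make_genotype_matrix(d)
        out = dedup_complete_ld(G)
        # x, its copy and its reflection collapse to the first column
        assert list(out.marker_ids) == ["m0", "m3"]

    def test_dedup_no_perfect_pairs_is_identity(self):
        rng = np.random.default_rng(1)
        G = make_genotype_matrix(rng.integers(0, 3, (30, 10)).astype(float))
        assert dedup_complete_ld(G).m == G.m

    def test_prune_two_marker_thresholds(self):
        # r² = 0.5 between the two markers by construction
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 4000).astype(float)
        noise = rng.integers(0, 3, 4000).astype(float)
        y = np.where(rng.random(4000) < 0.646, x, noise)
        r2 = pairwise_r2(np.column_stack([x, y]))[0, 1]
        assert 0.3 < r2 < 0.6
        G = make_genotype_matrix(np.column_stack([x, y]))
        assert ld_prune(G, max(r2 - 0.1, 0.05)).m == 1
        assert ld_prune(G, min(r2 + 0.1, 1.0)).m == 2

    def test_prune_count_monotone_in_threshold(self):
        G = simulate_genotypes(
            SimConfig(n_genotypes=120, n_markers=400, n_chromosomes=4,
                      ld_block_size=8, seed=3)
        )
        counts = [
            ld_prune(G, t).m for t in (0.1, 0.15, 0.2, 0.3, 0.4, 0.6, 0.8, 0.99)
        ]
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]

    def test_threshold_one_keeps_all_without_duplicates(self):
        rng = np.random.default_rng(4)
        G = make_genotype_matrix(rng.integers(0, 3, (50, 20)).astype(float))
        assert ld_prune(G, 1.0).m == 20

    def test_dedup_then_prune_high_threshold_idempotent(self):
        G = simulate_genotypes(
            SimConfig(n_genotypes=100, n_markers=200, n_chromosomes=2,
                      ld_block_size=5, seed=5)
        )
        once = ld_prune(dedup_complete_ld(G), 0.99)
        twice = ld_prune(dedup_complete_ld(once), 0.99)
        assert list(once.marker_ids) == list(twice.marker_ids)


class TestImputeMean:
    def test_fills_with_column_mean(self):
        G = make_genotype_matrix(np.array([[0.0], [2.0], [np.nan]]))
        out = impute_mean(G)
        assert out.dosages[2, 0] == pytest.approx(1.0)

    def test_column_means_preserved_and_complete_identity(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, (40, 12)).astype(float)
        complete = make_genotype_matrix(d.copy())
        assert np.array_equal(impute_mean(complete).dosages, d)
        d[rng.random(d.shape) < 0.15] = np.nan
        G = make_genotype_matrix(d)
        out = impute_mean(G)
        assert not np.isnan(out.dosages).any()
        np.testing.assert_allclose(
            out.dosages.mean(axis=0), np.nanmean(d, axis=0), atol=1e-12
        )

    def test_entirely_missing_marker_raises(self):
        G = make_genotype_matrix(np.array([[np.nan, 0.0], [np.nan, 2.0]]))
        with pytest.raises(ValueError, match="entirely missing"):
            impute_mean(G)


# ---------------------------------------------------------------------------
# GRMs
# ---------------------------------------------------------------------------


class TestBuildGrm:
    def test_vanraden_single_marker_hand_example(self):
        # p = 0.5, W = (−1, 0, 1), denominator 2p(1−p) = 0.5
        G = make_genotype_matrix(np.array([[0.0], [1.0], [2.0]]))
        GA = build_grm(impute_mean(G), "additive")
        np.testing.assert_allclose(
            GA.values, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]], atol=1e-12
        )

    def test_identical_individuals_share_diagonal(self):
        rng = np.random.default_rng(7)
        row = rng.integers(0, 3, 50).astype(float)
        other = rng.integers(0, 3, 50).astype(float)
        G = make_genotype_matrix(np.vstack([row, row, other]))
        GA = build_grm(impute_mean(G), "additive")
        assert GA.values[0, 1] == pytest.approx(GA.values[0, 0])
        assert GA.values[0, 1] == pytest.approx(GA.values[1, 1])

    def test_hwe_diagonal_near_one(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.1, 0.5, 2000)
        d = rng.binomial(2, p, size=(500, 2000)).astype(float)
        GA = build_grm(impute_mean(make_genotype_matrix(d)), "additive")
        assert 0.95 <= float(np.mean(np.diag(GA.values))) <= 1.05

    def test_dominance_orthogonal_to_additive_under_hwe(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 0.5, 5000)
        d = rng.binomial(2, p, size=(150, 5000)).astype(float)
        G = impute_mean(make_genotype_matrix(d))
        GA, GD = build_grm(G, "additive"), build_grm(G, "dominance")
        iu = np.triu_indices(150, k=1)
        r = np.corrcoef(GA.values[iu], GD.values[iu])[0, 1]
        assert abs(r) < 0.1

    def test_monomorphic_markers_warned_and_excluded(self):
        d = np.column_stack([[0, 1, 2, 1], [2, 2, 2, 2]]).astype(float)
        with pytest.warns(UserWarning, match="monomorphic"):
            GA = build_grm(impute_mean(make_genotype_matrix(d)), "additive")
        assert GA.values.shape == (4, 4)


# ---------------------------------------------------------------------------
# pedigree A and single-step H
# ---------------------------------------------------------------------------


def gene_drop_amatrix(ped, n_rep=100_000, seed=0, chunk=20_000):
    """Monte-Carlo oracle: drop founder alleles through the pedigree and
    estimate relationships as twice the realised kinship."""
    rng = np.random.default_rng(seed)
    n = len(ped)
    pos = {g: i for i, g in enumerate(ped.id)}
    A = np.zeros((n, n))
    done = 0
    while done < n_rep:
        r = min(chunk, n_rep - done)
        alleles = np.zeros((n, r, 2), dtype=np.int32)
        label = 1
        for i in range(n):
            s = pos.get(ped.sire[i]) if ped.sire[i] is not None else None
            d = pos.get(ped.dam[i]) if ped.dam[i] is not None else None
            for slot, parent in ((0, s), (1, d)):
                if parent is None:
                    alleles[i, :, slot] = label
                    label += 1
                else:
                    pick = rng.integers(0, 2, r)
                    alleles[i, :, slot] = alleles[parent, np.arange(r), pick]
        acc = np.zeros((n, n))
        for a in range(2):
            for b in range(2):
                acc += (alleles[:, None, :, a] == alleles[None, :, :, b]).mean(2)
        A += acc / 4.0 * 2.0 * r
        done += r
    return A / n_rep


class TestAmatrix:
    def test_founders_identity(self):
        ped = make_pedigree([("a", None, None), ("b", None, None)])
        np.testing.assert_allclose(amatrix(ped).values, np.eye(2))

    def test_fullsib_and_parent_offspring(self, fullsib_pedigree):
        A = amatrix(fullsib_pedigree).to_frame()
        assert A.loc["s1", "s2"] == pytest.approx(0.5)
        assert A.loc["f1", "s1"] == pytest.approx(0.5)
        assert A.loc["s1", "s1"] == pytest.approx(1.0)  # non-inbred sib

    def test_offspring_of_full_sibs_inbred_diagonal(self):
        ped = make_pedigree(
            [("f1", None, None), ("f2", None, None),
             ("s1", "f1", "f2"), ("s2", "f1", "f2"), ("x", "s1", "s2")]
        )
        A = amatrix(ped).to_frame()
        assert A.loc["x", "x"] == pytest.approx(1.25)

    def test_agrees_with_gene_dropping(self):
        ped = simulate_pedigree(
            SimConfig(n_genotypes=30, n_markers=10, pedigree_founder_frac=0.4,
                      seed=11)
        )
        A = amatrix(ped).values
        A_mc = gene_drop_amatrix(ped, n_rep=100_000, seed=1)
        assert np.max(np.abs(A - A_mc)) < 0.01

    def test_unsorted_pedigree_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            make_pedigree([("kid", "p", None), ("p", None, None)])


class TestHmatrix:
    def _setup(self, seed=12):
        cfg = SimConfig(n_genotypes=25, n_markers=200, seed=seed,
                        pedigree_founder_frac=0.4)
        ped = simulate_pedigree(cfg)
        A = amatrix(ped)
        return ped, A

    def test_all_genotyped_no_blend_gives_g(self):
        ped, A = self._setup()
        G = build_grm(impute_mean(simulate_genotypes(
            SimConfig(n_genotypes=25, n_markers=200, seed=12))), "additive")
        H = hmatrix(A, G, list(A.ids), tau_blend=0.0)
        np.testing.assert_allclose(H.align(G.ids), G.values, atol=1e-8)

    def test_none_genotyped_gives_a(self):
        ped, A = self._setup()
        G = build_grm(impute_mean(simulate_genotypes(
            SimConfig(n_genotypes=25, n_markers=200, seed=12))), "additive")
        H = hmatrix(A, G, [], tau_blend=0.0)
        np.testing.assert_allclose(H.values, A.values, atol=1e-8)

    def test_g_equal_a22_collapses_to_a(self):
        from canegps.genorel import RelationshipMatrix

        ped, A = self._setup()
        sub = list(A.ids[10:])
        G = RelationshipMatrix(kind="G_A", ids=np.array(sub, dtype=object),
                               values=A.align(sub))
        H = hmatrix(A, G, sub, tau_blend=0.0)
        np.testing.assert_allclose(H.values, A.values, atol=1e-8)


class TestHadamardAndHet:
    def test_identity_and_elementwise_square(self):
        from canegps.genorel import RelationshipMatrix

        ids = np.array(["a", "b"], dtype=object)
        GA = RelationshipMatrix("G_A", ids, np.array([[1.0, 0.5], [0.5, 1.0]]))
        GD = RelationshipMatrix("G_D", ids, np.eye(2))
        gaa, gad = hadamard_kernels(GA, GD, rescale=False)
        np.testing.assert_allclose(gaa.values, [[1, 0.25], [0.25, 1]])
        np.testing.assert_allclose(gad.values, np.eye(2))

    def test_hadamard_kernels_remain_psd(self):
        G = impute_mean(simulate_genotypes(
            SimConfig(n_genotypes=60, n_markers=300, seed=13)))
        gaa, gad = hadamard_kernels(build_grm(G, "additive"),
                                    build_grm(G, "dominance"))
        assert gaa.min_eigenvalue() >= -1e-8
        assert gad.min_eigenvalue() >= -1e-8
        assert np.mean(np.diag(gaa.values)) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "dosages, expected",
        [([[0, 1, 2, 1]], [0.5]), ([[0, 0, 2, 2]], [0.0]), ([[1, 1, 1, 1]], [1.0])],
    )
    def test_heterozygosity_fractions(self, dosages, expected):
        hv = heterozygosity(make_genotype_matrix(np.asarray(dosages, float)))
        np.testing.assert_allclose(hv.het, expected)


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------


def test_dosage_tsv_round_trip(tmp_path):
    cfg = SimConfig(n_genotypes=12, n_markers=30, missing_rate=0.1, seed=14)
    G = simulate_genotypes(cfg)
    path = tmp_path / "panel.tsv"
    write_dosage_tsv(G, path)
    back = read_dosage_tsv(path)
    np.testing.assert_allclose(back.dosages, G.dosages, equal_nan=True)
    assert list(back.ids) == list(G.ids)


def test_vcf_round_trip(tmp_path):
    pytest.importorskip("cyvcf2")
    from canegps.genorel import read_vcf, write_vcf

    cfg = SimConfig(n_genotypes=10, n_markers=20, missing_rate=0.1, seed=15)
    G = simulate_genotypes(cfg)
    path = tmp_path / "panel.vcf"
    write_vcf(G, path)
    back = read_vcf(path)
    np.testing.assert_allclose(back.dosages, G.dosages, equal_nan=True)


def test_pedigree_csv_round_trip(tmp_path, fullsib_pedigree):
    path = tmp_path / "ped.csv"
    write_pedigree_csv(fullsib_pedigree, path)
    back = read_pedigree_csv(path)
    assert list(back.id) == list(fullsib_pedigree.id)
    assert back.sire[2] == "f1" and back.sire[0] is None
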