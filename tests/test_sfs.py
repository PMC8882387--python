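import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mkomega import (
    PooledData,
    SiteFrequencySpectrum,
    downsample_counts,
    fold_sfs,
    pool_genes,
    project_sfs,
    read_dofe,
    read_gene_table,
    write_dofe,
    write_gene_table,
)
from mkomega.sfs import ClassCounts, GeneTableError, SYNONYMOUS, NONSYNONYMOUS
from .conftest import make_gene


def sfs(n, counts, **kw):
    return SiteFrequencySpectrum(n, np.asarray(counts, float), **kw)


class TestSpectrum:
    def test_length_validation(self):
        with pytest.raises(ValueError, match="does not match"):
            sfs(4, [1, 2, 3, 4])
        with pytest.raises(ValueError, match="non-negative"):
            sfs(4, [1, -2, 3])
        with pytest.raises(ValueError, match=">= 4"):
            sfs(3, [1, 1])

    def test_fold_even_and_odd(self):
        assert np.array_equal(fold_sfs(sfs(4, [5, 3, 2])).counts, [7, 3])
        assert np.array_equal(fold_sfs(sfs(5, [4, 1, 1, 2])).counts, [6, 2])

    def test_fold_rejects_folded(self):
        with pytest.raises(ValueError, match="already folded"):
            fold_sfs(fold_sfs(sfs(4, [5, 3, 2])))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(4, 30), st.integers(0, 6))
    def test_fold_preserves_total(self, n, seed):
        counts = np.random.default_rng(seed).integers(0, 50, size=n - 1)
        folded = fold_sfs(sfs(n, counts))
        assert folded.total == pytest.approx(counts.sum())
        assert len(folded.counts) == n // 2


class TestProjection:
    def test_singleton_survival_by_hand(self):
        # 6 singletons at n=5 projected to m=4: a singleton stays a singleton
        # with probability C(1,1)C(4,3)/C(5,4) = 4/5 and is otherwise lost.
        out = project_sfs(sfs(5, [6, 0, 0, 0]), 4)
        assert out.counts == pytest.approx([6 * 0.8, 0, 0])

    def test_neutral_shape_is_preserved(self):
        # brute-force hypergeometric oracle: theta/i at n=10 projects to
        # theta/j at m=5
        from scipy.special import comb

        n, m, theta = 10, 5, 12.0
        inp = theta / np.arange(1, n)
        expected = np.zeros(m - 1)
        for j in range(1, m):
            for i in range(1, n):
                p = comb(i, j) * comb(n - i, m - j) / comb(n, m)
                expected[j - 1] += inp[i - 1] * p
        out = project_sfs(sfs(n, inp), m)
        assert out.counts == pytest.approx(expected)
        assert out.counts == pytest.approx(theta / np.arange(1, m), rel=1e-12)

    def test_mass_accounting(self):
        # all input mass lands in classes 0..m; exhaustive sum at n=12
        from scipy.special import comb

        n, m = 12, 11
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 40, size=n - 1).astype(float)
        out = project_sfs(sfs(n, counts), m)
        lost = 0.0
        for i in range(1, n):
            for j in (0, m):
                lost += counts[i - 1] * comb(i, j) * comb(n - i, m - j) / comb(n, m)
        assert out.total + lost == pytest.approx(counts.sum())

    def test_bounds(self):
        with pytest.raises(ValueError):
            project_sfs(sfs(6, [1] * 5), 6)
        with pytest.raises(ValueError):
            project_sfs(sfs(6, [1] * 5), 3)


class TestPooling:
    def test_elementwise_sum(self):
        a = make_gene("a", sfs_syn=[1, 2, 0, 0, 0])
        b = make_gene("b", sfs_syn=[0, 1, 1, 0, 0])
        pooled = pool_genes([a, b])
        assert np.array_equal(pooled.sfs_syn.counts, [1, 3, 1, 0, 0])
        assert pooled.n_genes == 2
        assert pooled.L_syn == a.L_syn + b.L_syn

    def test_associative_and_identity(self):
        genes = [
            make_gene(f"g{k}", sfs_syn=np.arange(5) * k, D_syn=k) for k in range(1, 4)
        ]
        left = pool_genes(genes)
        right = pool_genes([genes[0]])
        for g in genes[1:]:
            right = pool_genes([make_gene("tmp", sfs_syn=right.sfs_syn.counts,
                                          L_syn=right.L_syn, D_syn=right.D_syn), g])
        assert np.array_equal(left.sfs_syn.counts, right.sfs_syn.counts)
        single = pool_genes([genes[0]])
        assert np.array_equal(single.sfs_syn.counts, genes[0].sfs_syn.counts)

    def test_mixed_sample_sizes_rejected(self):
        with pytest.raises(ValueError, match="project"):
            pool_genes([make_gene("a", n=6), make_gene("b", n=8)])


class TestDownsample:
    def _pooled(self, Ls=4000, Ln=12000):
        return PooledData(
            L_syn=Ls, L_nonsyn=Ln,
            sfs_syn=sfs(6, [60, 30, 20, 10, 5], site_class=SYNONYMOUS),
            sfs_nonsyn=sfs(6, [40, 15, 8, 4, 2], site_class=NONSYNONYMOUS),
            D_syn=50, D_nonsyn=30, n_genes=10,
        )

    def test_identity_at_full_size(self):
        p = self._pooled()
        assert downsample_counts(p, 16000, 0) is p

    def test_counts_never_exceed_originals(self):
        p = self._pooled()
        for seed in range(5):
            d = downsample_counts(p, 5000, seed)
            assert np.all(d.sfs_syn.counts <= p.sfs_syn.counts)
            assert d.D_syn <= p.D_syn and d.D_nonsyn <= p.D_nonsyn
            assert d.L_syn + d.L_nonsyn == 5000

    def test_hypergeometric_expectation(self):
        # half the sites -> every count's mean over seeds within 3 SE of half
        p = self._pooled()
        reps = 400
        rng = np.random.default_rng(42)
        sums = np.zeros_like(p.sfs_syn.counts)
        dsyn = 0.0
        for _ in range(reps):
            d = downsample_counts(p, 8000, rng)
            sums += d.sfs_syn.counts
            dsyn += d.D_syn
        for got, orig in zip(sums / reps, p.sfs_syn.counts):
            se = np.sqrt(orig * 0.25 / reps) + 1e-9  # binomial-variance bound
            assert abs(got - orig / 2) < 3 * se + 0.05
        assert abs(dsyn / reps - 25) < 3 * np.sqrt(50 * 0.25 / reps) + 0.05

    def test_target_too_large(self):
        with pytest.raises(ValueError, match="exceeds"):
            downsample_counts(self._pooled(), 20000, 0)


class TestGeneTable:
    def test_round_trip(self, tmp_path):
        genes = [
            make_gene("a", sfs_syn=[1, 2, 0, 1, 0], rec_rate=1.5, age_stratum=3,
                      expression=10.0, length=200.0, vip=True,
                      go_ids=frozenset({"GO:1", "GO:2"})),
            make_gene("b", sfs_nonsyn=[0, 0, 1, 0, 2], D_nonsyn=7.0),
            make_gene("c"),
        ]
        path = tmp_path / "genes.tsv"
        write_gene_table(genes, path)
        back = read_gene_table(path)
        assert len(back) == 3
        for g, h in zip(genes, back):
            assert g.gene_id == h.gene_id
            assert np.array_equal(g.sfs_syn.counts, h.sfs_syn.counts)
            assert np.array_equal(g.sfs_nonsyn.counts, h.sfs_nonsyn.counts)
            assert g.go_ids == h.go_ids
            assert g.vip == h.vip
        assert back[0].rec_rate == 1.5
        assert back[1].rec_rate is None  # absent, not zero

    def test_round_trip_with_class_split(self, tmp_path, small_world):
        path = tmp_path / "genes.tsv"
        subset = small_world.genes[:40]
        write_gene_table(subset, path)
        back = read_gene_table(path)
        for g, h in zip(subset, back):
            assert h.class_split is not None
            for cls in g.class_split:
                assert np.array_equal(
                    g.class_split[cls].sfs_syn, h.class_split[cls].sfs_syn
                )
                assert g.class_split[cls].D_nonsyn == h.class_split[cls].D_nonsyn

    def test_bad_sfs_length_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_gene_table([make_gene("ok"), make_gene("broken")], path)
        text = path.read_text().splitlines()
        # give gene "broken" an SFS with n entries instead of n-1
        fields = text[2].split("\t")
        fields[4] = fields[4] + ",0"
        text[2] = "\t".join(fields)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(GeneTableError, match="broken"):
            read_gene_table(path)

    def test_empty_table(self, tmp_path, caplog):
        path = tmp_path / "empty.tsv"
        write_gene_table([], path)
        with caplog.at_level("WARNING"):
            assert read_gene_table(path) == []
        assert "empty" in caplog.text

    def test_class_split_must_sum(self):
        with pytest.raises(ValueError, match="class_split"):
            make_gene(
                "bad",
                sfs_syn=[2, 0, 0, 0, 0],
                class_split={
                    "WW": ClassCounts(100, 300, [1, 0, 0, 0, 0], np.zeros(5), 2, 3)
                },
            )


class TestDofe:
    def test_round_trip_and_integer_fields(self, tmp_path, small_world):
        pooled = pool_genes(small_world.genes[:200])
        path = tmp_path / "pooled.dofe"
        write_dofe(pooled, path, label="blk")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("#")
        fields = lines[1].split("\t")
        n = pooled.sample_size
        assert fields[0] == "blk" and int(fields[1]) == n
        assert len(fields) == 2 + 2 * (n - 1) + 6
        for f in fields[1:]:
            assert f == str(int(f))  # bit-exact integer formatting
        back = read_dofe(path)
        assert back.L_syn == round(pooled.L_syn)
        assert back.L_nonsyn == round(pooled.L_nonsyn)
        assert np.array_equal(back.sfs_syn.counts, pooled.sfs_syn.counts)
        assert np.array_equal(back.sfs_nonsyn.counts, pooled.sfs_nonsyn.counts)
        assert back.D_syn == pooled.D_syn and back.D_nonsyn == pooled.D_nonsyn
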