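import math

import numpy as np
import pytest

from kmerdiff.difftest import (
    DiffParams,
    bh_adjust,
    compute_nf,
    de_filter,
    de_pvalues,
    glm_chunk_pvalues,
    nb_glm_pvalues,
    ttest_pvalue,
    ttest_pvalues,
)
from kmerdiff.errors import KmerdiffError
from kmerdiff.matrix import CountMatrix


def _matrix(counts, n_a=None):
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[1]
    n_a = n_a if n_a is not None else n // 2
    samples = [(f"a{i}", "A") for i in range(n_a)] + [
        (f"b{i}", "B") for i in range(n - n_a)
    ]
    return CountMatrix(
        kmers=[f"k{i:05d}" for i in range(counts.shape[0])],
        counts=counts,
        samples=samples,
    )


class TestComputeNF:
    def test_identical_columns_give_unit_nf(self, rng):
        col = rng.integers(1, 50, size=40)
        m = _matrix(np.column_stack([col, col]))
        nf = compute_nf(m, frac=1.0)
        assert nf["a0"] == pytest.approx(1.0)
        assert nf["b0"] == pytest.approx(1.0)

    def test_doubled_column_hand_example(self, rng):
        """s2 = 2*s1 elementwise: ratios are (1/sqrt2, sqrt2) exactly."""
        col = rng.integers(1, 50, size=40)
        m = _matrix(np.column_stack([col, 2 * col]))
        nf = compute_nf(m, frac=1.0)
        assert nf["a0"] == pytest.approx(1 / math.sqrt(2))
        assert nf["b0"] == pytest.approx(math.sqrt(2))

    def test_matches_median_of_ratios_oracle(self, rng):
        counts = rng.integers(1, 200, size=(120, 6))
        m = _matrix(counts)
        nf = compute_nf(m, frac=1.0)
        # independent oracle: loop over rows and samples
        logs = [sum(math.log(x) for x in row) / 6 for row in counts]
        geo = [math.exp(l) for l in logs]
        raw = []
        for j in range(6):
            ratios = sorted(counts[i][j] / geo[i] for i in range(120))
            raw.append((ratios[59] + ratios[60]) / 2)
        scale = math.exp(sum(math.log(r) for r in raw) / 6)
        expected = [r / scale for r in raw]
        got = [nf[l] for l, _ in m.samples]
        assert got == pytest.approx(expected)

    def test_product_is_one(self, rng):
        counts = rng.integers(1, 100, size=(80, 5))
        nf = compute_nf(_matrix(counts, n_a=2), frac=1.0)
        assert math.prod(nf.values()) == pytest.approx(1.0)

    def test_all_zero_rows_rejected(self):
        m = _matrix([[0, 5], [3, 0]])
        with pytest.raises(KmerdiffError):
            compute_nf(m, frac=1.0)

    def test_subsample_is_seeded(self, rng):
        counts = rng.integers(1, 100, size=(500, 4))
        m = _matrix(counts)
        assert compute_nf(m, frac=0.3, seed=5) == compute_nf(m, frac=0.3, seed=5)


class TestTtest:
    SAMPLES_6 = [(f"a{i}", "A") for i in range(3)] + [(f"b{i}", "B") for i in range(3)]
    NF_6 = {f"{c}{i}": 1.0 for c in "ab" for i in range(3)}

    def test_identical_groups_p_one(self):
        assert ttest_pvalue([4, 4, 4, 4, 4, 4], self.NF_6, self.SAMPLES_6) == 1.0

    def test_all_zero_degenerate_p_one(self):
        assert ttest_pvalue([0, 0, 0, 0, 0, 0], self.NF_6, self.SAMPLES_6) == 1.0

    def test_small_group_rejected(self):
        samples = [("a0", "A"), ("b0", "B"), ("b1", "B")]
        nf = {"a0": 1.0, "b0": 1.0, "b1": 1.0}
        with pytest.raises(KmerdiffError):
            ttest_pvalue([1, 2, 3], nf, samples)

    def test_matches_hand_welch_oracle(self, rng):
        """Agrees with an explicitly hand-coded Welch t-test to 1e-9."""
        from scipy.stats import t as tdist

        counts = rng.integers(0, 300, size=(50, 12)).astype(float)
        nf = np.exp(rng.normal(0, 0.2, size=12))
        ga = np.arange(12) < 6
        p = ttest_pvalues(counts, nf, ga, ~ga)
        for i in range(50):
            y = np.log2(counts[i] / nf + 1)
            a, b = y[:6], y[6:]
            va, vb = a.var(ddof=1) / 6, b.var(ddof=1) / 6
            tstat = (a.mean() - b.mean()) / math.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / 5 + vb**2 / 5)
            expected = 2 * tdist.sf(abs(tstat), df)
            assert p[i] == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_joint_rescaling(self, rng):
        counts = rng.integers(1, 200, size=(30, 12)).astype(float)
        nf = np.exp(rng.normal(0, 0.3, size=12))
        ga = np.arange(12) < 6
        p1 = ttest_pvalues(counts, nf, ga, ~ga)
        p2 = ttest_pvalues(counts * 3.0, nf * 3.0, ga, ~ga)
        assert p1 == pytest.approx(p2)


class TestGlm:
    def test_constant_row_p_one(self):
        y = np.full((3, 12), 7)
        p = nb_glm_pvalues(y, np.ones(12), np.arange(12) < 6, np.arange(12) >= 6)
        assert (p == 1.0).all()

    def test_null_type_one_error_bounded(self, rng):
        mu = np.exp(rng.uniform(np.log(50), np.log(500), size=2000))[:, None]
        lam = rng.gamma(10.0, mu * 0.1, size=(2000, 12))
        y = rng.poisson(lam)
        ga = np.arange(12) < 6
        p = nb_glm_pvalues(y, np.ones(12), ga, ~ga)
        assert (p < 0.05).mean() <= 0.10

    def test_more_powerful_than_ttest_at_fold_four(self, rng):
        mu = np.full((800, 12), 80.0)
        mu[:, 6:] *= 4.0
        y = rng.poisson(rng.gamma(10.0, mu * 0.1))
        ga = np.arange(12) < 6
        pg = nb_glm_pvalues(y, np.ones(12), ga, ~ga)
        pt = ttest_pvalues(y.astype(float), np.ones(12), ga, ~ga)
        assert (pg < 0.05).mean() >= (pt < 0.05).mean()

    def test_presence_absence_signal_detectable(self):
        """An all-zero condition must not defeat the Wald test (continuity
        correction at the group-mean boundary)."""
        y = np.hstack([np.zeros((2, 6)), np.full((2, 6), 20)]).astype(int)
        p = nb_glm_pvalues(y, np.ones(12), np.arange(12) < 6, np.arange(12) >= 6)
        assert (p < 0.01).all()

    def test_chunk_invariance(self, rng):
        counts = rng.integers(0, 200, size=(100, 12))
        m = _matrix(counts)
        nf = {l: 1.0 for l, _ in m.samples}
        whole = glm_chunk_pvalues(m, nf)
        top = glm_chunk_pvalues(_matrix(counts[:37]), nf)
        bottom = glm_chunk_pvalues(_matrix(counts[37:]), nf)
        assert whole == pytest.approx(np.concatenate([top, bottom]))


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_hand_stepup_example(self):
        # m=4: 0.01*4/1=0.04, 0.02*4/2=0.04, 0.03*4/3=0.04, 0.04*4/4=0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(0, 1, size=rng.integers(1, 60))
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p) == pytest.approx(expected)

    def test_monotone_on_sorted_input(self, rng):
        p = np.sort(rng.uniform(0, 1, size=200))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()


class TestDeFilter:
    def test_threshold_one_returns_all(self, rng):
        counts = rng.integers(0, 100, size=(50, 12))
        m = _matrix(counts)
        nf = {l: 1.0 for l, _ in m.samples}
        params = DiffParams(pvalue_threshold=0.999999)
        out = de_filter(m, nf, params)
        assert len(out) == 50
        assert all(d.p_adj >= d.p_raw for d in out)

    def test_spiked_sixteen_fold_all_recovered(self, rng):
        mu = np.full((500, 12), 100.0)
        mu[:20, 6:] *= 16.0
        y = rng.poisson(rng.gamma(10.0, mu * 0.1))
        m = _matrix(y)
        nf = {l: 1.0 for l, _ in m.samples}
        out = de_filter(m, nf, DiffParams())
        hits = {d.kmer for d in out}
        assert {f"k{i:05d}" for i in range(20)} <= hits
        spiked = [d for d in out if d.kmer in {f"k{i:05d}" for i in range(20)}]
        assert all(d.log2fc > 2 for d in spiked)

    def test_empty_matrix_warns(self):
        m = _matrix(np.zeros((0, 12)))
        with pytest.warns(UserWarning):
            assert de_filter(m, {l: 1.0 for l, _ in m.samples}, DiffParams()) == []
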