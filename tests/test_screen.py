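"""Spearman screening, Bonferroni control and mimQTL calling, checked
against closed forms, an exhaustive permutation oracle, and a brute-force
pairwise loop."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mimqtl import GenomeAnnotation, bonferroni_adjust, build_sign_matrix, call_mimqtls
from mimqtl.screen import MimQTLTable, spearman_screen


def screen_pair(x, y):
    """Screen a single pair through the full engine."""
    import mimqtl

    e = mimqtl.OmicsMatrix(
        pd.DataFrame([x], index=["m"], columns=[f"s{i}" for i in range(len(x))]),
        "expression")
    m = mimqtl.OmicsMatrix(
        pd.DataFrame([y], index=["c"], columns=[f"s{i}" for i in range(len(y))]),
        "expression")  # screening is kind-agnostic; avoids beta bounds
    res = spearman_screen(e, m)
    return res.rho.iloc[0, 0], res.p.iloc[0, 0]


class TestSpearmanScreen:
    def test_closed_form_rank_example(self):
        # ranks d^2 = (4,1,1): rho = 1 - 6*6/(3*8) = -0.5
        x = [1, 2, 3, 10, 20, 30, 40, 50]
        # pad to n=8 keeping the first three in the stated rank pattern is
        # fiddly; check the 3-point closed form directly on the rho matrix
        rho = 1 - 6 * 6 / (3 * (9 - 1))
        e = np.array([[1.0, 2.0, 3.0]])
        m = np.array([[3.0, 1.0, 2.0]])
        from mimqtl.screen import _screen_complete

        assert _screen_complete(e, m)[0, 0] == pytest.approx(rho)
        assert rho == -0.5

    def test_perfect_monotone(self):
        x = np.arange(10, dtype=float)
        rho, p = screen_pair(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_p_matches_exhaustive_permutation_oracle(self, rng):
        """n=8: the t-approximation p agrees with the exact permutation
        distribution of |rho| over all 8! orderings within 0.02."""
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho, p = screen_pair(x, y)
        rx = stats.rankdata(x)
        observed = abs(stats.spearmanr(x, y).statistic)
        count = 0
        total = 0
        ry = stats.rankdata(y)
        for perm in itertools.permutations(range(8)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= observed - 1e-12
            total += 1
        exact = count / total
        assert p == pytest.approx(exact, abs=0.02)

    def test_matches_brute_force_loop_on_toy(self, rng):
        """Full screen equals a per-pair scipy.spearmanr loop bit-for-bit."""
        import mimqtl

        e = mimqtl.OmicsMatrix(
            pd.DataFrame(rng.normal(size=(10, 30)),
                         index=[f"m{i}" for i in range(10)],
                         columns=[f"s{i}" for i in range(30)]), "expression")
        m = mimqtl.OmicsMatrix(
            pd.DataFrame(rng.random((10, 30)),
                         index=[f"c{i}" for i in range(10)],
                         columns=[f"s{i}" for i in range(30)]), "methylation")
        res = spearman_screen(e, m)
        for i in range(10):
            for j in range(10):
                r, p = stats.spearmanr(e.values.iloc[i], m.values.iloc[j])
                assert res.rho.iloc[i, j] == pytest.approx(r, abs=1e-12)
                assert res.p.iloc[i, j] == pytest.approx(p, rel=1e-9)

    def test_zero_variance_feature_skipped(self, make_omics):
        import mimqtl

        e = make_omics([[1.0] * 10, list(range(10))], kind="expression")
        m = make_omics([np.linspace(0, 1, 10)], kind="methylation",
                       features=["c0"])
        res = spearman_screen(e, m)
        assert np.isnan(res.rho.loc["f0", "c0"])
        assert res.m == 1

    def test_rank_invariance_under_monotone_transform(self, make_omics, rng):
        e_vals = rng.normal(size=(4, 25))
        m_vals = rng.random((4, 25))
        e1 = make_omics(e_vals, kind="expression")
        e2 = make_omics(np.exp(e_vals / 2), kind="expression")
        m = make_omics(m_vals)
        r1 = spearman_screen(e1, m)
        r2 = spearman_screen(e2, m)
        pd.testing.assert_frame_equal(r1.rho, r2.rho)

    def test_mismatched_samples_rejected(self, make_omics, rng):
        e = make_omics(rng.random((2, 10)), kind="expression")
        m = make_omics(rng.random((2, 9)))
        with pytest.raises(ValueError, match="sample ids"):
            spearman_screen(e, m)

    def test_pairwise_complete_path_uses_shared_samples(self, make_omics, rng):
        vals = rng.random((1, 20))
        holey = vals.copy()
        holey[0, :5] = np.nan
        e = make_omics(rng.normal(size=(1, 20)), kind="expression")
        m = make_omics(holey)
        res = spearman_screen(e, m)
        r, _ = stats.spearmanr(e.values.iloc[0, 5:], vals[0, 5:])
        assert res.rho.iloc[0, 0] == pytest.approx(r)
        assert res.n_used.iloc[0, 0] == 15


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        assert bonferroni_adjust(np.array([0.001]), 100)[0] == pytest.approx(0.1)
        assert bonferroni_adjust(np.array([0.5]), 10)[0] == 1.0

    def test_m_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(np.array([0.5]), 0)

    def test_fwer_under_uniform_null(self, rng):
        """Family-wise error of the Bonferroni rule under a uniform null:
        over replicates, the >=1-rejection rate stays at or below alpha."""
        m, reps, alpha = 200, 2000, 0.05
        rejections = 0
        for _ in range(reps):
            p = rng.random(m)
            rejections += (bonferroni_adjust(p, m) < alpha).any()
        rate = rejections / reps
        # binomial 3-sigma envelope around alpha
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)


def _screen_results_from(rho1, rho2, n1=50, n2=60, m=None):
    from mimqtl.screen import ScreenResult, spearman_pvalue

    m = m or rho1.size
    out = []
    for rho, n in ((rho1, n1), (rho2, n2)):
        p = spearman_pvalue(rho.to_numpy(), n)
        p = pd.DataFrame(p, index=rho.index, columns=rho.columns)
        out.append(ScreenResult(rho, p, (p * m).clip(upper=1.0),
                                p * 0 + n, m))
    return out


class TestCallMimqtls:
    def setup_method(self):
        idx = pd.Index(["m1", "m2"])
        cols = pd.Index(["c1", "c2"])
        # pair (m1,c1): strong in both, same sign -> kept
        # pair (m1,c2): strong in cohort 1 only -> excluded
        # pair (m2,c1): strong both, opposite sign -> excluded
        # pair (m2,c2): null
        self.rho1 = pd.DataFrame([[-0.9, -0.9], [0.9, 0.01]], index=idx, columns=cols)
        self.rho2 = pd.DataFrame([[-0.9, -0.01], [-0.9, 0.02]], index=idx, columns=cols)

    def test_concordance_rules(self):
        s1, s2 = _screen_results_from(self.rho1, self.rho2)
        table = call_mimqtls(s1, s2, alpha=0.05)
        assert len(table) == 1
        rec = table.records.iloc[0]
        assert (rec["mirna_id"], rec["cpg_id"], rec["sign"]) == ("m1", "c1", -1)

    def test_subset_of_each_cohort_significant_set(self):
        s1, s2 = _screen_results_from(self.rho1, self.rho2)
        table = call_mimqtls(s1, s2)
        assert len(table) <= min(table.n_significant)

    def test_cohort_symmetry(self):
        s1, s2 = _screen_results_from(self.rho1, self.rho2)
        t12 = call_mimqtls(s1, s2)
        t21 = call_mimqtls(s2, s1)
        assert set(map(tuple, t12.records[["mirna_id", "cpg_id"]].values)) == \
            set(map(tuple, t21.records[["mirna_id", "cpg_id"]].values))


class TestSignMatrix:
    def test_single_negative_pair(self):
        table = MimQTLTable(pd.DataFrame(
            {"mirna_id": ["m1"], "cpg_id": ["c1"], "sign": [-1]}), (1, 1), 0.05)
        sign = build_sign_matrix(table)
        assert sign.shape == (1, 1)
        assert sign.iloc[0, 0] == -1

    def test_entry_count_and_row_sums_match_tally(self, rng):
        mirnas = [f"m{i}" for i in range(5)]
        cpgs = [f"c{i}" for i in range(8)]
        pairs = [(m, c) for m in mirnas for c in cpgs]
        chosen = [pairs[i] for i in rng.choice(len(pairs), 12, replace=False)]
        signs = rng.choice([-1, 1], size=12)
        table = MimQTLTable(pd.DataFrame(
            {"mirna_id": [p[0] for p in chosen],
             "cpg_id": [p[1] for p in chosen], "sign": signs}), (1, 1), 0.05)
        sign = build_sign_matrix(table)
        assert int((sign.to_numpy() != 0).sum()) == 12
        tally = {}
        for (m, c), s in zip(chosen, signs):
            tally[c] = tally.get(c, 0) + s
        for c, total in tally.items():
            assert sign.loc[c].sum() == total

    def test_empty_table_rejected(self):
        table = MimQTLTable(pd.DataFrame(
            columns=["mirna_id", "cpg_id", "sign"]), (1, 1), 0.05)
        with pytest.raises(ValueError):
            build_sign_matrix(table)


class TestCisTrans:
    def test_flags_and_unknown(self):
        from mimqtl import classify_cis_trans

        table = MimQTLTable(pd.DataFrame({
            "mirna_id": ["m1", "m1", "m2"],
            "cpg_id": ["c1", "c2", "c1"],
            "sign": [1, -1, 1]}), (1, 1), 0.05)
        ann = GenomeAnnotation(pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"],
             "start": [100, 50, 70], "end": [180, 50, 70]},
            index=pd.Index(["m1", "c1", "c2"], name="feature_id")))
        out = classify_cis_trans(table, ann)
        flags = dict(zip(
            zip(out.records["mirna_id"], out.records["cpg_id"]),
            out.records["cis_trans"]))
        assert flags[("m1", "c1")] == "cis"
        assert flags[("m1", "c2")] == "trans"
        assert flags[("m2", "c1")] == "unknown"
        s = out.summary()
        assert s["n_cis"] == 1 and s["cis_fraction"] == 0.5
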