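import numpy as np
import pandas as pd
import pytest

from conftest import make_collapsed, random_cq_frame
from refstab import (
    InsufficientDataError,
    genorm_m,
    genorm_rank,
    genorm_v_curve,
    linearise,
    pairwise_v,
)

SQRT53 = np.sqrt(5.0 / 3.0)  # sample SD of log2 ratios {0,-1,-2,-3}


def brute_force_m_from_cq(cq: pd.DataFrame) -> pd.Series:
    """Independent oracle: at E=2, V_jk equals the sample SD of (Cq_k - Cq_j)."""
    out = {}
    for j in cq.index:
        vs = [np.std(cq.loc[k] - cq.loc[j], ddof=1) for k in cq.index if k != j]
        out[j] = float(np.mean(vs))
    return pd.Series(out)


class TestPairwiseV:
    def test_proportional_genes_have_zero_v(self, abc_rq):
        assert pairwise_v(abc_rq, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self, abc_rq):
        assert pairwise_v(abc_rq, "A", "C") == pytest.approx(SQRT53, abs=1e-4)

    def test_symmetry(self, abc_rq):
        for j, k in (("A", "B"), ("A", "C"), ("B", "C")):
            assert pairwise_v(abc_rq, j, k) == pairwise_v(abc_rq, k, j)

    def test_too_few_samples(self):
        rq = linearise(make_collapsed({"A": [20, 21], "B": [20, 20]}))
        with pytest.raises(InsufficientDataError):
            pairwise_v(rq, "A", "B")


class TestM:
    def test_hand_computed_fixture(self, abc_rq):
        m = genorm_m(abc_rq)
        assert m["A"] == pytest.approx(SQRT53 / 2, abs=1e-4)
        assert m["B"] == pytest.approx(SQRT53 / 2, abs=1e-4)
        assert m["C"] == pytest.approx(SQRT53, abs=1e-4)

    def test_identical_panel_all_zero(self):
        rq = linearise(make_collapsed({g: [20, 21, 22] for g in "ABCD"}))
        assert np.allclose(genorm_m(rq), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cq_difference_oracle(self, seed):
        cq = random_cq_frame(np.random.default_rng(seed))
        rq = linearise(make_collapsed({g: cq.loc[g].tolist() for g in cq.index}))
        m = genorm_m(rq)
        oracle = brute_force_m_from_cq(cq)
        assert np.allclose(m.sort_index(), oracle.sort_index(), atol=1e-9)


class TestRank:
    def test_single_exclusion_step(self, abc_rq):
        res = genorm_rank(abc_rq)
        assert [g for g, _ in res.removal_order] == ["C"]
        assert res.best_pair == ("A", "B")
        assert res.final_m == pytest.approx(0.0, abs=1e-12)

    def test_m_at_removal_shares_final_m(self, abc_rq):
        scores = genorm_rank(abc_rq).m_at_removal
        assert scores["A"] == scores["B"] == pytest.approx(0.0, abs=1e-12)
        assert scores["C"] == pytest.approx(SQRT53, abs=1e-4)

    def test_tie_break_reverse_alphabetical_recorded(self):
        # two flat genes and two identical rising genes: first-round M ties
        rq = linearise(make_collapsed({
            "A": [20, 21, 22, 23], "B": [20, 21, 22, 23],
            "C": [20, 20, 20, 20], "D": [20, 20, 20, 20],
        }))
        res = genorm_rank(rq)
        assert res.removal_order[0][0] == "D"
        assert res.tie_breaks


class TestVCurve:
    def test_identical_panel_v_zero(self):
        rq = linearise(make_collapsed({g: [20, 21, 22, 23] for g in "ABCD"}))
        v = genorm_v_curve(rq, genorm_rank(rq))
        assert np.allclose(v, 0.0)
        assert list(v.index) == ["V2/3", "V3/4"]

    def test_noisy_last_gene_raises_final_v(self):
        rng = np.random.default_rng(7)
        base = np.array([20.0, 21.0, 22.0, 23.0, 24.0, 25.0])
        rq = linearise(make_collapsed({
            "A": base.tolist(),
            "B": (base + 0.05 * rng.standard_normal(6)).tolist(),
            "C": (base + 0.05 * rng.standard_normal(6)).tolist(),
            "D": (base + 2.0 * rng.standard_normal(6)).tolist(),
        }))
        res = genorm_rank(rq)
        assert res.removal_order[0][0] == "D"
        v = genorm_v_curve(rq, res)
        assert v["V3/4"] > v["V2/3"]


class TestInvariances:
    @pytest.mark.parametrize("seed", range(3))
    def test_per_sample_global_offset(self, seed):
        rng = np.random.default_rng(seed)
        cq = random_cq_frame(rng)
        shifted = cq + rng.normal(0, 2, cq.shape[1])[None, :]
        m1 = genorm_m(linearise(make_collapsed({g: cq.loc[g].tolist() for g in cq.index})))
        m2 = genorm_m(linearise(make_collapsed({g: shifted.loc[g].tolist() for g in cq.index})))
        assert np.allclose(m1, m2, atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_per_gene_constant_offset(self, seed):
        rng = np.random.default_rng(seed)
        cq = random_cq_frame(rng)
        shifted = cq + rng.normal(0, 3, cq.shape[0])[:, None]
        r1 = genorm_rank(linearise(make_collapsed({g: cq.loc[g].tolist() for g in cq.index})))
        r2 = genorm_rank(linearise(make_collapsed({g: shifted.loc[g].tolist() for g in cq.index})))
        assert np.allclose(r1.m_full_panel, r2.m_full_panel, atol=1e-9)
        assert r1.best_pair == r2.best_pair
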