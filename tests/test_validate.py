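import numpy as np
import pandas as pd
import pytest

from conftest import make_collapsed
from refstab import (
    InsufficientDataError,
    SchemaError,
    compare_nfs,
    linearise,
    normalization_factor,
    normalize_goi,
    simulate,
    total_cov,
    validation_report,
)
from refstab.analysis import prepare


@pytest.fixture
def rq3():
    return linearise(make_collapsed({
        "R1": [20.0, 21.0, 22.0, 23.0],
        "R2": [25.0, 25.0, 25.0, 25.0],
        "G": [21.0, 21.5, 23.0, 22.0],
    }))


class TestNormalizationFactor:
    def test_single_reference_equals_its_rq(self, rq3):
        nf = normalization_factor(rq3, ["R1"])
        pd.testing.assert_series_equal(nf.nf, rq3.rq.loc["R1"], check_names=False)

    def test_geometric_mean_of_two(self):
        rq = linearise(make_collapsed({"R1": [20.0, 20.0, 25.0], "R2": [20.0, 25.0, 23.0],
                                       "G": [21.0, 22.0, 23.0]}))
        # sample s1: RQs are 1 and 1 -> NF 1; values 1 and 4 give NF 2
        nf = normalization_factor(rq, ["R1", "R2"])
        r1, r2 = rq.rq.loc["R1"], rq.rq.loc["R2"]
        assert np.allclose(nf.nf, np.sqrt(r1 * r2))

    def test_cube_root_of_product(self):
        rq_frame = pd.DataFrame(
            {"s1": [0.5, 0.5, 4.0]}, index=["R1", "R2", "R3"]
        )
        from refstab.io import RqTable
        rq = RqTable(rq=rq_frame, meta=pd.DataFrame(index=["s1"]),
                     efficiency=pd.Series(2.0, index=rq_frame.index))
        nf = normalization_factor(rq, ["R1", "R2", "R3"])
        assert nf.nf["s1"] == pytest.approx(1.0)

    def test_empty_refs_error(self, rq3):
        with pytest.raises(SchemaError):
            normalization_factor(rq3, [])


class TestNormalizeGoi:
    def test_division(self, rq3):
        nf = normalization_factor(rq3, ["R1"])
        goi = pd.Series(6.0, index=rq3.sample_ids)
        out = normalize_goi(goi, nf)
        assert np.allclose(out, 6.0 / nf.nf)

    def test_proportional_goi_becomes_constant(self, rq3):
        nf = normalization_factor(rq3, ["R1"])
        out = normalize_goi(3.0 * nf.nf, nf)
        assert np.allclose(out, 3.0)

    def test_self_normalization_identity(self, rq3):
        nf = normalization_factor(rq3, ["G"])
        out = normalize_goi(rq3.rq.loc["G"], nf)
        assert np.allclose(out, 1.0)

    def test_missing_nf_sample_dropped(self, rq3):
        nf = normalization_factor(rq3, ["R1"])
        goi = pd.Series(1.0, index=rq3.sample_ids + ["extra"])
        out = normalize_goi(goi, nf)
        assert "extra" not in out.index
        assert out.attrs["dropped_samples"] == ["extra"]


class TestTotalCov:
    def test_constant_values_zero(self):
        v = pd.Series([2.0] * 6, index=list("abcdef"))
        tp = pd.Series([1, 1, 1, 2, 2, 2], index=v.index)
        assert total_cov(v, tp) == 0.0

    def test_known_single_timepoint(self):
        v = pd.Series([1.0, 2.0, 3.0])
        tp = pd.Series(["t"] * 3)
        assert total_cov(v, tp) == pytest.approx(0.5)

    def test_sums_over_timepoints(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        tp = pd.Series(["t1"] * 3 + ["t2"] * 3)
        assert total_cov(v, tp) == pytest.approx(1.0)

    def test_singleton_timepoint_errors(self):
        v = pd.Series([1.0, 2.0, 3.0])
        tp = pd.Series(["t1", "t1", "t2"])
        with pytest.raises(InsufficientDataError):
            total_cov(v, tp)


class TestCompareNfs:
    def test_identity(self, rq3):
        nf = normalization_factor(rq3, ["R1"])
        cmp = compare_nfs(nf, nf)
        assert cmp.r == pytest.approx(1.0)
        assert cmp.gradient == pytest.approx(1.0)

    def test_pure_scaling_gradient_two(self, rq3):
        from refstab.validate import NormalizationFactor
        nf = normalization_factor(rq3, ["R1"])
        nf2 = NormalizationFactor(nf=2.0 * nf.nf, refs=["R1"])
        cmp = compare_nfs(nf, nf2)
        assert cmp.r == pytest.approx(1.0)
        assert cmp.gradient == pytest.approx(2.0)
        assert cmp.intercept == pytest.approx(0.0, abs=1e-12)

    def test_three_vs_two_gene_nf_on_synthetic_defaults(self):
        t, _ = simulate(seed=5)
        _, rq = prepare(t)
        nf3 = normalization_factor(rq, ["ACTB", "RPL13A", "AP3D1"])
        nf2 = normalization_factor(rq, ["ACTB", "RPL13A"])
        assert compare_nfs(nf3, nf2).r > 0.95


class TestValidationReport:
    def test_trending_gene_cov_drops_on_synthetic_defaults(self):
        t, truth = simulate(seed=3)
        _, rq = prepare(t)
        rep = validation_report(rq, ["ACTB", "RPL13A", "AP3D1"], ["HPRT1", "B2M"])
        total = rep.cov.groupby("gene")[["cov_raw", "cov_normalized"]].sum()
        assert (total["cov_normalized"] < total["cov_raw"]).all()

    def test_absent_target_errors(self, rq3):
        rq3.meta["tissue"] = "embryo"
        rq3.meta["age_days"] = [11.5, 11.5, 13.5, 13.5]
        with pytest.raises(SchemaError, match="nope"):
            validation_report(rq3, ["R1"], ["nope"])
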