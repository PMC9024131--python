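import dataclasses

import numpy as np
import pandas as pd
import pytest

from refstab import (
    SchemaError,
    SimParams,
    default_archetypes,
    default_design,
    deltact_scores,
    genorm_m,
    linearise,
    normfinder_ungrouped,
    read_cq,
    simulate,
    write_long_csv,
)
from refstab.analysis import prepare


class TestDefaultDesign:
    def test_sample_totals(self):
        d = default_design()
        assert d.n_samples == 44
        assert d.tissue_counts() == {"embryo": 24, "head": 11, "forelimb": 9}

    def test_embryo_age_layout(self):
        d = default_design()
        embryo = {(a, n) for t, a, n in d.blocks if t == "embryo"}
        assert (13.5, 4) in embryo and (18.5, 5) in embryo
        assert len([1 for t, *_ in d.blocks if t == "embryo"]) == 7

    def test_schema_completeness(self):
        t, _ = simulate(seed=0)
        for col in ("tissue", "age_days", "litter", "cdna_batch", "plate", "is_calibrator"):
            assert t.meta[col].notna().all(), col


class TestSimulate:
    def test_same_seed_identical_output(self):
        t1, tr1 = simulate(seed=42)
        t2, tr2 = simulate(seed=42)
        pd.testing.assert_frame_equal(t1.wells, t2.wells)
        pd.testing.assert_series_equal(tr1.q, tr2.q)

    def test_different_seeds_differ(self):
        t1, _ = simulate(seed=1)
        t2, _ = simulate(seed=2)
        assert not np.allclose(t1.wells["cq"], t2.wells["cq"])

    def test_noise_free_limit_all_scores_zero(self):
        arche = [dataclasses.replace(a, sigma_g=0.0, slopes={}, latent_loading=0.0)
                 for a in default_archetypes()]
        params = SimParams(sigma_q=0.0, sigma_tech=0.0, sigma_plate=0.0,
                           priming_batch=None)
        t, _ = simulate(archetypes=arche, params=params, seed=0)
        collapsed, rq = prepare(t)
        assert np.allclose(genorm_m(rq), 0.0, atol=1e-9)
        assert np.allclose(deltact_scores(collapsed).scores, 0.0, atol=1e-9)
        assert np.allclose(normfinder_ungrouped(rq).stability, 0.0, atol=1e-9)

    def test_negative_sigma_rejected(self):
        with pytest.raises(SchemaError):
            simulate(params=SimParams(sigma_q=-1.0), seed=0)

    def test_quality_effect_cancels_in_all_methods(self):
        # identical noise streams with sigma_q 0 vs large: the per-sample
        # quality offset is absorbed by every stability statistic
        t0, _ = simulate(params=SimParams(sigma_q=0.0), seed=9)
        t1, _ = simulate(params=SimParams(sigma_q=2.0), seed=9)
        c0, rq0 = prepare(t0)
        c1, rq1 = prepare(t1)
        assert np.allclose(genorm_m(rq0), genorm_m(rq1), atol=1e-9)
        assert np.allclose(deltact_scores(c0).scores, deltact_scores(c1).scores, atol=1e-9)
        assert np.allclose(normfinder_ungrouped(rq0).stability,
                           normfinder_ungrouped(rq1).stability, atol=1e-9)

    def test_truth_reconstructs_systematic_cq(self):
        arche = [dataclasses.replace(a, sigma_g=0.0) for a in default_archetypes()]
        params = SimParams(sigma_tech=0.0, sigma_plate=0.0)
        t, truth = simulate(archetypes=arche, params=params, seed=4)
        collapsed, _ = prepare(t, calibrate=True)
        expected = truth.expected_cq(t.meta)
        got = collapsed.cq.loc[expected.index, expected.columns]
        assert np.allclose(got, expected, atol=1e-9)

    def test_priming_shift_hits_only_sensitive_genes(self):
        t, truth = simulate(seed=6)
        collapsed, _ = prepare(t)
        bad = t.meta.index[t.meta["cdna_batch"] == "B2"]
        good = t.meta.index[t.meta["cdna_batch"] != "B2"]
        shift_18s = collapsed.cq.loc["18S", bad].mean() - collapsed.cq.loc["18S", good].mean()
        shift_actb = collapsed.cq.loc["ACTB", bad].mean() - collapsed.cq.loc["ACTB", good].mean()
        assert shift_18s == pytest.approx(3.0, abs=0.8)
        assert abs(shift_actb) < 1.0


class TestRoundTrip:
    def test_write_then_read_long_csv(self, tmp_path):
        t, _ = simulate(seed=7)
        path = tmp_path / "cq.csv"
        write_long_csv(t, path)
        back = read_cq(path, dialect="long")
        assert back.genes == sorted(t.genes)
        assert set(back.sample_ids) == set(t.sample_ids)
        merged = back.wells.merge(t.wells, on=["sample_id", "gene", "plate", "well"])
        assert np.allclose(merged["cq_x"], merged["cq_y"], atol=1e-9)
        pd.testing.assert_series_equal(
            back.meta["age_days"].astype(float).sort_index(),
            t.meta["age_days"].astype(float).sort_index(),
        )

    def test_truth_json(self, tmp_path):
        import json

        _, truth = simulate(seed=8)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        data = json.loads(p.read_text())
        assert data["seed"] == 8
        assert data["batch_offsets"] == {"B2": 3.0}
        assert len(data["q"]) == 44
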