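import numpy as np
import pandas as pd
import pytest

from refstab import CqTable, RqTable, linearise


def make_collapsed(cq: dict[str, list[float]], meta: pd.DataFrame | None = None) -> CqTable:
    """Collapsed CqTable from a {gene: per-sample Cq} dict."""
    frame = pd.DataFrame(cq).T
    frame.columns = [f"s{i + 1}" for i in range(frame.shape[1])]
    if meta is None:
        meta = pd.DataFrame(index=frame.columns)
        for col in ("tissue", "age_days", "litter", "cdna_batch"):
            meta[col] = np.nan
        meta["is_calibrator"] = False
    return CqTable(meta=meta, cq=frame)


@pytest.fixture
def abc_fixture() -> CqTable:
    """The hand-computed 3-gene x 4-sample panel.

    A rises one cycle per sample, B tracks A five cycles later (constant
    ratio to A), C is flat; at E=2 the known scores are
    M_A = M_B = 0.6455, M_C = 1.2910.
    """
    return make_collapsed(
        {
            "A": [20.0, 21.0, 22.0, 23.0],
            "B": [25.0, 26.0, 27.0, 28.0],
            "C": [20.0, 20.0, 20.0, 20.0],
        }
    )


@pytest.fixture
def abc_rq(abc_fixture) -> RqTable:
    return linearise(abc_fixture, efficiency=2.0)


def random_cq_frame(rng: np.random.Generator, n_genes: int = 6, n_samples: int = 10) -> pd.DataFrame:
    """Random collapsed Cq matrix with heterogeneous gene levels and noise."""
    base = rng.uniform(15, 30, n_genes)[:, None]
    noise = rng.normal(0, rng.uniform(0.2, 1.0, n_genes)[:, None], (n_genes, n_samples))
    frame = pd.DataFrame(
        base + noise,
        index=[f"g{i + 1}" for i in range(n_genes)],
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )
    return frame
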