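import numpy as np
import pandas as pd
import pytest

from methdml import synthetic as syn
from methdml.preprocess import compute_beta, four_route_betas


@pytest.fixture(scope="session")
def small_manifest():
    return syn.generate_manifest(n_loci=2000, n_genes=1000, seed=11)


@pytest.fixture(scope="session")
def planted_study(small_manifest):
    """Paired study with 40 hyper + 20 hypo planted loci at |delta beta| 0.35."""
    plan = syn.default_dml_plan(small_manifest, n_hyper=40, n_hypo=20, delta=0.35, seed=12)
    study, truth = syn.generate_paired_study(small_manifest, n_cases=24, dml_plan=plan, seed=13)
    return study, truth, plan


@pytest.fixture(scope="session")
def planted_routes(planted_study):
    study, truth, plan = planted_study
    return four_route_betas(study)


@pytest.fixture(scope="session")
def planted_beta(planted_study):
    study, _, _ = planted_study
    return compute_beta(study.M, study.U)


@pytest.fixture()
def tiny_samples():
    """Three complete cases, tissue + case only."""
    return pd.DataFrame(
        {
            "case_id": ["c1", "c1", "c2", "c2", "c3", "c3"],
            "tissue": ["tumor", "normal"] * 3,
            "sex": ["M"] * 6,
            "location": ["proximal"] * 6,
            "chip_id": ["chip1"] * 6,
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )


def spearman_oracle(x, y):
    """Pearson correlation of average ranks (the textbook rank formula)."""
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom else np.nan
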