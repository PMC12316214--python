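import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from replimeta import (
    CovariateMeta,
    EffectEstimate,
    ReplicationDataset,
    StudyPair,
    make_case_study_like,
)


def build_dataset(deltas, se_o, se_r=None, covariates=None, covariate_meta=()):
    """Dataset whose pair differences equal ``deltas`` exactly.

    The replication effect is pinned at 0 so that Delta_hat = theta_o;
    ``covariates`` maps names to per-pair value sequences.
    """
    deltas = np.asarray(deltas, dtype=float)
    se_o = np.asarray(se_o, dtype=float)
    se_r = np.full_like(se_o, 1e-6) if se_r is None else np.asarray(se_r, dtype=float)
    covariates = covariates or {}
    pairs = []
    for i, (d, so, sr) in enumerate(zip(deltas, se_o, se_r)):
        covs = {name: vals[i] for name, vals in covariates.items()}
        pairs.append(
            StudyPair(
                pair_id=f"p{i}",
                original=EffectEstimate(float(d), float(so)),
                replication=EffectEstimate(0.0, float(sr)),
                covariates=covs,
            )
        )
    if not covariate_meta and covariates:
        covariate_meta = tuple(CovariateMeta(n, "continuous") for n in covariates)
    return ReplicationDataset(tuple(pairs), tuple(covariate_meta))


@pytest.fixture(scope="session")
def case_like():
    return make_case_study_like(seed=1)


@pytest.fixture()
def three_row_csv(tmp_path):
    path = tmp_path / "pairs.csv"
    path.write_text(
        "pair_id,project,effect_o,se_o,effect_r,se_r\n"
        "a,RPP,0.5,0.1,0.2,0.15\n"
        "b,RPP,0.3,0.2,0.1,0.2\n"
        "c,RPEE,0.4,0.12,0.35,0.1\n"
    )
    return path
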