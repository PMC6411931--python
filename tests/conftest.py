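from __future__ import annotations

import numpy as np
import pytest

from berbp import (
    CandidateSequence,
    LabeledDataset,
    PWM,
    SyntheticSpec,
    compute_background_stats,
    feature_matrix,
    generate_negative_set,
    generate_positive_set,
    train_specific,
)
from berbp.folding import NussinovBackend


@pytest.fixture(scope="session")
def backend():
    return NussinovBackend()


@pytest.fixture(scope="session")
def uniform_pwm():
    return PWM(id="uniform4", freq=np.full((4, 4), 0.25))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_sequence(rng, length, seq_id="s"):
    bases = "".join("ACGU"[i] for i in rng.integers(0, 4, length))
    return CandidateSequence(id=seq_id, bases=bases)


def planted_labeled_dataset(seed, n=60, length=300, k=7, concentration=0.1, backend=None):
    """Featurized planted-motif pos/neg dataset (raw features)."""
    backend = backend or NussinovBackend()
    spec = SyntheticSpec(
        seed=seed, k=k, concentration=concentration, n_pos=n, n_neg=n, seq_length=length
    )
    pwm = spec.resolve_pwm()
    pos, _ = generate_positive_set(spec)
    neg = generate_negative_set(spec)
    Xp, pid, _ = feature_matrix(pos, pwm, backend)
    Xn, nid, _ = feature_matrix(neg, pwm, backend)
    return (
        LabeledDataset(
            X=np.vstack([Xp, Xn]),
            y=np.concatenate([np.ones(n, int), np.zeros(n, int)]),
            ids=pid + nid,
            pwm_id=pwm.id,
        ),
        pwm,
    )


@pytest.fixture(scope="session")
def planted_dataset(backend):
    """Shared separable dataset: 60 pos / 60 neg, strong 7-mer motif."""
    return planted_labeled_dataset(seed=11, backend=backend)


@pytest.fixture(scope="session")
def planted_model(planted_dataset):
    data, _ = planted_dataset
    return train_specific(data, n_trees=200, seed=11)


@pytest.fixture(scope="session")
def standardized_rbps(backend):
    """Four standardized synthetic PWM datasets plus their background stats."""
    from berbp.standardization import z_transform_matrix

    datasets, stats = [], {}
    for seed in (101, 202, 303, 404):
        spec = SyntheticSpec(
            seed=seed, k=7, concentration=0.1, n_pos=50, n_neg=50, seq_length=300
        )
        pwm = spec.resolve_pwm()
        pos, _ = generate_positive_set(spec)
        neg = generate_negative_set(spec)
        bg = generate_negative_set(
            SyntheticSpec(seed=seed + 1000, k=7, n_pos=1, n_neg=50,
                          seq_length=300, pwm=pwm)
        )
        Xp, pid, _ = feature_matrix(pos, pwm, backend)
        Xn, nid, _ = feature_matrix(neg, pwm, backend)
        st = compute_background_stats(bg, pwm, backend, seed=seed + 1000)
        stats[pwm.id] = st
        X = z_transform_matrix(np.vstack([Xp, Xn]), st)
        datasets.append(
            LabeledDataset(
                X=X,
                y=np.concatenate([np.ones(50, int), np.zeros(50, int)]),
                ids=pid + nid,
                pwm_id=pwm.id,
                standardized=True,
                stats_fingerprint=st.fingerprint,
            )
        )
    return datasets, stats
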