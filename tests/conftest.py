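import numpy as np
import pytest

from tildyn.model import ModelConfig, train_model
from tildyn.simulate import (
    CohortConfig,
    generate_cohort,
    manifest_frame,
    small_manifest,
)
from tildyn.tokenizer import fit_vocabulary, tokenize_stay


@pytest.fixture(scope="session")
def driver_manifest():
    return small_manifest(n_static=4, n_dynamic=8, driver_names=["icp_mean"])


@pytest.fixture(scope="session")
def driver_cohort(driver_manifest):
    """Small cohort with one injected escalation driver."""
    cfg = CohortConfig(
        n_patients=160,
        max_day=6,
        driver_effects={"icp_mean": 2.0},
        seed=11,
        variable_manifest=driver_manifest,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted(driver_cohort, driver_manifest):
    """Vocabulary + trained network + tokenised train/test split."""
    _, stays = driver_cohort
    train, test = stays[:120], stays[120:]
    vocab = fit_vocabulary(
        train, manifest_frame(driver_manifest), embed_dim=128, seed=0
    )
    tok = lambda ss: [tokenize_stay(s, vocab) for s in ss]
    config = ModelConfig(
        hidden_dim=16,
        learning_rate=0.02,
        weight_decay=3e-3,
        batch_size=16,
        max_epochs=40,
        patience=8,
        seed=0,
    )
    net, trajectory = train_model(tok(train[:100]), tok(train[100:]), config, vocab)
    return {
        "vocab": vocab,
        "net": net,
        "trajectory": trajectory,
        "train": train,
        "test": test,
        "tok_test": tok(test),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
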