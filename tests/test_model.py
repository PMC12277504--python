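"""Model mechanics: gradients, freeze discipline, determinism, phase contracts."""

import copy

import numpy as np
import pandas as pd
import pytest

from cdld import model as mdl
from cdld import preprocessing as prep
from cdld._nn import MLP, Adam, Embedding

from conftest import SMALL_MODEL, SMALL_SIM, full_run


@pytest.fixture(scope="module")
def trained():
    """One small end-to-end run shared by read-only assertions."""
    return full_run(SMALL_SIM, seed=1, model_config=SMALL_MODEL)


# ---------------------------------------------------------------------------
# numerical gradient check of the composite network


def test_backprop_matches_numerical_gradient():
    rng = np.random.default_rng(0)
    patient = MLP(rng, [9, 6, 4])
    emb = Embedding(rng, 5, 4, scale=0.5)
    head = MLP(rng, [8, 5, 1], sigmoid_out=True)
    X = rng.normal(size=(7, 9))
    codes = rng.integers(0, 5, size=7)
    y = rng.uniform(0, 1, size=7)

    def loss():
        h = np.concatenate([patient.forward(X), emb.forward(codes)], axis=1)
        return float(np.mean((head.forward(h)[:, 0] - y) ** 2))

    base = loss()
    h = np.concatenate([patient.forward(X), emb.forward(codes)], axis=1)
    yhat = head.forward(h)[:, 0]
    g_h = head.backward(((2.0 / len(y)) * (yhat - y))[:, None])
    patient.backward(g_h[:, :4])
    emb.backward(g_h[:, 4:])

    eps = 1e-6
    for params, grads in [
        (patient.params(), patient.grads()),
        (head.params(), head.grads()),
        (emb.params(), emb.grads()),
    ]:
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            for k in (0, flat.size // 2, flat.size - 1):
                orig = flat[k]
                flat[k] = orig + eps
                up = loss()
                flat[k] = orig - eps
                down = loss()
                flat[k] = orig
                num = (up - down) / (2 * eps)
                assert g.reshape(-1)[k] == pytest.approx(num, rel=1e-4, abs=1e-8)
    assert loss() == pytest.approx(base)


def test_adam_moves_toward_minimum():
    p = [np.array([5.0])]
    opt = Adam(p, lr=0.1)
    for _ in range(500):
        opt.step(p, [2.0 * p[0]])  # d/dx of x^2
    assert abs(p[0][0]) < 1e-2


# ---------------------------------------------------------------------------
# init and forward contracts


def test_init_deterministic_and_sized():
    a = mdl.init_model(SMALL_MODEL, n_providers=300)
    b = mdl.init_model(SMALL_MODEL, n_providers=300)
    assert a.provider_emb.table.shape == (301, SMALL_MODEL.latent_dim)
    for pa, pb in zip(a.patient_net.params(), b.patient_net.params()):
        assert np.array_equal(pa, pb)
    assert np.array_equal(a.head.Ws[0], b.head.Ws[0])


def test_forward_on_zero_input_finite_unit_interval():
    model = mdl.init_model(SMALL_MODEL, n_providers=3)
    out = mdl._forward(model, np.zeros((4, 9)), np.zeros(4, dtype=int))
    assert np.all(np.isfinite(out))
    assert np.all((out >= 0) & (out <= 1))


def test_bad_config_rejected():
    with pytest.raises(ValueError):
        mdl.init_model(mdl.ModelConfig(latent_dim=0), 3)
    with pytest.raises(ValueError):
        mdl.init_model(SMALL_MODEL, 0)


# ---------------------------------------------------------------------------
# cyclic training contracts


def test_sub_epochs_zero_is_noop(trained):
    table = trained["table"]
    model = mdl.init_model(SMALL_MODEL.__class__(sub_epochs=0), n_providers=5)
    before = [p.copy() for p in model.patient_net.params()]
    model, curve = mdl.cyclic_train(model, table, table)
    assert curve.empty
    for p, q in zip(model.patient_net.params(), before):
        assert np.array_equal(p, q)


def test_freeze_discipline_bitwise():
    """The frozen discoverer's parameters are bit-identical across a half-step."""
    run = full_run(SMALL_SIM, seed=2, model_config=SMALL_MODEL)
    model = run["model"]
    X, codes, y = prep.feature_matrix(run["table"])
    rng = np.random.default_rng(0)
    frozen = model.provider_emb.table.tobytes()
    mdl._pass(model, X, codes, y, rng, train_patient=True, train_provider=False, context="t")
    assert model.provider_emb.table.tobytes() == frozen
    frozen_patient = [p.tobytes() for p in model.patient_net.params()]
    mdl._pass(model, X, codes, y, rng, train_patient=False, train_provider=True, context="t")
    assert [p.tobytes() for p in model.patient_net.params()] == frozen_patient


def test_training_deterministic_given_seed():
    r1 = full_run(SMALL_SIM, seed=3, model_config=SMALL_MODEL)
    r2 = full_run(SMALL_SIM, seed=3, model_config=SMALL_MODEL)
    pd.testing.assert_frame_equal(r1["curves"][0], r2["curves"][0])
    pd.testing.assert_frame_equal(r1["curves"][1], r2["curves"][1])


def test_curve_log_structure(trained):
    cyclic, synth = trained["curves"]
    cfg = SMALL_MODEL
    assert len(cyclic) == 2 * cfg.epochs  # one row per phase per cyclic iteration
    assert len(synth) == cfg.epochs
    for frame in (cyclic, synth):
        assert (frame["train_mse"] >= 0).all() and (frame["valid_mse"] >= 0).all()
        np.testing.assert_allclose(frame["train_rmse"] ** 2, frame["train_mse"], rtol=1e-9)
        np.testing.assert_allclose(frame["valid_rmse"] ** 2, frame["valid_mse"], rtol=1e-9)
    assert set(cyclic["phase"]) == {"patient_discovery", "provider_discovery"}
    assert set(synth["phase"]) == {"synthesis"}


def test_train_loss_decreases_on_learnable_data():
    cfg = SMALL_SIM.__class__(
        n_patients=300, n_providers=5, n_admissions=300, noise_sd=0.0, provider_effect_sd=0.0, seed=4
    )
    run = full_run(cfg, seed=4, model_config=SMALL_MODEL.__class__(epochs=4, sub_epochs=3, seed=0))
    cyclic = run["curves"][0]
    patient = cyclic[cyclic["phase"] == "patient_discovery"]["train_mse"].to_numpy()
    assert patient[-1] <= patient[0]


def test_synthesis_requires_discovery(trained):
    model = mdl.init_model(SMALL_MODEL, n_providers=3)
    with pytest.raises(RuntimeError):
        mdl.synthesize_predictor(model, trained["table"], trained["table"])


def test_synthesis_freezes_discoverers():
    run = full_run(SMALL_SIM, seed=5, model_config=SMALL_MODEL)
    model = run["model"]
    # re-run the synthesis pass on a fresh copy and verify the discoverers hold
    clone = copy.deepcopy(model)
    before_patient = [p.tobytes() for p in clone.patient_net.params()]
    before_emb = clone.provider_emb.table[: clone.n_providers].tobytes()
    mdl.synthesize_predictor(clone, run["augmented"].frame, run["table"].iloc[run["splits"].valid_rows])
    assert [p.tobytes() for p in clone.patient_net.params()] == before_patient
    assert clone.provider_emb.table[: clone.n_providers].tobytes() == before_emb


# ---------------------------------------------------------------------------
# prediction contracts


def test_predict_requires_final_phase():
    model = mdl.init_model(SMALL_MODEL, n_providers=3)
    with pytest.raises(RuntimeError):
        mdl.predict(model, np.zeros((2, 9)), np.zeros(2, dtype=int))


def test_predict_order_equivariant(trained):
    model, table = trained["model"], trained["table"]
    X, codes, _ = prep.feature_matrix(table)
    perm = np.random.default_rng(0).permutation(len(table))
    assert np.array_equal(mdl.predict(model, X, codes)[perm], mdl.predict(model, X[perm], codes[perm]))


def test_unseen_provider_uses_fallback(trained):
    model, table = trained["model"], trained["table"]
    X, codes, _ = prep.feature_matrix(table)
    out = mdl.predict(model, X[:3], np.full(3, model.n_providers + 99))
    assert np.all(np.isfinite(out))
    fallback = model.provider_emb.table[model.n_providers]
    np.testing.assert_allclose(fallback, model.provider_emb.table[: model.n_providers].mean(axis=0))


def test_feature_width_mismatch_rejected(trained):
    with pytest.raises(ValueError):
        mdl.predict(trained["model"], np.zeros((2, 5)), np.zeros(2, dtype=int))


def test_checkpoint_round_trip(tmp_path, trained):
    model, table = trained["model"], trained["table"]
    mdl.save_model(model, tmp_path / "m.npz")
    back = mdl.load_model(tmp_path / "m.npz")
    np.testing.assert_array_equal(mdl.predict(back, table), mdl.predict(model, table))
    for phase in model.snapshots:
        np.testing.assert_array_equal(
            mdl.predict_phase(back, phase, table), mdl.predict_phase(model, phase, table)
        )


def test_baseline_deterministic_and_provider_free():
    run1 = full_run(SMALL_SIM, seed=6, model_config=SMALL_MODEL, baseline=True)
    run2 = full_run(SMALL_SIM, seed=6, model_config=SMALL_MODEL, baseline=True)
    pd.testing.assert_frame_equal(run1["baseline_report"].table, run2["baseline_report"].table)
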