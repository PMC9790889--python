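"""Network core: architecture shapes/counts, LSTM vs a direct transcription
oracle, fuzzy-block algebra, centroid refresh, and gradient checks."""

import numpy as np
import pytest

from fcrnet.network import (FNBLayer, LSTMLayer, LSTMParams, LSTMState,
                            NetworkConfig, assemble_fcrnet, build_compact_cnn,
                            count_trainable_parameters, fnb_forward,
                            fnb_membership, fuzzy_cmeans, lstm_step, sigmoid,
                            update_fnb_centroids)
from fcrnet.network.layers import softmax_cross_entropy

TABLE_CONFIG = NetworkConfig(input_shape=(22, 288))


# --- compact CNN architecture ---------------------------------------------

def test_reference_architecture_shapes():
    """Every intermediate shape of the (22, 288) reference configuration."""
    model = build_compact_cnn(TABLE_CONFIG)
    shapes = dict(model.layer_shapes())
    assert shapes["temporal_conv"] == (8, 22, 288)
    assert shapes["depthwise_conv"] == (16, 1, 288)
    assert shapes["avgpool_1"] == (16, 1, 72)
    assert shapes["separable_conv"] == (8, 1, 72)
    assert shapes["avgpool_2"] == (8, 1, 9)
    assert shapes["flatten"] == (72,)
    assert model.config.flatten_width == 72


def test_reference_architecture_parameter_counts():
    counts = count_trainable_parameters(build_compact_cnn(TABLE_CONFIG))
    assert counts["temporal_conv"] == 512
    assert counts["batchnorm_1"] == 16
    assert counts["depthwise_conv"] == 352
    assert counts["batchnorm_2"] == 32
    assert counts["separable_conv"] == 384
    assert counts["batchnorm_3"] == 16
    assert counts["dense"] == (72 + 1) * 4


def test_temporal_conv_count_formula():
    cfg = NetworkConfig(input_shape=(22, 288), F1=4)
    counts = count_trainable_parameters(build_compact_cnn(cfg))
    assert counts["temporal_conv"] == 4 * 64


def test_single_electrode_configuration_runs():
    cfg = NetworkConfig(input_shape=(1, 288))
    model = build_compact_cnn(cfg)
    probs = model.predict_proba(np.random.default_rng(0).standard_normal((3, 1, 288)))
    assert probs.shape == (3, 4)
    assert np.allclose(probs.sum(axis=1), 1.0)


def test_too_short_epoch_rejected():
    with pytest.raises(ValueError, match="kernel"):
        NetworkConfig(input_shape=(22, 32)).validate()


# --- LSTM ------------------------------------------------------------------

def reference_lstm(xs, params, mode):
    """Direct per-step transcription of the gate equations (test oracle)."""
    H = params.hidden
    h = np.zeros(H)
    c = np.zeros(H)
    for x in xs:
        i = 1 / (1 + np.exp(-(params.W["i"] @ x + params.U["i"] @ h + params.b["i"])))
        f = 1 / (1 + np.exp(-(params.W["f"] @ x + params.U["f"] @ h + params.b["f"])))
        o = 1 / (1 + np.exp(-(params.W["o"] @ x + params.U["o"] @ h + params.b["o"])))
        if mode == "tanh_standard":
            cand = np.tanh(params.W["c"] @ x + params.U["c"] @ h + params.b["c"])
        else:
            cand = params.W["c"] @ x + params.U["i"] @ h + params.b["c"]
        c = f * c + i * cand
        h = o * np.tanh(c) if mode == "tanh_standard" else o * c
    return h, c


def test_lstm_zero_everything():
    params = LSTMParams.zeros(3, 2)
    state = lstm_step(np.zeros(3), LSTMState(np.zeros(2), np.zeros(2)), params)
    assert np.allclose(state.h, 0.0)
    assert np.allclose(state.c, 0.0)


def test_lstm_literal_mode_hand_case():
    """Zero parameters, c_{t-1}=1: every gate is sigmoid(0)=1/2, the linear
    candidate is 0, so c_t = 1/2 and h_t = o*c_t = 1/4."""
    params = LSTMParams.zeros(1, 1)
    state = lstm_step(np.zeros(1), LSTMState(np.zeros(1), np.ones(1)), params,
                      mode="linear_literal")
    assert np.allclose(state.c, 0.5)
    assert np.allclose(state.h, 0.25)


@pytest.mark.parametrize("mode", ["tanh_standard", "linear_literal"])
def test_lstm_matches_reference_over_20_steps(mode):
    rng = np.random.default_rng(8)
    params = LSTMParams.random(4, 6, rng, scale=0.4)
    xs = rng.standard_normal((20, 4)) * 0.5
    h_ref, c_ref = reference_lstm(xs, params, mode)
    state = LSTMState(np.zeros(6), np.zeros(6))
    for x in xs:
        state = lstm_step(x, state, params, mode=mode)
    assert np.max(np.abs(state.h - h_ref)) < 1e-6
    assert np.max(np.abs(state.c - c_ref)) < 1e-6
    # the unrolled batched layer agrees too
    layer = LSTMLayer(4, 6, np.random.default_rng(0), mode=mode)
    for g in ("i", "f", "o", "c"):
        layer.Wp[g].value[...] = params.W[g]
        layer.Up[g].value[...] = params.U[g]
        layer.bp[g].value[...] = params.b[g]
    h_layer = layer.forward(xs[None, :, :])
    assert np.max(np.abs(h_layer[0] - h_ref)) < 1e-6


def test_lstm_gates_bounded(rng):
    params = LSTMParams.random(3, 4, rng)
    x = rng.standard_normal(3)
    i = sigmoid(params.W["i"] @ x + params.b["i"])
    assert np.all((i > 0) & (i < 1))


# --- fuzzy neural block ----------------------------------------------------

def test_membership_at_centroid_is_one():
    v = np.array([0.3, -1.2])
    assert np.allclose(fnb_membership(v, v, np.ones(2)), 1.0)


def test_membership_at_two_alpha():
    """|v - c| = 2*alpha gives exp(-1/4 * 4) = e^-1."""
    mu = fnb_membership(np.array([2.0]), np.array([0.0]), np.array([1.0]))
    assert np.allclose(mu, np.exp(-1.0))
    assert abs(mu[0] - 0.36788) < 1e-4


def test_membership_large_alpha_limit():
    mu = fnb_membership(np.array([5.0]), np.array([-5.0]), np.array([1e6]))
    assert np.allclose(mu, 1.0, atol=1e-9)


def test_membership_requires_positive_alpha():
    with pytest.raises(ValueError):
        fnb_membership(np.zeros(2), np.zeros(2), np.array([1.0, 0.0]))


def test_fnb_identical_centroids_uniform():
    out = fnb_forward(np.array([1.0, 2.0]), np.zeros((5, 2)), np.ones(2))
    assert np.allclose(out, 0.2)


def test_fnb_hand_case_two_rules():
    """d=1, v=0, centroids (0, 2), alpha=1: raw (1, e^-1) -> (0.7311, 0.2689)."""
    out = fnb_forward(np.array([0.0]), np.array([[0.0], [2.0]]), np.ones(1))
    expected = np.array([1.0, np.exp(-1.0)])
    expected /= expected.sum()
    assert np.allclose(out, expected, atol=1e-4)
    assert abs(out[0] - 0.7311) < 1e-3


def test_fnb_sums_to_one_even_under_underflow(rng):
    """Huge distances underflow any raw product; the log-domain path still
    returns a clean distribution."""
    d = 3000
    v = rng.standard_normal(d)
    centroids = rng.standard_normal((4, d)) * 50.0
    out = fnb_forward(v, centroids, np.full(d, 0.1))
    assert np.all(np.isfinite(out))
    assert abs(out.sum() - 1.0) < 1e-9


def test_fnb_rule_permutation_equivariance(rng):
    v = rng.standard_normal(5)
    centroids = rng.standard_normal((4, 5))
    alpha = np.abs(rng.standard_normal(5)) + 0.5
    out = fnb_forward(v, centroids, alpha)
    perm = np.array([2, 0, 3, 1])
    out_p = fnb_forward(v, centroids[perm], alpha)
    assert np.allclose(out_p, out[perm])


# --- centroid refresh ------------------------------------------------------

def test_initial_centroids_are_zero():
    c = update_fnb_centroids(np.ones((10, 3)), k=4, epoch_index=0)
    assert c.shape == (4, 3)
    assert np.allclose(c, 0.0)


def test_empty_history_after_first_epoch_rejected():
    with pytest.raises(ValueError):
        update_fnb_centroids(np.empty((0, 3)), k=2, epoch_index=1)


def test_cmeans_recovers_separated_clouds(rng):
    a = rng.normal(0.0, 0.1, size=(60, 2))
    b = rng.normal(5.0, 0.1, size=(60, 2)) + np.array([0.0, 3.0])
    data = np.vstack([a, b])
    centroids = update_fnb_centroids(data, k=2, epoch_index=3, seed=1)
    means = np.array([a.mean(axis=0), b.mean(axis=0)])
    # match clusters to clouds by nearest mean
    d = np.linalg.norm(centroids[:, None, :] - means[None], axis=-1)
    assert d.min(axis=1).max() < 0.1


def test_cmeans_single_cluster_is_weighted_mean(rng):
    data = rng.standard_normal((40, 3))
    c = fuzzy_cmeans(data, k=1, seed=0)
    assert np.allclose(c[0], data.mean(axis=0), atol=1e-6)


def test_cmeans_deterministic(rng):
    data = rng.standard_normal((50, 4))
    assert np.allclose(fuzzy_cmeans(data, 3, seed=5), fuzzy_cmeans(data, 3, seed=5))


# --- assembly --------------------------------------------------------------

SMALL = NetworkConfig(input_shape=(4, 96), F1=3, D=2, F2=4, temporal_kernel=16,
                      separable_kernel=8, lstm_units=5, fc_units=4,
                      fnb_rules=3, dropout=0.0)


def test_forward_pass_is_probability_vector(rng):
    model = assemble_fcrnet(SMALL, seed=1)
    probs = model.predict_proba(rng.standard_normal((2, 4, 96)))
    assert probs.shape == (2, 4)
    assert np.allclose(probs.sum(axis=1), 1.0)
    assert np.all(probs >= 0)


def test_fnb_toggle_changes_only_head_counts():
    with_fnb = count_trainable_parameters(assemble_fcrnet(SMALL, seed=1))
    without = count_trainable_parameters(
        assemble_fcrnet(SMALL.__class__(**{**SMALL.__dict__,
                                           "fnb_enabled": False}), seed=1))
    for layer in ("temporal_conv", "depthwise_conv", "separable_conv", "lstm",
                  "fc_branch"):
        assert with_fnb[layer] == without[layer]
    assert with_fnb["head"] != without["head"]
    assert "fnb" in with_fnb and "fnb" not in without


def test_inference_is_deterministic(rng):
    model = assemble_fcrnet(SMALL, seed=3)
    x = rng.standard_normal((3, 4, 96))
    assert np.array_equal(model.predict_proba(x), model.predict_proba(x))


def test_seeded_build_is_reproducible(rng):
    x = rng.standard_normal((2, 4, 96))
    a = assemble_fcrnet(SMALL, seed=9).predict_proba(x)
    b = assemble_fcrnet(SMALL, seed=9).predict_proba(x)
    assert np.array_equal(a, b)


def test_sum_merge_head(rng):
    cfg = NetworkConfig(**{**SMALL.__dict__, "head_merge": "sum",
                           "fc_units": 3, "fnb_rules": 3})
    probs = assemble_fcrnet(cfg, seed=2).predict_proba(
        rng.standard_normal((2, 4, 96)))
    assert np.allclose(probs.sum(axis=1), 1.0)
    with pytest.raises(ValueError, match="sum merge"):
        assemble_fcrnet(NetworkConfig(**{**SMALL.__dict__,
                                         "head_merge": "sum"}), seed=2)


def test_envelope_input_mode_feeds_network(rng):
    """MSFBCSP envelope rows form a rectangular epoch the network accepts."""
    from fcrnet import (FilterBankSpec, SimulationConfig, TimeStepSpec,
                        apply_filter_bank, design_filter_bank, fit_msfbcsp,
                        generate_session, segment_time_steps, envelope_pipeline)
    from fcrnet.csp import projected_blocks

    rec = generate_session(SimulationConfig(trials_per_class=3, n_channels=5,
                                            trial_duration=2.0, seed=31))
    bank = design_filter_bank(FilterBankSpec(bands=((8.0, 12.0),
                                                    (20.0, 24.0))), rec.fs)
    blocks = segment_time_steps(apply_filter_bank(rec, bank),
                                TimeStepSpec(intervals=((0.0, 2.0),)), rec.fs,
                                bands=bank.spec.bands)
    fitted = fit_msfbcsp(blocks, rec.labels, m=1)
    env = envelope_pipeline(projected_blocks(blocks, fitted), rec.fs,
                            n_points=40)
    x = env.as_epochs()
    cfg = NetworkConfig(input_shape=(x.shape[1], 40), F1=3, D=1, F2=3,
                        temporal_kernel=16, separable_kernel=8, lstm_units=4,
                        fc_units=3, fnb_rules=2, dropout=0.0,
                        input_mode="envelope")
    probs = assemble_fcrnet(cfg, seed=0).predict_proba(x)
    assert probs.shape == (rec.n_trials, 4)
    assert np.allclose(probs.sum(axis=1), 1.0)


def test_gradient_check_alpha_and_centroids(rng):
    """Analytic gradients of the loss w.r.t. the fuzzy block's scale vector
    and centroids match central finite differences within 1e-4 relative."""
    model = assemble_fcrnet(SMALL, seed=1)
    model.fnb.set_centroids(rng.standard_normal((3, 5)) * 0.3)
    model.fnb.alpha.value[:] = rng.uniform(0.5, 1.5, 5)
    x = rng.standard_normal((3, 4, 96))
    y = np.array([0, 1, 2])

    def loss():
        logits = model.forward_logits(x, training=True,
                                      rng=np.random.default_rng(0))
        return softmax_cross_entropy(logits, y)[0]

    model.zero_grads()
    logits = model.forward_logits(x, training=True,
                                  rng=np.random.default_rng(0))
    _, dlogits, _ = softmax_cross_entropy(logits, y)
    model.backward_logits(dlogits)
    eps = 1e-6
    for param in (model.fnb.alpha, model.fnb.centroids):
        flat, grad = param.value.ravel(), param.grad.ravel()
        for i in range(flat.size):
            old = flat[i]
            flat[i] = old + eps
            lp = loss()
            flat[i] = old - eps
            lm = loss()
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            denom = max(abs(num) + abs(grad[i]), 1e-8)
            assert abs(num - grad[i]) / denom < 1e-4, param.name
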