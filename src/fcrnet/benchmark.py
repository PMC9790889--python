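"""Reference protocols: the fixed desk-scale checks of the whole pipeline.

Each function recomputes one verifiable quantity from scratch by running the
package — architecture parameter counts, the kappa/accuracy identity points,
CSP algebra against a whiten-then-diagonalize reference, envelope identities,
fuzzy-block values, and the scaled-down end-to-end cross-validation on
synthetic sessions.  They are used by the acceptance machinery and are handy
as a quick self-test of an installation.

Problem sizes are deliberately desk-scale: the end-to-end run uses one
default-shaped session (288 trials, 22 channels) with epochs decimated to
125 Hz and a dozen training epochs per fold; the SNR sweep uses 36 trials per
class with a single stratified split per repetition.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

from .csp import solve_csp, fit_msfbcsp
from .envelope import analytic_envelope, lowpass_resample
from .filterbank import (FilterBankSpec, TimeStepSpec, apply_filter_bank,
                         design_filter_bank, segment_time_steps)
from .network import (LSTMParams, LSTMState, NetworkConfig, assemble_fcrnet,
                      build_compact_cnn, count_trainable_parameters,
                      fnb_forward, fnb_membership, lstm_step,
                      update_fnb_centroids)
from .network.layers import softmax_cross_entropy
from .simulate import SimulationConfig, generate_session, \
    generate_session_with_truth
from .training import TrainingConfig, cohen_kappa, cross_validate, train_model
from .training import decimate_epochs
from .tuning import ParameterSpec, SearchSpace, bayesian_optimize, \
    coordinate_descent

__all__ = [
    "architecture_report", "kappa_reference_points", "csp_oracle_errors",
    "csp_recovery_correlations", "envelope_identities", "fnb_identities",
    "fnb_gradient_check", "lstm_identities", "end_to_end_cv",
    "shuffled_label_control", "snr_accuracy_curve", "tuner_checks",
]


def architecture_report() -> dict:
    """Parameter counts and flatten width of the (22, 288) reference CNN."""
    model = build_compact_cnn(NetworkConfig(input_shape=(22, 288)))
    counts = count_trainable_parameters(model)
    return {
        "temporal_conv_params": counts["temporal_conv"],
        "depthwise_conv_params": counts["depthwise_conv"],
        "separable_conv_params": counts["separable_conv"],
        "flatten_width": model.config.flatten_width,
    }


def _balanced_confusion(accuracy: float, n_per_class: int = 750,
                        k: int = 4) -> np.ndarray:
    diag = accuracy * n_per_class
    off = (n_per_class - diag) / (k - 1)
    return np.full((k, k), off) + np.eye(k) * (diag - off)


def kappa_reference_points() -> dict:
    """Kappa at the two benchmark accuracy points (balanced 4-class)."""
    return {
        "kappa_at_88pct": cohen_kappa(_balanced_confusion(0.88)),
        "kappa_at_93_2pct": cohen_kappa(_balanced_confusion(0.932)),
    }


def _whiten_then_eigh_reference(Ri, Rj):
    """Independent route: whiten the composite, then ordinary eigh."""
    comp = Ri + Rj
    evals, evecs = np.linalg.eigh(comp)
    white = evecs @ np.diag(evals ** -0.5) @ evecs.T
    s = white @ Ri @ white.T
    d, v = np.linalg.eigh(0.5 * (s + s.T))
    order = np.argsort(d)[::-1]
    return (white.T @ v[:, order]).T, d[order]


def csp_oracle_errors(n_pairs: int = 100, seed: int = 0) -> dict:
    """Worst-case deviation from the reference solver over random SPD pairs,
    plus the eigenvalue-complementarity defect."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    max_comp = 0.0
    for _ in range(n_pairs):
        n = int(rng.integers(3, 9))
        a = rng.standard_normal((n, n))
        b = rng.standard_normal((n, n))
        Ri = a @ a.T + 0.1 * n * np.eye(n)
        Rj = b @ b.T + 0.1 * n * np.eye(n)
        sol = solve_csp(Ri, Rj, shrinkage=0.0)
        W_ref, D_ref = _whiten_then_eigh_reference(Ri, Rj)
        max_err = max(max_err, np.max(np.abs(sol.D - D_ref)))
        for row, ref in zip(sol.W, W_ref):
            max_err = max(max_err, min(np.abs(row - ref).max(),
                                       np.abs(row + ref).max()))
        lj = solve_csp(Rj, Ri, shrinkage=0.0).D
        max_comp = max(max_comp, np.max(np.abs(
            np.sort(sol.D) + np.sort(lj)[::-1] - 1.0)))
    return {"solver_max_abs_error": float(max_err),
            "complementarity_max_abs_error": float(max_comp)}


def csp_recovery_correlations(seeds=(101, 102, 103, 104, 105),
                              snr_db: float = 6.0) -> list:
    """|corr| between the mu-band class-0 top filter and the generator's true
    unmixing direction, one value per seed."""
    out = []
    for seed in seeds:
        rec, truth = generate_session_with_truth(
            SimulationConfig(snr_db=snr_db, seed=int(seed)))
        bank = design_filter_bank(FilterBankSpec(), rec.fs)
        band = apply_filter_bank(rec, bank)
        blocks = segment_time_steps(band, TimeStepSpec(intervals=((0.0, 4.0),)),
                                    rec.fs, bands=bank.spec.bands)
        fitted = fit_msfbcsp(blocks, rec.labels, m=2)
        w = fitted.filters[(1, 0, (0, "rest"))][0]
        out.append(float(abs(np.corrcoef(w, truth.unmixing_matrix[0])[0, 1])))
    return out


def envelope_identities() -> dict:
    """Sinusoid-envelope error and the 4 s -> 10 Hz -> 40-point example."""
    fs = 250.0
    t = np.arange(int(fs)) / fs
    env = analytic_envelope(2.0 * np.cos(2 * np.pi * 10.0 * t))
    sin_err = float(np.max(np.abs(env[50:-50] - 2.0)))
    resampled = lowpass_resample(np.full(1000, 1.0), fs, 40)
    return {
        "sinusoid_envelope_max_interior_error": sin_err,
        "resampled_points_from_4s_window": int(resampled.shape[-1]),
        "effective_rate_hz": 40 / (1000 / fs),
    }


def fnb_identities(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(6)
    mu_center = fnb_membership(v, v, np.ones(6))
    mu_2a = fnb_membership(np.array([2.0]), np.array([0.0]), np.array([1.0]))
    out = fnb_forward(rng.standard_normal(6), rng.standard_normal((4, 6)),
                      np.abs(rng.standard_normal(6)) + 0.5)
    c0 = update_fnb_centroids(np.ones((10, 6)), k=3, epoch_index=0)
    return {
        "membership_at_centroid": float(mu_center.min()),
        "membership_at_two_alpha": float(mu_2a[0]),
        "rule_output_sum_error": float(abs(out.sum() - 1.0)),
        "first_epoch_centroid_max_abs": float(np.abs(c0).max()),
    }


def fnb_gradient_check(seed: int = 0) -> float:
    """Max relative error, analytic vs central finite differences, for the
    loss gradients w.r.t. the fuzzy block's alpha and centroids (3 samples)."""
    cfg = NetworkConfig(input_shape=(4, 96), F1=3, D=2, F2=4,
                        temporal_kernel=16, separable_kernel=8, lstm_units=5,
                        fc_units=4, fnb_rules=3, dropout=0.0)
    rng = np.random.default_rng(seed)
    model = assemble_fcrnet(cfg, seed=seed + 1)
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
    eps, worst = 1e-6, 0.0
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
            worst = max(worst, abs(num - grad[i])
                        / max(abs(num) + abs(grad[i]), 1e-8))
    return float(worst)


def lstm_identities() -> dict:
    """The zero-parameter unit-cell case of the literal gate equations."""
    params = LSTMParams.zeros(1, 1)
    state = lstm_step(np.zeros(1), LSTMState(np.zeros(1), np.ones(1)), params,
                      mode="linear_literal")
    return {"literal_cell_state": float(state.c[0]),
            "literal_hidden_state": float(state.h[0])}


# --- end-to-end -----------------------------------------------------------

E2E_NET = NetworkConfig(input_shape=(22, 500), dropout=0.25)
E2E_TRAIN = TrainingConfig(epochs=12, batch_size=32, learning_rate=3e-3)
DECIMATE = 2


def _prepare(rec):
    x = decimate_epochs(rec.signals, DECIMATE).astype(np.float32)
    return x, rec.labels


def end_to_end_cv(seed: int = 1, k: int = 10):
    """Stratified k-fold CV of the full model on one default 10 dB session."""
    rec = generate_session(SimulationConfig(snr_db=10.0, seed=seed))
    x, y = _prepare(rec)
    return cross_validate(
        (x, y),
        lambda s: assemble_fcrnet(E2E_NET, seed=s, dtype=np.float32),
        k=k, seed=seed, training=E2E_TRAIN,
    )


def shuffled_label_control(seed: int = 1, k: int = 3) -> float:
    """Held-out accuracy with permuted labels (should sit at chance)."""
    rec = generate_session(SimulationConfig(snr_db=10.0, seed=seed))
    x, y = _prepare(rec)
    y = np.random.default_rng(seed).permutation(y)
    report = cross_validate(
        (x, y),
        lambda s: assemble_fcrnet(E2E_NET, seed=s, dtype=np.float32),
        k=k, seed=seed, training=E2E_TRAIN,
    )
    return report.mean_accuracy


def snr_accuracy_curve(seed: int = 1, snrs=(0.0, 6.0, 12.0),
                       n_reps: int = 3) -> dict:
    """Mean held-out accuracy per SNR (36 trials/class, one split per rep)."""
    out = {}
    for snr in snrs:
        accs = []
        for rep in range(n_reps):
            s = seed + rep
            rec = generate_session(SimulationConfig(trials_per_class=36,
                                                    snr_db=snr, seed=s))
            x, y = _prepare(rec)
            x = (x - x.mean(axis=(0, 2), keepdims=True)) / x.std(
                axis=(0, 2), keepdims=True)
            tr, te = train_test_split(np.arange(len(y)), test_size=48,
                                      stratify=y, random_state=s)
            model = assemble_fcrnet(E2E_NET, seed=s, dtype=np.float32)
            train_model(model, x[tr], y[tr],
                        TrainingConfig(epochs=10, batch_size=32,
                                       learning_rate=3e-3), seed=s)
            accs.append(float(np.mean(model.predict(x[te]) == y[te])))
        out[snr] = float(np.mean(accs))
    return out


def tuner_checks(seed: int = 0) -> dict:
    """Coordinate descent on the separable integer quadratic; BO on a 1-D
    quadratic over [0, 10]."""
    grid = SearchSpace.from_dict({"F1": [4, 8, 16], "D": [1, 2, 4],
                                  "F2": [4, 8, 16]})

    def quadratic(cfg):
        return -((cfg["F1"] - 8) ** 2 + (cfg["D"] - 2) ** 2
                 + (cfg["F2"] - 8) ** 2)

    cd = coordinate_descent(grid, quadratic, init={"F1": 4, "D": 1, "F2": 4},
                            n_sweeps=1)
    one_d = SearchSpace((ParameterSpec("x", "continuous", low=0.0,
                                       high=10.0),))
    bo = bayesian_optimize(one_d, lambda c: -(c["x"] - 5.0) ** 2, n_iter=20,
                           n_init=5, seed=seed)
    return {
        "cd_found_global_optimum": float(cd.best_config ==
                                         {"F1": 8, "D": 2, "F2": 8}),
        "bo_abs_error_1d_quadratic": float(abs(bo.best_config["x"] - 5.0)),
    }
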