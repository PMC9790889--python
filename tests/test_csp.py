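"""CSP algebra against independent oracles, and recovery on generator data."""

import numpy as np
import pytest

from fcrnet import (FilterBankSpec, SimulationConfig, TimeStepSpec,
                    apply_filter_bank, design_filter_bank, fit_msfbcsp,
                    generate_session_with_truth, normalized_covariance,
                    project, segment_time_steps, select_filters, solve_csp,
                    transform_msfbcsp)
from fcrnet.csp import DegenerateTrialError


def brute_force_csp(Ri, Rj):
    """Oracle: whiten the composite with an ordinary symmetric
    eigendecomposition, then diagonalize the whitened Ri."""
    comp = Ri + Rj
    evals, evecs = np.linalg.eigh(comp)
    white = evecs @ np.diag(evals ** -0.5) @ evecs.T
    s = white @ Ri @ white.T
    d, v = np.linalg.eigh(0.5 * (s + s.T))
    order = np.argsort(d)[::-1]
    return (white.T @ v[:, order]).T, d[order]


def random_spd(rng, n):
    a = rng.standard_normal((n, n))
    return a @ a.T + n * np.eye(n) * 0.1


# --- normalized covariance -------------------------------------------------

def test_covariance_identity_trial():
    cov = normalized_covariance(np.eye(2)[None])
    assert np.allclose(cov.matrix, np.eye(2) / 2.0)
    assert np.isclose(np.trace(cov.matrix), 1.0)


def test_covariance_hand_case():
    x = np.array([[[1.0, 1.0], [0.0, 0.0]]])
    cov = normalized_covariance(x)
    assert np.allclose(cov.matrix, [[1.0, 0.0], [0.0, 0.0]])


def test_covariance_average_of_copies(rng):
    x = rng.standard_normal((1, 4, 50))
    one = normalized_covariance(x).matrix
    many = normalized_covariance(np.repeat(x, 5, axis=0)).matrix
    assert np.allclose(one, many)


def test_covariance_invariants(rng):
    x = rng.standard_normal((6, 5, 100))
    m = normalized_covariance(x).matrix
    assert np.allclose(m, m.T, atol=1e-10)
    assert abs(np.trace(m) - 1.0) < 1e-8
    assert np.linalg.eigvalsh(m).min() >= -1e-10


def test_zero_power_trial_rejected():
    with pytest.raises(DegenerateTrialError, match="1"):
        normalized_covariance(np.stack([np.ones((2, 4)), np.zeros((2, 4))]))


# --- solve_csp -------------------------------------------------------------

def test_symmetric_classes_give_half_eigenvalues():
    sol = solve_csp(0.5 * np.eye(3), 0.5 * np.eye(3), shrinkage=0.0)
    assert np.allclose(sol.D, 0.5)


def test_diagonal_pair_closed_form():
    sol = solve_csp(np.diag([0.8, 0.2]), np.diag([0.2, 0.8]), shrinkage=0.0)
    assert np.allclose(sol.D, [0.8, 0.2], atol=1e-12)
    # filters along coordinate axes (up to the composite scaling)
    w = sol.W / np.abs(sol.W).max(axis=1, keepdims=True)
    assert np.allclose(np.abs(w), np.eye(2), atol=1e-10)


def test_matches_brute_force_oracle_on_100_pairs():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(3, 9)
        Ri, Rj = random_spd(rng, n), random_spd(rng, n)
        sol = solve_csp(Ri, Rj, shrinkage=0.0)
        W_ref, D_ref = brute_force_csp(Ri, Rj)
        assert np.allclose(sol.D, D_ref, atol=1e-8)
        for row, ref in zip(sol.W, W_ref):   # rows match up to sign
            assert min(np.abs(row - ref).max(),
                       np.abs(row + ref).max()) < 1e-8


def test_eigenvalue_complementarity(rng):
    Ri, Rj = random_spd(rng, 6), random_spd(rng, 6)
    li = solve_csp(Ri, Rj, shrinkage=0.0).D
    lj = solve_csp(Rj, Ri, shrinkage=0.0).D
    assert np.allclose(np.sort(li) + np.sort(lj)[::-1], 1.0, atol=1e-8)


def test_composite_normalization_and_rayleigh(rng):
    Ri, Rj = random_spd(rng, 5), random_spd(rng, 5)
    sol = solve_csp(Ri, Rj, shrinkage=0.0)
    assert np.allclose(sol.W @ (Ri + Rj) @ sol.W.T, np.eye(5), atol=1e-8)
    for w, lam in zip(sol.W, sol.D):
        ratio = (w @ Ri @ w) / (w @ Rj @ w)
        assert np.isclose(ratio, lam / (1 - lam), rtol=1e-6)


def test_scale_invariance_of_filters(rng):
    Ri, Rj = random_spd(rng, 4), random_spd(rng, 4)
    a = solve_csp(Ri, Rj, shrinkage=0.0)
    b = solve_csp(7.0 * Ri, 7.0 * Rj, shrinkage=0.0)
    assert np.allclose(a.D, b.D, atol=1e-10)
    # same filters up to the composite scaling (and the fixed sign rule)
    assert np.allclose(np.abs(a.W), np.abs(b.W) * np.sqrt(7.0), atol=1e-8)


# --- selection and projection ---------------------------------------------

def test_select_filters_ends():
    sol = solve_csp(np.diag([0.9, 0.5, 0.1]), np.diag([0.1, 0.5, 0.9]),
                    shrinkage=0.0)
    block = select_filters(sol, 1)
    assert block.shape == (2, 3)
    assert np.allclose(block[0], sol.W[0])
    assert np.allclose(block[1], sol.W[-1])
    with pytest.raises(ValueError):
        select_filters(sol, 2)


def test_project_identity_and_linearity(rng):
    x = rng.standard_normal((5, 200))
    eye_rows = np.eye(5)[[0, 3]]
    assert np.array_equal(project(x, eye_rows), x[[0, 3]])
    w = rng.standard_normal((2, 5))
    assert np.allclose(project(3.0 * x, w), 3.0 * project(x, w))
    with pytest.raises(ValueError, match="channels"):
        project(x, rng.standard_normal((2, 4)))


def test_top_component_beats_every_raw_channel():
    """CSP's first component has a larger between-class variance ratio than
    any single electrode (exhaustive comparison on generated data)."""
    cfg = SimulationConfig(n_classes=2, trials_per_class=40, n_channels=8,
                           trial_duration=2.0,
                           source_bands=((8.0, 12.0), (20.0, 24.0)),
                           snr_db=6.0, seed=21)
    rec, _ = generate_session_with_truth(cfg)
    x, y = rec.signals, rec.labels
    Ri = normalized_covariance(x[y == 0])
    Rj = normalized_covariance(x[y == 1])
    w = select_filters(solve_csp(Ri, Rj), m=1)[:1]
    proj = project(x, w)[:, 0, :]
    ratio_csp = proj[y == 0].var(axis=-1).mean() / proj[y == 1].var(axis=-1).mean()
    chan_ratios = (x[y == 0].var(axis=-1).mean(axis=0)
                   / x[y == 1].var(axis=-1).mean(axis=0))
    assert ratio_csp > chan_ratios.max()


# --- MSFBCSP ---------------------------------------------------------------

def _msfbcsp_blocks(rec, intervals=((0.0, 2.0),)):
    bank = design_filter_bank(FilterBankSpec(), rec.fs)
    band = apply_filter_bank(rec, bank)
    return segment_time_steps(band, TimeStepSpec(intervals=intervals), rec.fs,
                              bands=bank.spec.bands)


def test_filter_count_for_default_configuration(session_with_truth):
    rec, _ = session_with_truth
    bank = design_filter_bank(FilterBankSpec(), rec.fs)
    band = apply_filter_bank(rec, bank)
    steps = TimeStepSpec(intervals=((0.0, 1.0), (1.0, 2.0), (2.0, 3.0),
                                    (3.0, 4.0), (0.0, 2.0), (2.0, 4.0),
                                    (0.0, 4.0)))
    blocks = segment_time_steps(band, steps, rec.fs, bands=bank.spec.bands)
    fitted = fit_msfbcsp(blocks, rec.labels, m=2, scheme="one-vs-rest")
    assert len(fitted.filters) == 9 * 7 * 4
    assert all(f.shape == (4, 22) for f in fitted.filters.values())
    assert fitted.n_filters_total == 1008


def test_pairwise_two_class_single_contrast():
    cfg = SimulationConfig(n_classes=2, trials_per_class=10, n_channels=6,
                           trial_duration=1.0,
                           source_bands=((8, 12), (20, 24)), seed=3)
    rec, _ = generate_session_with_truth(cfg)
    blocks = _msfbcsp_blocks(rec, intervals=((0.0, 1.0),))
    fitted = fit_msfbcsp(blocks, rec.labels, m=2, scheme="pairwise")
    assert fitted.contrasts == ((0, 1),)


def test_missing_class_rejected():
    cfg = SimulationConfig(trials_per_class=4, n_channels=6,
                           trial_duration=1.0, seed=3)
    rec, _ = generate_session_with_truth(cfg)
    blocks = _msfbcsp_blocks(rec, intervals=((0.0, 1.0),))
    with pytest.raises(ValueError):
        fit_msfbcsp(blocks, np.zeros_like(rec.labels), m=2)


@pytest.mark.parametrize("seed", [101, 102, 103, 104, 105])
def test_unmixing_direction_recovery(seed):
    """The mu-band class-0 contrast's top filter aligns with the generator's
    true unmixing direction (|corr| >= 0.95) at 6 dB."""
    cfg = SimulationConfig(snr_db=6.0, seed=seed)
    rec, truth = generate_session_with_truth(cfg)
    blocks = _msfbcsp_blocks(rec, intervals=((0.0, 4.0),))
    fitted = fit_msfbcsp(blocks, rec.labels, m=2)
    w = fitted.filters[(1, 0, (0, "rest"))][0]       # band 8-12, top filter
    target = truth.unmixing_matrix[0]
    corr = np.corrcoef(w, target)[0, 1]
    assert abs(corr) >= 0.95


def test_variance_feature_shape_and_scaling(session_with_truth):
    rec, _ = session_with_truth
    sub = rec.signals[:40]
    labels = rec.labels[:40]
    rec40 = type(rec)(signals=sub, labels=labels, fs=rec.fs,
                      channel_names=rec.channel_names,
                      class_names=rec.class_names)
    blocks = _msfbcsp_blocks(rec40, intervals=((0.0, 1.0), (1.0, 2.0)))
    fitted = fit_msfbcsp(blocks, labels, m=2)
    feats = transform_msfbcsp(blocks, fitted)
    assert feats.shape == (40, 9, 2, 4, 4)
    assert np.all(feats >= 0.0)
    doubled = segment_time_steps(
        2.0 * apply_filter_bank(rec40, design_filter_bank(FilterBankSpec(),
                                                          rec.fs)),
        TimeStepSpec(intervals=((0.0, 1.0), (1.0, 2.0))), rec.fs)
    feats2 = transform_msfbcsp(doubled, fitted)
    assert np.allclose(feats2, 4.0 * feats, rtol=1e-6)


def test_zero_blocks_give_zero_variance(session_with_truth):
    rec, _ = session_with_truth
    blocks = _msfbcsp_blocks(rec, intervals=((0.0, 1.0),))
    fitted = fit_msfbcsp(blocks, rec.labels, m=2)
    zeros = {k: np.zeros_like(v) for k, v in blocks.blocks.items()}
    zblocks = type(blocks)(blocks=zeros, bands=blocks.bands,
                           intervals=blocks.intervals, fs=blocks.fs)
    feats = transform_msfbcsp(zblocks, fitted)
    assert np.allclose(feats, 0.0)
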