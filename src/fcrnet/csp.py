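"""Common spatial patterns and the multi-scale filter-bank extension.

CSP finds spatial filters ``w`` maximizing the variance ratio between two
trial populations.  With trace-normalized average covariance matrices
``R_i, R_j``, the filters solve the generalized eigenproblem

    R_i W = (R_i + R_j) W D

with the composite normalization ``W (R_i + R_j) W^T = I``, so the class-i and
class-j eigenvalues of each component sum to one.  Filters from both ends of
the eigenvalue spectrum are the discriminative ones; ``M`` per end are kept.

The multi-scale filter-bank model fits one such solution per (frequency band,
time-step window, class contrast) and summarizes projected components by their
variance over time.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import scipy.linalg

from .filterbank import MultiScaleBandTensor

__all__ = [
    "ClassCovariance",
    "CSPSolution",
    "CSPFilterBank",
    "normalized_covariance",
    "solve_csp",
    "select_filters",
    "project",
    "fit_msfbcsp",
    "transform_msfbcsp",
]


class DegenerateTrialError(ValueError):
    """A trial carries zero total power."""


@dataclass
class ClassCovariance:
    """Trace-normalized average covariance of one class (unit trace)."""

    matrix: np.ndarray
    class_id: object = None
    n_trials: int = 0


@dataclass
class CSPSolution:
    """Full CSP decomposition for one two-population contrast.

    ``W`` rows are filters sorted by descending eigenvalue ``D`` (eigenvalues
    of the first population against the composite; in [0, 1]).
    """

    W: np.ndarray
    D: np.ndarray
    contrast: tuple = (0, 1)


@dataclass
class CSPFilterBank:
    """Selected filters per (band, step, contrast): ``[2M x n_channels]``."""

    filters: dict
    bands: tuple
    intervals: tuple
    contrasts: tuple
    m_per_end: int
    scheme: str

    @property
    def n_filters_total(self) -> int:
        return sum(f.shape[0] for f in self.filters.values())


def normalized_covariance(trials: np.ndarray, class_id=None) -> ClassCovariance:
    """Average of per-trial trace-normalized covariance ``x x^T / tr(x x^T)``."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3:
        raise ValueError("trials must be [n x channels x samples]")
    n, n_ch, n_s = trials.shape
    if n < 1:
        raise ValueError("need at least one trial")
    if n_s < n_ch:
        warnings.warn(
            f"fewer samples ({n_s}) than channels ({n_ch}); covariance is "
            "rank deficient", stacklevel=2,
        )
    acc = np.zeros((n_ch, n_ch))
    for i, x in enumerate(trials):
        cov = x @ x.T
        tr = np.trace(cov)
        if tr <= 0.0:
            raise DegenerateTrialError(f"trial {i} has zero total power")
        acc += cov / tr
    mat = acc / n
    mat = 0.5 * (mat + mat.T)
    return ClassCovariance(matrix=mat, class_id=class_id, n_trials=n)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make each filter's largest-magnitude coefficient positive (determinism)."""
    W = W.copy()
    idx = np.argmax(np.abs(W), axis=1)
    signs = np.sign(W[np.arange(W.shape[0]), idx])
    signs[signs == 0] = 1.0
    return W * signs[:, None]


def solve_csp(R_i, R_j, shrinkage: float = 1e-6,
              contrast=(0, 1)) -> CSPSolution:
    """Solve ``R_i W = (R_i + R_j) W D`` with composite normalization.

    Both inputs may be ``ClassCovariance`` or plain symmetric PSD matrices.
    A small shrinkage ``R <- (1-g) R + g tr(R)/C I`` guards against
    rank-deficient covariances from short windows.
    """
    Ri = R_i.matrix if isinstance(R_i, ClassCovariance) else np.asarray(R_i, float)
    Rj = R_j.matrix if isinstance(R_j, ClassCovariance) else np.asarray(R_j, float)
    if Ri.shape != Rj.shape or Ri.shape[0] != Ri.shape[1]:
        raise ValueError("covariances must be square and same shape")
    c = Ri.shape[0]
    if shrinkage > 0:
        Ri = (1 - shrinkage) * Ri + shrinkage * (np.trace(Ri) / c) * np.eye(c)
        Rj = (1 - shrinkage) * Rj + shrinkage * (np.trace(Rj) / c) * np.eye(c)
    comp = Ri + Rj
    # scipy.linalg.eigh solves the symmetric-definite generalized problem with
    # eigenvectors normalized to V^T comp V = I, which is exactly the
    # composite normalization required here.
    try:
        vals, vecs = scipy.linalg.eigh(Ri, comp)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"composite covariance not positive definite: {exc}"
        ) from exc
    order = np.argsort(-vals, kind="stable")  # descending, ties keep solver order
    vals = np.clip(vals[order], 0.0, 1.0)
    W = _fix_signs(vecs[:, order].T)
    return CSPSolution(W=W, D=vals, contrast=tuple(contrast))


def select_filters(solution: CSPSolution, m: int) -> np.ndarray:
    """Keep the ``m`` largest- and ``m`` smallest-eigenvalue filters (2m rows)."""
    n = solution.W.shape[0]
    if 2 * m > n:
        raise ValueError(f"2M = {2 * m} filters requested from {n} channels")
    return np.vstack([solution.W[:m], solution.W[n - m:]])


def project(trial: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Spatially filter one trial (or a stack of trials): ``Y = w x``."""
    trial = np.asarray(trial, float)
    filters = np.asarray(filters, float)
    if trial.shape[-2] != filters.shape[1]:
        raise ValueError(
            f"trial has {trial.shape[-2]} channels, filters expect "
            f"{filters.shape[1]}"
        )
    return np.einsum("fc,...cs->...fs", filters, trial)


def _contrast_list(classes, scheme: str):
    classes = sorted(classes)
    if scheme == "one-vs-rest":
        return [(k, "rest") for k in classes]
    if scheme == "pairwise":
        return [(a, b) for i, a in enumerate(classes) for b in classes[i + 1:]]
    raise ValueError(f"unknown contrast scheme {scheme!r}")


def fit_msfbcsp(blocks: MultiScaleBandTensor, labels: np.ndarray, m: int = 2,
                scheme: str = "one-vs-rest", shrinkage: float = 0.3,
                return_solutions: bool = False):
    """Fit one CSP per (band, step, contrast) and select 2M filters each.

    With K classes, one-vs-rest yields K contrasts per block; pairwise yields
    K(K-1)/2 (a single pair for two-class data).

    The default shrinkage is substantially stronger than for broadband
    covariances: a 4 Hz-wide block of a few-second window carries only a few
    dozen effective samples per trial, so the composite covariance pencil is
    near-degenerate in the background subspace and the top filters would
    otherwise rotate freely into it (regularized-CSP practice picks
    intensities of this order by cross-validation).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes to fit CSP")
    contrasts = _contrast_list(classes.tolist(), scheme)
    filters = {}
    solutions = {}
    for (b, t), x in blocks.blocks.items():
        for contrast in contrasts:
            if contrast[1] == "rest":
                k = contrast[0]
                Ri = normalized_covariance(x[labels == k], k)
                Rj = normalized_covariance(x[labels != k], "rest")
            else:
                a, bb = contrast
                Ri = normalized_covariance(x[labels == a], a)
                Rj = normalized_covariance(x[labels == bb], bb)
            sol = solve_csp(Ri, Rj, shrinkage=shrinkage, contrast=contrast)
            filters[(b, t, contrast)] = select_filters(sol, m)
            if return_solutions:
                solutions[(b, t, contrast)] = sol
    bank = CSPFilterBank(
        filters=filters, bands=blocks.bands, intervals=blocks.intervals,
        contrasts=tuple(contrasts), m_per_end=m, scheme=scheme,
    )
    return (bank, solutions) if return_solutions else bank


def projected_blocks(blocks: MultiScaleBandTensor, bank: CSPFilterBank) -> dict:
    """Project every block through its selected filters.

    Returns ``(band, step, contrast) -> [n_trials x 2M x n_samples(step)]``.
    """
    _check_compat(blocks, bank)
    return {
        (b, t, contrast): project(blocks.block(b, t), w)
        for (b, t, contrast), w in bank.filters.items()
    }


def _check_compat(blocks: MultiScaleBandTensor, bank: CSPFilterBank) -> None:
    if blocks.bands != bank.bands or blocks.intervals != bank.intervals:
        raise ValueError("band/step layout differs from the fitted bank")


def transform_msfbcsp(blocks: MultiScaleBandTensor, bank: CSPFilterBank,
                      feature: str = "variance") -> np.ndarray:
    """Variance features of projected components.

    Returns ``[n_trials x N_F x N_T x n_contrasts x 2M]``; ``feature`` is
    ``"variance"`` (raw energy) or ``"log_normalized_variance"`` (log of each
    component's share of the per-block variance, the filter-bank-CSP
    convention).
    """
    if feature not in ("variance", "log_normalized_variance"):
        raise ValueError(f"unknown feature {feature!r}")
    _check_compat(blocks, bank)
    n_trials = next(iter(blocks.blocks.values())).shape[0]
    nf, nt = len(bank.bands), len(bank.intervals)
    nc, m2 = len(bank.contrasts), 2 * bank.m_per_end
    out = np.empty((n_trials, nf, nt, nc, m2))
    for b in range(nf):
        for t in range(nt):
            x = blocks.block(b, t)
            for ci, contrast in enumerate(bank.contrasts):
                y = project(x, bank.filters[(b, t, contrast)])
                var = y.var(axis=-1)
                if feature == "log_normalized_variance":
                    var = np.log(var / (var.sum(axis=-1, keepdims=True) + 1e-30)
                                 + 1e-30)
                out[:, b, t, ci, :] = var
    return out
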