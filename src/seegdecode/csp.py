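"""Common spatial patterns + linear discriminant baseline decoder.

CSP finds spatial filters that maximize the variance ratio between the two
classes by solving the generalized eigenproblem on the class covariance
matrices (each the average of Ledoit-Wolf regularized per-trial covariances).
Per-trial average power of the filtered signals feeds an LDA classifier; the
same stratified CV harness as the Riemannian pipeline yields per-fold AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score

from .preprocess import EpochSet
from .pipeline import make_folds
from .spd import lw_shrinkage_covariance


@dataclass
class CSPModel:
    """Fitted spatial filters; rows of ``filters`` are individual filters."""

    filters: np.ndarray  # (n_filters, n_channels)
    eigenvalues: np.ndarray  # normalized in (0, 1), one per filter
    class_order: tuple[str, str] = ("move", "rest")


def _class_covariances(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    mats = {"move": [], "rest": []}
    for trial, lab in zip(epochs.data, epochs.labels):
        mats[str(lab)].append(lw_shrinkage_covariance(trial))
    if not mats["move"] or not mats["rest"]:
        raise ValueError("both classes must be present to fit CSP")
    return np.mean(mats["move"], axis=0), np.mean(mats["rest"], axis=0)


def csp_fit(epochs: EpochSet, n_filters: int = 10) -> CSPModel:
    """Fit CSP filters from class-average regularized covariances.

    Solves C_move w = lambda (C_move + C_rest) w; eigenvalues near 1 favor
    move variance, near 0 favor rest. Filters are picked alternately from the
    two ends of the spectrum, most discriminative first.
    """
    n_ch = epochs.n_channels
    if n_filters > n_ch:
        raise ValueError("n_filters cannot exceed the channel count")
    c_move, c_rest = _class_covariances(epochs)
    evals, evecs = linalg.eigh(c_move, c_move + c_rest)  # ascending
    order = []
    lo, hi = 0, n_ch - 1
    for i in range(n_filters):
        if i % 2 == 0:
            order.append(hi)
            hi -= 1
        else:
            order.append(lo)
            lo += 1
    filters = evecs[:, order].T
    return CSPModel(filters=filters, eigenvalues=evals[order])


def csp_features(model: CSPModel, epochs: EpochSet, log: bool = False) -> np.ndarray:
    """Average power of each spatially filtered trial: (n_trials, n_filters)."""
    if epochs.n_channels != model.filters.shape[1]:
        raise ValueError("channel count does not match the fitted filters")
    filtered = np.einsum("fc,tcs->tfs", model.filters, epochs.data)
    power = np.mean(filtered ** 2, axis=-1)
    return np.log(power) if log else power


def csp_lda_cell(
    epochs: EpochSet,
    n_filters: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    log_power: bool = False,
) -> np.ndarray:
    """Cross-validated AUCs of the CSP-LDA decoder (same folds as run_cell)."""
    folds = make_folds(epochs, n_folds=n_folds, seed=seed)
    aucs = np.empty(len(folds))
    for f, (train_idx, test_idx) in enumerate(folds):
        train = EpochSet(epochs.data[train_idx], epochs.labels[train_idx],
                         epochs.band, epochs.sampling_rate_hz)
        test = EpochSet(epochs.data[test_idx], epochs.labels[test_idx],
                        epochs.band, epochs.sampling_rate_hz)
        model = csp_fit(train, min(n_filters, train.n_channels))
        x_train = csp_features(model, train, log=log_power)
        x_test = csp_features(model, test, log=log_power)
        y_train = (train.labels == "move").astype(int)
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
        lda.fit(x_train, y_train)
        scores = lda.decision_function(x_test)
        aucs[f] = roc_auc_score(test.labels == "move", scores)
    return aucs
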