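"""Cross-validated Riemannian decoding: standardize -> PCA -> covariance -> MDM.

Each (task, band, n_components) cell is evaluated with stratified 10-fold
cross-validation. Inside a fold, per-channel standardization statistics and
the PCA basis are fitted on the training trials only and applied to both
folds; per-trial Ledoit-Wolf covariances in component space feed the MDM
classifier, and performance is the AUC of its continuous decision values on
the test trials.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .preprocess import EpochSet, band_envelope, clean_filter, epoch
from .qc import run_qc
from .spd import CovarianceSet, MDMModel, lw_shrinkage_covariance, mdm_fit, mdm_score
from .synthetic import EventTable, Recording

logger = logging.getLogger(__name__)

#: principal-component grid swept by the full evaluation
COMPONENT_GRID: tuple[int, ...] = (3, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
ALL_BANDS: tuple[str, ...] = ("beta", "high_gamma", "beta_plus_high_gamma")
ALL_TASKS: tuple[str, ...] = ("executed", "imagined")


@dataclass
class FoldTransform:
    """Standardization + PCA fitted on one training fold."""

    channel_means: np.ndarray
    channel_stds: np.ndarray
    pca_components: np.ndarray  # (n_components, n_channels)
    explained_variance_ratio: np.ndarray

    def fingerprint(self) -> str:
        """Hash of the fitted parameters (leakage checks)."""
        h = hashlib.sha256()
        for arr in (self.channel_means, self.channel_stds,
                    self.pca_components, self.explained_variance_ratio):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


def model_fingerprint(model: MDMModel) -> str:
    """Hash of a fitted MDM model's class means."""
    h = hashlib.sha256()
    for cls in sorted(model.class_means):
        h.update(cls.encode())
        h.update(np.ascontiguousarray(model.class_means[cls]).tobytes())
    h.update(model.divergence.encode())
    return h.hexdigest()


def make_folds(epochs: EpochSet, n_folds: int = 10, seed: int = 0
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, shuffled CV folds over trials.

    Returns (train_indices, test_indices) pairs; the test sets partition all
    trials and each preserves the move/rest balance.
    """
    if epochs.n_trials < n_folds:
        raise ValueError("fewer trials than folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y = epochs.binary_labels()
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def fit_fold_transform(train_epochs: EpochSet, n_components: int) -> FoldTransform:
    """Fit per-channel z-scoring and PCA on the concatenated training trials.

    Standardization statistics are computed over all training-trial samples
    concatenated in time; PCA is fitted on the standardized (samples x
    channels) matrix. ``n_components`` above the channel count is clipped
    with a warning. Component signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    if train_epochs.n_trials == 0:
        raise ValueError("empty training set")
    n_ch = train_epochs.n_channels
    if n_components > n_ch:
        warnings.warn(f"n_components={n_components} clipped to {n_ch} channels")
        n_components = n_ch
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    # (n_trials, ch, samp) -> (n_trials * samp, ch)
    x = np.concatenate(list(train_epochs.data), axis=-1).T
    means = x.mean(axis=0)
    stds = x.std(axis=0)
    zero_var = stds == 0
    if np.any(zero_var):
        warnings.warn(f"{zero_var.sum()} zero-variance channels; std set to 1")
        stds = np.where(zero_var, 1.0, stds)
    z = (x - means) / stds
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(z)
    comps = pca.components_.copy()
    # deterministic sign: largest-|loading| entry positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return FoldTransform(
        channel_means=means,
        channel_stds=stds,
        pca_components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def apply_transform(epochs: EpochSet, t: FoldTransform) -> EpochSet:
    """Standardize with stored statistics and project onto the PCA basis."""
    if epochs.n_channels != t.channel_means.shape[0]:
        raise ValueError("channel count does not match the fitted transform")
    z = (epochs.data - t.channel_means[None, :, None]) / t.channel_stds[None, :, None]
    projected = np.einsum("kc,tcs->tks", t.pca_components, z)
    return EpochSet(
        data=projected,
        labels=epochs.labels.copy(),
        band=epochs.band,
        sampling_rate_hz=epochs.sampling_rate_hz,
        channel_names=[f"pc{i + 1}" for i in range(projected.shape[1])],
    )


def epochs_to_covs(epochs: EpochSet) -> CovarianceSet:
    """Ledoit-Wolf regularized sample covariance of each trial."""
    if epochs.n_samples < 2:
        raise ValueError("trials need at least 2 samples")
    mats = [lw_shrinkage_covariance(trial) for trial in epochs.data]
    return CovarianceSet(matrices=mats, labels=epochs.labels.copy())


def run_cell(
    epochs: EpochSet,
    n_components: int,
    divergence: str = "kl_sym",
    n_folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated AUCs for one (band, n_components) cell.

    For each fold: fit the standardize+PCA transform on the training trials,
    transform both folds, compute trial covariances, fit MDM on the training
    covariances, score the test trials, and take the AUC of scores against
    the move/rest labels. Returns one AUC per fold.
    """
    folds = make_folds(epochs, n_folds=n_folds, seed=seed)
    aucs = np.empty(len(folds))
    for f, (train_idx, test_idx) in enumerate(folds):
        train = EpochSet(epochs.data[train_idx], epochs.labels[train_idx],
                         epochs.band, epochs.sampling_rate_hz)
        test = EpochSet(epochs.data[test_idx], epochs.labels[test_idx],
                        epochs.band, epochs.sampling_rate_hz)
        if len(set(train.labels.tolist())) < 2:
            raise ValueError("a training fold contains a single class")
        t = fit_fold_transform(train, n_components)
        train_c = apply_transform(train, t)
        test_c = apply_transform(test, t)
        covs_train = epochs_to_covs(train_c)
        covs_test = epochs_to_covs(test_c)
        model = mdm_fit(covs_train, divergence)
        scores = np.array([mdm_score(model, c) for c in covs_test.matrices])
        aucs[f] = roc_auc_score(covs_test.labels == "move", scores)
    return aucs


def prepare_band_epochs(
    recording: Recording,
    events: EventTable,
    task: str,
    trial_duration_s: float = 3.0,
) -> dict[str, EpochSet]:
    """QC + filter + envelopes + epoching for all three band sets of one task."""
    retained, _report = run_qc(recording)
    cleaned = clean_filter(retained)
    envs = {b: band_envelope(cleaned, b) for b in ("beta", "high_gamma")}
    out = {}
    for band in ALL_BANDS:
        out[band] = epoch(envs, events, band,
                          trial_duration_s=trial_duration_s, task=task)
    return out


def analyze_session(
    recording: Recording,
    events: EventTable,
    task: str = "executed",
    band: str = "beta",
    n_components: int = 10,
    divergence: str = "kl_sym",
    n_folds: int = 10,
    seed: int = 0,
    trial_duration_s: float = 3.0,
) -> np.ndarray:
    """End-to-end decoding of one session cell from the raw recording."""
    retained, _report = run_qc(recording)
    cleaned = clean_filter(retained)
    if band == "beta_plus_high_gamma":
        envs = {b: band_envelope(cleaned, b) for b in ("beta", "high_gamma")}
    else:
        envs = {band: band_envelope(cleaned, band)}
    epochs = epoch(envs, events, band, trial_duration_s=trial_duration_s, task=task)
    return run_cell(epochs, n_components, divergence, n_folds, seed)


def run_grid(
    cohort: list,
    tasks: tuple[str, ...] = ALL_TASKS,
    bands: tuple[str, ...] = ALL_BANDS,
    component_grid: tuple[int, ...] = COMPONENT_GRID,
    divergence: str = "kl_sym",
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep the full (participant x task x band x components) grid.

    ``cohort`` holds (config, recording, events, ...) tuples as produced by
    :func:`seegdecode.generate_cohort`. Component counts above the available
    channel dimension in a cell are skipped (logged), mirroring a participant
    with fewer contacts than the largest grid value. Returns a long-format
    DataFrame with one row per fold.
    """
    if not cohort:
        raise ValueError("empty cohort")
    rows = []
    for session in cohort:
        config, recording, events = session[0], session[1], session[2]
        for task in tasks:
            if task not in set(events["task"]):
                continue
            band_epochs = prepare_band_epochs(
                recording, events, task, trial_duration_s=config.trial_duration_s)
            for band in bands:
                eps = band_epochs[band]
                for n_comp in component_grid:
                    if n_comp > eps.n_channels:
                        logger.info(
                            "skip %s %s %s %d components (> %d channels)",
                            config.participant_id, task, band, n_comp,
                            eps.n_channels)
                        continue
                    t0 = time.perf_counter()
                    aucs = run_cell(eps, n_comp, divergence, n_folds, seed)
                    logger.info(
                        "%s %s %s k=%d: mean AUC %.3f (%.1fs)",
                        config.participant_id, task, band, n_comp,
                        aucs.mean(), time.perf_counter() - t0)
                    for fold, auc in enumerate(aucs):
                        rows.append({
                            "participant": config.participant_id,
                            "task": task,
                            "band": band,
                            "n_components": n_comp,
                            "fold": fold,
                            "auc": float(auc),
                        })
    return pd.DataFrame(rows)
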