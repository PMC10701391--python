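"""SPD-matrix machinery: shrinkage covariance, KL geometry, and the MDM classifier.

A trial is summarized by the covariance matrix of its component-space
envelope signals — a symmetric positive-definite (SPD) matrix. Classification
is minimum distance to mean (MDM): each class is represented by the centroid
of its training covariances under a Kullback-Leibler (KL) divergence, and a
trial is assigned to the class with the nearest centroid.

For zero-mean Gaussians with covariances A, B (k x k):

    KL(A || B) = 1/2 [ tr(B^-1 A) - k + ln(det B / det A) ]

The symmetrized (Jeffreys) divergence is the average of the two one-sided
KLs. Its centroid over a set {C_i} has a closed form: the matrix geometric
mean of the arithmetic mean A and the harmonic mean H,

    M = A^{1/2} (A^{-1/2} H A^{-1/2})^{1/2} A^{1/2},

which we use instead of fixed-point iteration. The one-sided divergences pair
with their own centroids: the arithmetic mean minimizes sum_i KL(C_i || X)
and the harmonic mean minimizes sum_i KL(X || C_i).

Sample covariances of short trials are rank-deficient once the component
count approaches the trial length, so every trial covariance is regularized
with the Ledoit-Wolf optimal shrinkage toward a scaled identity, which keeps
it SPD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EIG_FLOOR = 1e-12
_SYM_RTOL = 1e-10

DIVERGENCES = ("kl_left", "kl_right", "kl_sym")


def _symmetrize(m: np.ndarray) -> np.ndarray:
    return (m + m.T) / 2.0


def check_spd(m: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate symmetry and positive-definiteness; return the symmetrized matrix."""
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - m.T).max() > _SYM_RTOL * scale:
        raise ValueError(f"{name} is not symmetric")
    m = _symmetrize(m)
    w = np.linalg.eigvalsh(m)
    if w.min() <= 0:
        raise ValueError(f"{name} is not positive definite (min eig {w.min():.3e})")
    return m


def _powm(m: np.ndarray, p: float) -> np.ndarray:
    """Matrix power of an SPD matrix via eigendecomposition, eigenvalues floored."""
    w, v = np.linalg.eigh(_symmetrize(m))
    w = np.maximum(w, _EIG_FLOOR)
    return _symmetrize((v * w ** p) @ v.T)


def lw_shrinkage_covariance(samples: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage covariance from a (k x n) sample matrix.

    Returns (1 - rho) S + rho mu I, where S is the sample covariance of the
    n observations (columns), mu = tr(S)/k, and rho in [0, 1] is the
    closed-form optimal shrinkage intensity. SPD whenever the input is not
    constant, even for n < k.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("samples must be 2-D (k x n)")
    k, n = x.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    x = x - x.mean(axis=1, keepdims=True)
    s = (x @ x.T) / n
    mu = np.trace(s) / k
    if np.allclose(s, 0):
        raise ValueError("degenerate covariance: input is constant")
    # d^2 = ||S - mu I||_F^2 / k ; b^2 = mean-squared estimation error of S
    d2 = np.sum((s - mu * np.eye(k)) ** 2) / k
    sq_norms = np.sum(x ** 2, axis=0)  # ||x_t||^2 per observation
    b2 = (np.sum(sq_norms ** 2) - n * np.sum(s ** 2)) / (k * n ** 2)
    b2 = min(b2, d2)
    rho = 0.0 if d2 == 0 else max(b2, 0.0) / d2
    out = (1.0 - rho) * s + rho * mu * np.eye(k)
    return _symmetrize(out)


def kl_divergence(a: np.ndarray, b: np.ndarray) -> float:
    """Gaussian KL divergence KL(a || b) between zero-mean covariances."""
    a = check_spd(a, "a")
    b = check_spd(b, "b")
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    k = a.shape[0]
    cho = np.linalg.cholesky(b)
    sol = np.linalg.solve(cho, np.linalg.solve(cho, a).T)  # b^-1 a (up to transpose)
    trace_term = np.trace(sol)
    sign_a, logdet_a = np.linalg.slogdet(a)
    sign_b, logdet_b = np.linalg.slogdet(b)
    if sign_a <= 0 or sign_b <= 0:
        raise ValueError("singular matrix")
    return 0.5 * float(trace_term - k + logdet_b - logdet_a)


def jeffreys_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetrized KL: 1/2 [KL(a||b) + KL(b||a)]. Zero iff a == b."""
    return 0.5 * (kl_divergence(a, b) + kl_divergence(b, a))


def mean_arithmetic(matrices: list[np.ndarray]) -> np.ndarray:
    """Elementwise average; the centroid of sum_i KL(C_i || X)."""
    mats = _validated_set(matrices)
    return _symmetrize(np.mean(mats, axis=0))


def mean_harmonic(matrices: list[np.ndarray]) -> np.ndarray:
    """Inverse of the averaged inverses; the centroid of sum_i KL(X || C_i)."""
    mats = _validated_set(matrices)
    inv_mean = np.mean([np.linalg.inv(m) for m in mats], axis=0)
    return _symmetrize(np.linalg.inv(inv_mean))


def mean_kl_sym(matrices: list[np.ndarray]) -> np.ndarray:
    """Symmetrized-KL centroid: geometric mean of arithmetic and harmonic means."""
    a = mean_arithmetic(matrices)
    h = mean_harmonic(matrices)
    a_half = _powm(a, 0.5)
    a_inv_half = _powm(a, -0.5)
    inner = _powm(a_inv_half @ h @ a_inv_half, 0.5)
    return _symmetrize(a_half @ inner @ a_half)


def _validated_set(matrices: list[np.ndarray]) -> np.ndarray:
    if len(matrices) == 0:
        raise ValueError("empty matrix list")
    mats = [check_spd(m) for m in matrices]
    k = mats[0].shape[0]
    if any(m.shape[0] != k for m in mats):
        raise ValueError("dimension mismatch within set")
    return np.stack(mats)


_MEANS = {
    "kl_sym": mean_kl_sym,
    "kl_left": mean_arithmetic,
    "kl_right": mean_harmonic,
}


def _divergence_distance(divergence: str, c: np.ndarray, mean: np.ndarray) -> float:
    if divergence == "kl_sym":
        return jeffreys_distance(c, mean)
    if divergence == "kl_left":
        return kl_divergence(c, mean)
    if divergence == "kl_right":
        return kl_divergence(mean, c)
    raise ValueError(f"unknown divergence {divergence!r}")


@dataclass
class CovarianceSet:
    """Per-trial SPD matrices with move/rest labels."""

    matrices: list[np.ndarray]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.matrices) != len(self.labels):
            raise ValueError("one label per matrix required")


@dataclass
class MDMModel:
    """Fitted minimum-distance-to-mean classifier."""

    class_means: dict[str, np.ndarray]
    divergence: str


def mdm_fit(covs: CovarianceSet, divergence: str = "kl_sym") -> MDMModel:
    """Fit per-class divergence-matched centroids.

    kl_sym uses the symmetrized-KL (geometric-mean) centroid, kl_left the
    arithmetic mean, kl_right the harmonic mean.
    """
    if divergence not in DIVERGENCES:
        raise ValueError(f"unknown divergence {divergence!r}")
    classes = sorted(set(covs.labels.tolist()))
    if len(classes) < 2:
        raise ValueError("both classes must be present to fit MDM")
    mean_fn = _MEANS[divergence]
    means = {}
    for cls in classes:
        members = [m for m, lab in zip(covs.matrices, covs.labels) if lab == cls]
        means[cls] = mean_fn(members)
    return MDMModel(class_means=means, divergence=divergence)


def mdm_score(model: MDMModel, c: np.ndarray) -> float:
    """Continuous decision value d(c, mean_rest) - d(c, mean_move).

    Positive means closer to the move centroid (predict move); ties at
    exactly zero resolve to rest, the null class.
    """
    c = check_spd(c, "c")
    d_move = _divergence_distance(model.divergence, c, model.class_means["move"])
    d_rest = _divergence_distance(model.divergence, c, model.class_means["rest"])
    return d_rest - d_move


def mdm_predict(model: MDMModel, c: np.ndarray) -> str:
    return "move" if mdm_score(model, c) > 0 else "rest"
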