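"""Kernel mean-embedding distances between per-patient latent batches.

Each patient is treated as a domain with an unknown latent distribution
P^(i).  A distribution is embedded in an RKHS as the mean of the kernel
feature map, mu(P) = E_{z~P}[h(z, .)], and the inter-domain distance is the
RKHS norm of the difference of embeddings (the maximum mean discrepancy).
The K-domain regularizer averages this distance over all K^2 ordered domain
pairs, including i = j.  Standardized-Euclidean and symmetric-KL distances
between diagonal-Gaussian batch fits are provided as alternative alignment
metrics for comparison runs.

All distances are implemented once, on autodiff tensors, so the same code
path serves both training (differentiable, with an epsilon inside the square
root) and analysis (numpy in, float out, exact at zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor

logger = logging.getLogger(__name__)

#: epsilon added inside sqrt on the differentiable path only
_GRAD_EPS = 1e-12
#: floor for per-dimension variance estimates in euclidean / kl metrics
_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class KernelConfig:
    """Kernel and estimator choices for the MMD.

    A mixture of RBF kernels, k(a, b) = sum_sigma exp(-||a-b||^2 / (2 sigma^2)),
    is the default; the bandwidth mixture makes the distance sensitive at
    several latent length scales without a per-run heuristic.
    """

    family: str = "rbf"
    bandwidths: tuple[float, ...] = (1.0, 5.0, 10.0)
    estimator: str = "biased"
    #: "fixed" uses `bandwidths` as-is; "median" rescales them by the median
    #: pairwise distance of the pooled batch (computed without gradient), so
    #: the distance is insensitive to the overall latent scale.
    bandwidth_mode: str = "fixed"
    #: lower bound on the median-mode scale: keeps the kernel from chasing a
    #: contracting latent cloud all the way to a point (degenerate optimum
    #: of the alignment penalty)
    median_floor: float = 1.0

    def __post_init__(self):
        if self.family not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.estimator not in ("biased", "unbiased"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.bandwidth_mode not in ("fixed", "median"):
            raise ValueError(f"unknown bandwidth_mode {self.bandwidth_mode!r}")
        if self.family == "rbf":
            if len(self.bandwidths) == 0 or any(s <= 0 for s in self.bandwidths):
                raise ValueError("bandwidths must be non-empty and positive")


@dataclass
class DomainLatents:
    """Per-domain latent batches Z = [z^(1), ..., z^(K)], each n_i x l."""

    per_domain: dict[str, np.ndarray]

    def __post_init__(self):
        dims = {np.asarray(z).shape[1] for z in self.per_domain.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent latent dimensions: {sorted(dims)}")

    @property
    def l(self) -> int:
        return next(iter(self.per_domain.values())).shape[1]


def median_heuristic(A: np.ndarray, B: np.ndarray) -> float:
    """Median pairwise distance between the pooled samples (a common
    bandwidth choice when latent scale is unknown)."""
    X = np.vstack([np.asarray(A), np.asarray(B)])
    d2 = _sq_dists(as_tensor(X), as_tensor(X)).value
    med = float(np.median(np.sqrt(d2[np.triu_indices_from(d2, k=1)])))
    return med if med > 0 else 1.0


def _sq_dists(A: Tensor, B: Tensor) -> Tensor:
    aa = (A * A).sum(axis=1, keepdims=True)
    bb = (B * B).sum(axis=1, keepdims=True)
    return (aa + bb.T - 2.0 * (A @ B.T)).relu()


def _gram(A: Tensor, B: Tensor, cfg: KernelConfig,
          sigmas: tuple[float, ...] | None = None) -> Tensor:
    if A.value.shape[1] != B.value.shape[1]:
        raise ValueError("latent dimension mismatch between batches")
    if cfg.family == "linear":
        return A @ B.T
    if sigmas is None:
        sigmas = _sigmas(A, B, cfg)
    d2 = _sq_dists(A, B)
    out = (d2 * (-1.0 / (2.0 * sigmas[0] ** 2))).exp()
    for s in sigmas[1:]:
        out = out + (d2 * (-1.0 / (2.0 * s ** 2))).exp()
    return out


def _sigmas(A: Tensor, B: Tensor, cfg: KernelConfig) -> tuple[float, ...]:
    if cfg.bandwidth_mode == "fixed" or cfg.family == "linear":
        return cfg.bandwidths
    med = max(median_heuristic(A.value, B.value), cfg.median_floor)
    return tuple(s * med for s in cfg.bandwidths)


def _mmd(zi: Tensor, zj: Tensor, cfg: KernelConfig, eps: float) -> Tensor:
    n, m = zi.value.shape[0], zj.value.shape[0]
    if n == 0 or m == 0:
        raise ValueError("empty latent batch")
    sigmas = _sigmas(zi, zj, cfg)      # shared across the three gram blocks
    k_ii = _gram(zi, zi, cfg, sigmas)
    k_jj = _gram(zj, zj, cfg, sigmas)
    k_ij = _gram(zi, zj, cfg, sigmas)
    if cfg.estimator == "unbiased":
        if n < 2 or m < 2:
            raise ValueError("unbiased estimator needs >= 2 samples per domain")
        # off-diagonal means: RBF mixtures have k(z,z) = n_bandwidths
        diag = float(len(cfg.bandwidths)) if cfg.family == "rbf" else None
        tr_ii = (zi * zi).sum() if diag is None else as_tensor(diag * n)
        tr_jj = (zj * zj).sum() if diag is None else as_tensor(diag * m)
        m_ii = (k_ii.sum() - tr_ii) * (1.0 / (n * (n - 1)))
        m_jj = (k_jj.sum() - tr_jj) * (1.0 / (m * (m - 1)))
    else:
        m_ii = k_ii.mean()
        m_jj = k_jj.mean()
    sq = (m_ii - 2.0 * k_ij.mean() + m_jj).relu()
    return (sq + eps).sqrt() if eps > 0 else sq.sqrt()


def _euclidean(zi: Tensor, zj: Tensor, eps: float = 0.0) -> Tensor:
    """Standardized Euclidean distance between batch means, per-dimension
    variance pooled across the two batches (unbiased, floored)."""
    n, m = zi.value.shape[0], zj.value.shape[0]
    mu_i = zi.mean(axis=0)
    mu_j = zj.mean(axis=0)
    var = _pooled_var(zi, zj, mu_i, mu_j, n, m)
    d = mu_i - mu_j
    sq = (d * d / var).sum()
    return (sq + eps).sqrt() if eps > 0 else sq.sqrt()


def _batch_var(z: Tensor, mu: Tensor, n: int) -> Tensor:
    c = z - mu.reshape(1, -1)
    denom = max(n - 1, 1)
    return (c * c).sum(axis=0) * (1.0 / denom)


def _pooled_var(zi, zj, mu_i, mu_j, n, m) -> Tensor:
    vi = _batch_var(zi, mu_i, n)
    vj = _batch_var(zj, mu_j, m)
    w_i, w_j = max(n - 1, 1), max(m - 1, 1)
    v = (vi * w_i + vj * w_j) * (1.0 / (w_i + w_j))
    if np.any(v.value < _VAR_FLOOR):
        logger.warning("degenerate pooled variance floored at %g", _VAR_FLOOR)
    return v + _VAR_FLOOR

def _sym_kl(zi: Tensor, zj: Tensor, eps: float = 0.0) -> Tensor:
    """Symmetric KL divergence between diagonal-Gaussian fits (unbiased
    sample moments, variances floored)."""
    n, m = zi.value.shape[0], zj.value.shape[0]
    if n < 2 or m < 2:
        raise ValueError("kl metric needs >= 2 samples per batch")
    mu_i, mu_j = zi.mean(axis=0), zj.mean(axis=0)
    vi = _batch_var(zi, mu_i, n) + _VAR_FLOOR
    vj = _batch_var(zj, mu_j, m) + _VAR_FLOOR
    if np.any(vi.value <= 2 * _VAR_FLOOR) or np.any(vj.value <= 2 * _VAR_FLOOR):
        logger.warning("degenerate batch variance floored at %g", _VAR_FLOOR)
    d = mu_i - mu_j
    d2 = d * d
    terms = (vi + d2) / (2.0 * vj) + (vj + d2) / (2.0 * vi) - 1.0
    return terms.sum()


_METRICS = {"mmd": None, "euclidean": _euclidean, "kl": _sym_kl}


def _dispatch(*arrays):
    """True if any input participates in a gradient graph."""
    return any(isinstance(a, Tensor) for a in arrays)


def kernel_gram(A, B, cfg: KernelConfig = KernelConfig()):
    """Gram matrix between two latent batches under the configured kernel."""
    if _dispatch(A, B):
        return _gram(as_tensor(A), as_tensor(B), cfg)
    return _gram(as_tensor(A), as_tensor(B), cfg).value


def mmd_distance(zi, zj, cfg: KernelConfig = KernelConfig()):
    """Empirical MMD ||mu_P(i) - mu_P(j)||_H between two latent batches.

    On numpy inputs the value is exact (zero for identical batches); on
    tensor inputs a small epsilon inside the square root keeps the distance
    differentiable at zero.
    """
    if _dispatch(zi, zj):
        return _mmd(as_tensor(zi), as_tensor(zj), cfg, _GRAD_EPS)
    return float(_mmd(as_tensor(zi), as_tensor(zj), cfg, 0.0).value)


def alt_distance(zi, zj, metric: str):
    """Alternative inter-domain distances for comparison runs."""
    if metric not in ("euclidean", "kl"):
        raise ValueError(f"unknown metric {metric!r}")
    fn = _METRICS[metric]
    if _dispatch(zi, zj):
        return fn(as_tensor(zi), as_tensor(zj), _GRAD_EPS)
    return float(fn(as_tensor(zi), as_tensor(zj)).value)


def domain_regularizer(Z, cfg: KernelConfig = KernelConfig(),
                       metric: str = "mmd"):
    """K-domain alignment penalty: (1/K^2) * sum over all ordered pairs
    (i, j), including i = j, of the inter-domain distance.

    `Z` may be a DomainLatents, a mapping patient_id -> batch, or a list of
    batches (numpy arrays or tensors).
    """
    if isinstance(Z, DomainLatents):
        batches = list(Z.per_domain.values())
    elif isinstance(Z, dict):
        batches = list(Z.values())
    else:
        batches = list(Z)
    if not batches:
        raise ValueError("no domains supplied")
    K = len(batches)
    tensor_mode = _dispatch(*batches)
    batches = [as_tensor(b) for b in batches]
    eps = _GRAD_EPS if tensor_mode else 0.0

    def dist(a, b):
        if metric == "mmd":
            return _mmd(a, b, cfg, eps)
        return _METRICS[metric](a, b, eps)

    total = None
    for i in range(K):
        for j in range(K):
            d = dist(batches[i], batches[j])
            total = d if total is None else total + d
    total = total * (1.0 / K ** 2)
    return total if tensor_mode else float(total.value)
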