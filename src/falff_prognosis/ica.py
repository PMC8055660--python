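"""Temporal-concatenation group spatial ICA with InfoMax unmixing.

The cohort decomposition follows the standard two-stage workflow: each
subject's masked series is reduced along time by PCA, reduced subjects are
stacked and reduced again to the requested component count, the group
matrix is whitened over voxels, and an InfoMax unmixing matrix (logistic
nonlinearity, natural-gradient updates) is estimated. Group spatial maps
are the unmixed rows; per-subject time courses and maps are recovered by
dual regression (data on group maps, then data on those time courses).
Decomposition stability under random restarts is quantified by an
ICASSO-style within-cluster correlation index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bold import Bold4D, check_consistent_masks
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "ReductionModel",
    "GroupDecomposition",
    "reduce_subject",
    "concatenate_and_reduce",
    "infomax_unmix",
    "back_project",
    "stability_restarts",
    "run_group_ica",
]

_RANK_RTOL = 1e-10


@dataclass
class ReductionModel:
    """A PCA reduction: orthonormal basis, spectrum, and centering vector."""

    basis: np.ndarray  # (original_dim, k), orthonormal columns
    eigenvalues: np.ndarray  # descending, of the covariance that was reduced
    explained_variance_fraction: np.ndarray
    centering: np.ndarray


@dataclass
class GroupDecomposition:
    """Group spatial components plus per-subject back-projections."""

    group_maps: np.ndarray  # (n_components, n_voxels)
    subject_timecourses: list[np.ndarray]  # per subject (t_i, n_components)
    subject_maps: list[np.ndarray]  # per subject (n_components, n_voxels)
    subject_ids: list[str]
    tr_by_subject: np.ndarray
    mask: np.ndarray
    n_components: int
    seed: int
    explained_order_energy: np.ndarray = field(default_factory=lambda: np.array([]))
    stability_index: np.ndarray | None = None
    whitened: np.ndarray | None = None  # kept to allow stability analysis afterwards

    def group_map_volumes(self) -> np.ndarray:
        out = np.zeros((self.n_components,) + self.mask.shape)
        out[:, self.mask] = self.group_maps
        return out


def reduce_subject(scan: Bold4D, k: int) -> tuple[np.ndarray, ReductionModel]:
    """Reduce one subject's (t, voxels) matrix to k uncorrelated rows.

    Voxel time courses are centered (temporal mean removed per voxel), the
    t x t temporal covariance ``X X^T / (V - 1)`` is eigendecomposed, and the
    data are projected on the top-k eigenvectors. The discarded eigenvalue
    sum equals the mean-squared reconstruction error, which tests exploit.
    """
    X = scan.in_mask_matrix()  # (t, V)
    t, V = X.shape
    centering = X.mean(axis=0)
    Xc = X - centering
    cov = Xc @ Xc.T / max(V - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    rank = int((eigvals > _RANK_RTOL * max(eigvals[0], 1e-300)).sum())
    if k > min(t, V):
        raise ConfigurationError(f"k={k} exceeds min(t, voxels)={min(t, V)}")
    if k > rank:
        raise ConfigurationError(
            f"k={k} exceeds the temporal rank of {scan.subject_id or 'scan'}; "
            f"achievable maximum is {rank}"
        )
    basis = eigvecs[:, :k]
    reduced = basis.T @ Xc  # (k, V)
    total = eigvals.sum()
    model = ReductionModel(
        basis=basis,
        eigenvalues=eigvals[:k],
        explained_variance_fraction=eigvals[:k] / total if total > 0 else eigvals[:k],
        centering=centering,
    )
    return reduced, model


def concatenate_and_reduce(
    reduced_subjects: list[np.ndarray], n_components: int
) -> tuple[np.ndarray, ReductionModel]:
    """Stack subject-reduced data and whiten down to ``n_components`` rows.

    Rows are centered over voxels; the stacked covariance is
    eigendecomposed and the data projected and scaled so the output rows
    have identity covariance (over voxels) to numerical tolerance.
    """
    if not reduced_subjects:
        raise ValueError("no reduced subjects given")
    V = reduced_subjects[0].shape[1]
    bad = [i for i, r in enumerate(reduced_subjects) if r.shape[1] != V]
    if bad:
        raise ValueError(f"subjects {bad} have inconsistent voxel counts")
    Z = np.vstack(reduced_subjects)
    centering = Z.mean(axis=1)
    Zc = Z - centering[:, None]
    cov = Zc @ Zc.T / (V - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals, eigvecs = np.clip(eigvals[::-1], 0.0, None), eigvecs[:, ::-1]
    rank = int((eigvals > _RANK_RTOL * max(eigvals[0], 1e-300)).sum())
    if n_components > rank:
        raise ConfigurationError(
            f"requested {n_components} components but the concatenated group "
            f"data has rank {rank}"
        )
    basis = eigvecs[:, :n_components]
    scale = 1.0 / np.sqrt(eigvals[:n_components])
    whitened = (basis * scale).T @ Zc  # (n_components, V), identity covariance
    total = eigvals.sum()
    model = ReductionModel(
        basis=basis,
        eigenvalues=eigvals[:n_components],
        explained_variance_fraction=eigvals[:n_components] / total if total > 0 else eigvals[:n_components],
        centering=centering,
    )
    return whitened, model


def infomax_unmix(
    whitened: np.ndarray,
    seed: int,
    max_iter: int = 1000,
    tol: float = 1e-7,
    learning_rate: float = 0.05,
) -> np.ndarray:
    """Estimate an InfoMax unmixing matrix on whitened data.

    Full-batch natural-gradient ascent on the entropy of logistic-squashed
    outputs: ``W <- W + lr * (I + (1 - 2 g(W Y)) (W Y)^T / V) W`` with
    ``g`` the logistic sigmoid. The learning rate halves whenever successive
    updates oscillate (negative inner product), and iteration stops once the
    relative update norm falls below ``tol``. Deterministic per seed (the
    seed draws the initial unmixing matrix).
    """
    Y = np.asarray(whitened, dtype=np.float64)
    n, V = Y.shape
    rng = np.random.default_rng(seed)
    W = np.eye(n) + 0.05 * rng.standard_normal((n, n))
    lr = learning_rate
    prev_delta = None
    eye = np.eye(n)
    for iteration in range(max_iter):
        U = W @ Y
        g = 1.0 / (1.0 + np.exp(-U))
        grad = (eye + (1.0 - 2.0 * g) @ U.T / V) @ W
        delta = lr * grad
        if not np.all(np.isfinite(delta)):
            raise ConfigurationError(
                "InfoMax diverged (non-finite weights); try a smaller learning_rate"
            )
        W = W + delta
        if prev_delta is not None and float(np.sum(delta * prev_delta)) < 0:
            lr *= 0.5  # oscillation: anneal
        prev_delta = delta
        if np.linalg.norm(delta) / max(np.linalg.norm(W), 1e-300) < tol:
            logger.debug("InfoMax converged in %d iterations", iteration + 1)
            break
    else:
        warnings.warn(f"InfoMax reached max_iter={max_iter} without meeting tol={tol}")
    return W


def back_project(
    group_maps: np.ndarray, scan: Bold4D
) -> tuple[np.ndarray, np.ndarray]:
    """Dual-regression back-projection of group maps onto one subject.

    Time courses are the least-squares regression of the subject's centered
    data on the group spatial maps; subject-specific maps are then the
    regression of the data on those time courses. Returns
    ``(timecourses (t, k), subject_maps (k, voxels))``.
    """
    M = np.asarray(group_maps, dtype=np.float64)  # (k, V)
    X = scan.in_mask_matrix()
    X = X - X.mean(axis=0)
    if X.shape[1] != M.shape[1]:
        raise ValueError("scan voxel count does not match group maps")
    gram = M @ M.T
    if np.linalg.matrix_rank(gram) < M.shape[0]:
        raise ValueError("group maps are rank-deficient; back-projection is degenerate")
    timecourses = X @ M.T @ np.linalg.inv(gram)  # (t, k)
    tt = timecourses.T @ timecourses
    if np.linalg.cond(tt) > 1e12:
        # zero-signal subject: all-zero time courses; maps are zero too
        subject_maps = np.zeros_like(M)
    else:
        subject_maps = np.linalg.solve(tt, timecourses.T @ X)
    return timecourses, subject_maps


def _greedy_match(reference: np.ndarray, candidate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy absolute-correlation assignment of candidate rows to reference rows.

    Returns (permutation, matched |correlation| per reference row).
    """
    k = reference.shape[0]
    corr = np.corrcoef(reference, candidate)[:k, k:]
    corr = np.abs(corr)
    perm = np.full(k, -1)
    matched = np.zeros(k)
    remaining = corr.copy()
    for _ in range(k):
        i, j = np.unravel_index(np.nanargmax(remaining), remaining.shape)
        perm[i] = j
        matched[i] = corr[i, j]
        remaining[i, :] = -np.inf
        remaining[:, j] = -np.inf
    return perm, matched


def stability_restarts(
    whitened: np.ndarray,
    n_restarts: int = 100,
    base_seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-7,
    seeds: list[int] | None = None,
) -> np.ndarray:
    """ICASSO-style stability index per component over random restarts.

    InfoMax is rerun with distinct seeds; each restart's source maps are
    matched to the first (reference) restart's by greedy absolute spatial
    correlation, and the index for a component is the mean matched
    |correlation| across restarts (1.0 = perfectly stable). Diverging
    restarts are excluded with a warning; more than half diverging is an
    error. Passing explicit ``seeds`` overrides ``base_seed`` fan-out.
    """
    if n_restarts < 2:
        raise ValueError("n_restarts must be >= 2")
    if seeds is None:
        seeds = [int(base_seed) + r for r in range(n_restarts)]
    sources = []
    for s in seeds:
        try:
            W = infomax_unmix(whitened, seed=s, max_iter=max_iter, tol=tol)
        except ConfigurationError:
            warnings.warn(f"restart seed {s} diverged; excluded from stability")
            continue
        sources.append(W @ whitened)
    if len(sources) <= len(seeds) // 2:
        raise ConfigurationError("more than half of the ICA restarts diverged")
    ref = sources[0]
    k = ref.shape[0]
    if len(sources) == 1:
        return np.ones(k)
    sums = np.zeros(k)
    for cand in sources[1:]:
        _, matched = _greedy_match(ref, cand)
        sums += matched
    return sums / (len(sources) - 1)


def run_group_ica(
    scans: list[Bold4D],
    n_components: int = 20,
    seed: int = 0,
    k_subject: int | None = None,
    max_iter: int = 1000,
    tol: float = 1e-7,
    n_restarts: int | None = None,
) -> GroupDecomposition:
    """Full group decomposition: reduce, concatenate, unmix, back-project.

    Components are ordered by descending energy in the concatenated group
    space and sign-fixed so each map's maximum-magnitude voxel is positive.
    ``k_subject`` defaults to ``ceil(1.5 * n_components)``, clipped to each
    subject's temporal rank. When ``n_restarts`` is given, restart
    stability indices are computed and stored.
    """
    if len(scans) < 2:
        raise ValueError("group ICA requires at least 2 scans")
    check_consistent_masks(scans)
    if k_subject is None:
        k_subject = int(np.ceil(1.5 * n_components))

    reduced = []
    for scan in scans:
        X = scan.in_mask_matrix()
        Xc = X - X.mean(axis=0)
        cov = Xc @ Xc.T / max(X.shape[1] - 1, 1)
        eigvals = np.linalg.eigvalsh(cov)[::-1]
        rank = int((np.clip(eigvals, 0, None) > _RANK_RTOL * max(eigvals[0], 1e-300)).sum())
        k_i = min(k_subject, rank, scan.n_timepoints)
        if k_i < k_subject:
            logger.info("%s: subject reduction clipped to rank %d", scan.subject_id, k_i)
        r, _ = reduce_subject(scan, k_i)
        reduced.append(r)

    whitened, _group_model = concatenate_and_reduce(reduced, n_components)
    W = infomax_unmix(whitened, seed=seed, max_iter=max_iter, tol=tol)
    sources = W @ whitened  # (n_components, V), ~unit variance rows

    # Order by mixing energy in the whitened group space, fix signs.
    A = np.linalg.inv(W)
    energy = (A**2).sum(axis=0)
    order = np.argsort(energy)[::-1]
    sources = sources[order]
    energy = energy[order]
    peak = np.abs(sources).argmax(axis=1)
    signs = np.sign(sources[np.arange(n_components), peak])
    signs[signs == 0] = 1.0
    sources = sources * signs[:, None]

    timecourses, subject_maps = [], []
    for scan in scans:
        tc, sm = back_project(sources, scan)
        timecourses.append(tc)
        subject_maps.append(sm)

    decomp = GroupDecomposition(
        group_maps=sources,
        subject_timecourses=timecourses,
        subject_maps=subject_maps,
        subject_ids=[s.subject_id for s in scans],
        tr_by_subject=np.array([s.tr_seconds for s in scans]),
        mask=scans[0].mask,
        n_components=n_components,
        seed=int(seed),
        explained_order_energy=energy,
        whitened=whitened,
    )
    if n_restarts is not None and n_restarts >= 2:
        decomp.stability_index = stability_restarts(
            whitened, n_restarts=n_restarts, base_seed=seed, max_iter=max_iter, tol=tol
        )
    return decomp
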