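"""Group spatial ICA: model-order selection, decomposition, RSN labeling.

Order selection maximizes the Laplace approximation to the Bayesian
evidence of a probabilistic PCA model (Minka's criterion) over the
eigen-spectrum of the temporal covariance, with voxels as observations.
Decomposition temporally concatenates all subjects, whitens to the chosen
order and runs a fixed-point negentropy-maximization ICA with symmetric
decorrelation on the spatial dimension, then Z-scales the component maps.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.special import gammaln
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.extmath import randomized_svd

from .containers import GroupICAResult, NetworkTemplate, Volume4D

__all__ = [
    "estimate_model_order",
    "laplace_evidence",
    "group_decompose",
    "classify_components",
    "power_low_ratio",
]

log = logging.getLogger(__name__)


def laplace_evidence(eigvals: np.ndarray, k: int, n_obs: int) -> float:
    """Log Laplace-approximated evidence of a rank-``k`` probabilistic PCA
    model given the covariance eigen-spectrum over ``n_obs`` observations.

    ``eigvals`` are the ``d`` eigenvalues (descending) of the sample
    covariance of ``d``-dimensional data.
    """
    lam = np.asarray(eigvals, dtype=float)
    d = lam.size
    if not 0 < k < d:
        raise ValueError("k must lie in 1..d-1")
    N = n_obs
    v = lam[k:].sum() / (d - k)  # isotropic noise variance estimate
    if v <= 0 or lam[k - 1] <= 0:
        return -np.inf
    # log prior of the principal axes (uniform on the Stiefel manifold)
    pu = -k * np.log(2.0)
    for i in range(1, k + 1):
        pu += gammaln((d - i + 1) / 2.0) - np.log(np.pi) * (d - i + 1) / 2.0
    pl = -0.5 * N * np.log(lam[:k]).sum()
    pv = -0.5 * N * (d - k) * np.log(v)
    m = d * k - k * (k + 1) / 2.0
    pp = np.log(2.0 * np.pi) * (m + k) / 2.0
    # log determinant of the Hessian blocks (pairs of eigen-directions)
    lam_hat = lam.copy()
    lam_hat[k:] = v
    pa = 0.0
    for i in range(k):
        diff = (lam[i] - lam[i + 1:]) * (1.0 / lam_hat[i + 1:] - 1.0 / lam[i])
        if (diff <= 0).any():
            return -np.inf
        pa += np.log(diff).sum() + (d - i - 1) * np.log(N)
    return pu + pl + pv + pp - pa / 2.0 - k * np.log(N) / 2.0


def estimate_model_order(concat_data: np.ndarray, max_order: int | None = None) -> int:
    """Estimate the pPCA model order of a ``samples x voxels`` matrix.

    Observations are voxels; the evidence is evaluated over candidate
    orders ``1 .. samples - 2`` (optionally capped by ``max_order``).
    Trailing zero eigenvalues (rank-deficient input) truncate the candidate
    range with a logged warning.
    """
    X = np.asarray(concat_data, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 samples")
    if p <= n:
        raise ValueError("need more voxels than samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = (Xc @ Xc.T) / (p - 1)
    lam = np.linalg.eigvalsh(cov)[::-1]
    lam = np.clip(lam, 0.0, None)
    tol = lam[0] * n * np.finfo(float).eps
    rank = int((lam > tol).sum())
    hi = n - 2
    if rank < n:
        log.warning(
            "rank-deficient input (numerical rank %d < %d samples); "
            "evidence computed up to the rank", rank, n,
        )
        if rank <= hi and (max_order is None or rank <= max_order):
            # exactly low-rank data: the rank-`rank` model fits perfectly
            # (zero residual variance), so its evidence is unbounded
            return rank
        hi = min(hi, rank - 1)
    if max_order is not None:
        hi = min(hi, max_order)
    ks = range(1, hi + 1)
    evid = [laplace_evidence(lam, k, p) for k in ks]
    return int(np.argmax(evid) + 1)


def _concatenate(subjects: list[Volume4D]) -> tuple[np.ndarray, np.ndarray, list]:
    mask = subjects[0].mask
    shape = subjects[0].shape3d
    for s in subjects[1:]:
        if s.shape3d != shape or not np.array_equal(s.mask, mask):
            raise ValueError("all subjects must share the same grid and mask")
    blocks, lengths = [], []
    for s in subjects:
        ts = s.timeseries()
        ts = ts - ts.mean(axis=0, keepdims=True)
        blocks.append(ts)
        lengths.append(ts.shape[0])
    return np.vstack(blocks), mask, lengths


def group_decompose(
    subjects: list[Volume4D],
    order: int,
    seed: int,
    max_restarts: int = 5,
) -> GroupICAResult:
    """Temporal-concatenation group spatial ICA at a fixed model order.

    Fixed-point (negentropy) iterations with symmetric decorrelation,
    convergence tolerance 1e-6, at most 500 iterations; non-convergence is
    retried up to ``max_restarts`` times with perturbed seeds.
    """
    if order < 2:
        raise ValueError("order must be at least 2")
    X, mask, lengths = _concatenate(subjects)
    X = X - X.mean(axis=0, keepdims=True)
    n_vox = X.shape[1]
    # spatial whitening via PCA of the concatenated data
    U, S, Vt = randomized_svd(X, n_components=order, random_state=seed, n_iter=7)
    white = Vt * np.sqrt(n_vox)  # (order, voxels), rows ~ unit-variance, orthogonal

    last_err: Exception | None = None
    for attempt in range(max_restarts):
        ica = FastICA(
            whiten=False,
            fun="logcosh",
            algorithm="parallel",
            max_iter=500,
            tol=1e-6,
            random_state=seed + 1000 * attempt,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(white.T).T  # (order, voxels)
                break
            except ConvergenceWarning as err:
                last_err = err
                log.warning("ICA did not converge (attempt %d); restarting", attempt + 1)
    else:
        raise RuntimeError(
            f"ICA failed to converge after {max_restarts} restarts"
        ) from last_err

    # Z-scale maps and fix sign so the heavier tail is positive
    maps = sources - sources.mean(axis=1, keepdims=True)
    maps /= maps.std(axis=1, keepdims=True)
    skew = (maps**3).mean(axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    maps *= flip[:, None]
    # sort components deterministically by peak voxel position, then by
    # decreasing peak amplitude, to decouple ordering from ICA internals
    peak_idx = np.argmax(np.abs(maps), axis=1)
    order_idx = np.lexsort((-np.abs(maps).max(axis=1), peak_idx))
    maps = maps[order_idx]

    # time courses: least-squares projection of the data onto the maps
    tcs, *_ = np.linalg.lstsq(maps.T, X.T, rcond=None)
    tcs = tcs.T  # (total_T, order)

    result = GroupICAResult(
        spatial_maps=maps,
        timecourses=tcs,
        order=order,
        mask=mask,
        tr=subjects[0].tr,
        subject_lengths=lengths,
    )
    result.power_low_ratio = power_low_ratio(result)
    return result


def power_low_ratio(result: GroupICAResult, band: tuple = (0.01, 0.1)) -> np.ndarray:
    """Fraction of each component time course's spectral power in ``band``.

    Spectra are computed per subject segment and averaged, excluding DC.
    """
    ratios = np.zeros(result.order)
    start = 0
    pow_band = np.zeros(result.order)
    pow_tot = np.zeros(result.order)
    for L in result.subject_lengths:
        seg = result.timecourses[start:start + L]
        start += L
        freqs = np.fft.rfftfreq(L, d=result.tr)
        spec = np.abs(np.fft.rfft(seg - seg.mean(axis=0), axis=0)) ** 2
        keep = freqs > 0
        inband = keep & (freqs >= band[0]) & (freqs <= band[1])
        pow_band += spec[inband].sum(axis=0)
        pow_tot += spec[keep].sum(axis=0)
    ok = pow_tot > 0
    ratios[ok] = pow_band[ok] / pow_tot[ok]
    return ratios


def classify_components(
    result: GroupICAResult,
    templates: list[NetworkTemplate],
    r_min: float = 0.4,
    p_min: float = 0.5,
) -> GroupICAResult:
    """Label components as RSNs (best-matching template) or artifacts.

    A component gets a template's name iff its best absolute spatial
    correlation is >= ``r_min`` and its low-frequency power ratio is >=
    ``p_min``; each template is assigned at most once, greedily by
    correlation with ties broken by lower component index.
    """
    if not templates:
        raise ValueError("templates must be nonempty")
    if result.power_low_ratio is None:
        result.power_low_ratio = power_low_ratio(result)
    tmpl_mat = np.stack([t.map[result.mask] for t in templates])
    cors = np.zeros((result.order, len(templates)))
    for i in range(result.order):
        for j in range(len(templates)):
            cors[i, j] = abs(np.corrcoef(result.spatial_maps[i], tmpl_mat[j])[0, 1])
    labels = ["artifact"] * result.order
    pairs = sorted(
        ((i, j) for i in range(result.order) for j in range(len(templates))),
        key=lambda ij: (-cors[ij], ij[0]),
    )
    used_c, used_t = set(), set()
    for i, j in pairs:
        if i in used_c or j in used_t:
            continue
        if cors[i, j] < r_min:
            break
        if result.power_low_ratio[i] >= p_min:
            labels[i] = templates[j].name
            used_c.add(i)
            used_t.add(j)
    result.labels = labels
    return result
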