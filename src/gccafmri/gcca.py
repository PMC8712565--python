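"""Common spatial subspace estimation via generalized CCA (MAXVAR).

Each subject's preprocessed ``voxels x time`` matrix spans a low-dimensional
spatial subspace (its left singular vectors). The MAXVAR generalized
canonical correlation solution finds directions that are maximally captured
by *every* subject's span: stacking the per-subject orthonormal bases
column-wise and taking the SVD, the leading left singular vectors maximize
the summed squared projections onto all subject subspaces — equivalently
they are the top eigenvectors of the sum of subject projection matrices
``sum_k U_k U_k^T``.

Each direction carries a *commonness score* in (0, 1]: the squared stacked
singular value divided by the number of subjects, so a direction lying in
every subject's span scores exactly 1 and a direction in none scores 0.
Projecting all subjects' data onto the leading common directions suppresses
responses not shared across the cohort — the denoising step that produces
the "gCCA-processed" arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import GridSpec, SubjectTimeseries

__all__ = [
    "SubjectBasis",
    "CommonSubspace",
    "subject_basis",
    "estimate_common_subspace",
    "select_dimension",
    "csf_overlap_filter",
    "project_denoise",
]


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(basis), axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    return basis * signs


@dataclass
class SubjectBasis:
    """Orthonormal spatial basis of one subject's data span."""

    basis: np.ndarray  # voxels x r
    singular_values: np.ndarray
    subject_id: str = "sub-00"

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        r = self.basis.shape[1]
        if self.singular_values.size != r:
            raise ValueError("one singular value per basis column required")
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be non-increasing")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(r), atol=1e-10):
            raise ValueError("basis columns are not orthonormal")

    @property
    def rank(self) -> int:
        return self.basis.shape[1]


@dataclass
class CommonSubspace:
    """Orthonormal basis of the estimated common spatial subspace.

    ``scores[i]`` is the commonness of direction i, normalized to (0, 1].
    """

    basis: np.ndarray  # voxels x d
    scores: np.ndarray
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        d = self.basis.shape[1]
        if d < 1:
            raise ValueError("subspace must have at least one direction")
        if self.scores.size != d:
            raise ValueError("one score per basis column required")
        if np.any(np.diff(self.scores) > 1e-10):
            raise ValueError("scores must be sorted non-increasing")
        if np.any(self.scores <= 0) or np.any(self.scores > 1 + 1e-10):
            raise ValueError("scores must lie in (0, 1]")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(d), atol=1e-10):
            raise ValueError("basis columns are not orthonormal")

    @property
    def dim(self) -> int:
        return self.basis.shape[1]


def subject_basis(
    ts: SubjectTimeseries | np.ndarray,
    energy_keep: float = 0.95,
    subject_id: str | None = None,
) -> SubjectBasis:
    """Left singular vectors retaining ``energy_keep`` of squared-singular-value energy.

    The smallest rank whose cumulative squared singular values reach the
    requested fraction is kept. Signs are fixed (largest-magnitude entry of
    each column positive) so results are deterministic.
    """
    if not 0 < energy_keep <= 1:
        raise ValueError("energy_keep must lie in (0, 1]")
    data = ts.data if isinstance(ts, SubjectTimeseries) else np.asarray(ts, float)
    sid = subject_id or (ts.subject_id if isinstance(ts, SubjectTimeseries)
                         else "sub-00")
    if not np.any(data):
        raise ValueError(f"all-zero data for {sid}")
    U, s, _ = np.linalg.svd(data, full_matrices=False)
    nonzero = s > s[0] * 1e-12
    U, s = U[:, nonzero], s[nonzero]
    energy = np.cumsum(s ** 2) / np.sum(s ** 2)
    r = int(np.searchsorted(energy, energy_keep - 1e-12) + 1)
    return SubjectBasis(
        basis=_fix_signs(U[:, :r]), singular_values=s[:r], subject_id=sid
    )


def estimate_common_subspace(
    bases: list[SubjectBasis],
    d: int | None = None,
    dim_threshold: float = 0.75,
    dim_method: str = "threshold",
    grid: GridSpec | None = None,
    route: str = "direct",
) -> CommonSubspace:
    """MAXVAR gCCA: SVD of the column-stacked subject bases.

    With stacked matrix ``S = [U_1 ... U_K]`` (voxels x sum r_k) and SVD
    ``S = W diag(sigma) V^T``, the common basis is the leading columns of
    ``W`` and the scores are ``sigma^2 / K``. If ``d`` is omitted the
    dimension is chosen by :func:`select_dimension` on the scores.

    ``route='gram'`` solves the (sum r_k)-sized eigenproblem of ``S^T S``
    instead of the voxel-sided SVD — cheaper when voxels greatly outnumber
    stacked columns; the two routes agree to about 1e-8.
    """
    if len(bases) < 2:
        raise ValueError("need at least 2 subjects")
    V = bases[0].basis.shape[0]
    for b in bases:
        if b.basis.shape[0] != V:
            raise ValueError(
                f"subject {b.subject_id} has {b.basis.shape[0]} voxels, "
                f"expected {V}"
            )
    K = len(bases)
    stacked = np.concatenate([b.basis for b in bases], axis=1)
    if route == "direct":
        W, s, _ = np.linalg.svd(stacked, full_matrices=False)
    elif route == "gram":
        evals, evecs = np.linalg.eigh(stacked.T @ stacked)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
        s = np.sqrt(evals)
        pos = s > s[0] * 1e-12
        W = (stacked @ evecs[:, pos]) / s[pos]
        s = s[pos]
    else:
        raise ValueError(f"unknown route {route!r}")
    scores = s ** 2 / K
    keep = scores > 1e-12
    W, scores = W[:, keep], scores[keep]
    if d is None:
        d = select_dimension(scores, threshold=dim_threshold, method=dim_method)
    if not 1 <= d <= W.shape[1]:
        raise ValueError(f"d={d} outside [1, {W.shape[1]}]")
    return CommonSubspace(
        basis=_fix_signs(W[:, :d]),
        scores=np.minimum(scores[:d], 1.0),
        grid=grid,
    )


def select_dimension(
    scores: np.ndarray, threshold: float = 0.75, method: str = "threshold"
) -> int:
    """Data-driven common-subspace dimension from the commonness scores.

    ``threshold``: count of scores >= threshold. ``gap``: index before the
    largest consecutive drop. Never returns 0: if nothing qualifies, 1 is
    returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    if np.any(np.diff(scores) > 1e-10):
        raise ValueError("scores must be sorted non-increasing")
    if method == "threshold":
        d = int(np.sum(scores >= threshold))
    elif method == "gap":
        if scores.size == 1:
            d = 1
        else:
            d = int(np.argmax(-np.diff(scores)) + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    if d == 0:
        warnings.warn(
            f"no commonness score reached {threshold}; keeping 1 dimension",
            stacklevel=2,
        )
        d = 1
    return d


def csf_overlap_filter(
    subspace: CommonSubspace,
    csf_mask: np.ndarray,
    overlap_frac: float = 0.5,
    grid: GridSpec | None = None,
) -> CommonSubspace:
    """Drop basis directions whose squared mass inside a CSF mask exceeds a fraction.

    For each column, overlap = (sum of squared entries at CSF voxels) /
    (total squared entries); columns with overlap strictly greater than
    ``overlap_frac`` are removed and the remainder re-orthonormalized.
    """
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must lie in (0, 1]")
    grid = grid or subspace.grid
    if grid is None:
        raise ValueError("a GridSpec is required to interpret the CSF mask")
    csf_mask = np.asarray(csf_mask, dtype=bool)
    if csf_mask.shape != grid.dims:
        raise ValueError(
            f"CSF mask shape {csf_mask.shape} != grid dims {grid.dims}"
        )
    inside = grid.extract(csf_mask)  # boolean over masked voxels
    sq = subspace.basis ** 2
    overlap = sq[inside].sum(axis=0) / sq.sum(axis=0)
    keep = overlap <= overlap_frac
    if not keep.any():
        raise ValueError(
            "CSF overlap filter would remove every common component "
            f"(overlaps: {np.round(overlap, 3)})"
        )
    basis = subspace.basis[:, keep]
    # Columns of an orthonormal set stay orthonormal after deletion; a QR
    # pass guards against accumulated round-off.
    q, r = np.linalg.qr(basis)
    q = _fix_signs(q * np.sign(np.diag(r)))
    return CommonSubspace(basis=q, scores=subspace.scores[keep], grid=grid)


def project_denoise(
    ts: SubjectTimeseries, subspace: CommonSubspace
) -> SubjectTimeseries:
    """Orthogonal projection of a subject's data onto the common subspace."""
    B = subspace.basis
    if ts.data.shape[0] != B.shape[0]:
        raise ValueError(
            f"data has {ts.data.shape[0]} voxels, subspace has {B.shape[0]}"
        )
    return ts.copy_with(B @ (B.T @ ts.data))
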