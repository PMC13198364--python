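"""Synthetic paired multi-omic data with known ground truth.

Emulates a co-assay: one latent cluster structure (a Gaussian mixture of
cell types, or optionally a 1-D trajectory) observed through two different
feature-space maps, giving two modalities with a known 1-1 cell
correspondence, known feature pairs, and — via per-cell-type downsampling —
controllable cell-type imbalance.  Every downstream solver and metric is
therefore testable without external downloads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import OmicsDataset
from .ot_core import DomainError

__all__ = ["SyntheticMultiOmic", "make_multiomic", "downsample_by_type"]

logger = logging.getLogger(__name__)

NONLINEARITIES = {
    "none": lambda z: z,
    "tanh": np.tanh,
    "quadratic": lambda z: z + 0.25 * z**2,
}


@dataclass
class SyntheticMultiOmic:
    """Two generated modalities plus every piece of ground truth."""

    X: OmicsDataset
    Y: OmicsDataset
    cell_pairs: list[tuple[int, int]]
    feature_pairs: list[tuple[int, int]]
    latent: np.ndarray
    seed: int


def _shared_maps(dx: int, dy: int, p: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Two feature maps (dx x p, dy x p) sharing their first min(dx,dy) rows.

    Rows of one tall matrix with orthonormal columns are distributed between
    the two maps; the first q = min(dx, dy) rows are common to both, so
    feature a of X and feature a of Y (a < q) load on the same latent
    directions.  When dx == dy the maps coincide and are exact isometries
    (up to the per-domain scale applied by the caller); otherwise they are
    near-isometries.
    """
    q = min(dx, dy)
    total = dx + dy - q
    G = rng.standard_normal((total, p))
    O, _ = np.linalg.qr(G)  # total x p, orthonormal columns
    A = np.vstack([O[:q], O[q:dx]])
    B = np.vstack([O[:q], O[dx : dx + (dy - q)]])
    return A, B


def make_multiomic(
    n_cells: int = 100,
    n_types: int = 3,
    dx: int = 10,
    dy: int = 10,
    nonlinearity: str = "none",
    noise_sd: float = 0.05,
    seed: int = 0,
    latent_dim: int | None = None,
    center_scale: float = 4.0,
    within_sd: float = 0.6,
    scale_x: float = 1.0,
    scale_y: float = 1.5,
    trajectory: bool = False,
) -> SyntheticMultiOmic:
    """Generate a paired two-modality dataset from one latent structure.

    Latent cells are a Gaussian mixture of ``n_types`` well-separated
    clusters (centers ~ N(0, center_scale^2), within-cluster sd
    ``within_sd``), or a 1-D trajectory when ``trajectory=True``.  The two
    modalities are ``X = scale_x * latent @ A^T + noise`` and
    ``Y = g(scale_y * latent @ B^T) + noise`` with ``g`` the chosen
    nonlinearity and A, B maps sharing their first min(dx, dy) rows (the
    ground-truth feature pairs).  Cell i of X corresponds to cell i of Y.

    Fully reproducible from ``seed``.
    """
    if n_types < 1 or n_cells < n_types:
        raise DomainError("need 1 <= n_types <= n_cells")
    if dx < 2 or dy < 2:
        raise DomainError("feature dimensions must be >= 2")
    if nonlinearity not in NONLINEARITIES:
        raise DomainError(f"nonlinearity must be one of {sorted(NONLINEARITIES)}")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    p = latent_dim if latent_dim is not None else max(2, min(n_types, min(dx, dy)))
    if p > min(dx, dy):
        raise DomainError("latent_dim cannot exceed min(dx, dy)")

    rng = np.random.default_rng(seed)
    if trajectory:
        t = np.sort(rng.uniform(0.0, 1.0, n_cells))
        direction = rng.standard_normal(p)
        direction /= np.linalg.norm(direction)
        latent = center_scale * t[:, None] * direction[None, :]
        latent += within_sd * 0.1 * rng.standard_normal((n_cells, p))
        labels = np.digitize(t, np.linspace(0, 1, n_types + 1)[1:-1]).astype(str)
    else:
        # Cell types are modelled as separated clusters: centers are redrawn
        # until all pairwise gaps exceed several within-cluster sds (the scale
        # grows if the draw keeps failing), so types never merge by accident.
        min_sep = 6.0 * within_sd
        scale = center_scale
        while True:
            centers = scale * rng.standard_normal((n_types, p))
            if n_types == 1:
                break
            gaps = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
            if gaps[np.triu_indices(n_types, 1)].min() >= min_sep:
                break
            scale *= 1.05
        # Real cell types differ in abundance and spread; distinct proportions
        # (~ 1 : 2 : ... : n_types) and per-type dispersions also break the
        # cluster-permutation symmetry that makes perfectly exchangeable
        # clusters unidentifiable for purely geometric alignment.
        weights = np.arange(1, n_types + 1, dtype=float)
        counts = np.floor(n_cells * weights / weights.sum()).astype(int)
        counts[counts == 0] = 1
        counts[-1] += n_cells - counts.sum()
        sd_factors = np.linspace(0.7, 1.3, n_types)
        labels_int = np.repeat(np.arange(n_types), counts)
        latent = centers[labels_int] + (
            within_sd * sd_factors[labels_int][:, None]
        ) * rng.standard_normal((n_cells, p))
        labels = labels_int.astype(str)

    A, B = _shared_maps(dx, dy, p, rng)
    g = NONLINEARITIES[nonlinearity]
    Xm = scale_x * latent @ A.T
    Ym = g(scale_y * latent @ B.T)
    if noise_sd > 0:
        Xm = Xm + noise_sd * rng.standard_normal(Xm.shape)
        Ym = Ym + noise_sd * rng.standard_normal(Ym.shape)

    labels = np.array([f"type{t}" for t in labels])
    X = OmicsDataset(
        matrix=Xm,
        sample_ids=[f"cellX{i}" for i in range(n_cells)],
        feature_ids=[f"fx{a}" for a in range(dx)],
        labels=labels.copy(),
    )
    Y = OmicsDataset(
        matrix=Ym,
        sample_ids=[f"cellY{i}" for i in range(n_cells)],
        feature_ids=[f"fy{a}" for a in range(dy)],
        labels=labels.copy(),
    )
    q = min(dx, dy)
    return SyntheticMultiOmic(
        X=X,
        Y=Y,
        cell_pairs=[(i, i) for i in range(n_cells)],
        feature_pairs=[(a, a) for a in range(q)],
        latent=latent,
        seed=seed,
    )


def downsample_by_type(
    data: OmicsDataset,
    max_fraction: float,
    seed: int,
    fractions: dict | None = None,
) -> tuple[OmicsDataset, np.ndarray]:
    """Discard a random fraction of each cell type's cells.

    For each type, a fraction ``f ~ Uniform(0, max_fraction)`` is drawn and
    ``round(f * n_type)`` uniformly chosen cells of that type are removed
    (round-half-even).  Applying this independently to the two modalities
    with different seeds produces the unbalanced cell-type regime.  Explicit
    per-type ``fractions`` override the random draw (for controlled tests).

    Returns the surviving dataset and the kept indices (into the original
    row order) for correspondence bookkeeping.
    """
    if data.labels is None:
        raise DomainError("downsample_by_type requires cell-type labels")
    if not (0.0 <= max_fraction <= 1.0):
        raise DomainError("max_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = np.asarray(data.labels)
    keep_mask = np.ones(data.n_cells, dtype=bool)
    for t in sorted(map(str, np.unique(labels))):
        members = np.flatnonzero(labels.astype(str) == t)
        f = (
            float(fractions[t])
            if fractions is not None and t in fractions
            else rng.uniform(0.0, max_fraction)
        )
        n_remove = int(np.round(f * members.size))
        if n_remove >= members.size:
            raise DomainError(
                f"type {t!r} would be reduced to zero cells (f={f:.3f})"
            )
        drop = rng.choice(members, size=n_remove, replace=False)
        keep_mask[drop] = False
    kept = np.flatnonzero(keep_mask)
    return data.subset(kept), kept
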