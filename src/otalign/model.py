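"""Model / Results surface over the alignment engine.

``MultiOmicAlignment`` is built from two datasets (plus options); ``fit()``
runs the preprocessing and block-coordinate-descent solver and returns an
``AlignmentResults`` object carrying the fitted couplings, diagnostics,
metric helpers and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from . import evaluate as _ev
from .formulations import (
    MODES,
    AlignmentResult,
    SolverConfig,
    align,
    coupling_density,
)
from .geometry import DistanceMatrix, knn_geodesic, normalize_distances, reduce_pca
from .io import OmicsDataset
from .ot_core import Marginal

__all__ = ["MultiOmicAlignment", "AlignmentResults"]

logger = logging.getLogger(__name__)


def _as_dataset(obj, prefix: str) -> OmicsDataset:
    if isinstance(obj, OmicsDataset):
        return obj
    m = np.asarray(obj, dtype=float)
    return OmicsDataset(
        matrix=m,
        sample_ids=[f"{prefix}{i}" for i in range(m.shape[0])],
        feature_ids=[f"{prefix}f{a}" for a in range(m.shape[1])],
    )


def _preprocess(matrix: np.ndarray, normalize: str, pca_components: int | None):
    Z = np.asarray(matrix, dtype=float)
    if normalize == "l2":
        norms = np.linalg.norm(Z, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        Z = Z / norms
    elif normalize == "zscore":
        sd = Z.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (Z - Z.mean(axis=0, keepdims=True)) / sd
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    if pca_components is not None:
        Z = reduce_pca(Z, pca_components)
    return Z


class MultiOmicAlignment:
    """Alignment model for two separately assayed modalities.

    Parameters
    ----------
    X, Y : OmicsDataset or array_like
        The two modalities, cells as rows.
    mode : str
        One of ``gw``, ``ugw``, ``coot``, ``ucoot``, ``agw``, ``uagw``.
    config : SolverConfig, optional
        Solver hyperparameters; sensible defaults otherwise.
    normalize : str
        Per-cell/feature normalization applied before anything else:
        ``none`` (default), ``l2`` (per-cell), or ``zscore`` (per-feature).
    pca_components : int, optional
        Reduce each modality to this many principal components first.
    k_neighbors : int
        Neighborhood size of the geodesic kNN graph (GW-bearing modes).
    normalize_dist : bool
        Rescale each geodesic matrix to max 1 (default) so eps is
        comparable across domains.
    """

    def __init__(
        self,
        X,
        Y,
        mode: str = "gw",
        config: SolverConfig | None = None,
        normalize: str = "none",
        pca_components: int | None = None,
        k_neighbors: int = 30,
        normalize_dist: bool = True,
    ):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.X = _as_dataset(X, "x")
        self.Y = _as_dataset(Y, "y")
        self.mode = mode
        self.config = config if config is not None else SolverConfig()
        self.normalize = normalize
        self.pca_components = pca_components
        self.k_neighbors = k_neighbors
        self.normalize_dist = normalize_dist

        self._Xp = _preprocess(self.X.matrix, normalize, pca_components)
        self._Yp = _preprocess(self.Y.matrix, normalize, pca_components)
        self._DX: DistanceMatrix | None = None
        self._DY: DistanceMatrix | None = None

    @classmethod
    def from_datasets(cls, X: OmicsDataset, Y: OmicsDataset, **kwargs):
        return cls(X, Y, **kwargs)

    def _needs_geometry(self) -> bool:
        if self.mode in ("gw", "ugw"):
            return True
        if self.mode in ("coot", "ucoot"):
            return False
        return self.config.alpha > 0

    def distances(self) -> tuple[DistanceMatrix, DistanceMatrix]:
        """Geodesic distance matrices of the two (preprocessed) modalities."""
        if self._DX is None:
            kx = min(self.k_neighbors, self._Xp.shape[0] - 1)
            ky = min(self.k_neighbors, self._Yp.shape[0] - 1)
            if kx < self.k_neighbors or ky < self.k_neighbors:
                logger.info("k_neighbors clipped to n-1 for a small dataset")
            DX = knn_geodesic(self._Xp, kx)
            DY = knn_geodesic(self._Yp, ky)
            if self.normalize_dist:
                DX = normalize_distances(DX)
                DY = normalize_distances(DY)
            self._DX, self._DY = DX, DY
        return self._DX, self._DY

    def fit(self, **config_overrides) -> "AlignmentResults":
        """Run the block-coordinate-descent solver; returns fitted results."""
        cfg = replace(self.config, **config_overrides) if config_overrides else self.config
        DX = DY = None
        if self._needs_geometry():
            DX, DY = self.distances()
        core = align(
            self.mode,
            X=self._Xp,
            Y=self._Yp,
            DX=DX,
            DY=DY,
            mu_s1=Marginal.uniform(self.X.n_cells),
            mu_s2=Marginal.uniform(self.Y.n_cells),
            config=cfg,
        )
        return AlignmentResults(self, core)


class AlignmentResults:
    """Fitted couplings with diagnostics, metrics and a summary table."""

    def __init__(self, model: MultiOmicAlignment, core: AlignmentResult):
        self.model = model
        self.core = core

    # -- estimates ---------------------------------------------------------
    @property
    def P(self):
        """Primary sample coupling (cells of X -> cells of Y)."""
        return self.core.P

    @property
    def P_prime(self):
        return self.core.P_prime

    @property
    def Q(self):
        """Feature coupling, present iff the COOT term is active."""
        return self.core.Q

    @property
    def loss_trace(self):
        return self.core.loss_trace

    @property
    def converged(self):
        return self.core.converged

    # -- downstream --------------------------------------------------------
    def project(self, direction: str = "xy") -> np.ndarray:
        """Barycentric projection: ``xy`` puts X's cells in Y's feature
        space, ``yx`` the reverse."""
        if direction == "xy":
            return _ev.barycentric_project(self.P, self.model._Yp)
        if direction == "yx":
            return _ev.barycentric_project(self.P.plan.T, self.model._Xp)
        raise ValueError("direction must be 'xy' or 'yx'")

    def foscttm(self) -> float:
        """FOSCTTM of the projected-X vs Y embedding (requires equal cell
        counts with rows matched by index)."""
        if self.model.X.n_cells != self.model.Y.n_cells:
            raise ValueError("FOSCTTM requires a known 1-1 correspondence")
        return _ev.foscttm(self.project("xy"), self.model._Yp)

    def label_transfer_accuracy(self) -> float:
        """kNN label-transfer accuracy: classifier trained on Y (original
        domain), evaluated on X's cells projected into Y's space."""
        if self.model.X.labels is None or self.model.Y.labels is None:
            raise ValueError("both datasets need labels for LTA")
        proj = self.project("xy")
        ok = ~np.isnan(proj).any(axis=1)
        return _ev.label_transfer_accuracy(
            self.model._Yp, self.model.Y.labels, proj[ok], self.model.X.labels[ok]
        )

    def diagnostics(self) -> dict:
        d = {
            "mode": self.model.mode,
            "n_cells_x": self.model.X.n_cells,
            "n_cells_y": self.model.Y.n_cells,
            "converged": bool(self.converged),
            "n_sweeps": int(len(self.loss_trace)),
            "final_loss": float(self.loss_trace[-1]),
            "mass_P": self.P.total_mass,
            "density_P": coupling_density(self.P),
        }
        if self.Q is not None:
            d["mass_Q"] = self.Q.total_mass
            d["density_Q"] = coupling_density(self.Q)
        return d

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        d = self.diagnostics()
        cfg = self.core.config_used
        lines = [
            "Multi-omic OT alignment results",
            "=" * 47,
            f"{'formulation':<28}{d['mode']:>19}",
            f"{'cells (X, Y)':<28}{str((d['n_cells_x'], d['n_cells_y'])):>19}",
            f"{'alpha':<28}{cfg.alpha:>19.3g}",
            f"{'eps (gw, coot)':<28}{f'{cfg.eps_gw:.3g}, {cfg.eps_coot:.3g}':>19}",
            f"{'rho_gw':<28}{f'{cfg.rho_gw1:.3g}, {cfg.rho_gw2:.3g}':>19}",
            f"{'rho_coot':<28}{f'{cfg.rho_coot1:.3g}, {cfg.rho_coot2:.3g}':>19}",
            f"{'BCD sweeps':<28}{d['n_sweeps']:>19d}",
            f"{'converged':<28}{str(d['converged']):>19}",
            f"{'final objective':<28}{d['final_loss']:>19.6g}",
            f"{'coupling mass (P)':<28}{d['mass_P']:>19.6g}",
            f"{'coupling density (P)':<28}{d['density_P']:>19.3g}",
        ]
        if self.Q is not None:
            lines.append(f"{'coupling mass (Q)':<28}{d['mass_Q']:>19.6g}")
            lines.append(f"{'coupling density (Q)':<28}{d['density_Q']:>19.3g}")
        lines.append("=" * 47)
        return "\n".join(lines)
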