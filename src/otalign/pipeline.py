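"""End-to-end pipeline and grid-search runner on top of the model surface."""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .formulations import SolverConfig, coupling_density
from .io import OmicsDataset, RunConfig, read_dataset, read_labels, write_coupling
from .model import MultiOmicAlignment

__all__ = ["run_pipeline", "grid_search", "solver_config_from_run_config"]

logger = logging.getLogger(__name__)


def solver_config_from_run_config(rc: RunConfig) -> SolverConfig:
    return SolverConfig(
        alpha=rc.alpha,
        eps_gw=rc.eps_gw,
        eps_coot=rc.eps_coot,
        rho_gw1=rc.rho_gw1,
        rho_gw2=rc.rho_gw2,
        rho_coot1=rc.rho_coot1,
        rho_coot2=rc.rho_coot2,
        beta_sample=rc.beta_sample,
        beta_feature=rc.beta_feature,
        n_outer=rc.n_outer,
        inner_max_iter=rc.inner_max_iter,
        inner_tol=rc.inner_tol,
        seed=rc.seed,
    )


def _attach_labels(ds: OmicsDataset, labels_path) -> OmicsDataset:
    if labels_path is None:
        return ds
    mapping = read_labels(labels_path)
    missing = [s for s in ds.sample_ids if s not in mapping]
    if missing:
        raise ValueError(
            f"labels file {labels_path} missing {len(missing)} sample ids "
            f"(first: {missing[0]!r})"
        )
    ds.labels = np.array([mapping[s] for s in ds.sample_ids])
    return ds


def run_pipeline(
    config: RunConfig, X: OmicsDataset | None = None, Y: OmicsDataset | None = None
):
    """normalize -> optional PCA -> geodesics -> align -> project -> metrics.

    Datasets may be passed in memory; otherwise they are read from the paths
    in ``config``.  Writes couplings (dense TSV with ids), the projected
    data, the loss trace, a JSON metrics report and the full configuration
    (with the package version) into ``config.out_dir``.  Returns
    ``(AlignmentResults, metrics dict)``.
    """
    if X is None:
        if config.x_path is None:
            raise ValueError("config.x_path is required when X is not supplied")
        X = read_dataset(config.x_path, transpose=config.transpose)
        X = _attach_labels(X, config.x_labels_path)
    if Y is None:
        if config.y_path is None:
            raise ValueError("config.y_path is required when Y is not supplied")
        Y = read_dataset(config.y_path, transpose=config.transpose)
        Y = _attach_labels(Y, config.y_labels_path)

    logger.info(
        "run_pipeline mode=%s n_x=%d n_y=%d version=%s",
        config.mode,
        X.n_cells,
        Y.n_cells,
        __version__,
    )
    model = MultiOmicAlignment(
        X,
        Y,
        mode=config.mode,
        config=solver_config_from_run_config(config),
        normalize=config.normalize,
        pca_components=config.pca_components,
        k_neighbors=config.k_neighbors,
        normalize_dist=config.normalize_distances,
    )
    res = model.fit()

    metrics = res.diagnostics()
    if (
        config.compute_foscttm
        and X.n_cells == Y.n_cells
    ):
        metrics["foscttm"] = res.foscttm()
    if config.compute_lta and X.labels is not None and Y.labels is not None:
        metrics["label_transfer_accuracy"] = res.label_transfer_accuracy()
    metrics["version"] = __version__
    metrics["config"] = json.loads(config.to_json())

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_coupling(res.P.plan, X.sample_ids, Y.sample_ids, out / "coupling_P.tsv")
    if res.Q is not None:
        write_coupling(res.Q.plan, X.feature_ids, Y.feature_ids, out / "coupling_Q.tsv")
    proj = res.project("xy")
    pd.DataFrame(proj, index=X.sample_ids).to_csv(out / "projected_X.tsv", sep="\t")
    np.savetxt(out / "loss_trace.txt", res.loss_trace)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float) + "\n")
    config.to_json(out / "config.json")
    return res, metrics


def grid_search(
    base_config: RunConfig,
    grid: dict,
    X: OmicsDataset | None = None,
    Y: OmicsDataset | None = None,
    rank_by: str = "foscttm",
    ascending: bool = True,
) -> pd.DataFrame:
    """Run every hyperparameter combination; rank by the chosen metric.

    ``grid`` maps RunConfig field names (e.g. ``eps_gw``, ``rho_gw1``,
    ``alpha``) to value lists.  Each run's metrics plus the coupling-density
    diagnostic are recorded; failed runs appear as rows with an ``error``
    column and do not stop the search.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    keys = sorted(grid)
    records = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, combo))
        cfg = dataclasses.replace(base_config, **overrides)
        cfg.out_dir = str(Path(base_config.out_dir) / "_".join(
            f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}" for k, v in overrides.items()
        ))
        row = dict(overrides)
        try:
            _, metrics = run_pipeline(cfg, X=X, Y=Y)
            row.update(
                {
                    k: v
                    for k, v in metrics.items()
                    if isinstance(v, (int, float, bool)) and not isinstance(v, dict)
                }
            )
        except Exception as exc:  # keep the grid alive, record the failure
            logger.warning("grid point %s failed: %s", overrides, exc)
            row["error"] = str(exc)
        records.append(row)
    df = pd.DataFrame.from_records(records)
    if rank_by in df.columns:
        df = df.sort_values(rank_by, ascending=ascending, kind="mergesort").reset_index(
            drop=True
        )
    return df
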