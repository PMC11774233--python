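"""Config-driven end-to-end pipeline.

One flat key=value config file drives the full analysis:
ingest → descriptor → (resample/subsample/scale) → statistics →
optional embedding → optional clustering + per-cluster property summary.
Every output is a CSV keyed by (traj, time) plus a JSON manifest recording
the seeds and parameters actually used, so a fixed config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import cluster_statistics, rmsd_series
from .clustering import run_algorithm, select_k_best
from .datasets import load_ensemble, write_dataset_csv
from .descriptors import DESCRIPTOR_CHOICES, descriptor_dataset
from .embedding import isomap_fit_transform, pca_fit_transform, tsne_fit_transform
from .exceptions import ConfigError, NamdclustError
from .preprocess import apply_scaler, random_subsample, resample_by_stride

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]


class StageError(NamdclustError):
    """A pipeline stage failed; ``stage`` names it and ``cause`` is kept."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat pipeline configuration (all keys accepted in the config file).

    ``n_clusters`` accepts an integer or ``"best"`` (requires ``k_range``,
    e.g. ``2:6``).  ``embed_method`` / ``algorithm`` left empty skip those
    stages.
    """

    root_dir: str = "."
    reference: str = ""  # optional explicit geom.xyz path
    descriptor: str = "r2"
    ring_atoms: str = ""  # comma-separated indices, cremer_pople only
    scaler: str = "none"
    force_scale: bool = False
    stride_fs: float = 0.0  # 0 disables resampling
    n_samples: int = 0  # 0 disables subsampling
    embed_method: str = ""  # pca | isomap | tsne | "" (skip)
    n_components: int = 2
    n_neighbors: int = 30
    perplexity: float = 30.0
    algorithm: str = ""  # kmeans | gmm | hierarchical | spectral | "" (skip)
    n_clusters: str = "3"  # int or "best"
    k_range: str = "2:6"
    linkage: str = "ward"
    summary_properties: str = "DE21,Hops_S21,Hops_S12"
    seed: int = 0
    out_dir: str = "namdclust_out"
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file (# starts a comment)."""
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
            ftype = known[key].type
            if ftype == "int":
                kwargs[key] = int(value)
            elif ftype == "float":
                kwargs[key] = float(value)
            elif ftype == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def parsed_k_range(self) -> list[int]:
        try:
            lo, hi = (int(x) for x in self.k_range.split(":"))
        except ValueError as exc:
            raise ConfigError(f"k_range must look like '2:6', got {self.k_range!r}") from exc
        return list(range(lo, hi + 1))

    def parsed_ring_atoms(self) -> list[int] | None:
        if not self.ring_atoms:
            return None
        return [int(x) for x in self.ring_atoms.split(",")]


def _write(df: pd.DataFrame, path: Path) -> Path:
    write_dataset_csv(df, path)
    return path


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Execute the configured pipeline; returns {artifact name: path}.

    Writes, in order: the merged ensemble CSV (properties + RMSD when a
    reference exists), the descriptor CSV, its descriptive statistics, and
    optionally the embedding CSV and the labels + cluster-summary CSVs.
    A stage failure raises :class:`StageError`; artifacts already written
    are retained.
    """
    if cfg.descriptor not in DESCRIPTOR_CHOICES:
        raise ConfigError(
            f"unknown descriptor {cfg.descriptor!r}; choose from {DESCRIPTOR_CHOICES}"
        )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "versions": _library_versions(),
    }

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except NamdclustError:
                raise
            except Exception as exc:  # noqa: BLE001 - map onto stage error
                raise StageError(name, exc) from exc

        return wrap

    # -- ingest ------------------------------------------------------------
    def _ingest():
        ens = load_ensemble(cfg.root_dir)
        if cfg.reference:
            from .datasets import read_xyz

            ens.reference = read_xyz(cfg.reference)
        table = ens.properties.copy()
        if ens.reference is not None:
            table = table.join(rmsd_series(ens))
        artifacts["ensemble"] = str(_write(table, out / "ensemble.csv"))
        return ens

    ens = stage("ingest")(_ingest)

    # -- descriptor --------------------------------------------------------
    def _describe():
        feats = descriptor_dataset(
            ens, cfg.descriptor, ring_atoms=cfg.parsed_ring_atoms()
        )
        if cfg.stride_fs > 0:
            feats = resample_by_stride(feats, cfg.stride_fs)
        if cfg.n_samples > 0:
            feats = random_subsample(feats, min(cfg.n_samples, len(feats)), cfg.seed)
        feats, scaler_params = apply_scaler(
            feats, cfg.scaler, descriptor=cfg.descriptor, force=cfg.force_scale
        )
        manifest["scaler"] = cfg.scaler if scaler_params is not None else "none"
        artifacts["descriptor"] = str(_write(feats, out / "descriptor.csv"))
        return feats

    feats = stage("descriptor")(_describe)

    # -- descriptive statistics -------------------------------------------
    def _stats():
        stats = pd.DataFrame(
            {
                "mean": feats.mean(axis=0),
                "median": feats.median(axis=0),
                "std": feats.std(axis=0, ddof=0),
            }
        )
        stats.index.name = "feature"
        path = out / "descriptor_stats.csv"
        stats.to_csv(path, float_format="%.6f")
        artifacts["descriptor_stats"] = str(path)

    stage("statistics")(_stats)

    # -- embedding ---------------------------------------------------------
    if cfg.embed_method:
        def _embed():
            if cfg.embed_method == "pca":
                emb = pca_fit_transform(feats, cfg.n_components)
            elif cfg.embed_method == "isomap":
                emb = isomap_fit_transform(feats, cfg.n_neighbors, cfg.n_components)
            elif cfg.embed_method == "tsne":
                emb = tsne_fit_transform(
                    feats, cfg.perplexity, cfg.n_components, cfg.seed
                )
            else:
                raise ConfigError(f"unknown embed method {cfg.embed_method!r}")
            artifacts["embedding"] = str(_write(emb.to_frame(), out / "embedding.csv"))

        stage("embedding")(_embed)

    # -- clustering --------------------------------------------------------
    if cfg.algorithm:
        def _cluster():
            if cfg.n_clusters == "best":
                k = select_k_best(
                    feats,
                    cfg.parsed_k_range(),
                    algorithm=cfg.algorithm,
                    seed=cfg.seed,
                    linkage=cfg.linkage,
                )
                manifest["selected_k"] = k
            else:
                k = int(cfg.n_clusters)
            res = run_algorithm(
                feats, cfg.algorithm, k, seed=cfg.seed, linkage=cfg.linkage
            )
            artifacts["labels"] = str(_write(res.to_frame(), out / "labels.csv"))
            manifest["cluster_metrics"] = {
                key: float(v) for key, v in res.metrics.items()
            }
            props = ens.properties.loc[res.keys]
            wanted = [
                p.strip()
                for p in cfg.summary_properties.split(",")
                if p.strip() and p.strip() in props.columns
            ]
            if wanted:
                summary = cluster_statistics(props, res.labels, wanted)
                path = out / "cluster_summary.csv"
                summary.to_csv(path, index=False, float_format="%.6f")
                artifacts["cluster_summary"] = str(path)

        stage("clustering")(_cluster)

    manifest["artifacts"] = artifacts
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts


def _library_versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy
    import sklearn

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
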