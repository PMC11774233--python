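"""Postprocessing analytics: RMSD, hop partitioning, per-cluster statistics.

In surface-hopping ensembles each frame may carry hop flags marking a
nonadiabatic transition (``Hops_S21`` excited → ground, ``Hops_S12`` the
back hop).  Partitioning frames on those flags and summarizing properties
per cluster label are the bridge from a clustering back to mechanism —
e.g. showing that hop frames concentrate at stretched bond geometries or
that one cluster carries a distinctly smaller energy gap.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import EnsembleDataset, Geometry
from .exceptions import DataError, SchemaError

__all__ = [
    "kabsch_rmsd",
    "rmsd_series",
    "hop_partition",
    "cluster_statistics",
]


def kabsch_rmsd(g: Geometry, ref: Geometry, align: bool = True) -> float:
    """Root-mean-square deviation between two geometries, Å.

    With ``align=True`` (default) both geometries are centered and ``g`` is
    superposed on ``ref`` by the optimal proper rotation (SVD with
    determinant correction, so reflections are disallowed) before the RMSD
    is taken.  All atoms are weighted equally; atom labels must match.
    """
    if g.labels != ref.labels:
        raise DataError("geometries have different atom labels/order")
    p = g.coords.astype(float)
    q = ref.coords.astype(float)
    if align:
        p = p - p.mean(axis=0)
        q = q - q.mean(axis=0)
        h = p.T @ q
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        p = p @ rot.T
    return float(np.sqrt(((p - q) ** 2).sum() / g.n_atoms))


def rmsd_series(
    ens: EnsembleDataset, ref: Geometry | None = None, align: bool = True
) -> pd.DataFrame:
    """Per-frame RMSD against a reference geometry.

    Uses the ensemble's own reference when ``ref`` is omitted.  Returns a
    one-column (``rmsd``) DataFrame indexed by ``(traj, time)``, ready for
    histogramming the ensemble's structural spread.
    """
    reference = ref if ref is not None else ens.reference
    if reference is None:
        raise DataError("no reference geometry available for RMSD")
    values = [
        kabsch_rmsd(ens.geometries[key], reference, align=align) for key in ens.keys
    ]
    return pd.DataFrame(
        {"rmsd": values},
        index=pd.MultiIndex.from_tuples(ens.keys, names=["traj", "time"]),
    )


def hop_partition(
    ens: EnsembleDataset, direction: str = "any"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the property table into (hop frames, non-hop frames).

    ``direction='any'`` flags a frame as hopping when either ``Hops_S21``
    or ``Hops_S12`` is set; ``'forward'``/``'back'`` restrict to one flag.
    The two parts are disjoint and jointly exhaustive.
    """
    props = ens.properties
    for col in ("Hops_S21", "Hops_S12"):
        if col not in props.columns:
            raise SchemaError(f"property table lacks hop-flag column {col}")
    if direction == "any":
        mask = (props["Hops_S21"] == 1) | (props["Hops_S12"] == 1)
    elif direction == "forward":
        mask = props["Hops_S21"] == 1
    elif direction == "back":
        mask = props["Hops_S12"] == 1
    else:
        raise DataError(f"unknown hop direction {direction!r}")
    return props.loc[mask], props.loc[~mask]


def cluster_statistics(
    props: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    properties: Sequence[str],
    stats: Sequence[str] = ("mean", "median", "std"),
) -> pd.DataFrame:
    """Descriptive statistics of selected properties per cluster label.

    Returns a tidy table with columns ``label, property, <stats>..., count``.
    The standard deviation is the population one (ddof 0), consistent with
    the z-score scaler.  Label coverage must match the table row count.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(props):
        raise DataError(
            f"{labels.shape[0]} labels for {len(props)} rows — labels must cover all rows"
        )
    missing = [p for p in properties if p not in props.columns]
    if missing:
        raise SchemaError(f"properties absent from table: {missing}")
    allowed = {"mean", "median", "std"}
    bad = set(stats) - allowed
    if bad:
        raise DataError(f"unsupported statistics {sorted(bad)}; allowed: {sorted(allowed)}")

    rows = []
    for lab in np.unique(labels):
        sub = props.loc[labels == lab, list(properties)]
        for prop in properties:
            x = sub[prop].to_numpy(dtype=float)
            row: dict[str, float | int | str] = {"label": int(lab), "property": prop}
            if "mean" in stats:
                row["mean"] = float(np.mean(x))
            if "median" in stats:
                row["median"] = float(np.median(x))
            if "std" in stats:
                row["std"] = float(np.std(x, ddof=0))
            row["count"] = int(len(x))
            rows.append(row)
    return pd.DataFrame(rows)
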