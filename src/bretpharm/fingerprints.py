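"""Conformational fingerprints and their clustering.

A fingerprint collects the gated net BRET changes of every FlAsH sensor
position (F1..F10) for one receptor x GRK condition x arrestin isoform:
non-responding positions are exactly zero, responding ones carry the
response at the highest ligand concentration.  Fingerprints can be
normalized to the maximally reacting sensor for display, and stacked
into a matrix for agglomerative clustering under Manhattan (city-block)
distance - the similarity analysis that reveals whether fingerprints
group by receptor C-terminus or helix-bundle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Fingerprint",
    "ClusterResult",
    "build_fingerprint",
    "build_fingerprint_matrix",
    "normalize_to_max_sensor",
    "manhattan_cluster",
]


@dataclass(frozen=True)
class Fingerprint:
    """Sensor-position -> gated response map for one condition."""

    receptor: str
    grk_condition: str
    arrestin: str
    values: dict[str, float]
    zeroed: tuple[str, ...] = ()  # audit: sensors gated to zero
    degenerate: bool = False  # all-zero fingerprint (nothing to normalize)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of fingerprint rows.

    ``distances`` is the symmetric Manhattan distance matrix,
    ``linkage`` the SciPy merge tree, ``leaf_order`` the deterministic
    dendrogram leaf sequence and ``tree`` a bracket-notation rendering
    of the merge tree with merge heights.
    """

    distances: pd.DataFrame
    linkage: np.ndarray
    leaf_order: tuple[str, ...]
    tree: str


def build_fingerprint(
    gates: pd.DataFrame,
    receptor: str,
    grk_condition: str,
    arrestin: str,
    sensors: tuple[str, ...] | None = None,
) -> Fingerprint:
    """Assemble one condition's fingerprint from a gated response table.

    Every configured sensor must have exactly one gate decision for the
    key; duplicates and missing sensors are errors.
    """
    rows = gates[
        (gates["receptor"] == receptor)
        & (gates["grk_condition"] == grk_condition)
        & (gates["arrestin"] == arrestin)
    ]
    if rows["sensor"].duplicated().any():
        dup = rows.loc[rows["sensor"].duplicated(), "sensor"].iloc[0]
        raise ValueError(f"duplicate gate rows for sensor {dup}")
    available = dict(zip(rows["sensor"], rows["gated_value"].astype(float)))
    wanted = tuple(sensors) if sensors is not None else tuple(sorted(available))
    missing = [s for s in wanted if s not in available]
    if missing:
        raise ValueError(
            f"missing sensors {missing} for "
            f"({receptor}, {grk_condition}, {arrestin})"
        )
    values = {s: available[s] for s in wanted}
    zeroed = tuple(s for s in wanted if values[s] == 0.0)
    return Fingerprint(receptor, grk_condition, arrestin, values, zeroed=zeroed)


def build_fingerprint_matrix(
    gates: pd.DataFrame, sensors: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Stack all conditions into a rectangular fingerprint matrix.

    Rows are (receptor, grk_condition, arrestin) keys, columns sensor
    positions, entries gated responses.  Missing entries are an error:
    the matrix must be complete for clustering.
    """
    if gates.duplicated(["receptor", "grk_condition", "arrestin", "sensor"]).any():
        raise ValueError("duplicate gate rows")
    matrix = gates.pivot_table(
        index=["receptor", "grk_condition", "arrestin"],
        columns="sensor",
        values="gated_value",
        aggfunc="first",
    )
    if sensors is not None:
        missing_cols = [s for s in sensors if s not in matrix.columns]
        if missing_cols:
            raise ValueError(f"missing sensors {missing_cols}")
        matrix = matrix[list(sensors)]
    if matrix.isna().any().any():
        raise ValueError("incomplete fingerprint matrix (missing sensor entries)")
    return matrix.astype(float)


def normalize_to_max_sensor(fp: Fingerprint) -> Fingerprint:
    """Scale a fingerprint by its maximally reacting sensor.

    Division is by the maximum *absolute* response so sign-mixed
    fingerprints stay within [-1, 1] and the strongest sensor maps to
    +/-1.  An all-zero fingerprint is returned unchanged and flagged
    degenerate.  The operation is idempotent and scale-invariant.
    """
    series = fp.as_series()
    peak = series.abs().max()
    if peak == 0:
        return Fingerprint(
            fp.receptor,
            fp.grk_condition,
            fp.arrestin,
            dict(fp.values),
            zeroed=fp.zeroed,
            degenerate=True,
        )
    return Fingerprint(
        fp.receptor,
        fp.grk_condition,
        fp.arrestin,
        {s: float(v / peak) for s, v in fp.values.items()},
        zeroed=fp.zeroed,
        degenerate=False,
    )


def _newick(node, labels, heights) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels, heights)
    right = _newick(node.get_right(), labels, heights)
    return f"({left},{right}):{node.dist:g}"


def manhattan_cluster(matrix: pd.DataFrame, method: str = "complete") -> ClusterResult:
    """Cluster fingerprint rows by Manhattan distance.

    ``method`` is the agglomerative linkage (complete by default;
    average and single are also meaningful for city-block distances).
    Rows are sorted lexicographically by key before clustering so merge
    ties break deterministically.
    """
    if method not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage method {method!r}")
    if len(matrix) < 2:
        raise ValueError("clustering needs at least two fingerprint rows")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite entries in fingerprint matrix")
    order = np.argsort([str(ix) for ix in matrix.index])
    matrix = matrix.iloc[order]
    values = matrix.to_numpy(dtype=float)
    labels = ["|".join(map(str, ix)) if isinstance(ix, tuple) else str(ix)
              for ix in matrix.index]
    condensed = pdist(values, metric="cityblock")
    link = hierarchy.linkage(condensed, method=method)
    dist = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
    tree_root = hierarchy.to_tree(link)
    leaf_order = tuple(labels[i] for i in hierarchy.leaves_list(link))
    newick = _newick(tree_root, labels, None) + ";"
    return ClusterResult(dist, link, leaf_order, newick)
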