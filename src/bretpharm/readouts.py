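"""Quantification of the downstream functional readouts.

Three assays feed the transferability comparison besides the BRET
fingerprints:

* **C-terminal receptor phosphorylation** measured as optical density
  (OD 405 nm) in a bead-based immunoassay: background-subtracted,
  loading-control corrected and rescaled so the unstimulated negative
  control maps to 0% and the maximal-agonist positive control (Control
  cells) to 100%.
* **ERK1/2 activation** from Western-blot densitometry: the pERK signal
  divided by total ERK per time point, summarised as trapezoidal area
  under the curve over the measured 0-30 min span.
* **Endosomal co-localization** (receptor-Rab5 and arrestin-Rab5) as
  fold change over the unstimulated GRK-knockout (dQ-GRK + empty
  vector) reference, with per-axis percent-of-maximum scaling for the
  2-D scatter display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import COLOC_BASAL_REFERENCE

__all__ = [
    "quantify_phospho",
    "erk_activation",
    "erk_auc",
    "erk_auc_table",
    "normalize_coloc",
]

_PHOSPHO_GROUP = ["plate_id", "receptor", "cluster"]
_PHOSPHO_SAMPLE = _PHOSPHO_GROUP + ["condition", "conc_uM", "replicate"]


def quantify_phospho(plate: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw immunoassay ODs to percent of the Control maximum.

    Per (plate, receptor, cluster): the mean background-well OD is
    subtracted from every signal, each phospho well is divided by its
    matched loading-control well (same condition/concentration/
    replicate), and the loading-corrected values are rescaled linearly
    so the negative control is 0% and the positive control 100%.
    Normalization is per plate, so plate-to-plate gain cancels.
    """
    if (plate["od_405"] < 0).any():
        raise ValueError("negative optical densities in input")
    out_rows = []
    for group_key, group in plate.groupby(_PHOSPHO_GROUP, sort=True):
        bg_wells = group[group["role"] == "background"]
        if bg_wells.empty:
            raise ValueError(f"no background wells for {group_key}")
        background = bg_wells["od_405"].mean()

        loading = group[group["role"] == "loading"].set_index(
            ["condition", "conc_uM", "replicate"]
        )["od_405"]

        def corrected(rows: pd.DataFrame) -> pd.Series:
            vals = []
            for _, row in rows.iterrows():
                lkey = (row["condition"], row["conc_uM"], row["replicate"])
                if lkey not in loading.index:
                    raise ValueError(
                        f"no matched loading control for {group_key} {lkey}"
                    )
                load = loading.loc[lkey] - background
                if load <= 0:
                    raise ValueError(
                        f"non-positive loading control for {group_key} {lkey}"
                    )
                vals.append((row["od_405"] - background) / load)
            return pd.Series(vals, index=rows.index, dtype=float)

        neg_rows = group[group["role"] == "neg_ctrl"]
        pos_rows = group[group["role"] == "pos_ctrl"]
        if neg_rows.empty or pos_rows.empty:
            raise ValueError(f"missing negative/positive control for {group_key}")
        neg = corrected(neg_rows).mean()
        pos = corrected(pos_rows).mean()
        if pos == neg:
            raise ValueError(f"degenerate control scale for {group_key}")

        samples = group[group["role"] == "sample"].copy()
        samples["value_pct"] = (corrected(samples) - neg) / (pos - neg) * 100.0
        out_rows.append(samples[_PHOSPHO_SAMPLE + ["value_pct"]])
    if not out_rows:
        raise ValueError("empty phospho plate")
    return pd.concat(out_rows, ignore_index=True)


def erk_activation(timecourse: pd.DataFrame) -> pd.DataFrame:
    """Add the pERK / total ERK ratio per time point."""
    if (timecourse["totalErk"] <= 0).any():
        raise ValueError("totalErk must be positive at every time point")
    out = timecourse.copy()
    out["ratio"] = out["pErk"] / out["totalErk"]
    return out


def erk_auc(time_min, ratio) -> float:
    """Trapezoidal area under an ERK activation time course.

    Time points must be strictly increasing (duplicates would
    double-count); with piecewise-linear input the trapezoid rule is
    exact.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(ratio, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    return float(np.trapezoid(y, t))


def erk_auc_table(
    timecourse: pd.DataFrame,
    group_cols=("receptor", "condition", "replicate"),
) -> pd.DataFrame:
    """AUC per group of an ERK time-course table (ratio column required)."""
    rows = []
    for key, group in timecourse.groupby(list(group_cols), sort=True):
        group = group.sort_values("time_min")
        rows.append(
            dict(
                zip(group_cols, key),
                auc=erk_auc(group["time_min"], group["ratio"]),
            )
        )
    return pd.DataFrame(rows)


def normalize_coloc(table: pd.DataFrame) -> pd.DataFrame:
    """Fold changes over the basal dQ-GRK reference, plus scatter axes.

    Signals are averaged over replicates per (pair, receptor,
    condition, stim state) and divided by the unstimulated
    dQ-GRK + empty-vector reference of the same pair and receptor.  For
    the 2-D scatter display each pair dimension is additionally scaled
    to percent of its maximal fold change over the dataset
    (``pct_of_max``); the receptor-Rab5 pair forms one axis and the
    arrestin-Rab5 pair the other.
    """
    if (table["signal"] < 0).any():
        raise ValueError("co-localization signals must be non-negative")
    means = (
        table.groupby(["pair", "receptor", "condition", "stim_state"], sort=True)[
            "signal"
        ]
        .mean()
        .reset_index()
    )
    refs = means[
        (means["condition"] == COLOC_BASAL_REFERENCE)
        & (means["stim_state"] == "basal")
    ].set_index(["pair", "receptor"])["signal"]
    folds = []
    for _, row in means.iterrows():
        ref_key = (row["pair"], row["receptor"])
        if ref_key not in refs.index:
            raise ValueError(f"missing basal {COLOC_BASAL_REFERENCE} reference "
                             f"for {ref_key}")
        ref = refs.loc[ref_key]
        if ref == 0:
            raise ValueError(f"zero basal reference signal for {ref_key}")
        folds.append(row["signal"] / ref)
    means = means.copy()
    means["fold"] = folds
    means["pct_of_max"] = np.nan
    for pair, idx in means.groupby("pair").groups.items():
        peak = means.loc[idx, "fold"].max()
        if peak <= 0:
            raise ValueError(f"non-positive maximal fold change for pair {pair}")
        means.loc[idx, "pct_of_max"] = means.loc[idx, "fold"] / peak * 100.0
    return means
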