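"""Raw BRET well processing.

Turns well-level acceptor/donor ratio time series into labeling-
corrected, baseline- and vehicle-normalized net BRET changes, then into
window-averaged concentration-response sets ready for 4PL fitting.

The processing chain mirrors standard plate-reader BRET analysis:

1. average technical replicates, subtract the mock-labeling wells
   (labeling-efficiency correction),
2. divide by the mean of the pre-stimulation baseline window
   (fold change over baseline),
3. divide by the time-matched vehicle trace (dynamic net change),
   optionally expressed in percent as ``(fold - 1) * 100``,
4. average the 2-4 min post-stimulation window into one scalar per
   concentration,
5. anchor the concentration series to the lowest tested concentration
   and sort by log10 concentration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "KEY_COLUMNS",
    "correct_labeling",
    "baseline_normalize",
    "vehicle_normalize",
    "window_average",
    "assemble_concentration_response",
    "process_wells",
]

#: identifies one biological condition; concentration and time vary inside it.
KEY_COLUMNS = ["receptor", "grk_condition", "arrestin", "sensor"]

_SERIES_COLUMNS = KEY_COLUMNS + ["treatment", "conc_uM"]


def correct_labeling(labeled: pd.DataFrame, mock: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates and subtract the mock-labeling signal.

    ``labeled`` and ``mock`` are wells tables (one row per well and
    time point, ``bret_ratio`` column).  Replicates are averaged per
    condition/time first; the corrected ratio is then
    ``mean(labeled) - mean(mock)`` on a shared time grid.  A labeled
    condition without mock wells, or mismatched time grids, is an error.
    """
    if labeled.empty:
        raise ValueError("no labeled wells")
    group_cols = _SERIES_COLUMNS + ["time_min"]
    lab = (
        labeled.groupby(group_cols, sort=True)["bret_ratio"].mean().rename("labeled")
    )
    mk = mock.groupby(group_cols, sort=True)["bret_ratio"].mean().rename("mock")
    merged = pd.concat([lab, mk], axis=1, join="outer")
    if merged["mock"].isna().any():
        missing = merged.index[merged["mock"].isna()][0]
        raise ValueError(f"no mock wells / mismatched time grid for {missing}")
    if merged["labeled"].isna().any():
        extra = merged.index[merged["labeled"].isna()][0]
        raise ValueError(f"mock time point without labeled counterpart: {extra}")
    out = merged.reset_index()
    out["corrected"] = out["labeled"] - out["mock"]
    return out[group_cols + ["corrected"]]


def baseline_normalize(
    corrected: pd.DataFrame,
    baseline_window: tuple[float, float] = (-3.0, 0.0),
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Divide each corrected series by its pre-stimulation baseline mean.

    The baseline window is a closed interval in minutes relative to
    stimulation (default: the 3 min of pre-stimulation monitoring).  A
    baseline mean with absolute value below ``eps`` marks an unusable
    well and raises.
    """
    lo, hi = baseline_window
    if lo > hi:
        raise ValueError("baseline window must satisfy lo <= hi")

    def _one(group: pd.DataFrame) -> pd.DataFrame:
        in_window = (group["time_min"] >= lo) & (group["time_min"] <= hi)
        if not in_window.any():
            raise ValueError(
                f"no baseline points in [{lo}, {hi}] for "
                f"{tuple(group.iloc[0][_SERIES_COLUMNS])}"
            )
        base = group.loc[in_window, "corrected"].mean()
        if abs(base) < eps:
            raise ValueError(
                f"near-zero baseline mean ({base!r}) for "
                f"{tuple(group.iloc[0][_SERIES_COLUMNS])}"
            )
        out = group.copy()
        out["fold"] = group["corrected"] / base
        return out

    parts = [
        _one(group) for _, group in corrected.groupby(_SERIES_COLUMNS, sort=True)
    ]
    return pd.concat(parts, ignore_index=True)[
        _SERIES_COLUMNS + ["time_min", "fold"]
    ]


def vehicle_normalize(folds: pd.DataFrame, convention: str = "percent") -> pd.DataFrame:
    """Divide stimulated fold series by the time-matched vehicle trace.

    ``convention`` selects the output scale of the net BRET change:
    ``fold`` keeps the raw ratio (vehicle maps to 1), ``percent``
    reports ``(fold_stim / fold_vehicle - 1) * 100`` (vehicle maps
    to 0).  The vehicle trace must be strictly positive.
    """
    if convention not in ("fold", "percent"):
        raise ValueError(f"unknown convention {convention!r}")
    vehicle = folds[folds["treatment"] == "vehicle"]
    if vehicle.empty:
        raise ValueError("no vehicle wells in input")
    if (vehicle["fold"] <= 0).any():
        raise ValueError("vehicle fold change must be positive at every time point")
    veh = vehicle.set_index(KEY_COLUMNS + ["time_min"])["fold"].rename("vehicle_fold")
    merged = folds.join(veh, on=KEY_COLUMNS + ["time_min"])
    if merged["vehicle_fold"].isna().any():
        bad = merged[merged["vehicle_fold"].isna()].iloc[0]
        raise ValueError(
            f"no time-matched vehicle trace for {tuple(bad[_SERIES_COLUMNS])} "
            f"at t={bad['time_min']}"
        )
    delta = merged["fold"] / merged["vehicle_fold"]
    if convention == "percent":
        delta = (delta - 1.0) * 100.0
    out = merged[_SERIES_COLUMNS + ["time_min"]].copy()
    out["delta_net"] = delta
    return out


def window_average(
    timecourse: pd.DataFrame, window: tuple[float, float] = (2.0, 4.0)
) -> pd.DataFrame:
    """Average the net change inside the post-stimulation window.

    The window is a closed interval (default 2-4 min after
    stimulation); it must contain at least one time point per series.
    Returns one scalar ``response`` per (condition, concentration).
    """
    lo, hi = window
    in_window = (timecourse["time_min"] >= lo) & (timecourse["time_min"] <= hi)
    windowed = timecourse[in_window]
    if windowed.empty:
        raise ValueError(f"no time points inside the window [{lo}, {hi}]")
    grouped = (
        windowed.groupby(_SERIES_COLUMNS, sort=True)["delta_net"]
        .mean()
        .rename("response")
        .reset_index()
    )
    n_series = timecourse.groupby(_SERIES_COLUMNS, sort=True).ngroups
    if len(grouped) != n_series:
        raise ValueError(f"some series have no points inside the window [{lo}, {hi}]")
    return grouped


def assemble_concentration_response(
    responses: pd.DataFrame, min_concentrations: int = 4
) -> pd.DataFrame:
    """Anchor window-averaged responses to the lowest tested concentration.

    Vehicle rows (concentration 0) are excluded from the fit input;
    they act only through the upstream vehicle normalization.  Each
    condition needs at least ``min_concentrations`` distinct ligand
    concentrations; the response at the lowest one (the anchor) is
    subtracted so the anchor maps to exactly 0, displaying the maximal
    measured range.  Output is sorted by log10 concentration.
    """
    ligand = responses[responses["conc_uM"] > 0]
    if ligand.empty:
        raise ValueError("no ligand concentrations to assemble")
    parts = []
    for key, group in ligand.groupby(KEY_COLUMNS, sort=True):
        if group["conc_uM"].duplicated().any():
            raise ValueError(f"duplicate unmerged concentrations for {key}")
        if group["conc_uM"].nunique() < min_concentrations:
            raise ValueError(
                f"{key}: fewer than {min_concentrations} concentrations; "
                "condition is unfittable"
            )
        group = group.sort_values("conc_uM").copy()
        anchor = group["response"].iloc[0]
        group["log10_conc_uM"] = np.log10(group["conc_uM"])
        group["response"] = group["response"] - anchor
        parts.append(group[KEY_COLUMNS + ["log10_conc_uM", "response"]])
    return pd.concat(parts, ignore_index=True)


def process_wells(
    wells: pd.DataFrame,
    convention: str = "percent",
    baseline_window: tuple[float, float] = (-3.0, 0.0),
    response_window: tuple[float, float] = (2.0, 4.0),
) -> dict[str, pd.DataFrame]:
    """Run the full chain from a wells table to concentration responses.

    Returns ``{"timecourse": ..., "responses": ..., "concresp": ...}``:
    the vehicle-normalized net-change time courses, the window-averaged
    scalars per concentration, and the anchored concentration-response
    sets ready for 4PL fitting.
    """
    if not np.isfinite(wells["bret_ratio"]).all():
        raise ValueError("non-finite BRET ratios in input")
    labeled = wells[wells["labeling"] == "flash"]
    mock = wells[wells["labeling"] == "mock"]
    corrected = correct_labeling(labeled, mock)
    folds = baseline_normalize(corrected, baseline_window=baseline_window)
    timecourse = vehicle_normalize(folds, convention=convention)
    responses = window_average(timecourse, window=response_window)
    concresp = assemble_concentration_response(responses)
    return {"timecourse": timecourse, "responses": responses, "concresp": concresp}
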