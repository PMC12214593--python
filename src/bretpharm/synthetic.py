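"""Synthetic-data generators with known ground truth.

Every input class consumed by the pipeline can be simulated here:

* BRET plates (well-level acceptor/donor ratio time series) with
  FlAsH-labeled and mock-labeled wells, vehicle and ligand treatments,
  technical replicates, multiplicative vehicle drift and additive
  plate-reader noise.  Concentration dependence follows a 4PL curve per
  (receptor, sensor) so the downstream fit can be checked against the
  generating parameters.
* Receptor-quartet responses whose variant pattern is driven by the
  receptor C-terminus (tail), the helix-bundle (core), or a mixture.
* ERK1/2 activation time courses with transient (class A like, peak at
  2 min) or sustained (class B like, peak at 5 min) kinetics.
* Phospho-immunoassay plates (OD 405 nm with background, loading and
  negative/positive control wells) and endosomal co-localization
  fold-change tables.

All generators are deterministic given (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .fourpl import fourpl
from .transferability import QUARTET_NAMES, VARIANTS, ReceptorQuartet

__all__ = [
    "AttributionTruth",
    "SensorTruth",
    "NoiseModel",
    "PlateDesign",
    "WELLS_COLUMNS",
    "gen_bret_plate",
    "gen_quartet_responses",
    "gen_erk_timecourses",
    "erk_ratio_truth",
    "ERK_RATE_PAIRS",
    "gen_phospho_plate",
    "gen_coloc_table",
    "COLOC_BASAL_REFERENCE",
]

WELLS_COLUMNS = [
    "plate_id",
    "well_id",
    "receptor",
    "grk_condition",
    "arrestin",
    "sensor",
    "labeling",
    "treatment",
    "conc_uM",
    "time_min",
    "replicate",
    "bret_ratio",
]

#: condition label of the unstimulated GRK-knockout reference used by
#: the co-localization normalization.
COLOC_BASAL_REFERENCE = "dQ-GRK+EV"


@dataclass(frozen=True)
class AttributionTruth:
    """Ground-truth domain attribution for one quartet readout.

    ``driver`` states which receptor domain carries the effect:
    ``tail`` (C-terminus only), ``core`` (helix-bundle only) or
    ``mixed`` (a ``mix_weight`` blend of the tail effect with the
    complementary weight on the core effect).
    """

    readout_id: str
    driver: str
    tail_effect: float = 0.0
    core_effect: float = 0.0
    mix_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.driver not in ("tail", "core", "mixed"):
            raise ValueError(f"unknown driver {self.driver!r}")
        if not 0.0 <= self.mix_weight <= 1.0:
            raise ValueError("mix_weight must lie in [0, 1]")

    def weights(self) -> tuple[float, float]:
        """(tail weight, core weight) implied by the driver."""
        if self.driver == "tail":
            return 1.0, 0.0
        if self.driver == "core":
            return 0.0, 1.0
        return self.mix_weight, 1.0 - self.mix_weight

    def expected_response(self, receptor: str, base: float = 0.0) -> float:
        """Noiseless response of one quartet member."""
        variant = VARIANTS[receptor]
        w_tail, w_core = self.weights()
        value = base
        if variant.tail == "V2":
            value += w_tail * self.tail_effect
        if variant.bundle == "V2":
            value += w_core * self.core_effect
        return value


@dataclass(frozen=True)
class SensorTruth:
    """Generating 4PL parameters of one (receptor, sensor) condition.

    ``bottom``/``top`` are in fold-change units of the processed signal
    (0.2 means a 20% net BRET change at saturation).  A non-responder is
    a flat curve: ``top == bottom``.
    """

    receptor: str
    sensor: str
    bottom: float
    top: float
    log_ec50: float
    hill: float
    responder: bool

    def __post_init__(self) -> None:
        if self.responder:
            if self.hill == 0 or self.top == self.bottom:
                raise ValueError(
                    f"{self.receptor}/{self.sensor}: a responder needs "
                    "|hill| > 0 and top != bottom"
                )
        elif self.top != self.bottom:
            raise ValueError(
                f"{self.receptor}/{self.sensor}: non-responders must be flat "
                "(top == bottom)"
            )

    def response(self, conc_uM: float) -> float:
        """Processed fold-change response at a ligand concentration."""
        if not self.responder:
            return float(self.bottom)
        return float(
            fourpl(np.log10(conc_uM), self.bottom, self.top, self.log_ec50, self.hill)
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise on the raw instrument scales."""

    sd_ratio: float = 0.0  # BRET-ratio units
    sd_od: float = 0.0  # OD units
    sd_densitometry: float = 0.0  # pERK/totalERK ratio units
    replicate_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_ratio", "sd_od", "sd_densitometry"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PlateDesign:
    """Layout of a simulated BRET plate.

    ``timepoints_min`` must contain a pre-stimulation baseline window
    (times <= stimulation_offset) and post-stimulation points covering
    the 2-4 min response window.  Vehicle wells are generated implicitly
    for every (receptor, sensor).
    """

    receptors: tuple[str, ...]
    sensors: tuple[str, ...]
    concentrations_uM: tuple[float, ...]
    timepoints_min: tuple[float, ...]
    grk_condition: str = "Control"
    arrestin: str = "beta-arrestin2"
    plate_id: str = "plate1"
    base_ratio: float = 0.8  # donor-normalised acceptor signal at rest
    mock_background: float = 0.05  # additive labeling background
    drift_per_min: float = 0.0  # relative vehicle drift (shared by all wells)
    stimulation_offset_min: float = 0.0  # midpoint of ligand-addition time

    def __post_init__(self) -> None:
        if not self.receptors or not self.sensors:
            raise ValueError("design needs at least one receptor and one sensor")
        if not self.concentrations_uM:
            raise ValueError("design needs at least one ligand concentration")
        if any(c <= 0 for c in self.concentrations_uM):
            raise ValueError("ligand concentrations must be positive")
        times = np.asarray(self.timepoints_min, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        t0 = self.stimulation_offset_min
        if not np.any(times <= t0):
            raise ValueError("timepoints must include a pre-stimulation baseline")
        post = times - t0
        if not np.any((post >= 2.0) & (post <= 4.0)):
            raise ValueError(
                "timepoints must cover the 2-4 min post-stimulation window"
            )


def gen_bret_plate(
    design: PlateDesign,
    truths: Mapping[tuple[str, str], SensorTruth],
    noise: NoiseModel,
) -> pd.DataFrame:
    """Simulate a BRET plate as a long-format wells table.

    For each (receptor, sensor) the plate holds FlAsH-labeled and
    mock-labeled wells for the vehicle and every ligand concentration,
    each seeded as ``noise.replicate_count`` technical replicates.  The
    expected processed signal (after labeling correction, baseline and
    vehicle normalization) of a stimulated well at concentration ``c``
    is ``1 + truth.response(c)`` in fold units: the 4PL value of the
    sensor's ground truth.

    Mock wells carry only the additive labeling background; vehicle
    drift multiplies stimulated and vehicle wells alike and therefore
    cancels in processing.
    """
    times = np.asarray(design.timepoints_min, dtype=float)
    rng = noise.rng()
    step = (times > design.stimulation_offset_min).astype(float)
    drift = 1.0 + design.drift_per_min * (times - times[0])

    records: list[tuple] = []
    well_counter = 0
    for receptor in design.receptors:
        for sensor in design.sensors:
            key = (receptor, sensor)
            if key not in truths:
                raise KeyError(f"no SensorTruth for {key}")
            truth = truths[key]
            treatments = [("vehicle", 0.0)] + [
                ("ligand", c) for c in design.concentrations_uM
            ]
            for treatment, conc in treatments:
                r = truth.response(conc) if treatment == "ligand" else 0.0
                expected_flash = design.mock_background + (
                    design.base_ratio * drift * (1.0 + r * step)
                )
                expected_mock = np.full_like(times, design.mock_background)
                for labeling, expected in (
                    ("flash", expected_flash),
                    ("mock", expected_mock),
                ):
                    for replicate in range(1, noise.replicate_count + 1):
                        well_counter += 1
                        well_id = f"W{well_counter:04d}"
                        values = expected + rng.normal(
                            0.0, noise.sd_ratio, size=times.size
                        )
                        for t, v in zip(times, values):
                            records.append(
                                (
                                    design.plate_id,
                                    well_id,
                                    receptor,
                                    design.grk_condition,
                                    design.arrestin,
                                    sensor,
                                    labeling,
                                    treatment,
                                    conc,
                                    t,
                                    replicate,
                                    v,
                                )
                            )
    return pd.DataFrame.from_records(records, columns=WELLS_COLUMNS)


def gen_quartet_responses(
    truth: AttributionTruth,
    base: float = 0.0,
    sd: float = 0.0,
    seed: int = 0,
    replicate_count: int = 1,
) -> ReceptorQuartet:
    """Simulate harmonized quartet responses with a known domain driver.

    Noise is added per technical replicate and replicates are averaged,
    mirroring how real per-receptor responses are summarised before the
    transferability calculation.
    """
    if not np.isfinite(base):
        raise ValueError("base must be finite")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if replicate_count < 1:
        raise ValueError("replicate_count must be >= 1")
    rng = np.random.default_rng(seed)
    responses = {}
    for name in QUARTET_NAMES:
        expected = truth.expected_response(name, base=base)
        draws = expected + rng.normal(0.0, sd, size=replicate_count)
        responses[name] = float(np.mean(draws))
    return ReceptorQuartet(
        readout_id=truth.readout_id, condition="synthetic", responses=responses
    )


#: ten half-log ligand dilutions, 1e-3 .. 10^1.5 uM: the standard
#: concentration-response design used by the panel generator.
PANEL_LOG_CONCENTRATIONS = tuple(np.arange(-3.0, 1.6, 0.5))


def gen_responder_panel(
    n_responders: int = 50,
    n_flat: int = 50,
    sd: float = 0.0,
    seed: int = 0,
    replicate_count: int = 3,
    log_concentrations=PANEL_LOG_CONCENTRATIONS,
    top_range: tuple[float, float] = (5.0, 25.0),
    log_ec50_range: tuple[float, float] = (-2.0, -0.2),
    hill_range: tuple[float, float] = (0.7, 1.5),
) -> tuple[pd.DataFrame, dict[str, SensorTruth]]:
    """Generate a responder/non-responder validation panel.

    Produces anchored concentration-response sets (the input of the 4PL
    fit) for ``n_responders`` sigmoidal sensors with parameters drawn
    from realistic conformational-sensor ranges (responses in percent;
    EC50 well inside the tested dilution series; Hill slopes near 1)
    and ``n_flat`` flat non-responders.  Additive Gaussian noise of
    standard deviation ``sd`` is applied per technical-replicate
    measurement; replicates are averaged before assembly, as in the
    plate-processing chain.  Returns the concentration-response table
    and the ground truth keyed by the synthetic receptor label.
    """
    if replicate_count < 1:
        raise ValueError("replicate_count must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.asarray(log_concentrations, dtype=float)
    rows = []
    truths: dict[str, SensorTruth] = {}
    total = n_responders + n_flat
    for i in range(total):
        label = f"R{i:03d}"
        if i < n_responders:
            truth = SensorTruth(
                receptor=label,
                sensor="F1",
                bottom=0.0,
                top=float(rng.uniform(*top_range)),
                log_ec50=float(rng.uniform(*log_ec50_range)),
                hill=float(rng.uniform(*hill_range)),
                responder=True,
            )
            y = fourpl(x, truth.bottom, truth.top, truth.log_ec50, truth.hill)
        else:
            truth = SensorTruth(label, "F1", 0.0, 0.0, 0.0, 1.0, False)
            y = np.zeros_like(x)
        noise = rng.normal(0.0, sd, size=(replicate_count, x.size)).mean(axis=0)
        y = y + noise
        y = y - y[0]  # anchored to the lowest tested concentration
        truths[label] = truth
        for xi, yi in zip(x, y):
            rows.append((label, "Control", "beta-arrestin2", "F1", xi, yi))
    frame = pd.DataFrame(
        rows,
        columns=[
            "receptor",
            "grk_condition",
            "arrestin",
            "sensor",
            "log10_conc_uM",
            "response",
        ],
    )
    return frame, truths


# ---------------------------------------------------------------------------
# ERK kinetics
# ---------------------------------------------------------------------------

#: (fast, slow) rate constants per kinetic class, 1/min.  Chosen so the
#: noiseless response on the measurement grid {0, 2, 5, 10, 30} min peaks
#: at 2 min for the transient class (decaying to ~6% of peak by 10 min)
#: and at 5 min for the sustained class with a gradual decay.
ERK_RATE_PAIRS = {
    "transient": (2.0, 0.35),
    "sustained": (0.8, 0.05),
}


def erk_ratio_truth(
    kinetic_class: str,
    t,
    baseline: float = 1.0,
    amplitude: float = 1.0,
):
    """Noiseless pERK/totalERK ratio over time for one kinetic class.

    A difference of exponentials ``exp(-k_slow t) - exp(-k_fast t)``,
    scaled so the continuous-time peak equals ``baseline + amplitude``.
    """
    try:
        k_fast, k_slow = ERK_RATE_PAIRS[kinetic_class]
    except KeyError:
        raise ValueError(
            f"unknown kinetic_class {kinetic_class!r}; "
            f"expected one of {sorted(ERK_RATE_PAIRS)}"
        ) from None
    t = np.asarray(t, dtype=float)
    raw = np.where(t > 0, np.exp(-k_slow * t) - np.exp(-k_fast * t), 0.0)
    t_peak = np.log(k_fast / k_slow) / (k_fast - k_slow)
    peak = np.exp(-k_slow * t_peak) - np.exp(-k_fast * t_peak)
    return baseline + amplitude * raw / peak


def gen_erk_timecourses(
    kinetic_class: str,
    timepoints_min,
    sd: float = 0.0,
    seed: int = 0,
    baseline: float = 1.0,
    amplitude: float = 1.0,
    replicate_count: int = 3,
    receptor: str = "",
    condition: str = "Control",
) -> pd.DataFrame:
    """Simulate pERK/totalERK densitometry time courses.

    Timepoints (minutes) must be sorted and include 0 (the unstimulated
    baseline).  ``totalErk`` is the loading-normalised reference and is
    generated as 1; noise of sd ``sd`` is added to the pERK channel and
    truncated at the physical floor of zero.
    """
    times = np.asarray(timepoints_min, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if 0.0 not in times:
        raise ValueError("timepoints must include 0 (pre-stimulation)")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    truth = erk_ratio_truth(kinetic_class, times, baseline, amplitude)
    frames = []
    for replicate in range(1, replicate_count + 1):
        perk = np.maximum(truth + rng.normal(0.0, sd, size=times.size), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "receptor": receptor,
                    "condition": condition,
                    "kinetic_class": kinetic_class,
                    "replicate": replicate,
                    "time_min": times,
                    "pErk": perk,
                    "totalErk": 1.0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Phospho-immunoassay plates
# ---------------------------------------------------------------------------


def gen_phospho_plate(
    truth: Mapping[tuple[str, str, str, float], float],
    noise: NoiseModel,
    background: float = 0.05,
    loading_od: float = 1.0,
    neg_level: float = 0.1,
    pos_level: float = 1.0,
    plate_id: str = "phos1",
) -> pd.DataFrame:
    """Simulate a bead-based phosphorylation immunoassay plate.

    ``truth`` maps (receptor, cluster, condition, conc_uM) to the target
    normalized response as a fraction of the Control-cell maximum (0 =
    negative control level, 1 = positive control level).  Each sample is
    split into a phospho-detection well and a matched loading-control
    well; background wells and per-(receptor, cluster) negative/positive
    controls are added so the plate inverts exactly through
    :func:`bretpharm.readouts.quantify_phospho` at zero noise.
    """
    if pos_level == neg_level:
        raise ValueError("degenerate controls: pos_level equals neg_level")
    if loading_od <= background:
        raise ValueError("loading_od must exceed background")
    rng = noise.rng()
    span = loading_od - background

    def od_for(fraction_of_max: float) -> float:
        corrected = neg_level + fraction_of_max * (pos_level - neg_level)
        return background + corrected * span

    records: list[tuple] = []

    def emit(receptor, cluster, condition, conc, role, expected):
        for replicate in range(1, noise.replicate_count + 1):
            od = max(expected + rng.normal(0.0, noise.sd_od), 0.0)
            records.append(
                (plate_id, receptor, cluster, condition, conc, role, replicate, od)
            )

    groups = sorted({(r, c) for (r, c, _, _) in truth})
    if not groups:
        raise ValueError("empty phospho truth table")
    for receptor, cluster in groups:
        emit(receptor, cluster, "background", 0.0, "background", background)
        emit(receptor, cluster, "neg_ctrl", 0.0, "neg_ctrl", od_for(0.0))
        emit(receptor, cluster, "neg_ctrl", 0.0, "loading", loading_od)
        emit(receptor, cluster, "pos_ctrl", 0.0, "pos_ctrl", od_for(1.0))
        emit(receptor, cluster, "pos_ctrl", 0.0, "loading", loading_od)
    for (receptor, cluster, condition, conc), fraction in sorted(truth.items()):
        emit(receptor, cluster, condition, conc, "sample", od_for(fraction))
        emit(receptor, cluster, condition, conc, "loading", loading_od)
    return pd.DataFrame.from_records(
        records,
        columns=[
            "plate_id",
            "receptor",
            "cluster",
            "condition",
            "conc_uM",
            "role",
            "replicate",
            "od_405",
        ],
    )


# ---------------------------------------------------------------------------
# Co-localization fold-change tables
# ---------------------------------------------------------------------------


def gen_coloc_table(
    truth: Mapping[tuple[str, str, str, str], float],
    ref_signal: float = 1.0,
    sd: float = 0.0,
    seed: int = 0,
    replicate_count: int = 3,
) -> pd.DataFrame:
    """Simulate Rab5 co-localization signals at the fold-change level.

    ``truth`` maps (pair, receptor, condition, stim_state) to the fold
    change over the unstimulated dQ-GRK + empty-vector reference; the
    reference row itself (fold 1.0) is added automatically for every
    (pair, receptor) unless supplied.  Image segmentation is upstream:
    this emulates the quantified signal table, not microscopy.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if ref_signal <= 0:
        raise ValueError("ref_signal must be positive")
    rng = np.random.default_rng(seed)
    entries = dict(truth)
    for pair, receptor in sorted({(p, r) for (p, r, _, _) in entries}):
        ref_key = (pair, receptor, COLOC_BASAL_REFERENCE, "basal")
        entries.setdefault(ref_key, 1.0)
    records = []
    for (pair, receptor, condition, stim_state), fold in sorted(entries.items()):
        for replicate in range(1, replicate_count + 1):
            signal = max(fold * ref_signal + rng.normal(0.0, sd), 0.0)
            records.append((pair, receptor, condition, stim_state, replicate, signal))
    return pd.DataFrame.from_records(
        records,
        columns=["pair", "receptor", "condition", "stim_state", "replicate", "signal"],
    )
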