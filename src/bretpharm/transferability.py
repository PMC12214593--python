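"""Receptor domain-swap transferability analysis.

The experimental design behind this module is a quartet of receptors:
the wild-type beta-2 adrenergic receptor (b2AR, class A), the wild-type
vasopressin V2 receptor (V2R, class B), and the two chimeras obtained by
swapping their C-terminal tails (b2V2 = b2AR helix-bundle + V2R tail,
V2b2 = V2R helix-bundle + b2AR tail).  Comparing any quantitative
readout across the four variants asks which receptor domain the
phenotype "follows":

* ``transferability_tail``  = |r(b2AR) - r(b2V2)| + |r(V2R) - r(V2b2)|
  (each wild type vs the chimera sharing its helix-bundle, i.e. the
  effect of exchanging only the tail),
* ``transferability_core``  = |r(b2AR) - r(V2b2)| + |r(V2R) - r(b2V2)|
  (each wild type vs the chimera sharing its tail),
* coefficient = tail - core.

A positive coefficient means the readout follows the receptor
C-terminus ("C-terminus transferable"), a negative one means it follows
the transmembrane helix-bundle ("helix-bundle transferable").  The
absolute wild-type difference |r(b2AR) - r(V2R)| is carried along as the
bubble-size magnitude used when plotting coefficients.

Readouts from different assays are brought onto comparable scales by
:func:`harmonize` before coefficients are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReceptorVariant",
    "VARIANTS",
    "QUARTET_NAMES",
    "ReceptorQuartet",
    "TransferabilityResult",
    "transferability_tail",
    "transferability_core",
    "transferability_coefficient",
    "harmonize",
    "harmonize_conformational",
    "harmonize_erk_auc",
    "harmonize_fold_change",
    "harmonize_phospho",
    "transferability_table",
]


@dataclass(frozen=True)
class ReceptorVariant:
    """One member of the wild-type/chimera quartet."""

    name: str
    bundle: str  # transmembrane helix-bundle identity: "b2" or "V2"
    tail: str  # C-terminus identity: "b2" or "V2"

    @property
    def wild_type(self) -> bool:
        return self.bundle == self.tail


VARIANTS: dict[str, ReceptorVariant] = {
    "b2AR": ReceptorVariant("b2AR", "b2", "b2"),
    "b2V2": ReceptorVariant("b2V2", "b2", "V2"),
    "V2b2": ReceptorVariant("V2b2", "V2", "b2"),
    "V2R": ReceptorVariant("V2R", "V2", "V2"),
}

QUARTET_NAMES = ("b2AR", "b2V2", "V2b2", "V2R")


@dataclass
class ReceptorQuartet:
    """Harmonized responses of the four receptor variants for one readout."""

    readout_id: str
    condition: str
    responses: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.responses) != set(QUARTET_NAMES):
            raise ValueError(
                f"quartet must contain exactly {QUARTET_NAMES}, "
                f"got {sorted(self.responses)}"
            )
        for name, value in self.responses.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite response for {name}: {value}")

    def __getitem__(self, name: str) -> float:
        return float(self.responses[name])


@dataclass(frozen=True)
class TransferabilityResult:
    readout_id: str
    condition: str
    tail: float
    core: float
    coefficient: float  # tail - core
    wt_difference: float  # |r(b2AR) - r(V2R)|, bubble-size magnitude
    label: str


def transferability_tail(q: ReceptorQuartet) -> float:
    """C-terminus transferability: wild type vs same-bundle chimera."""
    return abs(q["b2AR"] - q["b2V2"]) + abs(q["V2R"] - q["V2b2"])


def transferability_core(q: ReceptorQuartet) -> float:
    """Helix-bundle transferability: wild type vs same-tail chimera."""
    return abs(q["b2AR"] - q["V2b2"]) + abs(q["V2R"] - q["b2V2"])


def transferability_coefficient(q: ReceptorQuartet) -> TransferabilityResult:
    """Compute tail/core transferability and their difference.

    The sign convention: positive coefficients mean the readout is
    C-terminus transferable, negative ones helix-bundle transferable.
    An exact zero is labelled indeterminate rather than forced into
    either class.
    """
    tail = transferability_tail(q)
    core = transferability_core(q)
    coefficient = tail - core
    if coefficient > 0:
        label = "C-terminus transferable"
    elif coefficient < 0:
        label = "helix-bundle transferable"
    else:
        label = "indeterminate"
    return TransferabilityResult(
        readout_id=q.readout_id,
        condition=q.condition,
        tail=tail,
        core=core,
        coefficient=coefficient,
        wt_difference=abs(q["b2AR"] - q["V2R"]),
        label=label,
    )


# ---------------------------------------------------------------------------
# Per-assay harmonization schemes
# ---------------------------------------------------------------------------


def _require_quartet(mapping: Mapping[str, float], what: str) -> dict[str, float]:
    missing = set(QUARTET_NAMES) - set(mapping)
    if missing:
        raise ValueError(f"{what}: missing receptor variants {sorted(missing)}")
    return {name: float(mapping[name]) for name in QUARTET_NAMES}


def harmonize_conformational(
    fingerprints: pd.DataFrame, condition: str = ""
) -> list[ReceptorQuartet]:
    """Harmonize gated conformational fingerprints of the quartet.

    ``fingerprints`` is a matrix with the four receptor names as index
    and sensor positions as columns, holding gated responses (zeros for
    non-responders, assigned *before* this normalization).  Each
    receptor row is divided by its maximum absolute value, so every
    receptor's strongest sensor maps to +/-1; an all-zero row is left at
    zero.  One quartet per sensor position is returned.
    """
    _require_quartet({r: 0.0 for r in fingerprints.index}, "conformational")
    scaled = fingerprints.astype(float).copy()
    for receptor, row in scaled.iterrows():
        peak = row.abs().max()
        if peak > 0:
            scaled.loc[receptor] = row / peak
    return [
        ReceptorQuartet(
            readout_id=str(sensor),
            condition=condition,
            responses={r: float(scaled.loc[r, sensor]) for r in QUARTET_NAMES},
        )
        for sensor in scaled.columns
    ]


def harmonize_erk_auc(
    auc: Mapping[str, float],
    control_peak: Mapping[str, float],
    condition: str = "",
    readout_id: str = "ERK1/2 AUC",
) -> ReceptorQuartet:
    """Harmonize ERK activation AUCs.

    Each receptor's AUC is divided by the value of the time point with
    the maximal response measured in Control cells for that receptor,
    making the quartet comparable despite receptor-specific kinetics.
    """
    auc = _require_quartet(auc, "erk auc")
    peak = _require_quartet(control_peak, "erk control peak")
    for name, p in peak.items():
        if p <= 0:
            raise ValueError(f"non-positive control peak for {name}: {p}")
    return ReceptorQuartet(
        readout_id=readout_id,
        condition=condition,
        responses={name: auc[name] / peak[name] for name in QUARTET_NAMES},
    )


def harmonize_fold_change(
    stimulated: Mapping[str, float],
    basal_reference: Mapping[str, float],
    condition: str = "",
    readout_id: str = "fold change",
) -> ReceptorQuartet:
    """Harmonize recruitment/co-localization style readouts.

    Stimulated signals are divided by the basal reference of the
    GRK-knockout (dQ-GRK) condition per receptor and then by the maximum
    over the quartet, yielding unitless responses in [0, 1] (for
    non-negative inputs).
    """
    stim = _require_quartet(stimulated, "fold-change stimulated")
    ref = _require_quartet(basal_reference, "fold-change basal reference")
    for name, r in ref.items():
        if r == 0:
            raise ValueError(f"zero basal reference for {name}")
    fold = {name: stim[name] / ref[name] for name in QUARTET_NAMES}
    peak = max(abs(v) for v in fold.values())
    if peak == 0:
        raise ValueError("all fold changes are zero; cannot normalize to maximum")
    return ReceptorQuartet(
        readout_id=readout_id,
        condition=condition,
        responses={name: fold[name] / peak for name in QUARTET_NAMES},
    )


def harmonize_phospho(
    normalized_pct: Mapping[str, float],
    condition: str = "",
    readout_id: str = "phosphorylation",
) -> ReceptorQuartet:
    """Harmonize phospho-immunoassay readouts.

    Input values are already percentages of the Control-cell maximum
    (the assay's own negative/positive control rescaling); they are
    converted to unitless fractions.
    """
    pct = _require_quartet(normalized_pct, "phospho")
    return ReceptorQuartet(
        readout_id=readout_id,
        condition=condition,
        responses={name: pct[name] / 100.0 for name in QUARTET_NAMES},
    )


_SCHEMES = {
    "conformational": harmonize_conformational,
    "erk_auc": harmonize_erk_auc,
    "recruitment": harmonize_fold_change,
    "confocal": harmonize_fold_change,
    "phospho": harmonize_phospho,
}


def harmonize(scheme: str, *args, **kwargs):
    """Dispatch to the per-assay harmonization scheme by name.

    ``scheme`` is one of ``conformational``, ``erk_auc``,
    ``recruitment``, ``confocal`` or ``phospho``; arguments are passed
    through to the scheme function.
    """
    try:
        fn = _SCHEMES[scheme]
    except KeyError:
        raise ValueError(
            f"unknown harmonization scheme {scheme!r}; "
            f"expected one of {sorted(_SCHEMES)}"
        ) from None
    return fn(*args, **kwargs)


def transferability_table(
    quartets: Iterable[ReceptorQuartet],
) -> pd.DataFrame:
    """Compute coefficients for many quartets as a tidy table."""
    rows = [transferability_coefficient(q) for q in quartets]
    return pd.DataFrame(
        {
            "readout_id": [r.readout_id for r in rows],
            "condition": [r.condition for r in rows],
            "tail": [r.tail for r in rows],
            "core": [r.core for r in rows],
            "coefficient": [r.coefficient for r in rows],
            "wt_difference": [r.wt_difference for r in rows],
            "label": [r.label for r in rows],
        }
    )
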