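"""Four-parameter logistic (4PL) concentration-response model.

The model is shared between the synthetic-data generator (forward
simulation) and the curve fitter, so both sides agree on one
parameterisation:

    y(x) = bottom + (top - bottom) / (1 + 10**((log_ec50 - x) * hill))

with ``x = log10(concentration in uM)``.  ``hill`` is the Hill slope;
``log_ec50`` is the log10 of the half-maximal effective concentration.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fourpl"]

# Exponent clip keeps 10**z finite for extreme (hill, log_ec50) trials
# during optimisation; 10**50 already saturates the sigmoid to 0/1.
_MAX_EXP = 50.0


def fourpl(x, bottom: float, top: float, log_ec50: float, hill: float):
    """Evaluate the 4PL curve at log10 concentration ``x``.

    Parameters
    ----------
    x : array_like
        log10 of ligand concentration in uM.
    bottom, top : float
        Lower and upper response asymptotes (response units).
    log_ec50 : float
        log10(EC50 / uM): inflection point of the sigmoid.
    hill : float
        Hill slope; the sign sets the direction of the curve.

    Returns
    -------
    ndarray or float
        Model response, same shape as ``x``.
    """
    x = np.asarray(x, dtype=float)
    z = np.clip((log_ec50 - x) * hill, -_MAX_EXP, _MAX_EXP)
    out = bottom + (top - bottom) / (1.0 + 10.0 ** z)
    if out.ndim == 0:
        return float(out)
    return out
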