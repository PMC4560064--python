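"""Scoring functions of the nonlinear regulatory OTU-triplet (NRO) model.

The NRO model assumes a cooperation-competition system: within an ordered
OTU-triplet {O_m, O_c, O_t} the target's standardized relative proportion
(SRP) is high when the cooperator O_m is high and the competitor O_c is low,
and vice versa.  That assumption is encoded by a piecewise tanh response
surface ``P(P_m, P_c)`` predicting the target SRP from the cooperator and
competitor SRPs.  A triplet is scored by

* ``L`` -- lack-of-fit: squared deviation of the observed target series from
  the surface prediction, normalized by the deviation from the target mean
  (0 = perfect fit, 1 = no better than the mean);
* ``D`` -- adjustment: a leave-one-out stability penalty flagging triplets
  whose fit hinges on single time points;
* ``I = L * (1 + D)`` -- the integrated score used for ranking (ascending);
* ``L_d = L / (1 - L)`` -- the odds-like transform used for thresholding.

All functions here are pure and array-friendly; no file I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TripletScores",
    "DegenerateTargetError",
    "model_surface",
    "lack_of_fit",
    "leave_one_out_lack_of_fit",
    "adjustment",
    "integrated_score",
    "ld_transform",
    "score_triplet",
]

#: Gain inside the tanh response; a fixed model constant, not a tuning knob,
#: so scores stay comparable across analyses.
TANH_GAIN = 1.1


class DegenerateTargetError(ValueError):
    """Raised when a target SRP series is constant (zero lack-of-fit denominator)."""


@dataclass(frozen=True)
class TripletScores:
    """Score bundle for one OTU-triplet.

    Attributes
    ----------
    L : float
        Lack-of-fit, >= 0.
    D : float
        Leave-one-out adjustment, >= 0.
    I : float
        Integrated score ``L * (1 + D)``.
    L_d : float
        ``L / (1 - L)`` for L < 1, ``inf`` for L >= 1.
    """

    L: float
    D: float
    I: float
    L_d: float


def model_surface(p_m, p_c):
    """Evaluate the three-dimensional model surface ``P(P_m, P_c)``.

    Parameters
    ----------
    p_m, p_c : array_like
        Cooperator and competitor SRPs in [0, 1]; broadcast together.

    Returns
    -------
    ndarray or float
        Inferred target SRP, clamped to [0, 1].

    Notes
    -----
    The surface has three branches::

        2*tanh(1.1*pm) * (1 - tanh(1.1*pc))      if pm < 0.5 and pc > 0.5
        1 - 2*(1 - tanh(1.1*pm)) * tanh(1.1*pc)  if pm > 0.5 and pc < 0.5
        tanh(1.1*pm) - tanh(1.1*pc) + 0.5        otherwise

    The boundary lines ``pm = 0.5`` and ``pc = 0.5`` belong to the
    "otherwise" branch.  The raw otherwise branch can overshoot [0, 1] by
    about ``tanh(0.55) - 0.5 ~ 5e-4``, hence the clamp, which preserves the
    exact antisymmetry ``P(x, y) + P(y, x) = 1`` and ``P(x, x) = 0.5``.
    """
    p_m = np.asarray(p_m, dtype=float)
    p_c = np.asarray(p_c, dtype=float)
    if np.any((p_m < 0) | (p_m > 1)) or np.any((p_c < 0) | (p_c > 1)):
        raise ValueError("SRP inputs to model_surface must lie in [0, 1]")
    tm = np.tanh(TANH_GAIN * p_m)
    tc = np.tanh(TANH_GAIN * p_c)
    out = tm - tc + 0.5
    branch_a = (p_m < 0.5) & (p_c > 0.5)
    branch_b = (p_m > 0.5) & (p_c < 0.5)
    out = np.where(branch_a, 2.0 * tm * (1.0 - tc), out)
    out = np.where(branch_b, 1.0 - 2.0 * (1.0 - tm) * tc, out)
    out = np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def lack_of_fit(srp_m, srp_c, srp_t) -> float:
    """Lack-of-fit ``L`` of a triplet against the model surface.

    ``L = sum_n (P_tn - Phat_tn)^2 / sum_n (P_tn - Pbar_t)^2`` where
    ``Phat_tn = model_surface(P_mn, P_cn)`` and ``Pbar_t`` is the mean of the
    observed target series.

    Raises
    ------
    DegenerateTargetError
        If the target series is constant.
    """
    srp_m, srp_c, srp_t = _as_series(srp_m, srp_c, srp_t, k_min=2)
    pred = model_surface(srp_m, srp_c)
    if np.ptp(srp_t) == 0.0:
        raise DegenerateTargetError("degenerate target: constant SRP series")
    den = float(np.sum((srp_t - srp_t.mean()) ** 2))
    num = float(np.sum((srp_t - pred) ** 2))
    return num / den


def leave_one_out_lack_of_fit(srp_m, srp_c, srp_t) -> np.ndarray:
    """Vector of ``L_(n)``: the lack-of-fit with time point ``n`` removed.

    The target mean is recomputed on the k-1 remaining points.  If deleting a
    point leaves a constant target series that entry is NaN (skipped later by
    :func:`adjustment`) and a warning is emitted.
    """
    srp_m, srp_c, srp_t = _as_series(srp_m, srp_c, srp_t, k_min=3)
    k = srp_t.size
    out = np.empty(k)
    degenerate = False
    for n in range(k):
        keep = np.arange(k) != n
        try:
            out[n] = lack_of_fit(srp_m[keep], srp_c[keep], srp_t[keep])
        except DegenerateTargetError:
            out[n] = np.nan
            degenerate = True
    if degenerate:
        warnings.warn(
            "leave-one-out produced a constant target subseries; "
            "the affected terms are skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def adjustment(L: float, loo) -> float:
    """Adjustment ``D = sum_n |(L_(n)/L) * log10(L_(n)/L)|``.

    ``L = 0`` yields ``D = 0`` (a perfect fit is maximally reliable) and a
    zero ``L_(n)`` contributes 0 by the limit ``x*log(x) -> 0``.  NaN entries
    of ``loo`` (degenerate leave-one-out subseries) are skipped.
    """
    if L < 0:
        raise ValueError("L must be non-negative")
    loo = np.asarray(loo, dtype=float)
    if L == 0.0:
        return 0.0
    r = loo / L
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.abs(r * np.log10(r))
    terms = np.where(r == 0.0, 0.0, terms)
    return float(np.nansum(terms))


def integrated_score(L: float, D: float) -> float:
    """Integrated score ``I = L * (1 + D)``; triplets are ranked ascending by I."""
    return L * (1.0 + D)


def ld_transform(L):
    """``L_d = L / (1 - L)`` for L < 1; +inf for L >= 1.  Array-friendly."""
    L = np.asarray(L, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(L < 1.0, L / (1.0 - L), np.inf)
    if out.ndim == 0:
        return float(out)
    return out


def score_triplet(srp_m, srp_c, srp_t) -> TripletScores:
    """Compute the full :class:`TripletScores` for one triplet of SRP series."""
    L = lack_of_fit(srp_m, srp_c, srp_t)
    loo = leave_one_out_lack_of_fit(srp_m, srp_c, srp_t)
    D = adjustment(L, loo)
    return TripletScores(L=L, D=D, I=integrated_score(L, D), L_d=ld_transform(L))


def _as_series(*series, k_min: int):
    arrays = [np.asarray(s, dtype=float).ravel() for s in series]
    k = arrays[0].size
    if any(a.size != k for a in arrays):
        raise ValueError("SRP series must have equal length")
    if k < k_min:
        raise ValueError(f"SRP series must have length >= {k_min}")
    for a in arrays:
        if np.any((a < 0) | (a > 1)) or not np.all(np.isfinite(a)):
            raise ValueError("SRP series values must be finite and in [0, 1]")
    return arrays
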