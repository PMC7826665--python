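"""Method-agreement statistics between an estimated and a reference modality.

Tracking accuracy is summarized by the per-axis mean absolute error (MAE)
between time-aligned trajectories (a reference system typically samples
much faster than the scanner, so the denser series is linearly
interpolated onto the sparser one over their overlap).  Agreement between
paired per-trial parameter values is assessed by Pearson regression and
Bland-Altman analysis: bias = mean(est - ref) and the 95% limits of
agreement bias +- 1.96 x SD of the differences (sample SD, n-1
denominator).  Those dashed lines are limits of agreement in the
Bland-Altman sense; some reports label them "95% confidence intervals",
but they bound individual differences, not the bias estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scan_io import TrajectorySample

__all__ = [
    "AlignmentError",
    "AlignedPairSeries",
    "AgreementSummary",
    "align_series",
    "align_values",
    "mae",
    "agreement",
    "bland_altman_plot",
]


class AlignmentError(ValueError):
    """The two series do not overlap in time."""


@dataclass(frozen=True)
class AlignedPairSeries:
    """Two series resampled onto common timestamps (overlap window only).

    ``est``/``ref`` are (n,) arrays for scalar series or (n, k) arrays for
    vector-valued series (e.g. x/y positions).
    """

    timestamps: np.ndarray
    est: np.ndarray
    ref: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        est = np.asarray(self.est, dtype=float)
        ref = np.asarray(self.ref, dtype=float)
        if not (len(t) == len(est) == len(ref)):
            raise ValueError("timestamps, est and ref must have equal length")
        if len(t) < 2:
            raise ValueError("aligned series needs at least 2 samples")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "est", est)
        object.__setattr__(self, "ref", ref)


@dataclass(frozen=True)
class AgreementSummary:
    """MAE, Pearson regression, and Bland-Altman summary of paired values."""

    mae: float
    pearson_r: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


def align_values(t_est, v_est, t_ref, v_ref) -> AlignedPairSeries:
    """Align two sampled series by linear interpolation of the denser one
    onto the sparser one's timestamps, restricted to their time overlap.

    No extrapolation is performed.  Raises :class:`AlignmentError` when
    the series do not overlap.
    """
    t_est = np.asarray(t_est, dtype=float)
    t_ref = np.asarray(t_ref, dtype=float)
    v_est = np.asarray(v_est, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    lo = max(t_est.min(), t_ref.min())
    hi = min(t_est.max(), t_ref.max())
    if hi <= lo:
        raise AlignmentError(f"series do not overlap (gap: [{lo:.3f}, {hi:.3f}] s)")

    est_denser = len(t_est) >= len(t_ref)
    t_target = t_ref if est_denser else t_est
    sel = (t_target >= lo) & (t_target <= hi)
    t_out = t_target[sel]
    if len(t_out) < 2:
        raise AlignmentError("fewer than 2 samples in the overlap window")

    def interp(tq, t, v):
        if v.ndim == 1:
            return np.interp(tq, t, v)
        return np.column_stack([np.interp(tq, t, v[:, j]) for j in range(v.shape[1])])

    if est_denser:
        return AlignedPairSeries(t_out, interp(t_out, t_est, v_est), v_ref[sel])
    return AlignedPairSeries(t_out, v_est[sel], interp(t_out, t_ref, v_ref))


def _samples_to_arrays(samples: list[TrajectorySample]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([s.timestamp for s in samples])
    xy = np.array([[s.position.x, s.position.y] for s in samples])
    return t, xy


def align_series(
    est: list[TrajectorySample], ref: list[TrajectorySample]
) -> AlignedPairSeries:
    """Align two trajectories (x/y positions) onto common timestamps."""
    if not est or not ref:
        raise AlignmentError("cannot align an empty trajectory")
    t_e, v_e = _samples_to_arrays(est)
    t_r, v_r = _samples_to_arrays(ref)
    return align_values(t_e, v_e, t_r, v_r)


def mae(series: AlignedPairSeries):
    """Mean absolute error; a scalar for 1-D series, per-axis for 2-D."""
    err = np.abs(series.est - series.ref)
    out = err.mean(axis=0)
    return float(out) if np.ndim(out) == 0 else out


def agreement(est_values, ref_values) -> AgreementSummary:
    """Pearson regression + Bland-Altman agreement of paired values.

    Requires at least 3 pairs and non-zero variance in both series (the
    correlation is undefined otherwise); the p-value is the exact
    two-sided t-transform with n-2 degrees of freedom.
    """
    est = np.asarray(est_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("est and ref must be 1-D arrays of equal length")
    n = len(est)
    if n < 3:
        raise ValueError(f"need >= 3 paired values, got {n}")
    if np.std(est) == 0 or np.std(ref) == 0:
        raise ValueError("correlation undefined: one series has zero variance")
    r, p = stats.pearsonr(est, ref)
    diff = est - ref
    bias = float(diff.mean())
    sd = float(np.std(diff, ddof=1))
    return AgreementSummary(
        mae=float(np.abs(diff).mean()),
        pearson_r=float(r),
        p_value=float(p),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def bland_altman_plot(est_values, ref_values, ax=None, label: str | None = None):
    """Convenience Bland-Altman plot (requires matplotlib)."""
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    est = np.asarray(est_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    summ = agreement(est, ref)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((est + ref) / 2.0, est - ref, s=18)
    ax.axhline(summ.bias, color="k")
    ax.axhline(summ.loa_low, color="k", linestyle="--")
    ax.axhline(summ.loa_high, color="k", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (est - ref)")
    if label:
        ax.set_title(label)
    return ax
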