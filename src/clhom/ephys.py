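"""Electrophysiology analysis operators.

E_GABA from GABA I-V relations (x-axis intercept of the least-squares line,
with off-line liquid-junction-potential correction), [Cl-]_i estimation via
GHK inversion, depression metrics of evoked-IPSC trains (25 pulses at
20 Hz), and charge-transfer integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .ionlib import IonConditions, cl_from_reversal

__all__ = [
    "JUNCTION_OFFSETS",
    "IVRecording",
    "TrainRecording",
    "DepressionFit",
    "fit_egaba",
    "estimate_cl",
    "normalize_and_bin",
    "fit_depression",
    "depression_difference",
    "charge_transfer",
]

#: Liquid-junction-potential presets (mV) by pipette solution.
JUNCTION_OFFSETS = {"high_cl": 8.0, "low_cl": 9.0}

TRAIN_LENGTH = 25  # pulses per 20 Hz stimulation train


@dataclass
class IVRecording:
    """Peak GABA current vs holding potential, possibly with repeats.

    ``voltages`` and ``currents`` are parallel arrays; repeated voltage values
    are repeats of the same step (the protocol averages three responses per
    step).  ``junction_offset`` (mV) is subtracted from the fitted reversal.
    """

    voltages: np.ndarray  # mV
    currents: np.ndarray  # pA
    junction_offset: float = 0.0
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape or self.voltages.ndim != 1:
            raise ValueError("voltages and currents must be 1-D arrays of equal length")
        uniq, counts = np.unique(self.voltages, return_counts=True)
        if uniq.size < 2:
            raise ValueError("need at least two distinct holding voltages")
        self.excess_repeats = bool(np.any(counts > 3))

    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        """Repeat-averaged (voltage, mean current) pairs, sorted by voltage."""
        uniq = np.unique(self.voltages)
        means = np.array([self.currents[self.voltages == v].mean() for v in uniq])
        return uniq, means


@dataclass
class TrainRecording:
    """Per-stimulus peak amplitudes of one 25-pulse 20 Hz eIPSC train."""

    amplitudes: np.ndarray  # pA, length 25
    holding_mv: float = 0.0  # 0 or -90 mV protocol tag
    trace: np.ndarray | None = None  # optional full current trace, pA
    trace_dt_ms: float | None = None
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.size != TRAIN_LENGTH:
            raise ValueError(f"expected {TRAIN_LENGTH} amplitudes, got {self.amplitudes.size}")
        if self.amplitudes[0] == 0:
            raise ValueError("first eIPSC amplitude must be non-zero for normalization")


def fit_egaba(iv: IVRecording) -> tuple[float, float]:
    """Reversal potential (mV) and slope conductance (nS) from an I-V relation.

    Repeats are averaged per voltage, an ordinary least-squares line is fit,
    and E_GABA is the x-axis intercept minus the junction offset.
    """
    v, i = iv.averaged()
    slope, intercept = np.polyfit(v, i, 1)
    if abs(slope) < 1e-12:
        raise ValueError("zero slope conductance; reversal potential undefined")
    e_rev = -intercept / slope
    return float(e_rev - iv.junction_offset), float(slope)


def estimate_cl(iv: IVRecording, cond: IonConditions, ratio: float = 0.25) -> float:
    """[Cl-]_i (mM) implied by the fitted E_GABA under the given conditions."""
    e_gaba, _ = fit_egaba(iv)
    return cl_from_reversal(e_gaba, cond, ratio)


def normalize_and_bin(
    train: TrainRecording, bin_stimuli: tuple[int, ...] = (5, 10, 15, 20, 25)
) -> np.ndarray:
    """Relative amplitudes binned as 3-stimulus means centred every 5 stimuli.

    Amplitudes are normalized to the first eIPSC; each bin centred on stimulus
    k averages stimuli {k-1, k, k+1}, clipped at the ends of the train (so the
    bin at 25 averages {24, 25}).  The centring of the 3-point window is a
    package convention; pass different ``bin_stimuli`` to re-anchor.
    """
    rel = train.amplitudes / train.amplitudes[0]
    out = []
    for k in bin_stimuli:
        lo = max(k - 1, 1)
        hi = min(k + 1, rel.size)
        out.append(rel[lo - 1 : hi].mean())  # stimulus numbers are 1-based
    return np.asarray(out)


@dataclass
class DepressionFit:
    plateau: float
    rate: float  # K, per stimulus
    residual: float  # RMS of fit residuals
    flags: tuple[str, ...] = ()


def _one_phase(n: np.ndarray, plateau: float, rate: float) -> np.ndarray:
    return plateau + (1.0 - plateau) * np.exp(-rate * n)


def fit_depression(
    binned: np.ndarray, bin_stimuli: tuple[int, ...] = (5, 10, 15, 20, 25)
) -> DepressionFit:
    """One-phase exponential decay fit of binned relative amplitudes.

    Model y(n) = plateau + (1 - plateau) exp(-K n) with n the number of
    stimuli after the first (unit amplitude at n = 0).  A flat train leaves
    the rate unconstrained (flagged); a fitted plateau below zero is clipped
    to zero and flagged.
    """
    y = np.asarray(binned, dtype=float)
    if y.size < 3:
        raise ValueError("need at least three binned points for a two-parameter fit")
    n = np.asarray(bin_stimuli, dtype=float) - 1.0
    if np.ptp(y) < 1e-12:
        return DepressionFit(plateau=float(y.mean()), rate=0.0, residual=0.0,
                             flags=("rate_unconstrained",))
    try:
        popt, _ = curve_fit(
            _one_phase, n, y, p0=(max(float(y[-1]), 1e-3), 0.2),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"one-phase decay fit did not converge (initial guess plateau={y[-1]:.3g}, K=0.2)"
        ) from exc
    plateau, rate = float(popt[0]), float(popt[1])
    flags: list[str] = []
    if plateau < 0:
        plateau = 0.0
        flags.append("plateau_clipped")
        popt2, _ = curve_fit(lambda nn, k: _one_phase(nn, 0.0, k), n, y, p0=(rate,), maxfev=20000)
        rate = float(popt2[0])
    resid = float(np.sqrt(np.mean((_one_phase(n, plateau, rate) - y) ** 2)))
    return DepressionFit(plateau=plateau, rate=rate, residual=resid, flags=tuple(flags))


def depression_difference(train_0mv: TrainRecording, train_minus90mv: TrainRecording) -> float:
    """Cl--accumulation component of train depression.

    End-of-train depression fraction (1 - last bin) at 0 mV minus the same at
    -90 mV; the -90 mV train isolates Cl--independent depression, so the
    difference reflects Cl- accumulation.
    """
    d0 = 1.0 - normalize_and_bin(train_0mv)[-1]
    d90 = 1.0 - normalize_and_bin(train_minus90mv)[-1]
    return float(d0 - d90)


def charge_transfer(
    trace: np.ndarray,
    dt: float,
    window: tuple[float, float],
    baseline_window: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal charge integral (pC) of a baseline-subtracted current trace.

    ``trace`` in pA sampled at ``dt`` ms; ``window`` and the optional
    pre-stimulus ``baseline_window`` are (start, stop) in ms.  The baseline is
    the mean current over ``baseline_window`` (zero if not given).
    """
    trace = np.asarray(trace, dtype=float)
    t = np.arange(trace.size) * dt
    lo, hi = window
    if lo < 0 or hi > t[-1] or hi <= lo:
        raise ValueError("integration window must lie within the trace")
    baseline = 0.0
    if baseline_window is not None:
        bsel = (t >= baseline_window[0]) & (t <= baseline_window[1])
        if not np.any(bsel):
            raise ValueError("baseline window contains no samples")
        baseline = trace[bsel].mean()
    sel = (t >= lo) & (t <= hi)
    q_pa_ms = np.trapezoid(trace[sel] - baseline, t[sel])
    return float(q_pa_ms * 1e-3)  # pA ms -> pC
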