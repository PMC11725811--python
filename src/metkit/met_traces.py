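"""Analysis of mechanoelectrical transducer (MET) currents.

Hair-bundle deflection gates MET channels at the stereocilia tips.  Under
voltage clamp, a sinusoidal fluid-jet stimulus drives the bundle back and
forth; the recorded current alternates between the fully-open and
fully-closed levels of the transducer conductance once the stimulus
saturates.  This module extracts, from stimulus-annotated current traces:

* the cycle-averaged response to a periodic driver,
* the peak-to-peak (excitatory minus inhibitory) MET current,
* the resting open probability
  ``P_open = (i_hold - i_inhib) / (i_exc - i_inhib)``,
  i.e. the fraction of the maximal MET current flowing with the bundle at
  its resting position,
* the peak-to-peak current-voltage relation and its interpolated reversal
  potential, and
* a saturation check for protocols that ramp the stimulus amplitude.

Sign conventions: inward current is negative; positive driver voltage (DV)
deflects the bundle in the excitatory direction (toward the tallest
stereocilia row) and opens channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


__all__ = [
    "CurrentTrace",
    "CycleAverage",
    "METSummary",
    "IVCurve",
    "SaturationResult",
    "AperiodicDriverError",
    "cycle_average",
    "met_summary",
    "peak_to_peak_current",
    "resting_open_probability",
    "build_iv_and_reversal",
    "detect_saturation",
    "summaries_to_frame",
]

#: default pre-stimulus baseline window when the trace carries no annotation
DEFAULT_BASELINE_S = 0.010

#: |i_max| below this multiple of the baseline noise SD flags P_open as
#: unreliable (P_open is meaningless without a transducer current)
MIN_SNR = 5.0


class AperiodicDriverError(ValueError):
    """Raised when cycle averaging is asked for a non-periodic driver."""


@dataclass
class CurrentTrace:
    """One voltage-clamp current recording with its stimulus record.

    ``samples`` is the membrane current in pA, ``driver`` the fluid-jet
    driver voltage (DV, volts) on the same time base.  ``stim_onset_s`` /
    ``stim_offset_s`` optionally annotate the stimulus window; when absent
    the first :data:`DEFAULT_BASELINE_S` seconds are taken as baseline.
    """

    samples: np.ndarray
    sample_rate: float
    driver: np.ndarray
    v_m: float
    buffer_label: str = "EGTA_1mM"
    cell_id: str = "cell0"
    genotype: str = "control"
    age: str = "P20"
    stim_onset_s: float | None = None
    stim_offset_s: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.driver = np.asarray(self.driver, dtype=float)
        if self.samples.shape != self.driver.shape:
            raise ValueError("samples and driver must have the same length")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    def baseline_slice(self) -> slice:
        if self.stim_onset_s is not None:
            n = int(round(self.stim_onset_s * self.sample_rate))
        else:
            n = int(round(DEFAULT_BASELINE_S * self.sample_rate))
        return slice(0, max(1, min(n, self.samples.size)))


@dataclass
class CycleAverage:
    """Mean single-cycle response of a periodic stimulus protocol."""

    current: np.ndarray
    driver: np.ndarray
    period_samples: int
    n_cycles: int
    sample_rate: float


@dataclass
class METSummary:
    """Per-trace MET current summary.

    ``i_max = i_exc - i_inhib`` (signed peak-to-peak transducer current);
    ``p_open_rest`` is reported raw (not clamped) with a quality flag when
    it falls outside [-0.05, 1.05].
    """

    i_hold: float
    i_inhib: float
    i_exc: float
    i_max: float
    p_open_rest: float
    baseline_sd: float
    flags: list[str] = field(default_factory=list)

    @property
    def i_max_magnitude(self) -> float:
        return abs(self.i_max)


@dataclass
class IVCurve:
    """Peak-to-peak current-voltage relation with interpolated reversal."""

    v_mV: np.ndarray
    i_pp_pA: np.ndarray
    reversal_mV: float | None


@dataclass
class SaturationResult:
    saturated: bool
    i_max_final: float
    i_max_series: np.ndarray
    amplitudes: np.ndarray


def _stimulus_window(driver: np.ndarray) -> tuple[int, int]:
    peak = np.max(np.abs(driver))
    if peak == 0:
        raise AperiodicDriverError(
            "driver carries no stimulus; cycle averaging is undefined"
        )
    on = np.nonzero(np.abs(driver) > 0.05 * peak)[0]
    return int(on[0]), int(on[-1]) + 1


def _detect_period(d: np.ndarray) -> int:
    """Driver period in samples from the autocorrelation's first peak."""
    d0 = d - d.mean()
    if np.allclose(d0, 0):
        raise AperiodicDriverError(
            "driver is constant over the stimulus window; "
            "use step-mode analysis"
        )
    ac = np.correlate(d0, d0, mode="full")[d0.size - 1 :]
    neg = np.nonzero(ac < 0)[0]
    if neg.size == 0:
        raise AperiodicDriverError(
            "driver autocorrelation never decays: aperiodic stimulus; "
            "use step-mode analysis"
        )
    lo = int(neg[0])
    hi = d0.size // 2 + 1
    if hi <= lo:
        raise AperiodicDriverError("fewer than two stimulus cycles detected")
    period = lo + int(np.argmax(ac[lo:hi]))
    if ac[period] < 0.5 * ac[0]:
        raise AperiodicDriverError(
            "driver is not periodic (autocorrelation peak below 0.5); "
            "use step-mode analysis"
        )
    return period


def cycle_average(trace: CurrentTrace) -> CycleAverage:
    """Average the response over complete stimulus cycles.

    The driver period is detected from its autocorrelation inside the
    stimulus-on window (the stimulus annotation, when present, anchors the
    window so that cycles start at stimulus onset); at least two full
    cycles are required.  Averaging n cycles shrinks uncorrelated noise by
    ~sqrt(n).
    """
    start, stop = _stimulus_window(trace.driver)
    if trace.stim_onset_s is not None:
        start = int(round(trace.stim_onset_s * trace.sample_rate))
    period = _detect_period(trace.driver[start:stop])
    # the sinusoid's sub-threshold tails belong to the cycle: round the
    # detected stimulus length to whole periods
    n_cycles = int(round((stop - start) / period))
    n_cycles = min(n_cycles, (trace.samples.size - start) // period)
    if n_cycles < 2:
        raise AperiodicDriverError("fewer than two stimulus cycles detected")
    n = n_cycles * period
    cur = trace.samples[start : start + n].reshape(n_cycles, period).mean(axis=0)
    drv = trace.driver[start : start + n].reshape(n_cycles, period).mean(axis=0)
    return CycleAverage(cur, drv, period, n_cycles, trace.sample_rate)


def _smooth_cycle(current: np.ndarray, period: int) -> np.ndarray:
    """Circular moving-average smoothing before taking extrema.

    A raw extremum of a noisy averaged cycle is biased outward by the
    extreme-value statistics of the residual noise; a boxcar over ~1/16 of
    the cycle removes that bias while preserving the saturated plateaus,
    and (unlike polynomial smoothing) never overshoots the data range.
    """
    window = max(3, (period // 16) | 1)
    if window >= current.size:
        return current
    kernel = np.full(window, 1.0 / window)
    padded = np.concatenate([current[-(window // 2):], current,
                             current[: window // 2]])
    return np.convolve(padded, kernel, mode="valid")


def _phase_extrema(
    current: np.ndarray, driver: np.ndarray
) -> tuple[float, float]:
    """(i_exc, i_inhib) from the smoothed cycle.

    Phases follow the driver sign (positive DV = excitatory); samples at
    exactly DV = 0 belong to neither phase.  The transduction direction
    (inward vs outward on opening) is chosen from the data as whichever
    excitatory/inhibitory extremum pairing yields the larger peak-to-peak
    current.
    """
    exc = current[driver > 0]
    inh = current[driver < 0]
    if exc.size == 0 or inh.size == 0:
        raise ValueError("driver lacks an excitatory or inhibitory phase")
    inward = exc.min() - inh.max()
    outward = exc.max() - inh.min()
    if abs(inward) >= abs(outward):
        return float(exc.min()), float(inh.max())
    return float(exc.max()), float(inh.min())


def _step_extrema(trace: CurrentTrace) -> tuple[float, float]:
    """Extrema for step (aperiodic) protocols, by driver sign."""
    cur = trace.samples
    drv = trace.driver
    exc = cur[drv > 0]
    inh = cur[drv < 0]
    base = float(np.mean(cur[trace.baseline_slice()]))
    if exc.size == 0:
        raise ValueError("step protocol has no excitatory (DV > 0) phase")
    e_lo, e_hi = float(np.min(exc)), float(np.max(exc))
    i_exc = e_lo if abs(e_lo - base) >= abs(e_hi - base) else e_hi
    if inh.size == 0:
        return i_exc, float("nan")
    i_lo, i_hi = float(np.min(inh)), float(np.max(inh))
    i_inhib = i_lo if abs(i_lo - base) >= abs(i_hi - base) else i_hi
    return i_exc, i_inhib


def met_summary(trace: CurrentTrace, mode: str = "auto") -> METSummary:
    """Full per-trace summary: holding, phase extrema, i_max and P_open.

    ``mode``: "sinusoid" forces cycle averaging, "step" forces step-mode
    phase extrema, "auto" tries the former and falls back to the latter.
    """
    base = trace.samples[trace.baseline_slice()]
    i_hold = float(np.mean(base))
    baseline_sd = float(np.std(base))
    flags: list[str] = []

    if mode not in ("auto", "sinusoid", "step"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "step":
        i_exc, i_inhib = _step_extrema(trace)
    else:
        try:
            ca = cycle_average(trace)
            smooth = _smooth_cycle(ca.current, ca.period_samples)
            i_exc, i_inhib = _phase_extrema(smooth, ca.driver)
        except AperiodicDriverError:
            if mode == "sinusoid":
                raise
            i_exc, i_inhib = _step_extrema(trace)
            flags.append("step_mode")

    i_max = i_exc - i_inhib
    if np.isnan(i_inhib):
        p_open = float("nan")
        flags.append("no_inhibitory_phase")
    elif i_max == 0:
        p_open = float("nan")
        flags.append("zero_met_current")
    else:
        p_open = (i_hold - i_inhib) / i_max
    if baseline_sd > 0 and abs(i_max) < MIN_SNR * baseline_sd:
        flags.append("low_met_current")
    if np.isfinite(p_open) and not (-0.05 <= p_open <= 1.05):
        flags.append("p_open_out_of_range")
    return METSummary(i_hold, i_inhib, i_exc, i_max, p_open, baseline_sd, flags)


def peak_to_peak_current(
    trace: CurrentTrace, mode: str = "auto"
) -> tuple[float, float, float]:
    """(i_exc, i_inhib, i_max) of the averaged response."""
    s = met_summary(trace, mode=mode)
    return s.i_exc, s.i_inhib, s.i_max


def resting_open_probability(trace: CurrentTrace, mode: str = "auto") -> float:
    """Fraction of the maximal MET current active at rest.

    ``(i_hold - i_inhib) / i_max``: the holding current minus the current
    during inhibitory bundle deflection, divided by the peak-to-peak
    (maximal) MET current.  Use :func:`met_summary` for quality flags.
    """
    return met_summary(trace, mode=mode).p_open_rest


def build_iv_and_reversal(
    traces: "list[CurrentTrace]", mode: str = "auto"
) -> IVCurve:
    """Signed peak-to-peak I-V relation and its zero crossing.

    The reversal potential is linearly interpolated between the pair of
    adjacent voltages bracketing the sign change of the transduction
    current; with no sign change it is reported absent (None), never
    extrapolated.
    """
    traces = sorted(traces, key=lambda t: t.v_m)
    v = np.array([t.v_m for t in traces], dtype=float)
    if v.size < 2:
        warnings.warn("fewer than two voltages: reversal undefined")
        i = np.array([met_summary(t, mode=mode).i_max for t in traces])
        return IVCurve(v, i, None)
    if np.any(np.diff(v) <= 0):
        raise ValueError("membrane potentials must be strictly increasing")
    i = np.array([met_summary(t, mode=mode).i_max for t in traces])

    reversal: float | None = None
    for k in range(v.size - 1):
        a, b = i[k], i[k + 1]
        if a == 0:
            reversal = float(v[k])
            break
        if a * b < 0:
            reversal = float(v[k] - a * (v[k + 1] - v[k]) / (b - a))
            break
    else:
        if i[-1] == 0:
            reversal = float(v[-1])
    if reversal is None:
        warnings.warn("transduction current does not change sign: "
                      "reversal potential absent")
    return IVCurve(v, i, reversal)


def detect_saturation(
    traces: "list[CurrentTrace]", rel_tol: float = 0.05, mode: str = "auto"
) -> SaturationResult:
    """Saturation check for a gradually-increased stimulus series.

    ``traces`` must be ordered by non-decreasing stimulus amplitude (taken
    as max |DV|).  The response is saturated when the last amplitude
    increment grows |i_max| by less than ``rel_tol`` (default 5%).
    """
    if len(traces) < 2:
        raise ValueError("need at least two stimulus amplitudes")
    amps = np.array([float(np.max(np.abs(t.driver))) for t in traces])
    if np.any(np.diff(amps) < -1e-12 * max(amps.max(), 1.0)):
        raise ValueError("stimulus amplitudes must be non-decreasing")
    i_abs = np.array([abs(met_summary(t, mode=mode).i_max) for t in traces])
    prev, last = i_abs[-2], i_abs[-1]
    if prev > 0:
        saturated = (last - prev) / prev < rel_tol
    else:
        saturated = last == 0
    return SaturationResult(bool(saturated), float(i_abs[-1]), i_abs, amps)


def summaries_to_frame(
    traces: "list[CurrentTrace]", mode: str = "auto"
) -> pd.DataFrame:
    """Per-cell summary rows (cell_id, genotype, age, v_mV, i_max_pA,
    p_open, flags) ready for CSV export."""
    rows = []
    for t in traces:
        s = met_summary(t, mode=mode)
        rows.append(
            {
                "cell_id": t.cell_id,
                "genotype": t.genotype,
                "age": t.age,
                "v_mV": t.v_m,
                "buffer": t.buffer_label,
                "i_hold_pA": s.i_hold,
                "i_exc_pA": s.i_exc,
                "i_inhib_pA": s.i_inhib,
                "i_max_pA": s.i_max,
                "p_open": s.p_open_rest,
                "flags": ";".join(s.flags),
            }
        )
    return pd.DataFrame(rows)
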