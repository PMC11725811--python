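"""Sub-pixel hair-bundle tracking and fluid-jet stiffness estimation.

A fast camera films the hair bundle while a fluid jet applies force steps.
Reslicing the movie along a line orthogonal to the bundle edge gives a
kymograph (space x time); each row's intensity profile is min-max
normalized and fitted with a Gaussian amplitude function
``offset + A * exp(-(p - c)^2 / (2 s^2))`` whose center ``c`` localizes the
bundle to a small fraction of a pixel.  The apparent overall steady-state
bundle stiffness is the applied force divided by the displacement at the
end of the step, ``k = F / x_steady`` (nN / nm -> mN/m after unit scaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage.measure import profile_line

__all__ = [
    "Kymograph",
    "GaussianFit",
    "DisplacementTrace",
    "StiffnessEstimate",
    "reslice_kymograph",
    "normalize_profile",
    "fit_gaussian_position",
    "track_displacement",
    "estimate_stiffness",
]

#: fraction of failed row fits above which a trace is flagged unusable
MAX_FAIL_FRACTION = 0.20

#: steady-state window = this trailing fraction of the force step
STEADY_FRACTION = 0.20


@dataclass
class Kymograph:
    """Space x time reslice of a bundle movie.

    ``image`` has one row per frame; ``positions`` are the sample positions
    along the measurement line in nm.  ``stimulus`` (optional) is the
    applied force per frame in nN, aligned to rows.
    """

    image: np.ndarray
    pixel_size: float
    frame_rate: float
    stimulus: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("kymograph image must be 2-D (frames x positions)")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.stimulus is not None:
            self.stimulus = np.asarray(self.stimulus, dtype=float)
            if self.stimulus.size != self.image.shape[0]:
                raise ValueError("stimulus length must equal the frame count")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.image.shape[1]) * self.pixel_size


@dataclass
class GaussianFit:
    center: float
    sigma: float
    amplitude: float
    offset: float
    fit_ok: bool


@dataclass
class DisplacementTrace:
    """Per-frame bundle position relative to the pre-stimulus mean."""

    t: np.ndarray
    x: np.ndarray
    fit_ok: np.ndarray
    fit_sigma: np.ndarray
    amplitude: np.ndarray
    offset: np.ndarray
    usable: bool


@dataclass
class StiffnessEstimate:
    force: float            # nN
    x_steady: float         # nm
    k: float                # mN/m
    window: tuple[int, int]  # frame range used for the steady state
    quality: float          # sd(x in window) / |x_steady|; lower is better
    flags: list[str]


def reslice_kymograph(movie, line=None) -> Kymograph:
    """Build a kymograph from a movie: row f is frame f's line profile.

    ``line`` selects the measurement line within each frame:

    * ``None`` - the middle image row (the line must be orthogonal to the
      bundle edge, i.e. along the motion axis);
    * ``int`` - a specific row index;
    * ``(r0, c0, r1, c1)`` - an arbitrary line, sampled with
      :func:`skimage.measure.profile_line`.
    """
    frames = np.asarray(movie.frames, dtype=float)
    n_frames, ny, nx = frames.shape
    stim = getattr(movie, "stimulus_force", None)
    if line is None:
        line = ny // 2
    if isinstance(line, (int, np.integer)):
        if not 0 <= line < ny:
            raise ValueError(f"line row {line} outside frame bounds (0..{ny - 1})")
        image = frames[:, line, :]
    else:
        r0, c0, r1, c1 = line
        for r, c in ((r0, c0), (r1, c1)):
            if not (0 <= r <= ny - 1 and 0 <= c <= nx - 1):
                raise ValueError(f"line endpoint ({r}, {c}) outside frame bounds")
        image = np.stack(
            [profile_line(f, (r0, c0), (r1, c1), order=1, mode="constant")
             for f in frames]
        )
    return Kymograph(image, movie.pixel_size, movie.frame_rate, stimulus=stim)


def normalize_profile(values: np.ndarray) -> np.ndarray:
    """Min-max normalize a gray-value profile to [0, 1].

    Invariant under affine changes of camera gain/offset.  A constant
    profile has no contrast and raises ``ValueError``.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("no contrast: constant intensity profile")
    return (v - lo) / (hi - lo)


def _gauss(p, c, s, a, o):
    return o + a * np.exp(-((p - c) ** 2) / (2.0 * s**2))


def fit_gaussian_position(
    positions: np.ndarray,
    values: np.ndarray,
    p0: tuple[float, float, float, float] | None = None,
) -> GaussianFit:
    """Least-squares Gaussian amplitude fit of a (raw) intensity profile.

    The profile is min-max normalized before fitting, so the returned
    amplitude and offset are in normalized units; ``center`` and ``sigma``
    are in the units of ``positions`` (nm).  Initialization: intensity-
    weighted centroid, sigma = 2 pixels.  ``fit_ok`` is False when the
    solver fails, the center leaves the profile support, or sigma collapses
    below half a pixel; no exception is raised for fit failures.
    """
    p = np.asarray(positions, dtype=float)
    if p.size < 5:
        raise ValueError("need at least 5 profile samples")
    pixel = float(np.median(np.diff(p)))
    try:
        v = normalize_profile(values)
    except ValueError:
        return GaussianFit(float("nan"), float("nan"), float("nan"),
                           float("nan"), False)
    if p0 is None:
        c0 = float(np.sum(p * v) / np.sum(v))
        p0 = (c0, 2.0 * pixel, 1.0, 0.0)
    try:
        popt, _ = curve_fit(_gauss, p, v, p0=p0, maxfev=2000)
    except (RuntimeError, ValueError):
        return GaussianFit(float("nan"), float("nan"), float("nan"),
                           float("nan"), False)
    c, s, a, o = (float(x) for x in popt)
    s = abs(s)
    ok = (p[0] <= c <= p[-1]) and s >= 0.5 * pixel
    return GaussianFit(c, s, a, o, bool(ok))


def _pre_stimulus_frames(n_frames: int, stimulus: np.ndarray | None) -> int:
    """Frames before stimulus onset (default: leading 10% of the movie)."""
    if stimulus is not None:
        on = np.nonzero(stimulus != 0)[0]
        if on.size and on[0] > 0:
            return int(on[0])
    return max(1, n_frames // 10)


def track_displacement(kymo: Kymograph) -> DisplacementTrace:
    """Fit every kymograph row; report position relative to the mean
    pre-stimulus center (positive toward the excitatory direction).

    Rows whose fit fails are flagged and excluded from the reference;
    a trace with more than 20% failed rows is flagged unusable.
    """
    n_frames = kymo.image.shape[0]
    pos = kymo.positions
    centers = np.full(n_frames, np.nan)
    sigmas = np.full(n_frames, np.nan)
    amps = np.full(n_frames, np.nan)
    offs = np.full(n_frames, np.nan)
    ok = np.zeros(n_frames, dtype=bool)
    p0 = None
    for f in range(n_frames):
        fit = fit_gaussian_position(pos, kymo.image[f], p0=p0)
        if fit.fit_ok:
            centers[f] = fit.center
            sigmas[f] = fit.sigma
            amps[f] = fit.amplitude
            offs[f] = fit.offset
            ok[f] = True
            p0 = (fit.center, fit.sigma, fit.amplitude, fit.offset)
        else:
            p0 = None
    n_pre = _pre_stimulus_frames(n_frames, kymo.stimulus)
    pre_ok = ok[:n_pre]
    if not pre_ok.any():
        warnings.warn("no usable pre-stimulus frames; reference set to the "
                      "first fitted center")
        ref = centers[ok][0] if ok.any() else float("nan")
    else:
        ref = float(np.mean(centers[:n_pre][pre_ok]))
    x = centers - ref
    usable = (~ok).mean() <= MAX_FAIL_FRACTION
    t = np.arange(n_frames) / kymo.frame_rate
    return DisplacementTrace(t, x, ok, sigmas, amps, offs, bool(usable))


def _find_step(stimulus: np.ndarray) -> tuple[int, int, float]:
    """Longest contiguous nonzero-force segment: (start, stop, force)."""
    on = stimulus != 0
    if not on.any():
        raise ValueError("stimulus record contains no force step")
    edges = np.flatnonzero(np.diff(on.astype(int)))
    starts = [0] if on[0] else []
    starts += [int(e) + 1 for e in edges if on[e + 1]]
    stops = [int(e) + 1 for e in edges if on[e]]
    if on[-1]:
        stops.append(on.size)
    seg = max(zip(starts, stops), key=lambda ab: ab[1] - ab[0])
    force = float(np.mean(stimulus[seg[0] : seg[1]]))
    if np.ptp(stimulus[seg[0] : seg[1]]) > 0.01 * abs(force):
        warnings.warn("force is not constant over the detected step")
    return seg[0], seg[1], force


def estimate_stiffness(
    trace: DisplacementTrace,
    stimulus: np.ndarray,
    steady_fraction: float = STEADY_FRACTION,
) -> StiffnessEstimate:
    """Steady-state stiffness from a force-step displacement trace.

    ``x_steady`` is the mean displacement over the trailing
    ``steady_fraction`` of the step (default 20%); ``k = F / x_steady``
    with F in nN and x in nm gives k in mN/m after the factor 1000.
    A zero applied force is an error; a displacement indistinguishable
    from zero (|x_steady| < 3 x pre-stimulus SD) leaves k undefined with a
    flag.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.size != trace.x.size:
        raise ValueError("stimulus length must equal the trace length")
    start, stop, force = _find_step(stimulus)
    if force == 0:
        raise ValueError("zero force step: stiffness undefined")
    n_win = max(1, int(round(steady_fraction * (stop - start))))
    w0, w1 = stop - n_win, stop
    sel = trace.fit_ok[w0:w1]
    flags: list[str] = []
    if not sel.any():
        raise ValueError("no usable frames in the steady-state window")
    xw = trace.x[w0:w1][sel]
    x_steady = float(np.mean(xw))
    n_pre = _pre_stimulus_frames(trace.x.size, stimulus)
    pre = trace.x[:n_pre][trace.fit_ok[:n_pre]]
    pre_sd = float(np.std(pre)) if pre.size else 0.0
    if abs(x_steady) < 3.0 * pre_sd:
        flags.append("displacement_indistinguishable_from_zero")
        k = float("nan")
    else:
        k = force / x_steady * 1000.0
    quality = float(np.std(xw) / abs(x_steady)) if x_steady else float("inf")
    if not trace.usable:
        flags.append("trace_unusable")
    return StiffnessEstimate(force, x_steady, k, (w0, w1), quality, flags)
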