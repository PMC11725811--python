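"""Ground-truth synthetic data for every analysis modality.

This module emulates the raw data of a hair-cell mechanotransduction study
so that every analysis stage can be validated against known ground truth:

* MET current traces under 50 Hz sinusoidal (or step) fluid-jet
  stimulation across a -124 to +96 mV membrane-potential series.  The
  transducer is a two-state Boltzmann,
  ``P_open(x) = 1 / (1 + exp(-(x - x_half) / lambda))``, driven by the
  damped-spring response of the bundle to the low-passed jet force.
  Ca2+-dependent adaptation is a static set-point shift: the half-
  activation point moves by ``adapt_gain * max(0, E_Ca - V)`` nm, so
  hyperpolarized cells (large Ca2+ driving force) sit at a lower resting
  open probability; the shift is zeroed under 5 mM BAPTA, which emulates
  the large resting MET current seen with fast Ca2+ buffering.
* Bundle movies whose bright edge follows a force step with a known
  stiffness (steady-state displacement F / k), imaged as a Gaussian line
  profile with shot noise.
* Two-channel confocal stacks with compartment-specific MYO7A / F-actin
  intensity ratios.
* Differential-expression tables whose rows pass or fail the DEG
  thresholds exactly as a known set-membership structure dictates.

All randomness flows through explicit integer seeds; identical spec + seed
reproduces bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .bundle_motion import Kymograph  # noqa: F401  (re-exported context)
from .confocal import LANDMARK_NAMES, ConfocalStack
from .met_traces import CurrentTrace

__all__ = [
    "E_REV_CA_MV",
    "ChannelModel",
    "FluidJetModel",
    "Sinusoid",
    "Step",
    "TraceProtocol",
    "MovieSpec",
    "BundleMovie",
    "StackSpec",
    "GeneSetSpec",
    "GeneUniverseSpec",
    "METTraceSimulation",
    "MovieSimulation",
    "StackSimulation",
    "GeneTableSimulation",
    "VOLTAGE_SERIES",
    "boltzmann_open_probability",
    "simulate_met_traces",
    "simulate_bundle_movie",
    "simulate_confocal_stack",
    "simulate_gene_tables",
]

#: reversal potential of the Ca2+ driving-force term in the adaptation
#: set-point shift (mV); the shift vanishes at and above this potential
E_REV_CA_MV = 40.0

#: the standard membrane-potential series: -124 mV, then 20 mV increments
#: from -84 mV up to +96 mV
VOLTAGE_SERIES: tuple[float, ...] = (-124.0,) + tuple(
    float(v) for v in range(-84, 97, 20)
)


def _require_finite(**params: float) -> None:
    for name, value in params.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------

@dataclass
class ChannelModel:
    """MET channel population model.

    ``p_rest`` is the resting open probability in the absence of the
    adaptation shift (i.e. with strong Ca2+ buffering or at potentials
    positive to the Ca2+ reversal); it fixes the Boltzmann half-point via
    ``x_half = lambda_slope * ln(1/p_rest - 1)``.  ``adapt_gain`` (nm/mV,
    >= 0) scales the Ca2+-dependent set-point shift; 0 emulates high
    BAPTA.  Currents: pS x mV / 1000 = pA.
    """

    n_channels: int = 160
    g_single: float = 50.0       # pS
    e_rev: float = 0.0           # mV
    p_rest: float = 0.5
    lambda_slope: float = 20.0   # nm
    adapt_gain: float = 0.35     # nm/mV
    i_leak: float = -20.0        # pA
    noise_sd: float = 15.0       # pA

    def __post_init__(self) -> None:
        _require_finite(
            g_single=self.g_single, e_rev=self.e_rev,
            lambda_slope=self.lambda_slope, adapt_gain=self.adapt_gain,
            i_leak=self.i_leak, noise_sd=self.noise_sd, p_rest=self.p_rest,
        )
        if not 0.0 <= self.p_rest <= 1.0:
            raise ValueError("p_rest must lie in [0, 1]")
        if not self.lambda_slope > 0:
            raise ValueError("lambda_slope must be positive")
        if self.n_channels < 0 or self.g_single < 0:
            raise ValueError("n_channels and g_single must be >= 0")
        if self.adapt_gain < 0 or self.noise_sd < 0:
            raise ValueError("adapt_gain and noise_sd must be >= 0")

    @property
    def x_half(self) -> float:
        """Half-activation displacement (nm); +/-inf at p_rest = 0 / 1."""
        if self.p_rest <= 0.0:
            return math.inf
        if self.p_rest >= 1.0:
            return -math.inf
        return self.lambda_slope * math.log(1.0 / self.p_rest - 1.0)

    def set_point_shift(self, v_m: float, buffer_label: str) -> float:
        """Adaptation shift of x_half (nm) at membrane potential v_m."""
        gain = 0.0 if buffer_label == "BAPTA_5mM" else self.adapt_gain
        return gain * max(0.0, E_REV_CA_MV - v_m)


def boltzmann_open_probability(
    x: np.ndarray, x_half: float, lambda_slope: float
) -> np.ndarray:
    """Two-state Boltzmann activation curve."""
    x = np.asarray(x, dtype=float)
    if math.isinf(x_half):
        return np.zeros_like(x) if x_half > 0 else np.ones_like(x)
    return expit((x - x_half) / lambda_slope)


@dataclass
class FluidJetModel:
    """Piezo-driven fluid jet plus lumped bundle mechanics.

    Force on the bundle is ``dv_gain`` times the driver voltage after a
    first-order low-pass with time constant ``tau_jet``; the bundle is an
    overdamped Hookean spring (stiffness ``k_true``, damping ``c_drag``)
    whose mechanical time constant is ``c_drag / k_true`` ms for the units
    below.  Steady-state displacement: x[nm] = 1000 * F[nN] / k[mN/m].
    """

    dv_gain: float = 100.0   # nN per V of driver voltage
    tau_jet: float = 0.5     # ms
    k_true: float = 3.0      # mN/m
    c_drag: float = 2.0      # uN*s/m

    def __post_init__(self) -> None:
        _require_finite(dv_gain=self.dv_gain, tau_jet=self.tau_jet,
                        k_true=self.k_true, c_drag=self.c_drag)
        if not self.k_true > 0:
            raise ValueError("k_true must be positive")
        if self.tau_jet < 0 or self.c_drag < 0:
            raise ValueError("tau_jet and c_drag must be >= 0")

    @property
    def tau_mech_ms(self) -> float:
        return self.c_drag / self.k_true

    def displacement_nm(self, driver_V: np.ndarray, dt_ms: float) -> np.ndarray:
        """Bundle displacement (nm) for a driver-voltage time series."""
        force = self.dv_gain * _lowpass(np.asarray(driver_V, float),
                                        dt_ms, self.tau_jet)
        return _lowpass(1000.0 * force / self.k_true, dt_ms, self.tau_mech_ms)


def _lowpass(x: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """First-order low-pass (zero initial state), exact for
    piecewise-constant input: y[i] = y[i-1] + alpha (x[i] - y[i-1])."""
    if tau <= 0:
        return x.astype(float, copy=True)
    alpha = 1.0 - math.exp(-dt / tau)
    from scipy.signal import lfilter

    return lfilter([alpha], [1.0, alpha - 1.0], x.astype(float))


@dataclass
class Sinusoid:
    frequency: float = 50.0   # Hz
    amplitude: float = 0.005  # V
    cycles: int = 10


@dataclass
class Step:
    amplitude: float          # V
    duration_ms: float


@dataclass
class TraceProtocol:
    """Stimulus and voltage-clamp protocol for a MET recording."""

    sample_rate: float = 50_000.0
    waveform: Sinusoid | Step = field(default_factory=Sinusoid)
    voltage_steps: tuple[float, ...] = VOLTAGE_SERIES
    holding_potential: float = -84.0
    buffer_label: str = "EGTA_1mM"
    pre_ms: float = 20.0
    post_ms: float = 10.0

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if len(self.voltage_steps) == 0:
            raise ValueError("voltage_steps must be nonempty")
        if self.buffer_label not in ("EGTA_1mM", "BAPTA_5mM"):
            raise ValueError("buffer_label must be EGTA_1mM or BAPTA_5mM")

    def driver(self) -> tuple[np.ndarray, float, float]:
        """(DV time series in V, stim onset s, stim offset s)."""
        fs = self.sample_rate
        onset = self.pre_ms / 1000.0
        if isinstance(self.waveform, Sinusoid):
            stim_dur = self.waveform.cycles / self.waveform.frequency
        else:
            stim_dur = self.waveform.duration_ms / 1000.0
        total = onset + stim_dur + self.post_ms / 1000.0
        n = int(round(total * fs))
        t = np.arange(n) / fs
        dv = np.zeros(n)
        on = (t >= onset) & (t < onset + stim_dur)
        if isinstance(self.waveform, Sinusoid):
            dv[on] = self.waveform.amplitude * np.sin(
                2.0 * math.pi * self.waveform.frequency * (t[on] - onset)
            )
        else:
            dv[on] = self.waveform.amplitude
        return dv, onset, onset + stim_dur


@dataclass
class METTraceSimulation:
    """Simulated trace set plus its ground-truth record."""

    traces: list[CurrentTrace]
    ground_truth: pd.DataFrame  # v_mV, p_open_rest, i_pp_pA
    channel: ChannelModel
    jet: FluidJetModel
    protocol: TraceProtocol


def simulate_met_traces(
    channel: ChannelModel,
    jet: FluidJetModel,
    protocol: TraceProtocol,
    seed: int,
    cell_id: str = "cell0",
    genotype: str = "control",
    age: str = "P20",
) -> METTraceSimulation:
    """One current trace per membrane potential, with ground truth.

    ``I(t) = N g (V - e_rev) P_open(x(t)) / 1000 + i_leak + noise`` with
    x(t) the damped-spring response to the low-passed jet force and the
    Boltzmann set point shifted by the Ca2+-dependent adaptation term.
    The ground-truth record stores, per voltage, the analytic resting open
    probability and the noise-free peak-to-peak transducer current.
    """
    rng = np.random.default_rng(seed)
    dv, onset, offset = protocol.driver()
    dt_ms = 1000.0 / protocol.sample_rate
    x = jet.displacement_nm(dv, dt_ms)

    traces: list[CurrentTrace] = []
    truth_rows = []
    for v in protocol.voltage_steps:
        shift = channel.set_point_shift(v, protocol.buffer_label)
        x_half = channel.x_half + shift
        p = boltzmann_open_probability(x, x_half, channel.lambda_slope)
        gain = channel.n_channels * channel.g_single * (v - channel.e_rev) / 1000.0
        clean = gain * p + channel.i_leak
        noise = (rng.normal(0.0, channel.noise_sd, x.size)
                 if channel.noise_sd > 0 else 0.0)
        traces.append(
            CurrentTrace(
                samples=clean + noise,
                sample_rate=protocol.sample_rate,
                driver=dv.copy(),
                v_m=v,
                buffer_label=protocol.buffer_label,
                cell_id=cell_id,
                genotype=genotype,
                age=age,
                stim_onset_s=onset,
                stim_offset_s=offset,
            )
        )
        p_rest_v = float(
            boltzmann_open_probability(np.zeros(1), x_half, channel.lambda_slope)[0]
        )
        truth_rows.append(
            {
                "v_mV": v,
                "p_open_rest": p_rest_v,
                "i_pp_pA": float(gain * (p.max() - p.min())),
            }
        )
    return METTraceSimulation(
        traces, pd.DataFrame(truth_rows), channel, jet, protocol
    )


# ---------------------------------------------------------------------------
# bundle movies
# ---------------------------------------------------------------------------

@dataclass
class MovieSpec:
    """Imaging model for the bundle-edge movie.

    The bundle edge appears as a vertical Gaussian line profile of width
    ``edge_sigma`` centered at the (time-varying) bundle position.  Shot
    noise: pixel counts are Poisson with ``photon_scale`` counts per gray
    unit; ``photon_scale = inf`` gives a noise-free movie.
    """

    pixel_size: float = 50.0      # nm
    frame_rate: float = 5000.0    # Hz
    n_frames: int = 900
    edge_sigma: float = 150.0     # nm
    amplitude: float = 100.0      # gray values
    background: float = 10.0      # gray values
    photon_scale: float = 2.0     # counts per gray unit
    x_rest: float | None = None   # nm; default = field-of-view center
    height_px: int = 8
    width_px: int = 64

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.edge_sigma > 0:
            raise ValueError("edge_sigma must be positive")
        if self.x_rest is None:
            self.x_rest = 0.5 * (self.width_px - 1) * self.pixel_size


@dataclass
class BundleMovie:
    frames: np.ndarray            # (n_frames, ny, nx)
    pixel_size: float             # nm
    frame_rate: float             # Hz
    stimulus_force: np.ndarray    # nN per frame


@dataclass
class MovieSimulation:
    movie: BundleMovie
    truth_x: np.ndarray           # displacement from rest, nm, per frame
    truth_steady_nm: list[float]  # F/k per force step
    spec: MovieSpec
    jet: FluidJetModel


def simulate_bundle_movie(
    spec: MovieSpec,
    jet: FluidJetModel,
    force_steps: "list[tuple[float, float, float]]",
    seed: int,
) -> MovieSimulation:
    """Movie of a bundle edge responding to fluid-jet force steps.

    ``force_steps`` is a list of (amplitude nN, onset ms, duration ms);
    steps must lie within the movie duration, and the resulting edge
    position must stay inside the field of view (the error names the first
    offending frame).
    """
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / spec.frame_rate
    t_ms = np.arange(spec.n_frames) * dt_ms
    duration_ms = spec.n_frames * dt_ms
    force = np.zeros(spec.n_frames)
    steady = []
    for amp, onset, duration in force_steps:
        if onset < 0 or onset + duration > duration_ms:
            raise ValueError(
                f"force step ({amp} nN @ {onset} ms, {duration} ms) exceeds "
                f"the movie duration ({duration_ms:.1f} ms)"
            )
        force[(t_ms >= onset) & (t_ms < onset + duration)] += amp
        steady.append(1000.0 * amp / jet.k_true)

    smoothed = _lowpass(force, dt_ms, jet.tau_jet)
    disp = _lowpass(1000.0 * smoothed / jet.k_true, dt_ms, jet.tau_mech_ms)
    x_c = spec.x_rest + disp

    x_px = np.arange(spec.width_px) * spec.pixel_size
    lo, hi = x_px[0], x_px[-1]
    bad = np.nonzero((x_c < lo) | (x_c > hi))[0]
    if bad.size:
        raise ValueError(
            f"bundle edge leaves the field of view at frame {int(bad[0])} "
            f"(position {x_c[bad[0]]:.1f} nm)"
        )

    profiles = spec.background + spec.amplitude * np.exp(
        -((x_px[None, :] - x_c[:, None]) ** 2) / (2.0 * spec.edge_sigma**2)
    )
    frames = np.broadcast_to(
        profiles[:, None, :], (spec.n_frames, spec.height_px, spec.width_px)
    ).copy()
    if np.isfinite(spec.photon_scale):
        frames = rng.poisson(frames * spec.photon_scale) / spec.photon_scale
    movie = BundleMovie(frames.astype(float), spec.pixel_size,
                        spec.frame_rate, force)
    return MovieSimulation(movie, disp, steady, spec, jet)


# ---------------------------------------------------------------------------
# confocal stacks
# ---------------------------------------------------------------------------

def _default_landmarks(shape, voxel_size) -> dict[str, tuple[float, float, float]]:
    nz, ny, nx = shape
    vx, vy, vz = voxel_size
    cx, cy = 0.5 * (nx - 1) * vx, 0.5 * (ny - 1) * vy
    z_extent = (nz - 1) * vz
    fractions = {
        "stereocilia_tips": 0.07,
        "stereocilia_bases": 0.22,
        "cuticular_plate": 0.40,
        "cytoplasm_apex": 0.62,
        "cytoplasm_base": 0.85,
    }
    return {name: (cx, cy, f * z_extent) for name, f in fractions.items()}


@dataclass
class StackSpec:
    """Two-channel stack model with per-landmark ratio ground truth.

    The F-actin channel takes the compartment level of the nearest
    landmark (a Voronoi partition of the stack); the MYO7A channel is the
    per-compartment ``true_ratio`` times the actin field.  Independent
    Gaussian noise of SD ``noise_sd`` is added to each channel.
    """

    shape: tuple[int, int, int] = (32, 48, 48)         # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (50.0, 50.0, 250.0)  # x, y, z nm
    landmarks: dict[str, tuple[float, float, float]] | None = None
    true_ratio: dict[str, float] = field(default_factory=lambda: {
        "stereocilia_tips": 1.2, "stereocilia_bases": 1.0,
        "cuticular_plate": 0.9, "cytoplasm_apex": 0.7, "cytoplasm_base": 0.6,
    })
    actin_level: dict[str, float] = field(default_factory=lambda: {
        "stereocilia_tips": 120.0, "stereocilia_bases": 150.0,
        "cuticular_plate": 180.0, "cytoplasm_apex": 80.0, "cytoplasm_base": 70.0,
    })
    noise_sd: float = 4.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.landmarks is None:
            self.landmarks = _default_landmarks(self.shape, self.voxel_size)
        if set(self.landmarks) != set(LANDMARK_NAMES):
            raise ValueError(f"exactly five landmarks required: {LANDMARK_NAMES}")
        for name, ratio in self.true_ratio.items():
            if ratio < 0:
                raise ValueError(f"true_ratio[{name!r}] must be >= 0")
        nz, ny, nx = self.shape
        vx, vy, vz = self.voxel_size
        for name, (x, y, z) in self.landmarks.items():
            if not (0 <= x <= (nx - 1) * vx and 0 <= y <= (ny - 1) * vy
                    and 0 <= z <= (nz - 1) * vz):
                raise ValueError(f"landmark {name!r} lies outside the stack")

    def scaled_ratios(self, factor: float) -> "StackSpec":
        """Copy of the spec with every compartment ratio multiplied by
        ``factor`` (e.g. 0.1 emulates a 90% knockdown)."""
        new = {k: v * factor for k, v in self.true_ratio.items()}
        return StackSpec(self.shape, self.voxel_size, dict(self.landmarks),
                         new, dict(self.actin_level), self.noise_sd)


@dataclass
class StackSimulation:
    stack: ConfocalStack
    truth_ratio: dict[str, float]
    spec: StackSpec


def simulate_confocal_stack(spec: StackSpec, seed: int) -> StackSimulation:
    """Generate a two-channel stack with known per-landmark ratios."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    vx, vy, vz = spec.voxel_size
    zc = np.arange(nz) * vz
    yc = np.arange(ny) * vy
    xc = np.arange(nx) * vx
    names = list(spec.landmarks)
    d2 = np.empty((len(names), nz, ny, nx))
    for i, name in enumerate(names):
        lx, ly, lz = spec.landmarks[name]
        d2[i] = (
            (zc[:, None, None] - lz) ** 2
            + (yc[None, :, None] - ly) ** 2
            + (xc[None, None, :] - lx) ** 2
        )
    nearest = np.argmin(d2, axis=0)
    actin_levels = np.array([spec.actin_level[n] for n in names])
    ratios = np.array([spec.true_ratio[n] for n in names])
    actin = actin_levels[nearest]
    myo7a = ratios[nearest] * actin
    if spec.noise_sd > 0:
        myo7a = myo7a + rng.normal(0.0, spec.noise_sd, myo7a.shape)
        actin = actin + rng.normal(0.0, spec.noise_sd, actin.shape)
    stack = ConfocalStack(myo7a, actin, spec.voxel_size)
    return StackSimulation(stack, dict(spec.true_ratio), spec)


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

@dataclass
class GeneSetSpec:
    label: str
    size: int
    frac_down: float = 0.5


@dataclass
class GeneUniverseSpec:
    """Universe of gene identifiers with named DEG sets and known pairwise
    overlaps.  Exact overlap construction is supported for up to two sets
    (or any number of mutually disjoint sets)."""

    universe_size: int = 20_000
    sets: tuple[GeneSetSpec, ...] = (
        GeneSetSpec("ko_p30", 1739),
        GeneSetSpec("maturation", 3266),
    )
    overlaps: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("ko_p30", "maturation"): 1007}
    )
    frac_missing_padj: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sets]
        if len(set(labels)) != len(labels):
            raise ValueError("set labels must be unique")
        sizes = {s.label: s.size for s in self.sets}
        for s in self.sets:
            if s.size > self.universe_size:
                raise ValueError(f"set {s.label!r} larger than the universe")
        total_ov = 0
        for (a, b), n_ov in self.overlaps.items():
            if a not in sizes or b not in sizes:
                raise ValueError(f"overlap references unknown set: ({a}, {b})")
            if n_ov > min(sizes[a], sizes[b]):
                raise ValueError(
                    f"overlap {n_ov} exceeds min size of ({a}, {b})"
                )
            total_ov += n_ov
        if len(self.sets) > 2 and any(self.overlaps.values()):
            raise NotImplementedError(
                "exact overlap construction supports at most two overlapping sets"
            )
        union = sum(sizes.values()) - total_ov
        if union > self.universe_size:
            raise ValueError("sets do not fit in the universe")


@dataclass
class GeneTableSimulation:
    tables: dict[str, pd.DataFrame]
    truth_sets: dict[str, frozenset[str]]
    truth_directions: dict[str, dict[str, str]]
    spec: GeneUniverseSpec


def _in_set_row(rng, down: bool) -> tuple[float, float, float]:
    fc = 0.5 + rng.exponential(0.8) + 1e-6
    if down:
        fc = -fc
    se = rng.uniform(0.05, 0.45)
    padj = 10.0 ** rng.uniform(-12.0, math.log10(0.0099))
    return fc, se, padj


def _out_set_row(rng) -> tuple[float, float, float]:
    mode = rng.choice(3, p=[0.5, 0.2, 0.3])
    fc = rng.uniform(-2.0, 2.0)
    se = rng.uniform(0.05, 0.45)
    padj = 10.0 ** rng.uniform(-6.0, 0.0)
    if mode == 0:      # fold change too small (boundary 0.5 occasionally exact)
        fc = math.copysign(0.5 if rng.random() < 0.02 else rng.uniform(0, 0.5), fc)
    elif mode == 1:    # standard error too large
        se = 0.5 if rng.random() < 0.02 else rng.uniform(0.5, 1.5)
    else:              # adjusted p not significant
        padj = 0.01 if rng.random() < 0.02 else rng.uniform(0.01, 1.0)
    return fc, se, padj


def simulate_gene_tables(spec: GeneUniverseSpec) -> GeneTableSimulation:
    """Differential-expression tables with known DEG membership.

    Every universe gene appears in every table; a gene inside a set's
    ground-truth membership passes all three DEG thresholds in that set's
    table, every other gene fails at least one (strictly).
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"gene{i:05d}" for i in range(spec.universe_size)])
    perm = rng.permutation(spec.universe_size)

    sizes = {s.label: s.size for s in spec.sets}
    members: dict[str, set[int]] = {s.label: set() for s in spec.sets}
    cursor = 0
    if len(spec.sets) <= 2 and spec.overlaps:
        (a, b), n_ov = next(iter(spec.overlaps.items()))
        shared = perm[cursor : cursor + n_ov]
        cursor += n_ov
        members[a].update(shared)
        members[b].update(shared)
    for s in spec.sets:
        need = sizes[s.label] - len(members[s.label])
        members[s.label].update(perm[cursor : cursor + need])
        cursor += need

    tables: dict[str, pd.DataFrame] = {}
    truth_sets: dict[str, frozenset[str]] = {}
    truth_dirs: dict[str, dict[str, str]] = {}
    for s in spec.sets:
        idx_in = members[s.label]
        fc = np.empty(spec.universe_size)
        se = np.empty(spec.universe_size)
        padj = np.empty(spec.universe_size)
        dirs: dict[str, str] = {}
        for i in range(spec.universe_size):
            if i in idx_in:
                down = rng.random() < s.frac_down
                fc[i], se[i], padj[i] = _in_set_row(rng, down)
                dirs[genes[i]] = "down" if down else "up"
            else:
                fc[i], se[i], padj[i] = _out_set_row(rng)
                if spec.frac_missing_padj > 0 and rng.random() < spec.frac_missing_padj:
                    padj[i] = math.nan
        tables[s.label] = pd.DataFrame(
            {"gene_id": genes, "log2FC": fc, "lfcSE": se, "padj": padj}
        )
        truth_sets[s.label] = frozenset(genes[sorted(idx_in)])
        truth_dirs[s.label] = dirs
    return GeneTableSimulation(tables, truth_sets, truth_dirs, spec)
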