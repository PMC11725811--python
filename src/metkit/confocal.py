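"""Ratiometric Gaussian-volume quantification of confocal z-stacks.

MYO7A immunofluorescence is quantified at five anatomical landmarks along a
hair cell (stereocilia tips, stereocilia bases, cuticular plate, apical and
basal cytoplasm).  At each landmark the MYO7A intensity is averaged in a
small anisotropic Gaussian volume and divided by the F-actin (phalloidin)
intensity averaged with the identical weights; the actin normalization
cancels staining-depth and gain variation.  Group summaries report mean +/-
SD per (genotype, age, landmark), and percent reduction of the knockout
relative to control, ``100 * (1 - mean_ko / mean_control)``.

Landmark kernel widths (SD, nm) default to the anatomical convention:
(x-y, z) = (250, 500) for both stereocilia positions, (1000, 500) for the
cuticular plate and (1000, 1000) for the two cytoplasmic positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LANDMARK_NAMES",
    "DEFAULT_SIGMAS",
    "ConfocalStack",
    "Landmark",
    "RatioMeasurement",
    "gaussian_weights",
    "local_ratio",
    "percent_reduction",
    "profile_cells",
    "reduction_table",
]

LANDMARK_NAMES = (
    "stereocilia_tips",
    "stereocilia_bases",
    "cuticular_plate",
    "cytoplasm_apex",
    "cytoplasm_base",
)

#: per-landmark Gaussian SDs (sigma_xy, sigma_z) in nm
DEFAULT_SIGMAS: dict[str, tuple[float, float]] = {
    "stereocilia_tips": (250.0, 500.0),
    "stereocilia_bases": (250.0, 500.0),
    "cuticular_plate": (1000.0, 500.0),
    "cytoplasm_apex": (1000.0, 1000.0),
    "cytoplasm_base": (1000.0, 1000.0),
}

#: kernels are truncated at +/- this many SDs per axis, then renormalized
TRUNCATE_SD = 4.0

#: actin weighted average below this fraction of the channel max flags the
#: ratio invalid (division by a noise-dominated denominator)
ACTIN_FLOOR_FRACTION = 0.01


@dataclass
class ConfocalStack:
    """Two-channel voxel data: arrays are (z, y, x) with index 0 the most
    apical plane; ``voxel_size`` is (x, y, z) in nm."""

    myo7a: np.ndarray
    actin: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.myo7a = np.asarray(self.myo7a, dtype=float)
        self.actin = np.asarray(self.actin, dtype=float)
        if self.myo7a.shape != self.actin.shape:
            raise ValueError("channels must share the same shape")
        if self.myo7a.ndim != 3:
            raise ValueError("stacks must be 3-D (z, y, x)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")


@dataclass
class Landmark:
    """A named anatomical sampling point with its kernel widths.

    ``position`` is (x, y, z) in nm from the stack origin (voxel [0,0,0]
    center).  Sigmas default by name; a landmark named outside the five
    canonical positions must supply both sigmas.  Placement of
    "stereocilia_tips" should follow the anatomical guidance of sampling
    toward the tips of the tallest row but above the middle row - this is
    annotation guidance, not enforced geometry.
    """

    name: str
    position: tuple[float, float, float]
    sigma_xy: float | None = None
    sigma_z: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_xy is None or self.sigma_z is None:
            try:
                d_xy, d_z = DEFAULT_SIGMAS[self.name]
            except KeyError:
                raise ValueError(
                    f"landmark {self.name!r} has no default sigmas; "
                    "supply sigma_xy and sigma_z"
                ) from None
            self.sigma_xy = d_xy if self.sigma_xy is None else self.sigma_xy
            self.sigma_z = d_z if self.sigma_z is None else self.sigma_z
        if not (self.sigma_xy > 0 and self.sigma_z > 0):
            raise ValueError("sigmas must be positive")


@dataclass
class RatioMeasurement:
    landmark: str
    myo7a_avg: float
    actin_avg: float
    ratio: float
    valid: bool
    cell_id: str = "cell0"
    genotype: str = "control"
    age: str = "P20"
    flags: list[str] = field(default_factory=list)


def _axis_weights(n: int, step: float, center: float, sigma: float) -> np.ndarray:
    coords = np.arange(n) * step
    w = np.zeros(n)
    m = np.abs(coords - center) <= TRUNCATE_SD * sigma
    w[m] = np.exp(-((coords[m] - center) ** 2) / (2.0 * sigma**2))
    return w


def gaussian_weights(
    shape: tuple[int, int, int],
    landmark: Landmark,
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Normalized anisotropic Gaussian weight field for one landmark.

    The kernel has SDs (sigma_xy, sigma_xy, sigma_z) along (x, y, z), is
    truncated at +/-4 SD per axis (and at the stack boundary) and
    renormalized to sum exactly 1.
    """
    nz, ny, nx = shape
    vx, vy, vz = voxel_size
    x, y, z = landmark.position
    if not (0 <= x <= (nx - 1) * vx and 0 <= y <= (ny - 1) * vy
            and 0 <= z <= (nz - 1) * vz):
        raise ValueError(f"landmark {landmark.name!r} lies outside the stack")
    for sig, vox, ax in ((landmark.sigma_xy, vx, "x"), (landmark.sigma_xy, vy, "y"),
                         (landmark.sigma_z, vz, "z")):
        if sig < vox:
            warnings.warn(
                f"landmark {landmark.name!r}: sigma along {ax} ({sig} nm) is "
                f"below one voxel ({vox} nm)"
            )
    wx = _axis_weights(nx, vx, x, landmark.sigma_xy)
    wy = _axis_weights(ny, vy, y, landmark.sigma_xy)
    wz = _axis_weights(nz, vz, z, landmark.sigma_z)
    w = wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
    total = w.sum()
    if total == 0:
        raise ValueError(f"landmark {landmark.name!r}: empty weight support")
    return w / total


def local_ratio(
    stack: ConfocalStack,
    landmark: Landmark,
    floor_fraction: float = ACTIN_FLOOR_FRACTION,
    **meta: str,
) -> RatioMeasurement:
    """MYO7A / F-actin ratio of Gaussian-weighted local averages.

    Both channels are averaged with the identical weight field, so the
    ratio is invariant to any gain applied jointly to both channels.  A
    weighted actin average below ``floor_fraction`` of the actin channel
    maximum marks the measurement invalid.
    """
    w = gaussian_weights(stack.myo7a.shape, landmark, stack.voxel_size)
    m_avg = float(np.sum(w * stack.myo7a))
    a_avg = float(np.sum(w * stack.actin))
    floor = floor_fraction * float(stack.actin.max())
    flags: list[str] = []
    if a_avg > floor:
        ratio, valid = m_avg / a_avg, True
    else:
        ratio, valid = float("nan"), False
        flags.append("actin_below_floor")
    return RatioMeasurement(landmark.name, m_avg, a_avg, ratio, valid,
                            flags=flags, **meta)


def percent_reduction(mean_ko: float, mean_control: float) -> float:
    """``100 * (1 - mean_ko / mean_control)``; undefined (NaN, with a
    warning) when the control mean is not positive."""
    if not mean_control > 0:
        warnings.warn("control mean is not positive: percent reduction undefined")
        return float("nan")
    return 100.0 * (1.0 - mean_ko / mean_control)


def profile_cells(measurements: "list[RatioMeasurement]") -> pd.DataFrame:
    """Group summary: mean, SD, n per (genotype, age, landmark).

    Invalid measurements are excluded from the statistics and counted in
    ``n_invalid``.  Empty groups are simply absent from the table.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    df = pd.DataFrame(
        {
            "genotype": m.genotype,
            "age": m.age,
            "landmark": m.landmark,
            "cell_id": m.cell_id,
            "ratio": m.ratio,
            "valid": m.valid,
        }
        for m in measurements
    )
    out = (
        df[df["valid"]]
        .groupby(["genotype", "age", "landmark"], sort=True)["ratio"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=0) if len(s) > 1 else 0.0,
             n="count")
        .reset_index()
    )
    invalid = (
        df[~df["valid"]]
        .groupby(["genotype", "age", "landmark"])
        .size()
        .rename("n_invalid")
        .reset_index()
    )
    out = out.merge(invalid, how="left",
                    on=["genotype", "age", "landmark"])
    out["n_invalid"] = out["n_invalid"].fillna(0).astype(int)
    return out


def reduction_table(
    summary: pd.DataFrame,
    ko: str,
    control: str,
) -> pd.DataFrame:
    """Percent reduction of the knockout vs control.

    Returns one row per (age, landmark) plus, per age, an ``all_landmarks``
    row computed from the across-landmark average of group means (the two
    aggregation conventions are both reported since either may underlie a
    single summary range).
    """
    rows = []
    for age in sorted(summary["age"].unique()):
        sub = summary[summary["age"] == age]
        ko_m = sub[sub["genotype"] == ko].set_index("landmark")["mean"]
        ct_m = sub[sub["genotype"] == control].set_index("landmark")["mean"]
        common = ko_m.index.intersection(ct_m.index)
        for lm in common:
            rows.append({"age": age, "landmark": lm,
                         "percent_reduction": percent_reduction(ko_m[lm], ct_m[lm])})
        if len(common):
            rows.append(
                {
                    "age": age,
                    "landmark": "all_landmarks",
                    "percent_reduction": percent_reduction(
                        float(ko_m[common].mean()), float(ct_m[common].mean())
                    ),
                }
            )
    return pd.DataFrame(rows)
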