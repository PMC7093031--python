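"""Confocal Z-stack post-processing.

Fluorescence emitted at depth inside a strongly absorbing suspension (whole
blood) is attenuated before reaching the objective.  With a measured
absorbance spectrum A(lambda) at a known sample path length, the Beer-Lambert
transmittance over the optical path from the imaging plane to the
objective-side wall is ``T = 10^(-A * path / L_sample)`` and the raw platelet
signal is corrected by dividing by T.  Also provides the parallel-plate
channel wall-shear-rate relationship used to set the flow rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "AbsorbanceSpectrum",
    "ZStackProfile",
    "PlateChannelSpec",
    "transmittance_per_depth",
    "correct_zstack",
    "wall_concentration",
    "plate_wall_shear",
]


@dataclass
class AbsorbanceSpectrum:
    """Base-10 absorbance vs wavelength, measured at path length
    ``path_length_mm`` (default: the 100 uL microplate well, 3.108 mm)."""

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    path_length_mm: float = 3.108
    absorbance_sd: np.ndarray | None = None

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.absorbance < 0):
            raise ValueError("absorbance must be non-negative")
        if self.path_length_mm <= 0:
            raise ValueError("path length must be positive")
        if self.absorbance_sd is not None:
            self.absorbance_sd = np.asarray(self.absorbance_sd, dtype=float)

    def at(self, wavelength_nm: float) -> float:
        """Linearly interpolated absorbance at the given wavelength."""
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside spectrum range [{lo}, {hi}]"
            )
        return float(np.interp(wavelength_nm, self.wavelengths_nm, self.absorbance))

    def sd_at(self, wavelength_nm: float) -> float:
        if self.absorbance_sd is None:
            return 0.0
        return float(
            np.interp(wavelength_nm, self.wavelengths_nm, self.absorbance_sd)
        )

    @classmethod
    def from_csv(cls, path: str, **kw) -> "AbsorbanceSpectrum":
        """Read a wavelength,absorbance[,sd] CSV."""
        df = pd.read_csv(path)
        sd = df["sd"].to_numpy() if "sd" in df.columns else None
        return cls(
            df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), absorbance_sd=sd, **kw
        )


@dataclass
class ZStackProfile:
    """Fluorescence intensity vs height across the channel.

    ``objective_at_top`` records which wall faces the objective: the optical
    path of the plane at height h is (H - h) when the objective is at the top.
    """

    heights_um: np.ndarray
    intensity: np.ndarray
    intensity_sd: np.ndarray | None = None
    channel_height_um: float | None = None
    objective_at_top: bool = True
    unreliable: np.ndarray = field(default=None, repr=False)  # set by correct_zstack

    def __post_init__(self):
        self.heights_um = np.asarray(self.heights_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        inc = np.diff(self.heights_um)
        if len(inc) and not np.allclose(inc, inc[0]):
            raise ValueError("height increments must be uniform")
        if self.channel_height_um is None:
            self.channel_height_um = float(self.heights_um[-1])
        if np.any(self.heights_um < 0) or np.any(
            self.heights_um > self.channel_height_um + 1e-9
        ):
            raise ValueError("heights outside channel")
        if self.intensity_sd is not None:
            self.intensity_sd = np.asarray(self.intensity_sd, dtype=float)

    @classmethod
    def from_csv(cls, path: str, **kw) -> "ZStackProfile":
        df = pd.read_csv(path)
        sd = df["sd"].to_numpy() if "sd" in df.columns else None
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), intensity_sd=sd, **kw)

    def to_csv(self, path: str) -> None:
        cols = {"height_um": self.heights_um, "intensity": self.intensity}
        if self.intensity_sd is not None:
            cols["sd"] = self.intensity_sd
        pd.DataFrame(cols).to_csv(path, index=False)


def transmittance_per_depth(
    spectrum: AbsorbanceSpectrum, wavelength_nm: float, depth_um
):
    """Beer-Lambert transmittance over `depth_um` of sample at the given
    wavelength: ``10^(-A(lambda) * depth / L_sample)``."""
    a = spectrum.at(wavelength_nm)
    depth_mm = np.asarray(depth_um, dtype=float) * 1e-3
    out = 10.0 ** (-a * depth_mm / spectrum.path_length_mm)
    return out if out.ndim else float(out)


def correct_zstack(
    profile: ZStackProfile,
    spectrum: AbsorbanceSpectrum,
    emission_nm: float = 660.0,
    t_floor: float = 1e-6,
) -> ZStackProfile:
    """Divide the raw signal by the transmittance over the optical path from
    the objective-side wall to each imaging plane.

    Uncertainty is propagated in quadrature from the intensity and absorbance
    standard deviations.  Depths with transmittance below ``t_floor`` are
    flagged unreliable (mask in ``.unreliable``) rather than silently divided.
    """
    h = profile.heights_um
    height = profile.channel_height_um
    path_um = (height - h) if profile.objective_at_top else h
    t = np.asarray(transmittance_per_depth(spectrum, emission_nm, path_um))
    unreliable = t < t_floor
    if np.any(unreliable):
        warnings.warn(
            f"{unreliable.sum()} depths below transmittance floor {t_floor}; flagged"
        )
    t_safe = np.where(unreliable, 1.0, t)
    corrected = profile.intensity / t_safe
    # quadrature propagation: relative sd of raw signal and of the
    # transmittance factor (d ln T = -ln10 * path/L * dA)
    a_sd = spectrum.sd_at(emission_nm)
    rel_t = np.log(10.0) * (path_um * 1e-3) / spectrum.path_length_mm * a_sd
    if profile.intensity_sd is not None or a_sd:
        raw_sd = (
            profile.intensity_sd
            if profile.intensity_sd is not None
            else np.zeros_like(corrected)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_raw = np.where(profile.intensity != 0, raw_sd / profile.intensity, 0.0)
        sd = np.abs(corrected) * np.sqrt(rel_raw**2 + rel_t**2)
    else:
        sd = None
    out = ZStackProfile(
        h.copy(),
        corrected,
        intensity_sd=sd,
        channel_height_um=height,
        objective_at_top=profile.objective_at_top,
    )
    out.unreliable = unreliable
    return out


def wall_concentration(
    profile: ZStackProfile,
    region_width_um: float = 5.0,
    reference: ZStackProfile | None = None,
) -> float:
    """Mean intensity over the near-wall region closest to the objective,
    optionally normalised by the same quantity of a reference profile."""
    if region_width_um > profile.channel_height_um:
        raise ValueError("near-wall region wider than the channel")
    h = profile.heights_um
    if profile.objective_at_top:
        mask = h >= profile.channel_height_um - region_width_um
    else:
        mask = h <= region_width_um
    value = float(profile.intensity[mask].mean())
    if reference is not None:
        ref = wall_concentration(reference, region_width_um)
        if ref == 0:
            raise ZeroDivisionError("reference wall concentration is zero")
        value /= ref
    return value


@dataclass(frozen=True)
class PlateChannelSpec:
    """Parallel-plate channel and flow specification (units in field names)."""

    q_ul_per_min: float  # volumetric flow rate [uL/min]
    height_mm: float  # a, plate separation [mm]
    width_mm: float  # b, channel width [mm]
    viscosity_pa_s: float  # mu of the suspending medium [Pa s]

    def __post_init__(self):
        if min(self.q_ul_per_min, self.height_mm, self.width_mm, self.viscosity_pa_s) <= 0:
            raise ValueError("all plate-channel quantities must be positive")
        if self.width_mm / self.height_mm < 10:
            warnings.warn(
                "b/a < 10: parallel-plate wall-shear formula is inaccurate"
            )

    @classmethod
    def from_si(cls, q_m3_per_s: float, a_m: float, b_m: float, mu_pa_s: float):
        return cls(q_m3_per_s * 6e10, a_m * 1e3, b_m * 1e3, mu_pa_s)


def plate_wall_shear(spec: PlateChannelSpec) -> tuple[float, float]:
    """Wall shear rate [1/s] and wall shear stress [Pa] of the plate channel:
    ``tau_w = mu * gammadot = 6 mu Q / (a^2 b)``."""
    q = spec.q_ul_per_min * 1e-9 / 60.0  # m^3/s
    a = spec.height_mm * 1e-3
    b = spec.width_mm * 1e-3
    gammadot = 6.0 * q / (a * a * b)
    return gammadot, spec.viscosity_pa_s * gammadot
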