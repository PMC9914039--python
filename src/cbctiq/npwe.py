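"""Non-prewhitening model observer with eye filter (NPWE).

The detectability index for a circular lesion-detection task is

    d'^2 = [∬ W^2 TTF^2 E^2 du dv]^2 / ∬ W^2 TTF^2 NPS E^4 du dv

where W is the task function (Fourier transform of the object-present minus
object-absent difference — here a flat disk of given diameter and contrast,
evaluated analytically through the Airy pattern 2*J1(x)/x), TTF the measured
task transfer function applied radially, NPS the measured 2D noise power
spectrum, and E the eye filter mapping image frequencies to angular
frequencies at the viewer's retina for the given display geometry.

The eye filter uses the visual-response family E(rho) = rho^n * exp(-c rho^2)
(rho in cycles/degree), with the exponent n = 1.3 and c chosen so the
response peaks at 4 cycles/degree, normalized to a maximum of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import j1

from .nps import NpsResult
from .ttf import Curve, TtfResult

__all__ = [
    "TaskSpec",
    "ViewingConditions",
    "DetectabilityResult",
    "task_function",
    "eye_filter",
    "compute_dprime",
]


@dataclass(frozen=True)
class TaskSpec:
    """A flat-disk detection task: lesion diameter (mm) and signed contrast
    amplitude (HU) of the present-vs-absent difference."""

    contrast_hu: float
    lesion_diameter_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.lesion_diameter_mm <= 0:
            raise ValueError("lesion_diameter_mm must be positive")


@dataclass(frozen=True)
class ViewingConditions:
    """Display/eye geometry for the eye filter."""

    distance_mm: float = 500.0
    zoom: float = 1.5
    display_pixel_pitch_mm: float = 0.2
    eye_exponent: float = 1.3
    eye_peak_cyc_per_deg: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "distance_mm",
            "zoom",
            "display_pixel_pitch_mm",
            "eye_exponent",
            "eye_peak_cyc_per_deg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DetectabilityResult:
    dprime: float
    task: TaskSpec
    grid_shape: tuple[int, int]
    meta: dict


def task_function(task: TaskSpec, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Analytic task function W(u, v) of a flat disk (HU mm^2).

    W(rho) = C * pi r^2 * 2 J1(2 pi rho r) / (2 pi rho r), with the DC value
    C * pi r^2. Evaluated in closed form (no discrete transform) so there is
    no rasterization/truncation error; the first zero sits at the first
    Bessel-J1 root, rho = 3.8317 / (2 pi r).
    """
    r = task.lesion_diameter_mm / 2.0
    rho = np.hypot(np.asarray(u, float)[:, None], np.asarray(v, float)[None, :])
    x = 2.0 * np.pi * rho * r
    with np.errstate(invalid="ignore", divide="ignore"):
        airy = np.where(x > 0, 2.0 * j1(x) / np.where(x > 0, x, 1.0), 1.0)
    return task.contrast_hu * np.pi * r**2 * airy


def eye_filter(
    view: ViewingConditions,
    u: np.ndarray,
    v: np.ndarray,
    pixel_spacing_mm: float,
) -> np.ndarray:
    """Eye filter E(u, v) on an image-frequency grid (mm^-1), max-normalized.

    One image pixel is displayed at ``zoom * display_pixel_pitch`` mm, so an
    image frequency f maps to the display as
    f * pixel_spacing / (zoom * pitch) and to angular frequency as
    rho_deg = f_display * distance * pi / 180 cycles/degree.
    """
    rho_img = np.hypot(np.asarray(u, float)[:, None], np.asarray(v, float)[None, :])
    mag = pixel_spacing_mm / (view.zoom * view.display_pixel_pitch_mm)
    rho_deg = rho_img * mag * view.distance_mm * np.pi / 180.0
    n = view.eye_exponent
    c = n / (2.0 * view.eye_peak_cyc_per_deg**2)
    peak_val = view.eye_peak_cyc_per_deg**n * np.exp(-n / 2.0)
    return rho_deg**n * np.exp(-c * rho_deg**2) / peak_val


def _ttf_on_grid(ttf, rho: np.ndarray) -> np.ndarray:
    if ttf is None:
        return np.ones_like(rho)
    curve = ttf.ttf if isinstance(ttf, TtfResult) else ttf
    if not isinstance(curve, Curve):
        raise TypeError("ttf must be a TtfResult, Curve or None")
    return np.interp(rho, curve.x, curve.y, right=0.0)


def compute_dprime(
    ttf: TtfResult | Curve | None,
    nps: NpsResult,
    task: TaskSpec,
    view: ViewingConditions | None = None,
) -> DetectabilityResult:
    """NPWE detectability index on the NPS frequency grid.

    The TTF is applied radially (rotational symmetry); ``ttf=None`` means an
    ideal (unity) transfer and ``view=None`` disables the eye filter. The 2D
    integrals use the trapezoid rule on the DC-centered NPS grid.
    """
    if task.contrast_hu == 0:
        # zero task amplitude: nothing to detect
        return DetectabilityResult(
            dprime=0.0, task=task, grid_shape=nps.nps2d.shape, meta={"degenerate": True}
        )
    u, v = nps.f_y, nps.f_x
    rho = np.hypot(u[:, None], v[None, :])
    w2 = task_function(task, u, v) ** 2
    t2 = _ttf_on_grid(ttf, rho) ** 2
    e = (
        eye_filter(view, u, v, pixel_spacing_mm=float(np.mean(nps.pixel_spacing_mm)))
        if view is not None
        else np.ones_like(rho)
    )

    def integrate(z: np.ndarray) -> float:
        return float(np.trapezoid(np.trapezoid(z, v, axis=1), u, axis=0))

    numerator = integrate(w2 * t2 * e**2) ** 2
    denominator = integrate(w2 * t2 * nps.nps2d * e**4)
    if denominator <= 0:
        raise ValueError("degenerate (noiseless) NPS: NPWE denominator is zero")
    dprime = float(np.sqrt(numerator / denominator))
    return DetectabilityResult(
        dprime=dprime,
        task=task,
        grid_shape=nps.nps2d.shape,
        meta={"eye_filter": view is not None, "ttf": ttf is not None},
    )
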