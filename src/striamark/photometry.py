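"""Image contrast of casting materials and oblique-light rendering.

Casting materials are screened by how much contrast their surface shows
under a microscope: the image contrast ``IC`` is simply the sample
standard deviation of the 0–255 pixel brightness values. Physically the
contrast arises from the reflectance law

    I_R = I_I * |sin(lambda)| * tau,

where ``I_I`` is the illumination intensity, ``lambda`` the angle between
the incoming ray and the local tangent plane, and ``tau`` the material's
degree of reflection. A facet facing away from the light contributes
``lambda = 0``.

:func:`render_oblique` turns a height map into a synthetic grazing-light
image: per-pixel surface normals from central differences, per-pixel
incidence angle against a directional light, and a brightness of
``base + gain * I_R`` where ``base`` maps from the material's light
reflectance value (LRV, 0 = ideal black, 100 = ideal white). The model is
deliberately minimal — no cast shadows, no diffuse inter-reflection, no
translucency.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError, StatisticsError, ValidationError
from .scan_io import HeightMap, Image

__all__ = [
    "IlluminationConfig",
    "MaterialOptics",
    "image_contrast",
    "reflected_intensity",
    "render_oblique",
    "contrast_by_group",
]

#: Brightness gain: a 45-degree facet at tau = 1, I_I = 1 adds 64 counts.
DEFAULT_GAIN = 64.0 / np.sin(np.deg2rad(45.0))


@dataclass
class IlluminationConfig:
    """Directional light: azimuth 0 = perpendicular to the grooves."""

    azimuth: float = 0.0      # degrees in the surface plane
    elevation: float = 5.0    # degrees above the surface plane
    intensity: float = 1.0    # I_I, arbitrary linear units

    def __post_init__(self) -> None:
        if not 0.0 < self.elevation < 90.0:
            raise ValidationError("elevation must lie strictly between 0 and 90 degrees")
        if self.intensity < 0:
            raise ValidationError("intensity must be non-negative")

    def direction(self) -> np.ndarray:
        """Unit vector pointing from the surface toward the light."""
        az = np.deg2rad(self.azimuth)
        el = np.deg2rad(self.elevation)
        # Grooves run along rows (y); azimuth 0 points along the profile
        # axis (x, columns), i.e. perpendicular to the grooves.
        return np.array(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
        )


@dataclass
class MaterialOptics:
    """Reflective properties of a casting material."""

    tau: float = 0.8  # degree of reflection, [0, 1]
    lrv: float = 20.0  # light reflectance value, [0, 100]

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ParameterError("tau must lie in [0, 1]")
        if not 0.0 <= self.lrv <= 100.0:
            raise ParameterError("LRV must lie in [0, 100]")


def image_contrast(img: Image | np.ndarray) -> float:
    """Image contrast IC: sample standard deviation of pixel brightness.

    IC = sqrt( sum_i (b_i - mean(b))^2 / (n - 1) ) over all n pixels.
    """
    b = img.b if isinstance(img, Image) else np.asarray(img)
    b = b.astype(float)
    if b.size < 2:
        raise StatisticsError("image contrast is undefined for fewer than 2 pixels")
    return float(np.std(b, ddof=1))


def reflected_intensity(incident: float, incidence_angle_deg, optics: MaterialOptics):
    """Reflectance law: I_R = I_I * |sin(lambda)| * tau.

    ``incidence_angle_deg`` is the angle between the incoming ray and the
    surface plane, in degrees; scalar or array.
    """
    if incident < 0:
        raise ParameterError("incident intensity must be non-negative")
    lam = np.deg2rad(np.asarray(incidence_angle_deg, dtype=float))
    out = incident * np.abs(np.sin(lam)) * optics.tau
    return float(out) if np.isscalar(incidence_angle_deg) else out


def _incidence_sin(hm: HeightMap, illum: IlluminationConfig) -> np.ndarray:
    """sin(lambda) per pixel; 0 where the facet faces away from the light."""
    gy, gx = np.gradient(hm.z, hm.dy, hm.dx)
    # Surface normal of z = f(x, y): (-df/dx, -df/dy, 1), normalized.
    norm = np.sqrt(gx**2 + gy**2 + 1.0)
    light = illum.direction()
    sin_lam = (-gx * light[0] - gy * light[1] + light[2]) / norm
    return np.clip(sin_lam, 0.0, 1.0)


def render_oblique(
    hm: HeightMap,
    illum: IlluminationConfig | None = None,
    optics: MaterialOptics | None = None,
    *,
    gain: float = DEFAULT_GAIN,
    quantize: bool = True,
):
    """Render a height map under oblique directional light.

    Brightness per pixel is ``base + gain * I_R`` with
    ``base = 255 * LRV / 100``; with ``quantize=True`` (default) values are
    rounded half-away-from-zero and clamped to [0, 255], returning an
    :class:`Image`. ``quantize=False`` returns the raw float field, useful
    for verifying the linearity of the reflectance law.
    """
    illum = illum or IlluminationConfig()
    optics = optics or MaterialOptics()
    sin_lam = _incidence_sin(hm, illum)
    i_r = illum.intensity * sin_lam * optics.tau
    base = 255.0 * optics.lrv / 100.0
    raw = base + gain * i_r
    if not quantize:
        return raw
    quantized = np.clip(np.floor(raw + 0.5), 0, 255)
    return Image(quantized.astype(np.uint8))


def contrast_by_group(groups: dict, lrv: dict | None = None):
    """Pairwise Mann–Whitney tests of IC between groups, plus IC–LRV Pearson r.

    Parameters
    ----------
    groups : dict
        ``group name -> list of IC values`` (>= 2 groups of >= 2 values).
    lrv : dict, optional
        ``group name -> list of LRV values`` paired with the IC values;
        when given, a Pearson correlation of IC against LRV is computed
        over all pairs (>= 3 points required).

    Returns
    -------
    (pandas.DataFrame, (r, p) or None)
        Symmetric p-value table and, if LRV data were supplied, the
        Pearson correlation.
    """
    from .scoring import test_battery

    names = list(groups.keys())
    if len(names) < 2 or any(len(groups[g]) < 2 for g in names):
        raise StatisticsError("need >= 2 groups with >= 2 IC values each")
    table = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, j in itertools.combinations(range(len(names)), 2):
        _, p = test_battery(groups[names[i]], groups[names[j]], test="mann-whitney-u")
        table.iloc[i, j] = table.iloc[j, i] = p

    pearson = None
    if lrv is not None:
        ics, lrvs = [], []
        for g in names:
            if g not in lrv or len(lrv[g]) != len(groups[g]):
                raise StatisticsError(f"LRV values for group {g!r} do not pair with IC values")
            ics.extend(groups[g])
            lrvs.extend(lrv[g])
        if len(ics) < 3:
            raise StatisticsError("Pearson correlation needs >= 3 points")
        if np.std(ics) == 0 or np.std(lrvs) == 0:
            raise StatisticsError("zero-variance input: correlation undefined")
        r, p = stats.pearsonr(ics, lrvs)
        pearson = (float(r), float(p))
    return table, pearson
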