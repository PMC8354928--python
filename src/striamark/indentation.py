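"""Hertzian spherical indentation: forward model and modulus estimation.

For the elastic contact of a rigid sphere (radius R) with a flat,
incompressible sample, force grows with indentation depth h as

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * h^(3/2),

so the Young's modulus of indentation is

    E_i = (3/4) * F * (1 - nu^2) / (sqrt(R) * h^(3/2)).

Units are MPa (= N/mm^2), mm and N throughout; with those, the formula is
dimensionally consistent without conversion factors.

The measurement protocol emulated by :func:`simulate_indentation`: after a
preload the displacement and force are re-zeroed, then the indenter ramps
at constant speed to a maximum depth while force is sampled at a fixed
rate (defaults: R = 1.5 mm, nu = 0.5, preload 0.1 N, h_max = 0.9 mm,
0.5 mm/s, 50 Hz — a 90-sample loading curve).

:class:`HertzIndentationModel` wraps estimation in a fit interface with
two estimators: an origin-constrained regression of F on h^(3/2)
(default; robust to force noise) and a pointwise mean of per-sample E_i
values (shallow samples excluded, since h^(-3/2) amplifies noise there).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, SizeError, ValidationError

__all__ = [
    "IndentationCurve",
    "ModulusEstimate",
    "hertz_force",
    "estimate_modulus",
    "simulate_indentation",
    "HertzIndentationModel",
    "HertzIndentationResult",
    "write_curve",
    "read_curve",
]

#: Fraction of h_max below which samples are excluded from the pointwise mean.
POINTWISE_DEPTH_CUTOFF = 0.05


@dataclass
class IndentationCurve:
    """A loading-segment force–displacement record.

    ``h`` in mm (non-decreasing), ``F`` in N, indenter radius ``R`` in mm,
    Poisson ratio ``nu``; the curve is assumed re-zeroed after the preload.
    """

    h: np.ndarray
    F: np.ndarray
    R: float = 1.5
    nu: float = 0.5
    preload: float = 0.1
    h_max: float | None = None
    rate_hz: float = 50.0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.h.shape != self.F.shape or self.h.ndim != 1:
            raise ValidationError("h and F must be 1-D arrays of equal length")
        if self.h.size < 5:
            raise ValidationError("an indentation curve needs at least 5 samples")
        if np.any(self.h < 0) or np.any(np.diff(self.h) < 0):
            raise ValidationError("depths must be non-negative and non-decreasing")
        if self.R <= 0:
            raise ValidationError("indenter radius must be positive")
        if not 0.0 <= self.nu <= 0.5:
            raise ValidationError("Poisson ratio must lie in [0, 0.5]")
        if self.h_max is None:
            self.h_max = float(self.h.max())


@dataclass
class ModulusEstimate:
    """An estimated indentation modulus with its fit residual."""

    e_i: float  # MPa
    method: str  # {"pointwise-mean", "regression"}
    rms_residual: float  # N


def hertz_force(E: float, h, R: float = 1.5, nu: float = 0.5):
    """Forward Hertz model: force (N) at depth(s) h (mm).

    F = (4/3) * E/(1-nu^2) * sqrt(R) * h^(3/2), E in MPa, R in mm.
    """
    if E <= 0:
        raise ParameterError("modulus must be positive")
    if R <= 0:
        raise ParameterError("indenter radius must be positive")
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ParameterError("indentation depth must be non-negative")
    out = (4.0 / 3.0) * E / (1.0 - nu**2) * np.sqrt(R) * h_arr**1.5
    return float(out) if np.isscalar(h) else out


def estimate_modulus(curve: IndentationCurve, method: str = "regression") -> ModulusEstimate:
    """Estimate the indentation modulus from a loading curve.

    ``regression``: origin-constrained least squares of F against
    h^(3/2); the slope converts to E. ``pointwise-mean``: mean of
    per-sample E_i over samples with h >= 0.05 * h_max.
    """
    h, F = curve.h, curve.F
    pos = h > 0
    if pos.sum() < 5:
        raise SizeError("need at least 5 samples with positive depth")
    factor = (4.0 / 3.0) / (1.0 - curve.nu**2) * np.sqrt(curve.R)

    if method == "regression":
        x = h[pos] ** 1.5
        y = F[pos]
        slope = float(x @ y) / float(x @ x)
        e_i = slope / factor
    elif method == "pointwise-mean":
        deep = h >= POINTWISE_DEPTH_CUTOFF * curve.h_max
        if not deep.any():
            raise SizeError("all samples below the depth cutoff")
        e_i = float(np.mean(F[deep] / (factor * h[deep] ** 1.5)))
    else:
        raise ParameterError(f"unknown estimation method {method!r}")

    if e_i <= 0:
        raise ValidationError("estimated modulus is non-positive; curve is unphysical")
    fitted = factor * e_i * h**1.5
    rms = float(np.sqrt(np.mean((F - fitted) ** 2)))
    return ModulusEstimate(e_i=e_i, method=method, rms_residual=rms)


def simulate_indentation(
    E: float,
    R: float = 1.5,
    nu: float = 0.5,
    h_max: float = 0.9,
    rate_hz: float = 50.0,
    speed: float = 0.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> IndentationCurve:
    """Simulate a loading curve under the standard ramp protocol.

    Depth is sampled uniformly in time at ``rate_hz`` while the indenter
    descends at ``speed`` mm/s until ``h_max``; the defaults give 90
    samples over 1.8 s. Optional iid Gaussian force noise (``noise_sd`` in
    N) is seeded for exact reproducibility.
    """
    if E <= 0 or R <= 0 or h_max <= 0 or rate_hz <= 0 or speed <= 0:
        raise ParameterError("E, R, h_max, rate_hz and speed must all be positive")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    n = int(round(h_max / speed * rate_hz))
    t = np.arange(1, n + 1) / rate_hz
    h = np.minimum(speed * t, h_max)
    F = hertz_force(E, h, R=R, nu=nu)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sd, size=F.shape)
    return IndentationCurve(h=h, F=F, R=R, nu=nu, h_max=h_max, rate_hz=rate_hz)


class HertzIndentationModel:
    """Hertz contact model for one indentation curve.

    ``fit(method=...)`` estimates the modulus and returns a
    :class:`HertzIndentationResult` carrying the estimate, an uncertainty
    (sd of per-sample moduli over the retained depth range) and fit
    diagnostics.
    """

    def __init__(self, curve: IndentationCurve):
        self.curve = curve

    @classmethod
    def from_file(cls, path) -> "HertzIndentationModel":
        return cls(read_curve(path))

    def fit(self, method: str = "regression") -> "HertzIndentationResult":
        estimate = estimate_modulus(self.curve, method=method)
        c = self.curve
        deep = c.h >= POINTWISE_DEPTH_CUTOFF * c.h_max
        factor = (4.0 / 3.0) / (1.0 - c.nu**2) * np.sqrt(c.R)
        pointwise = c.F[deep] / (factor * c.h[deep] ** 1.5)
        sd = float(np.std(pointwise, ddof=1)) if pointwise.size > 1 else float("nan")
        return HertzIndentationResult(self, estimate, pointwise_sd=sd)


class HertzIndentationResult:
    """Fitted indentation modulus with diagnostics."""

    def __init__(self, model: HertzIndentationModel, estimate: ModulusEstimate,
                 pointwise_sd: float):
        self.model = model
        self.estimate = estimate
        self.pointwise_sd = pointwise_sd

    @property
    def e_i(self) -> float:
        """Indentation modulus, MPa."""
        return self.estimate.e_i

    def summary(self) -> str:
        c = self.model.curve
        lines = [
            "Hertz indentation fit",
            "=====================",
            f"samples:        {c.h.size} (h up to {c.h.max():.3f} mm)",
            f"indenter R:     {c.R} mm, nu = {c.nu}",
            f"method:         {self.estimate.method}",
            f"E_i:            {self.e_i:.4f} MPa (pointwise sd {self.pointwise_sd:.4f})",
            f"rms residual:   {self.estimate.rms_residual:.4g} N",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# curve file format: time / depth / force columns with a '#' header

def write_curve(curve: IndentationCurve, path) -> None:
    """Write a curve as delimited text (t s, h mm, F N) with a header."""
    t = np.arange(1, curve.h.size + 1) / curve.rate_hz
    with open(path, "w") as fh:
        fh.write("# striamark indentation curve\n")
        fh.write(f"# R {curve.R!r}\n")
        fh.write(f"# nu {curve.nu!r}\n")
        fh.write(f"# preload {curve.preload!r}\n")
        fh.write(f"# rate_hz {curve.rate_hz!r}\n")
        for ti, hi, fi in zip(t, curve.h, curve.F):
            fh.write(f"{float(ti)!r}\t{float(hi)!r}\t{float(fi)!r}\n")


def read_curve(path) -> IndentationCurve:
    """Read a curve written by :func:`write_curve`."""
    meta: dict[str, str] = {}
    h, F = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("#").strip().split(None, 1)
                if len(parts) == 2:
                    meta[parts[0]] = parts[1]
                continue
            cols = line.split()
            h.append(float(cols[1]))
            F.append(float(cols[2]))
    return IndentationCurve(
        h=np.array(h),
        F=np.array(F),
        R=float(meta.get("R", 1.5)),
        nu=float(meta.get("nu", 0.5)),
        preload=float(meta.get("preload", 0.1)),
        rate_hz=float(meta.get("rate_hz", 50.0)),
    )
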