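"""Synthetic knives, marks, materials and whole KM/KNM studies.

The generator emulates the data a striation scanner produces from cut
marks in soft test materials, so the entire analysis pipeline can be
exercised without physical scans:

* a *knife* is a 1-D edge-damage profile (smoothed Gaussian noise with a
  chosen correlation length and amplitude) that is shared by every mark
  the knife cuts;
* a *mark* is an S × P height grid whose rows are the knife profile
  subjected to material-dependent per-row lateral jitter, per-point
  height noise, a smooth form term (tilt plus a single-period bow), and —
  for cartilage-like materials — grain-like "dot" bumps whose diameters
  follow a truncated normal around 26.3 ± 5.1 µm (casting material
  filling chondrocyte lacunae produces such dots on real casts);
* a *study* is the standard validation design: n knives, two marks per
  knife, giving n known matches and (cyclically) n known non-matches.

Every output is a pure function of its parameters and seed. Material
presets are invented engineering constants chosen to span high to low
replication fidelity; their ``E`` fields carry literature moduli for
documentation only and are never fitted to any measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import DEFAULT_DX_UM, DEFAULT_DY_UM
from .exceptions import ParameterError
from .scan_io import HeightMap

__all__ = [
    "KnifeProfile",
    "MaterialModel",
    "StudyConfig",
    "generate_knife",
    "generate_mark",
    "generate_study",
    "material_presets",
    "sample_dot_diameter",
    "DOT_DIAMETER_MEAN_UM",
    "DOT_DIAMETER_SD_UM",
]

#: Diameter statistics of grain-like cast dots, µm.
DOT_DIAMETER_MEAN_UM = 26.3
DOT_DIAMETER_SD_UM = 5.1


@dataclass
class KnifeProfile:
    """The edge-damage height profile an individual knife imprints."""

    values: np.ndarray
    correlation_length: float  # µm
    amplitude_sd: float  # µm
    knife_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class MaterialModel:
    """Synthetic material parameters.

    ``lag_sd`` (samples) controls per-row lateral jitter; ``lag_walk``
    chooses iid jitter or a random walk (progressive drift). ``noise_sd``
    (µm) is iid per-point height noise. ``form_amplitude`` (µm) scales a
    smooth tilt + bow term removed by detrending. Dots are a spatial
    Poisson process (``dot_density`` per mm²) of radially symmetric bumps.
    ``tau``/``lrv`` feed the photometry module and ``E`` (MPa) the
    indentation module.
    """

    name: str = "custom"
    lag_sd: float = 1.0
    lag_walk: str = "iid"  # {"iid", "random-walk"}
    noise_sd: float = 0.3
    form_amplitude: float = 2.0
    dot_density: float = 0.0  # per mm^2
    dot_diameter: tuple[float, float] = (DOT_DIAMETER_MEAN_UM, DOT_DIAMETER_SD_UM)
    dot_height: float = 3.0
    tau: float = 0.8
    lrv: float = 20.0
    E: float = 1.0

    def __post_init__(self) -> None:
        if self.lag_sd < 0 or self.noise_sd < 0 or self.dot_density < 0:
            raise ParameterError("material parameters must be non-negative")
        if self.lag_walk not in ("iid", "random-walk"):
            raise ParameterError(f"unknown jitter model {self.lag_walk!r}")
        if not 0.0 <= self.tau <= 1.0 or not 0.0 <= self.lrv <= 100.0:
            raise ParameterError("tau must lie in [0,1], lrv in [0,100]")


@dataclass
class StudyConfig:
    """Design of a KM/KNM validation study (defaults: the standard design)."""

    n_knives: int = 10
    marks_per_knife: int = 2
    S: int = 261
    P: int = 1004
    dx: float = DEFAULT_DX_UM
    dy: float = DEFAULT_DY_UM
    material: MaterialModel = field(default_factory=MaterialModel)
    knife_amplitude_sd: float = 2.0  # µm
    knife_correlation_length: float = 30.0  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_knives < 1 or self.marks_per_knife < 1 or self.S < 2 or self.P < 3:
            raise ParameterError("study counts out of range")


def generate_knife(
    P: int,
    amplitude_sd: float = 2.0,
    correlation_length: float = 30.0,
    dx: float = DEFAULT_DX_UM,
    seed: int | None = None,
    knife_id: str = "",
) -> KnifeProfile:
    """Draw a random knife-edge profile.

    Gaussian white noise smoothed by a moving-average kernel of width
    ``correlation_length / dx`` samples, then centred and rescaled so the
    sample standard deviation equals ``amplitude_sd`` exactly.
    """
    if P < 3 or amplitude_sd <= 0 or dx <= 0:
        raise ParameterError("P, amplitude_sd and dx must be positive")
    if correlation_length < dx:
        raise ParameterError("correlation_length must be at least one sample (dx)")
    rng = np.random.default_rng(seed)
    width = max(int(round(correlation_length / dx)), 1)
    raw = rng.standard_normal(P + width - 1)
    smooth = np.convolve(raw, np.ones(width) / width, mode="valid")
    smooth = smooth - smooth.mean()
    sd = smooth.std()
    if sd == 0:
        raise ParameterError("degenerate knife profile (zero variance)")
    return KnifeProfile(
        values=smooth * (amplitude_sd / sd),
        correlation_length=correlation_length,
        amplitude_sd=amplitude_sd,
        knife_id=knife_id,
    )


def _shift_with_edge_fill(values: np.ndarray, lag: int) -> np.ndarray:
    """Shift a profile by ``lag`` samples, extending the edge value."""
    if lag == 0:
        return values.copy()
    out = np.empty_like(values)
    if lag > 0:
        out[lag:] = values[:-lag]
        out[:lag] = values[0]
    else:
        out[:lag] = values[-lag:]
        out[lag:] = values[-1]
    return out


def sample_dot_diameter(rng: np.random.Generator,
                        mean: float = DOT_DIAMETER_MEAN_UM,
                        sd: float = DOT_DIAMETER_SD_UM) -> float:
    """Draw one dot diameter (µm): normal truncated to positive values.

    At the default parameters the truncation correction is < 1%, so the
    sample mean and sd track the nominal values closely.
    """
    d = -1.0
    while d <= 0:
        d = rng.normal(mean, sd)
    return d


def _add_dots(z: np.ndarray, mat: MaterialModel, dx: float, dy: float,
              rng: np.random.Generator) -> int:
    """Superimpose grain-like dot bumps; returns the dot count."""
    s, p = z.shape
    area_mm2 = (s * dy) * (p * dx) / 1e6
    count = rng.poisson(mat.dot_density * area_mm2)
    mean_d, sd_d = mat.dot_diameter
    for _ in range(count):
        row = rng.uniform(0, s)
        col = rng.uniform(0, p)
        radius = sample_dot_diameter(rng, mean_d, sd_d) / 2.0
        r_rows = int(np.ceil(radius / dy)) + 1
        r_cols = int(np.ceil(radius / dx)) + 1
        rows = np.arange(max(0, int(row) - r_rows), min(s, int(row) + r_rows + 1))
        cols = np.arange(max(0, int(col) - r_cols), min(p, int(col) + r_cols + 1))
        if rows.size == 0 or cols.size == 0:
            continue
        yy = (rows[:, None] - row) * dy
        xx = (cols[None, :] - col) * dx
        r2 = (yy**2 + xx**2) / radius**2
        bump = mat.dot_height * np.clip(1.0 - r2, 0.0, None)
        z[np.ix_(rows, cols)] += bump
    return count


def generate_mark(
    knife: KnifeProfile,
    mat: MaterialModel,
    S: int = 261,
    seed: int | None = None,
    dx: float = DEFAULT_DX_UM,
    dy: float = DEFAULT_DY_UM,
    label: str = "",
) -> HeightMap:
    """Cut one synthetic mark with ``knife`` into material ``mat``.

    Each row is the knife profile shifted by an integer jitter lag, plus
    iid height noise, a smooth form term and optional dot bumps.
    Shifted-out samples are filled by edge-value extension (profiles are
    not periodic).
    """
    rng = np.random.default_rng(seed)
    p = knife.values.size
    if mat.lag_sd > 0:
        steps = rng.normal(0.0, mat.lag_sd, size=S)
        if mat.lag_walk == "random-walk":
            steps = np.cumsum(steps) / np.sqrt(np.arange(1, S + 1))
        lags = np.round(steps).astype(int)
        lags[0] = 0
    else:
        lags = np.zeros(S, dtype=int)

    z = np.empty((S, p))
    for j in range(S):
        z[j] = _shift_with_edge_fill(knife.values, int(lags[j]))

    if mat.noise_sd > 0:
        z += rng.normal(0.0, mat.noise_sd, size=z.shape)

    if mat.form_amplitude > 0:
        x = np.linspace(-0.5, 0.5, p)
        tilt = rng.uniform(-1, 1) * mat.form_amplitude
        phase = rng.uniform(0, 2 * np.pi)
        bow = mat.form_amplitude * np.sin(2 * np.pi * x + phase)
        z += tilt * x + bow

    if mat.dot_density > 0:
        _add_dots(z, mat, dx, dy, rng)

    return HeightMap(z, dx=dx, dy=dy, kind="cast", label=label)


def generate_study(cfg: StudyConfig) -> dict:
    """Generate a full labelled study.

    Returns ``knife_id -> list of HeightMap``. Knife profiles and
    per-mark jitter/noise/dots are drawn from sub-seeds derived
    deterministically from ``cfg.seed``, so the same config always yields
    the identical study.
    """
    root = np.random.SeedSequence(cfg.seed)
    knife_seeds, mark_seeds = root.spawn(2)
    knife_children = knife_seeds.spawn(cfg.n_knives)
    mark_children = mark_seeds.spawn(cfg.n_knives * cfg.marks_per_knife)

    marks: dict[str, list[HeightMap]] = {}
    mark_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for i in range(cfg.n_knives):
        knife_id = f"knife{i + 1:02d}"
        knife = generate_knife(
            cfg.P,
            amplitude_sd=cfg.knife_amplitude_sd,
            correlation_length=cfg.knife_correlation_length,
            dx=cfg.dx,
            seed=knife_children[i],
            knife_id=knife_id,
        )
        marks[knife_id] = []
        for m in range(cfg.marks_per_knife):
            letter = mark_letters[m % len(mark_letters)]
            label = f"{knife_id}-{letter}"
            hm = generate_mark(
                knife,
                cfg.material,
                S=cfg.S,
                seed=mark_children[i * cfg.marks_per_knife + m],
                dx=cfg.dx,
                dy=cfg.dy,
                label=label,
            )
            marks[knife_id].append(hm)
    return marks


def material_presets() -> dict[str, MaterialModel]:
    """Named material presets spanning replication fidelity.

    ``high-fidelity`` behaves like a fine-grained hydrogel (crisp, straight
    marks), ``low-fidelity`` like a coarse gel (noisy, wandering marks);
    ``cartilage-like`` adds the dot artifacts seen on casts of cut
    cartilage. Parameter values are invented engineering constants; the
    ``E`` fields carry reported literature moduli for context only.
    """
    return {
        "high-fidelity": MaterialModel(
            name="high-fidelity", lag_sd=0.8, noise_sd=0.15, form_amplitude=2.0,
            tau=0.85, lrv=35.0, E=1.39,
        ),
        "medium-fidelity": MaterialModel(
            name="medium-fidelity", lag_sd=3.0, noise_sd=0.6, form_amplitude=3.0,
            tau=0.7, lrv=25.0, E=4.01,
        ),
        "low-fidelity": MaterialModel(
            name="low-fidelity", lag_sd=6.0, noise_sd=1.2, form_amplitude=4.0,
            tau=0.5, lrv=15.0, E=0.12,
        ),
        "cartilage-like": MaterialModel(
            name="cartilage-like", lag_sd=2.0, noise_sd=0.5, form_amplitude=3.0,
            dot_density=20.0, dot_height=3.0, tau=0.75, lrv=30.0, E=14.55,
        ),
    }
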