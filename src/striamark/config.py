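"""Central defaults for the analysis pipeline.

Every constant that the standard protocol fixes lives here so that a run
is reproducible from its logged configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Scanner lateral resolution, µm per pixel, both axes.
DEFAULT_DX_UM = 3.0
DEFAULT_DY_UM = 3.0

#: Samples per cross-section signal (columns of the scan grid).
DEFAULT_POINTS_PER_SIGNAL = 1004

#: Moving-average detrending window (odd, samples). ~153 µm at 3 µm/px:
#: well above striation spacing, below the wavelength of mark form.
DEFAULT_DETREND_WINDOW = 51

#: Half-width of the exhaustive lag search (samples).
DEFAULT_MAX_LAG = 50

#: Minimum fraction of signals that must cover a sample for it to survive
#: signature trimming.
SIGNATURE_COVERAGE_FRACTION = 0.9

#: Two-sided significance threshold used throughout the statistics.
SIGNIFICANCE_LEVEL = 0.05


@dataclass
class PipelineConfig:
    """Parameters of the mark → signature pipeline."""

    points_per_signal: int = DEFAULT_POINTS_PER_SIGNAL
    window: int = DEFAULT_DETREND_WINDOW
    max_lag: int = DEFAULT_MAX_LAG
    coverage_fraction: float = SIGNATURE_COVERAGE_FRACTION

    def to_dict(self) -> dict:
        return asdict(self)
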