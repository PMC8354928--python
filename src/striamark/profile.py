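"""From a scanned mark to its signature.

A striated cut mark is digitized as an S × P height grid. Each of the S
rows is one cross-section signal through the striation pattern. The
pipeline (a) splits the grid into signals, (b) detrends each signal by
subtracting its centred moving average (removing tilt and form, keeping the
fine blade structure), (c) sequentially aligns the signals by maximizing
the overlap-normalized cross-correlation

    X(L) = sum_i S1[i] * S2[i+L] / sqrt(sum_i S1[i]^2 * sum_i S2[i+L]^2),

where every sum runs over the overlap region only, and (d) averages the
aligned signals into a single *signature* profile.

Two quality metrics fall out of the alignment: ``x_max``, the mean of the
S−1 maximum step coefficients (close to 1 for a consistent mark), and
``l_xmax``, the mean magnitude of the applied lags (small for a straight
mark).

The statsmodels-style entry point is :class:`MarkSignatureModel`; its
:meth:`~MarkSignatureModel.fit` returns a :class:`MarkSignatureResult`.
Invalid (shifted-out) samples are carried as NaN and never wrapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .exceptions import (
    AlignmentError,
    DegenerateSignatureError,
    ParameterError,
    SizeError,
    UndefinedCorrelationError,
    ValidationError,
)
from .scan_io import HeightMap

__all__ = [
    "ProfileSignal",
    "SignalSet",
    "AlignmentResult",
    "Signature",
    "split_signals",
    "detrend_signal",
    "xcorr_at_lag",
    "best_lag",
    "align_signals",
    "build_signature",
    "mark_signature",
    "MarkSignatureModel",
    "MarkSignatureResult",
    "write_signature",
    "read_signature",
]


@dataclass
class ProfileSignal:
    """One cross-section signal: heights (µm) at spacing ``dx`` (µm)."""

    values: np.ndarray
    dx: float = 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 3:
            raise ValidationError("signal must be 1-D with at least 3 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("signal contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SignalSet:
    """Ordered signals of one mark, all sharing length and spacing.

    ``offsets`` records the lag applied to each signal during alignment
    (all zero beforehand). Aligned signals may contain NaN where samples
    were shifted out of range.
    """

    signals: np.ndarray  # (S, P), NaN marks invalid samples
    dx: float = 3.0
    detrended: bool = False
    offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValidationError("signal set must be a 2-D array")
        if self.offsets is None:
            self.offsets = np.zeros(self.signals.shape[0], dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=int)
        if self.offsets.shape != (self.signals.shape[0],):
            raise ValidationError("one offset per signal required")

    @property
    def n_signals(self) -> int:
        return self.signals.shape[0]

    @property
    def n_points(self) -> int:
        return self.signals.shape[1]


@dataclass
class AlignmentResult:
    """Bookkeeping of the sequential alignment of one mark.

    ``step_coeffs`` and ``step_lags`` hold the S−1 per-step maxima;
    ``x_max`` is their mean and ``l_xmax`` the mean absolute lag.
    """

    step_coeffs: np.ndarray
    step_lags: np.ndarray

    def __post_init__(self) -> None:
        self.step_coeffs = np.asarray(self.step_coeffs, dtype=float)
        self.step_lags = np.asarray(self.step_lags, dtype=int)
        if self.step_coeffs.shape != self.step_lags.shape:
            raise ValidationError("step coefficients and lags must align")

    @property
    def x_max(self) -> float:
        return float(np.mean(self.step_coeffs))

    @property
    def l_xmax(self) -> float:
        return float(np.mean(np.abs(self.step_lags)))


@dataclass
class Signature:
    """The averaged aligned profile representing one mark."""

    values: np.ndarray
    coverage: np.ndarray
    dx: float = 3.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=int)
        if self.values.shape != self.coverage.shape:
            raise ValidationError("signature values and coverage must align")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("signature contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# operations

def split_signals(data, points_per_signal: int | None = None, dx: float = 3.0) -> SignalSet:
    """Split a mark into individual cross-section signals.

    A :class:`HeightMap` is split along its rows (one signal per row). A
    flat sequence is chopped into consecutive blocks of
    ``points_per_signal`` samples, discarding any remainder: the standard
    262,044-point scan yields 261 signals of 1004 points.
    """
    if isinstance(data, HeightMap):
        grid = data.z
        if points_per_signal is not None and points_per_signal != grid.shape[1]:
            raise SizeError(
                f"grid rows have {grid.shape[1]} points, not {points_per_signal}"
            )
        return SignalSet(grid.copy(), dx=data.dx, detrended=False)

    flat = np.asarray(data, dtype=float).ravel()
    if points_per_signal is None:
        raise ParameterError("points_per_signal is required for stream input")
    if points_per_signal < 3:
        raise ParameterError("points_per_signal must be at least 3")
    n_signals = flat.size // points_per_signal
    if n_signals < 2:
        raise SizeError(
            f"{flat.size} points give only {n_signals} complete signals of "
            f"{points_per_signal}; at least 2 required"
        )
    grid = flat[: n_signals * points_per_signal].reshape(n_signals, points_per_signal)
    return SignalSet(grid, dx=dx, detrended=False)


def _moving_average_affine_exact(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average whose edge windows shrink symmetrically.

    At index i the window reaches min(half, i, n-1-i) samples each side, so
    the average of any affine sequence equals the sequence itself.
    """
    n = values.size
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    reach = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo = idx - reach
    hi = idx + reach
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def detrend_signal(s: ProfileSignal, window: int = 51) -> ProfileSignal:
    """Subtract the centred moving average from a signal.

    Removes low-frequency form (tilt, unevenness) while retaining the
    high-frequency structure imprinted by the blade edge. Any affine
    input maps exactly to zero.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be an odd integer >= 3, got {window}")
    avg = _moving_average_affine_exact(s.values, window)
    return ProfileSignal(s.values - avg, dx=s.dx)


def _as_values(s) -> np.ndarray:
    return s.values if isinstance(s, ProfileSignal) else np.asarray(s, dtype=float)


def _overlap(v1: np.ndarray, v2: np.ndarray, lag: int):
    """Overlapping slices of v1[i] and v2[i+lag]; NaN samples drop out."""
    p = v1.size
    if lag >= 0:
        a, b = v1[: p - lag], v2[lag:]
    else:
        a, b = v1[-lag:], v2[: p + lag]
    valid = np.isfinite(a) & np.isfinite(b)
    return a[valid], b[valid]


def xcorr_at_lag(s1, s2, lag: int) -> float:
    """Overlap-normalized cross-correlation of s1[i] with s2[i+lag].

    Numerator and both denominator sums run over the overlap region only,
    so any non-zero signal against itself at lag 0 returns exactly 1.
    """
    v1, v2 = _as_values(s1), _as_values(s2)
    if v1.size != v2.size:
        raise ValidationError("signals must share length")
    if abs(lag) >= v1.size:
        raise ParameterError(f"|lag| must be below signal length {v1.size}")
    a, b = _overlap(v1, v2, lag)
    if a.size < 3:
        raise SizeError(f"only {a.size} overlapping samples at lag {lag}; need >= 3")
    den = math.sqrt(float(a @ a) * float(b @ b))
    if den == 0.0:
        raise UndefinedCorrelationError(f"all-zero overlap at lag {lag}")
    return float(a @ b) / den


def best_lag(s1, s2, max_lag: int = 50, min_overlap: int = 3):
    """Exhaustive lag search for the maximum cross-correlation.

    Searches lags in [−max_lag, +max_lag]; ties break toward the smaller
    |lag|, then toward the negative lag. Returns ``(coefficient, lag)``.
    """
    v1, v2 = _as_values(s1), _as_values(s2)
    if v1.size != v2.size:
        raise ValidationError("signals must share length")
    p = v1.size
    if not 0 < max_lag < p / 2:
        raise ParameterError(f"max_lag must satisfy 0 < max_lag < P/2 = {p / 2}")

    best_c, best_l = -np.inf, 0
    # Visiting lags as 0, −1, +1, −2, +2, … makes "strictly greater wins"
    # realise the tie-break (smaller |lag| first, negative before positive).
    for k in range(0, max_lag + 1):
        lags = (0,) if k == 0 else (-k, k)
        for lag in lags:
            a, b = _overlap(v1, v2, lag)
            if a.size < min_overlap:
                continue
            den = math.sqrt(float(a @ a) * float(b @ b))
            if den == 0.0:
                continue
            c = float(a @ b) / den
            if c > best_c:
                best_c, best_l = c, lag
    if not np.isfinite(best_c):
        raise UndefinedCorrelationError("no lag with a defined correlation")
    return best_c, best_l


def _shift(values: np.ndarray, lag: int) -> np.ndarray:
    """Return values[i + lag] with shifted-out samples set to NaN."""
    p = values.size
    out = np.full(p, np.nan)
    if lag >= 0:
        out[: p - lag] = values[lag:]
    else:
        out[-lag:] = values[: p + lag]
    return out


def align_signals(ss: SignalSet, max_lag: int = 50):
    """Sequentially align the signals of one mark.

    Signal 2 is aligned to signal 1; signal j ≥ 3 to the running per-sample
    mean of the already-aligned signals. Shifted-out samples become NaN
    (profiles are not periodic). Returns the aligned set and an
    :class:`AlignmentResult` carrying the S−1 step coefficients and lags.
    """
    if not ss.detrended:
        raise ValidationError("signals must be detrended before alignment")
    s_count, p = ss.signals.shape
    if s_count < 2:
        raise SizeError("alignment needs at least 2 signals")

    aligned = np.empty_like(ss.signals)
    aligned[0] = ss.signals[0]
    run_sum = np.where(np.isfinite(aligned[0]), aligned[0], 0.0)
    run_cnt = np.isfinite(aligned[0]).astype(float)

    coeffs = np.empty(s_count - 1)
    lags = np.empty(s_count - 1, dtype=int)
    offsets = np.zeros(s_count, dtype=int)

    for j in range(1, s_count):
        with np.errstate(invalid="ignore"):
            reference = np.where(run_cnt > 0, run_sum / np.maximum(run_cnt, 1), np.nan)
        try:
            c, lag = best_lag(reference, ss.signals[j], max_lag=max_lag)
        except (UndefinedCorrelationError, SizeError) as exc:
            raise AlignmentError(f"alignment failed at step {j}: {exc}") from exc
        shifted = _shift(ss.signals[j], lag)
        if np.isfinite(shifted).sum() < 3:
            raise AlignmentError(f"alignment failed at step {j}: overlap below 3 samples")
        aligned[j] = shifted
        coeffs[j - 1], lags[j - 1] = c, lag
        offsets[j] = lag
        ok = np.isfinite(shifted)
        run_sum[ok] += shifted[ok]
        run_cnt += ok

    out = SignalSet(aligned, dx=ss.dx, detrended=True, offsets=offsets)
    return out, AlignmentResult(coeffs, lags)


def build_signature(ss: SignalSet, coverage_fraction: float = 0.9, label: str = "") -> Signature:
    """Average the aligned signals into the mark's signature.

    Each sample is the mean over valid contributions; samples covered by
    fewer than ``coverage_fraction`` of the signals are trimmed from both
    ends to bound edge bias.
    """
    s_count = ss.n_signals
    counts = np.isfinite(ss.signals).sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.nansum(np.nan_to_num(ss.signals, nan=0.0), axis=0) / np.maximum(counts, 1)

    need = math.ceil(coverage_fraction * s_count)
    good = counts >= need
    if not good.any():
        raise DegenerateSignatureError("no sample reaches the coverage threshold")
    lo = int(np.argmax(good))
    hi = int(len(good) - np.argmax(good[::-1]))
    if hi - lo < 10:
        raise DegenerateSignatureError(
            f"coverage trimming leaves {hi - lo} samples; at least 10 required"
        )
    return Signature(means[lo:hi], counts[lo:hi], dx=ss.dx, label=label)


def mark_signature(hm: HeightMap, cfg: PipelineConfig | None = None):
    """Full pipeline: split → detrend → align → signature.

    Deterministic for a fixed input and configuration. Returns
    ``(Signature, AlignmentResult)``.
    """
    cfg = cfg or PipelineConfig()
    ss = split_signals(hm)
    det = np.vstack(
        [
            detrend_signal(ProfileSignal(row, dx=ss.dx), cfg.window).values
            for row in ss.signals
        ]
    )
    dset = SignalSet(det, dx=ss.dx, detrended=True)
    aligned, result = align_signals(dset, max_lag=cfg.max_lag)
    sig = build_signature(aligned, cfg.coverage_fraction, label=hm.label)
    return sig, result


# ---------------------------------------------------------------------------
# model / results facade

class MarkSignatureModel:
    """Signature model for one scanned mark.

    Wraps the split/detrend/align/average pipeline behind a fit interface::

        result = MarkSignatureModel(heightmap, window=51, max_lag=50).fit()
        result.x_max, result.l_xmax, result.signature

    Parameters
    ----------
    heightmap : HeightMap
        The scanned mark (or cast).
    window : int
        Detrending moving-average window (odd samples).
    max_lag : int
        Half-width of the alignment lag search (samples).
    """

    def __init__(self, heightmap: HeightMap, *, window: int = 51, max_lag: int = 50,
                 coverage_fraction: float = 0.9):
        self.heightmap = heightmap
        self.config = PipelineConfig(
            points_per_signal=heightmap.n_cols,
            window=window,
            max_lag=max_lag,
            coverage_fraction=coverage_fraction,
        )

    @classmethod
    def from_file(cls, path, format: str = "grid-text", **kwargs) -> "MarkSignatureModel":
        from .scan_io import read_heightmap

        return cls(read_heightmap(path, format=format), **kwargs)

    def fit(self) -> "MarkSignatureResult":
        signature, alignment = mark_signature(self.heightmap, self.config)
        return MarkSignatureResult(self, signature, alignment)


class MarkSignatureResult:
    """Fitted signature of one mark with its alignment diagnostics."""

    def __init__(self, model: MarkSignatureModel, signature: Signature,
                 alignment: AlignmentResult):
        self.model = model
        self.signature = signature
        self.alignment = alignment

    @property
    def x_max(self) -> float:
        """Mean maximum step correlation — mark quality, close to 1 is good."""
        return self.alignment.x_max

    @property
    def l_xmax(self) -> float:
        """Mean absolute alignment lag (samples) — mark straightness."""
        return self.alignment.l_xmax

    def summary(self) -> str:
        cfg = self.model.config
        hm = self.model.heightmap
        sd = float(np.std(self.alignment.step_coeffs, ddof=1)) if len(
            self.alignment.step_coeffs) > 1 else float("nan")
        lines = [
            "Mark signature fit",
            "==================",
            f"label:            {hm.label or '(unnamed)'}",
            f"grid:             {hm.n_rows} x {hm.n_cols} @ {hm.dx} um/px",
            f"detrend window:   {cfg.window} samples",
            f"max lag searched: +/-{cfg.max_lag} samples",
            f"signature length: {len(self.signature)} samples",
            f"X_max:            {self.x_max:.4f} (step sd {sd:.4f})",
            f"L_Xmax:           {self.l_xmax:.2f} samples",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# signature file format

def write_signature(sig: Signature, path, *, meta: dict | None = None) -> None:
    """Write a signature as delimited text with a ``#`` header."""
    with open(path, "w") as fh:
        fh.write("# striamark signature\n")
        fh.write(f"# dx {sig.dx!r}\n")
        fh.write(f"# label {sig.label}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key} {value}\n")
        for v, c in zip(sig.values, sig.coverage):
            fh.write(f"{float(v)!r}\t{int(c)}\n")


def read_signature(path) -> Signature:
    """Read a signature written by :func:`write_signature`."""
    meta: dict[str, str] = {}
    values, coverage = [], []
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
            v, c = line.split()
            values.append(float(v))
            coverage.append(int(c))
    return Signature(
        np.array(values),
        np.array(coverage),
        dx=float(meta.get("dx", 3.0)),
        label=meta.get("label", ""),
    )
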