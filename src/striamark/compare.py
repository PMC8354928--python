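"""Comparison of mark signatures and KM/KNM study organisation.

Two marks are compared by sliding one signature over the other and taking
the maximum overlap-normalized cross-correlation; the score is called
``x_c``. Two marks cut by the same knife form a *known match* (KM); marks
from different knives form a *known non-match* (KNM). For a validation
study (n knives, two marks each) the KM scores should concentrate near 1
and the KNM scores near 0, and the two score distributions should separate
under a Mann–Whitney U test.

:class:`ToolmarkStudy` is the model-style entry point: built from labelled
height maps or pre-computed signatures, its :meth:`~ToolmarkStudy.fit`
computes per-mark signatures, all configured KM/KNM comparisons and
per-material summaries, returned as a :class:`ToolmarkStudyResult`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .exceptions import DesignError, SizeError, StatisticsError, UnitError, ValidationError
from .profile import (
    AlignmentResult,
    MarkSignatureModel,
    ProfileSignal,
    Signature,
    best_lag,
)
from .scan_io import HeightMap

__all__ = [
    "ComparisonResult",
    "MaterialSummary",
    "compare_signatures",
    "km_knm_matrix",
    "summarize_material",
    "compare_materials",
    "ToolmarkStudy",
    "ToolmarkStudyResult",
]


@dataclass
class ComparisonResult:
    """Outcome of one signature-vs-signature comparison."""

    x_c: float
    lag: int
    label: str = "unknown"  # {"KM", "KNM", "unknown"}
    pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.x_c <= 1.0 + 1e-12:
            raise ValidationError(f"x_c = {self.x_c} outside [-1, 1]")
        if self.label not in ("KM", "KNM", "unknown"):
            raise ValidationError(f"unknown comparison label {self.label!r}")


@dataclass
class MaterialSummary:
    """Per-material summary: (mean, sd, n) triples plus KM/KNM separation."""

    material: str
    x_max_stats: tuple[float, float, int]
    l_xmax_stats: tuple[float, float, int]
    xc_km_stats: tuple[float, float, int]
    xc_knm_stats: tuple[float, float, int]
    separation_p: float
    # raw per-pair / per-mark values, retained for cross-material testing
    raw: dict = field(default_factory=dict)


def _mean_sd_n(values) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise StatisticsError("empty group")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sd, int(arr.size)


def compare_signatures(a: Signature, b: Signature, max_lag: int = 50) -> ComparisonResult:
    """Maximum cross-correlation between two mark signatures.

    Signatures of unequal length are compared over their common span,
    left-aligned (trimming makes lengths differ by at most 2·max_lag).
    """
    if not np.isclose(a.dx, b.dx):
        raise UnitError(f"signature spacings differ: {a.dx} vs {b.dx} um")
    n = min(len(a), len(b))
    va, vb = a.values[:n], b.values[:n]
    if n < 2 * max_lag + 10:
        raise SizeError(f"signatures too short ({n}) for a +/-{max_lag} lag search")
    c, lag = best_lag(ProfileSignal(va, a.dx), ProfileSignal(vb, b.dx),
                      max_lag=max_lag, min_overlap=10)
    return ComparisonResult(x_c=c, lag=lag, pair=(a.label, b.label))


def km_knm_matrix(marks: dict, pairing: str = "cyclic", max_lag: int = 50) -> list[ComparisonResult]:
    """Build the KM and KNM comparisons of a validation study.

    Parameters
    ----------
    marks : dict
        Mapping ``knife_id -> sequence of Signature`` (>= 2 marks per
        knife; marks beyond the first two are ignored for pairing).
    pairing : {"cyclic", "all-knm"}
        KM pairs are always the two marks of each knife. ``cyclic`` pairs
        mark A of knife i with mark B of knife i+1 (cyclically): exactly
        one KNM per knife. ``all-knm`` compares every mark against every
        mark of every other knife.
    """
    knives = list(marks.keys())
    if len(knives) < 2:
        raise DesignError("KNM pairs require at least 2 knives")
    for k in knives:
        if len(marks[k]) < 2:
            raise DesignError(f"knife {k!r} has fewer than 2 marks")

    results: list[ComparisonResult] = []
    for k in knives:
        a, b = marks[k][0], marks[k][1]
        r = compare_signatures(a, b, max_lag=max_lag)
        r.label = "KM"
        results.append(r)

    if pairing == "cyclic":
        for i, k in enumerate(knives):
            k_next = knives[(i + 1) % len(knives)]
            r = compare_signatures(marks[k][0], marks[k_next][1], max_lag=max_lag)
            r.label = "KNM"
            results.append(r)
    elif pairing == "all-knm":
        for ka, kb in itertools.combinations(knives, 2):
            for a in marks[ka][:2]:
                for b in marks[kb][:2]:
                    r = compare_signatures(a, b, max_lag=max_lag)
                    r.label = "KNM"
                    results.append(r)
    else:
        raise DesignError(f"unknown pairing scheme {pairing!r}")
    return results


def summarize_material(
    results: list[ComparisonResult],
    per_mark: list[AlignmentResult] | None = None,
    material: str = "",
) -> MaterialSummary:
    """Summarize one material's study: means ± sd and KM/KNM separation.

    The separation p-value is a two-sided Mann–Whitney U test of the KM
    scores against the KNM scores (exact method for small groups).
    """
    km = [r.x_c for r in results if r.label == "KM"]
    knm = [r.x_c for r in results if r.label == "KNM"]
    if not km or not knm:
        raise StatisticsError("need at least one KM and one KNM result")
    from .scoring import test_battery

    _, p = test_battery(km, knm, test="mann-whitney-u")
    per_mark = per_mark or []
    x_max_vals = [a.x_max for a in per_mark]
    l_vals = [a.l_xmax for a in per_mark]
    return MaterialSummary(
        material=material,
        x_max_stats=_mean_sd_n(x_max_vals) if x_max_vals else (float("nan"), float("nan"), 0),
        l_xmax_stats=_mean_sd_n(l_vals) if l_vals else (float("nan"), float("nan"), 0),
        xc_km_stats=_mean_sd_n(km),
        xc_knm_stats=_mean_sd_n(knm),
        separation_p=float(p),
        raw={"x_max": x_max_vals, "l_xmax": l_vals, "xc_km": km, "xc_knm": knm},
    )


def compare_materials(summaries: list[MaterialSummary], metric: str = "x_max") -> pd.DataFrame:
    """Pairwise two-sided Mann–Whitney U p-values between materials.

    ``metric`` selects which retained raw values are tested: ``x_max``,
    ``l_xmax``, ``xc_km`` or ``xc_knm``. The table is symmetric with a
    unit diagonal.
    """
    if len(summaries) < 2:
        raise StatisticsError("need at least 2 materials")
    names = [s.material for s in summaries]
    from .scoring import test_battery

    table = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, j in itertools.combinations(range(len(names)), 2):
        xi = summaries[i].raw.get(metric)
        xj = summaries[j].raw.get(metric)
        if not xi or not xj:
            raise StatisticsError(f"raw {metric!r} values missing for a material")
        _, p = test_battery(xi, xj, test="mann-whitney-u")
        table.iloc[i, j] = table.iloc[j, i] = p
    return table


# ---------------------------------------------------------------------------
# study model

class ToolmarkStudy:
    """A KM/KNM validation study for one material.

    Parameters
    ----------
    marks : dict
        ``knife_id -> list of HeightMap`` (two marks per knife in the
        standard design).
    material : str
        Material name for reporting.
    window, max_lag : int
        Pipeline parameters passed to each mark's signature fit.
    pairing : {"cyclic", "all-knm"}
        KNM pairing scheme.
    """

    def __init__(self, marks: dict, material: str = "", *, window: int = 51,
                 max_lag: int = 50, pairing: str = "cyclic"):
        self.marks = marks
        self.material = material
        self.window = window
        self.max_lag = max_lag
        self.pairing = pairing

    @classmethod
    def from_directory(cls, directory, manifest: str = "manifest.tsv", **kwargs) -> "ToolmarkStudy":
        """Load a simulated or exported study from grid-text files.

        The manifest is a TSV with columns mark_id, knife_id, material,
        path (relative to the directory).
        """
        from pathlib import Path

        from .scan_io import read_heightmap

        directory = Path(directory)
        table = pd.read_csv(directory / manifest, sep="\t")
        marks: dict[str, list[HeightMap]] = {}
        material = ""
        for _, row in table.iterrows():
            hm = read_heightmap(directory / row["path"], format="grid-text")
            hm.label = str(row["mark_id"])
            marks.setdefault(str(row["knife_id"]), []).append(hm)
            material = str(row.get("material", material))
        return cls(marks, material=material, **kwargs)

    def fit(self) -> "ToolmarkStudyResult":
        signatures: dict[str, list[Signature]] = {}
        alignments: list[AlignmentResult] = []
        for knife_id, mark_list in self.marks.items():
            signatures[knife_id] = []
            for hm in mark_list:
                res = MarkSignatureModel(hm, window=self.window, max_lag=self.max_lag).fit()
                signatures[knife_id].append(res.signature)
                alignments.append(res.alignment)
        comparisons = km_knm_matrix(signatures, pairing=self.pairing, max_lag=self.max_lag)
        summary = summarize_material(comparisons, alignments, material=self.material)
        return ToolmarkStudyResult(self, signatures, alignments, comparisons, summary)


class ToolmarkStudyResult:
    """Fitted study: signatures, comparisons and the material summary."""

    def __init__(self, model, signatures, alignments, comparisons, material_summary):
        self.model = model
        self.signatures = signatures
        self.alignments = alignments
        self.comparisons = comparisons
        self.material_summary = material_summary

    def to_frame(self) -> pd.DataFrame:
        """One row per comparison: pair ids, label, x_c, lag."""
        return pd.DataFrame(
            {
                "material": self.model.material,
                "mark_a": r.pair[0],
                "mark_b": r.pair[1],
                "label": r.label,
                "x_c": r.x_c,
                "lag": r.lag,
            }
            for r in self.comparisons
        )

    def summary(self) -> str:
        s = self.material_summary
        def fmt(t):
            return f"{t[0]:.3f} +/- {t[1]:.3f} (n={t[2]})"

        lines = [
            f"Tool-mark study: {s.material or '(unnamed material)'}",
            "=" * 40,
            f"X_max:    {fmt(s.x_max_stats)}",
            f"L_Xmax:   {fmt(s.l_xmax_stats)}",
            f"X_C (KM):  {fmt(s.xc_km_stats)}",
            f"X_C (KNM): {fmt(s.xc_knm_stats)}",
            f"KM vs KNM Mann-Whitney p: {s.separation_p:.2e}",
        ]
        return "\n".join(lines)
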