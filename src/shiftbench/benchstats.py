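"""Error statistics, method ranking, difference histograms, and reports.

The two headline statistics are the root-mean-square deviation
RMSD = sqrt(mean(residual^2)) and the maximum absolute deviation
MD = max|residual| of predicted minus experimental shifts, computed per
method and nucleus (and optionally per compound).  Ranking is ascending by
RMSD; "lowest-or-tied" tallies compare cells after rounding to the printed
precision, so two methods sharing a printed best cell both count as best.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .dataset import Nucleus, ProbeRecord
from .scaling import ShiftPrediction

__all__ = [
    "BenchmarkSummary",
    "HistogramSpec",
    "HistogramResult",
    "evaluate",
    "rank_methods",
    "lowest_or_tied_tally",
    "histogram_diff",
    "render_report",
    "round_half_up",
]

# printed decimals per nucleus in the benchmark tables
_DISPLAY_DECIMALS = {Nucleus.H1: 3, Nucleus.C13: 2}
_DISPLAY_DECIMALS_MD = {Nucleus.H1: 2, Nucleus.C13: 1}


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed tables do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BenchmarkSummary:
    """Residual summary for one method and nucleus."""

    method_label: str
    nucleus: Nucleus
    residuals: tuple[float, ...]
    rmsd: float
    md: float
    n: int
    per_compound: dict[str, "BenchmarkSummary"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n != len(self.residuals):
            raise ValueError("n must equal the residual count")
        if self.md < self.rmsd - 1e-12:
            raise ValueError("md must be >= rmsd")


def evaluate(
    predictions: Sequence[ShiftPrediction], method_label: str = ""
) -> BenchmarkSummary:
    """RMSD/MD summary over predictions carrying residuals.

    Also computes per-compound sub-summaries (probe-table granularity) at full
    precision; display rounding happens only at render time.
    """
    preds = [p for p in predictions if p.residual is not None]
    if not preds:
        raise ValueError("no predictions with residuals")
    nuclei = {p.nucleus for p in preds}
    if len(nuclei) > 1:
        raise ValueError("predictions mix nuclei; summarize each nucleus separately")
    nucleus = next(iter(nuclei))

    def summarize(ps: Sequence[ShiftPrediction]) -> tuple[tuple[float, ...], float, float]:
        res = tuple(float(p.residual) for p in ps)
        arr = np.asarray(res)
        return res, float(np.sqrt(np.mean(arr**2))), float(np.max(np.abs(arr)))

    per_compound: dict[str, BenchmarkSummary] = {}
    for cid in sorted({p.compound_id for p in preds}):
        sub = [p for p in preds if p.compound_id == cid]
        res, rmsd, md = summarize(sub)
        per_compound[cid] = BenchmarkSummary(
            method_label=method_label, nucleus=nucleus,
            residuals=res, rmsd=rmsd, md=md, n=len(res),
        )
    res, rmsd, md = summarize(preds)
    return BenchmarkSummary(
        method_label=method_label, nucleus=nucleus,
        residuals=res, rmsd=rmsd, md=md, n=len(res),
        per_compound=per_compound,
    )


def rank_methods(summaries: Sequence[BenchmarkSummary]) -> list[BenchmarkSummary]:
    """Order summaries ascending by RMSD; ties break by MD, then label."""
    if not summaries:
        return []
    nuclei = {s.nucleus for s in summaries}
    if len(nuclei) > 1:
        raise ValueError("cannot rank across different nuclei")
    return sorted(summaries, key=lambda s: (s.rmsd, s.md, s.method_label))


def lowest_or_tied_tally(
    records: Sequence[ProbeRecord],
    method: str,
    nucleus: Nucleus,
    decimals: int = 2,
) -> int:
    """Count probe records where ``method`` has the lowest-or-tied RMSD.

    Cells are compared after half-up rounding to the table's printed decimals,
    so a shared printed best counts for every method holding it.  Records where
    the method has no printed cell are skipped.
    """
    count = 0
    for rec in records:
        mine = rec.rmsd.get((method, nucleus))
        if mine is None:
            continue
        others = [
            v for (meth, nuc), v in rec.rmsd.items()
            if nuc == nucleus and meth != method
        ]
        mine_r = round_half_up(mine, decimals)
        if all(mine_r <= round_half_up(v, decimals) for v in others):
            count += 1
    return count


@dataclass(frozen=True)
class HistogramSpec:
    """Half-open binning grid [lo, hi) anchored at ``center``."""

    bin_width: float
    center: float = 0.0
    counts: dict[float, int] = field(default_factory=dict)  # keyed by bin lower edge

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass(frozen=True)
class HistogramResult:
    spec: HistogramSpec
    n: int
    n_within_one_width: int  # |diff| <= bin_width
    n_beyond_two_widths: int  # |diff| > 2 * bin_width
    max_abs_diff: float


def histogram_diff(
    values_a: Sequence[float],
    values_b: Sequence[float],
    spec: HistogramSpec,
) -> HistogramResult:
    """Bin pairwise differences (a - b) on a half-open grid.

    Also reports how many differences fall within +-bin_width, how many exceed
    +-2*bin_width (outliers), and the largest absolute difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matched shift lists must have equal length")
    diffs = a - b
    w = spec.bin_width
    edges = np.floor((diffs - spec.center) / w)
    counts: dict[float, int] = {}
    for e in edges:
        lo = round(spec.center + e * w, 12)
        counts[lo] = counts.get(lo, 0) + 1
    filled = HistogramSpec(bin_width=w, center=spec.center, counts=counts)
    return HistogramResult(
        spec=filled,
        n=diffs.size,
        n_within_one_width=int(np.sum(np.abs(diffs) <= w)),
        n_beyond_two_widths=int(np.sum(np.abs(diffs) > 2 * w)),
        max_abs_diff=float(np.max(np.abs(diffs))) if diffs.size else 0.0,
    )


def render_report(
    summaries: Sequence[BenchmarkSummary], fmt: str = "text"
) -> str:
    """Deterministic benchmark table: method label, RMSD, MD, n, rank order.

    ``fmt`` is ``"text"`` (aligned columns) or ``"json"``.  RMSD/MD print at
    3/2 decimals for 1H and 2/1 for 13C, matching the field's table style.
    """
    if fmt not in ("text", "json"):
        raise ValueError(f"unknown report format {fmt!r}")
    ranked = rank_methods(summaries) if summaries else []
    rows = []
    for s in ranked:
        d = _DISPLAY_DECIMALS[s.nucleus]
        dm = _DISPLAY_DECIMALS_MD[s.nucleus]
        rows.append(
            {
                "method": s.method_label,
                "nucleus": s.nucleus.value,
                "rmsd": round_half_up(s.rmsd, d),
                "md": round_half_up(s.md, dm),
                "n": s.n,
            }
        )
    if fmt == "json":
        return json.dumps(rows, indent=1)
    header = f"{'method':<40} {'nucleus':<7} {'rmsd':>8} {'md':>8} {'n':>5}"
    lines = [header]
    for r in rows:
        lines.append(
            f"{r['method']:<40} {r['nucleus']:<7} {r['rmsd']:>8g} {r['md']:>8g} {r['n']:>5d}"
        )
    return "\n".join(lines)
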