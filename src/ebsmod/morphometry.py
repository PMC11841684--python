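"""Blister morphometry along the basement membrane zone (BMZ).

Organotypic skin equivalents deficient in a BMZ scaffold protein develop
spontaneous subepidermal blisters.  The readout is the fraction of the BMZ
contour length that is blistering: an annotated trace (the BMZ polyline plus
blister intervals in arclength coordinates) yields a dimensionless fraction,
and groups of fractions are compared with a Welch two-sided t-test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats


class MorphometryError(ValueError):
    pass


@dataclass(frozen=True)
class BmzTrace:
    """BMZ polyline (ordered 2-D points, pixel or micron units) with blister
    intervals given as (start, end) arclength pairs along the polyline."""

    polyline: np.ndarray
    blister_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        poly = np.asarray(self.polyline, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
            raise MorphometryError("polyline must be an (n>=2, 2) point array")
        if not np.all(np.isfinite(poly)):
            raise MorphometryError("non-finite polyline coordinates")
        object.__setattr__(self, "polyline", poly)
        total = self.total_length
        for s, e in self.blister_intervals:
            if not s < e:
                raise MorphometryError(f"interval ({s}, {e}) must have start < end")
            if s < 0 or e > total + 1e-9:
                raise MorphometryError(
                    f"interval ({s}, {e}) outside [0, {total:.6g}]"
                )

    @property
    def total_length(self) -> float:
        segs = np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)
        return float(segs.sum())


def merge_intervals(
    intervals: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Union of possibly-overlapping intervals; never longer than their sum."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def blister_fraction(trace: BmzTrace) -> float:
    """Blistering arclength divided by total BMZ arclength, in [0, 1]."""
    total = trace.total_length
    if total == 0.0:
        raise MorphometryError("zero-length polyline")
    covered = sum(e - s for s, e in merge_intervals(trace.blister_intervals))
    return min(covered / total, 1.0)


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float


def compare_fractions(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TTestResult:
    """Welch two-sided t-test between two groups of blister fractions."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise MorphometryError("each group needs at least 2 fractions")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.pvalue))


def read_traces_json(path: str | Path) -> dict[str, BmzTrace]:
    """Read traces from JSON: {"traces": [{"id", "polyline": [[x,y],...],
    "blister_intervals": [[s,e],...]}, ...]}."""
    data = json.loads(Path(path).read_text())
    out = {}
    for t in data.get("traces", []):
        out[str(t["id"])] = BmzTrace(
            polyline=np.asarray(t["polyline"], dtype=float),
            blister_intervals=tuple((float(s), float(e)) for s, e in t.get("blister_intervals", [])),
        )
    if not out:
        raise MorphometryError(f"{path}: no traces")
    return out


def write_traces_json(traces: dict[str, BmzTrace], path: str | Path) -> None:
    data = {
        "traces": [
            {
                "id": tid,
                "polyline": t.polyline.tolist(),
                "blister_intervals": [list(iv) for iv in t.blister_intervals],
            }
            for tid, t in traces.items()
        ]
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
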