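"""Retention indices from n-alkane ladders and cross-setup shift diagnostics.

The retention index (RI) expresses retention relative to co-injected
n-alkanes: at the alkane with carbon number n the index is 100·n by
definition, and between alkanes it is interpolated.  For temperature-
programmed GC the van den Dool–Kratz convention applies — linear
interpolation in retention time:

    RI(rt) = 100 · ( n_i + (n_{i+1} − n_i) · (rt − rt_i) / (rt_{i+1} − rt_i) )

for the two anchors bracketing ``rt``.  Outside the ladder the terminal
segment is continued linearly and the value is flagged as extrapolated.
The ladder used here routinely spans C10–C36 with uneven carbon gaps
(C10, C12, C15, C17, C19, C22, C28, C32, C36), which the formula handles
without special cases.

Retention is only as comparable as the setups that produced it: columns from
different vendors (or a replaced LC column) shift RIs/RTs non-uniformly and
can even invert the elution order of close pairs.  :func:`shift_report`
quantifies this — per-compound deltas, summary statistics, a histogram, and
the explicit list of order inversions between two setups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import CompoundLibrary, LibraryEntry

__all__ = [
    "AlkaneLadder",
    "ShiftReport",
    "compute_ri",
    "rt_for_ri",
    "shift_report",
    "ambiguity_risk",
]


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear continuation of the terminal segments."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if np.any(lo):
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y = np.where(lo, fp[0] + slope * (x - xp[0]), y)
    if np.any(hi):
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(hi, fp[-1] + slope * (x - xp[-1]), y)
    return y


@dataclass(frozen=True)
class AlkaneLadder:
    """Retention-index anchors: (carbon number, retention time in seconds).

    Anchors must be strictly increasing in both carbon number and RT
    (chromatography is monotone); at least two are required.
    """

    carbon: np.ndarray
    rt: np.ndarray

    def __post_init__(self) -> None:
        carbon = np.asarray(self.carbon, dtype=float)
        rt = np.asarray(self.rt, dtype=float)
        if carbon.ndim != 1 or carbon.shape != rt.shape or carbon.size < 2:
            raise ValueError("ladder needs >= 2 (carbon, rt) anchor pairs")
        if np.any(np.diff(carbon) <= 0):
            raise ValueError("carbon numbers must be strictly increasing")
        if np.any(np.diff(rt) <= 0):
            raise ValueError("anchor retention times must be strictly increasing")
        object.__setattr__(self, "carbon", carbon)
        object.__setattr__(self, "rt", rt)

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[int, float]]) -> "AlkaneLadder":
        arr = np.asarray(sorted(pairs), dtype=float)
        return cls(arr[:, 0], arr[:, 1])

    @property
    def ri_anchors(self) -> np.ndarray:
        return 100.0 * self.carbon

    @property
    def rt_range(self) -> tuple[float, float]:
        return float(self.rt[0]), float(self.rt[-1])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"carbon_number": self.carbon.astype(int), "rt_seconds": self.rt}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlkaneLadder":
        df = pd.read_csv(path, sep="\t")
        return cls(df["carbon_number"].to_numpy(), df["rt_seconds"].to_numpy())


def compute_ri(
    rt: float | np.ndarray,
    ladder: AlkaneLadder,
    return_extrapolated: bool = False,
):
    """Convert retention time(s) to retention index via the ladder.

    Linear (van den Dool–Kratz) interpolation between the bracketing anchors;
    RI is exactly 100·carbon at every anchor.  Times outside the ladder are
    extrapolated along the terminal segment; with ``return_extrapolated`` a
    boolean flag (array) marking those values is returned as well.
    """
    rt_arr = np.asarray(rt, dtype=float)
    if not np.all(np.isfinite(rt_arr)):
        raise ValueError("retention time must be finite")
    ri = _interp_extrap(rt_arr, ladder.rt, ladder.ri_anchors)
    extrap = (rt_arr < ladder.rt[0]) | (rt_arr > ladder.rt[-1])
    if np.isscalar(rt) or rt_arr.ndim == 0:
        ri, extrap = float(ri), bool(extrap)
    if return_extrapolated:
        return ri, extrap
    return ri


def rt_for_ri(ri: float | np.ndarray, ladder: AlkaneLadder) -> float | np.ndarray:
    """Inverse of :func:`compute_ri`: retention time at a given index.

    Exact inverse on (and beyond, by linear continuation) the ladder range:
    ``compute_ri(rt_for_ri(x)) == x`` to 1e-9 relative.
    """
    ri_arr = np.asarray(ri, dtype=float)
    if not np.all(np.isfinite(ri_arr)):
        raise ValueError("retention index must be finite")
    rt = _interp_extrap(ri_arr, ladder.ri_anchors, ladder.rt)
    if np.isscalar(ri) or ri_arr.ndim == 0:
        return float(rt)
    return rt


# ---------------------------------------------------------------------------
# Cross-setup diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ShiftReport:
    """Per-compound retention deltas between two setups plus summaries.

    ``delta`` is setup-b minus setup-a.  ``inversions`` lists every pair of
    shared compounds whose elution order differs between the setups — the
    pairs a library transfer would silently mis-assign.
    """

    per_compound: pd.DataFrame  # columns: compound, value_a, value_b, delta
    summary: dict[str, float]
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    inversions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_inversions(self) -> int:
        return len(self.inversions)

    def to_tsv(self, path: str | Path) -> None:
        self.per_compound.to_csv(path, sep="\t", index=False)

    def summary_json(self) -> dict:
        return {
            **self.summary,
            "n_inversions": self.n_inversions,
            "inversions": [list(p) for p in self.inversions],
            "histogram": {
                "bin_edges": self.bin_edges.tolist(),
                "counts": self.bin_counts.tolist(),
            },
        }


def shift_report(
    a: Mapping[str, float],
    b: Mapping[str, float],
    bin_width: float = 5.0,
) -> ShiftReport:
    """Compare per-compound retention values measured on two setups.

    Only compounds present in both maps are compared.  The default histogram
    bin width of 5 suits both RI units (GC) and seconds (LC).  An inversion
    is a shared pair (x, y) with strictly opposite order in the two setups;
    ties in either setup are not counted.
    """
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no shared compounds between the two setups")
    va = np.array([a[c] for c in shared], dtype=float)
    vb = np.array([b[c] for c in shared], dtype=float)
    delta = vb - va
    df = pd.DataFrame(
        {"compound": shared, "value_a": va, "value_b": vb, "delta": delta}
    )
    summary = {
        "n": len(shared),
        "mean": float(np.mean(delta)),
        "median": float(np.median(delta)),
        "sd": float(np.std(delta, ddof=1)) if len(shared) > 1 else 0.0,
        "mean_abs": float(np.mean(np.abs(delta))),
    }
    lo = np.floor(delta.min() / bin_width) * bin_width
    hi = np.ceil(delta.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(delta, bins=edges)

    inversions = [
        (shared[i], shared[j])
        for i in range(len(shared))
        for j in range(i + 1, len(shared))
        if (va[i] - va[j]) * (vb[i] - vb[j]) < 0
    ]
    return ShiftReport(
        per_compound=df,
        summary=summary,
        bin_edges=edges,
        bin_counts=counts,
        inversions=inversions,
    )


def ambiguity_risk(
    library: CompoundLibrary,
    tolerance: float,
) -> list[list[LibraryEntry]]:
    """Groups of library entries whose expected RIs fall within a shift range.

    Single linkage along the RI axis: sorted entries are chained while the
    gap to the next entry is <= ``tolerance``; any group of two or more is a
    potential mis-identification cluster should retention shift by that much.
    With tolerance 0 only exact RI ties group.
    """
    entries = [e for e in library if e.expected_ri is not None]
    entries.sort(key=lambda e: e.expected_ri)
    groups: list[list[LibraryEntry]] = []
    current: list[LibraryEntry] = []
    for e in entries:
        if current and e.expected_ri - current[-1].expected_ri <= tolerance:
            current.append(e)
        else:
            if len(current) > 1:
                groups.append(current)
            current = [e]
    if len(current) > 1:
        groups.append(current)
    return groups
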