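"""Mass-spectral similarity: forward and reverse match factors (0–1000).

Electron-impact spectra of isomers can be nearly indistinguishable (the
aldohexoses score above 900 against each other), so a single match-factor
number decides little on its own — but it is the standard first filter, and
its reverse variant is what spectral search tools report when the query may
contain impurity peaks.

The score is the Stein–Scott weighted dot product: peaks are binned to unit
m/z, weighted as

    w = intensity^a · mz^b        (defaults a = 0.6, b = 3)

and the squared cosine between the weighted vectors is scaled to 0–1000.
In *forward* mode the vectors run over the union of occupied bins; in
*reverse* mode only bins occupied by the reference count, so query-only
peaks (impurities, coeluters) do not penalise the match.  1000 means
identical, 0 means no shared fragment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .library import CompoundLibrary, Spectrum

__all__ = [
    "MatchResult",
    "match_factor",
    "compare",
    "pairwise_matrix",
    "DEFAULT_INTENSITY_EXPONENT",
    "DEFAULT_MZ_EXPONENT",
]

DEFAULT_INTENSITY_EXPONENT = 0.6
DEFAULT_MZ_EXPONENT = 3.0

Mode = Literal["forward", "reverse"]


def _binned(spectrum: Spectrum, bin_width: float) -> dict[int, float]:
    """Sum intensities into unit-m/z (or bin_width) bins keyed by bin index."""
    bins: dict[int, float] = {}
    idx = np.rint(spectrum.mz / bin_width).astype(int)
    for i, inten in zip(idx, spectrum.intensity):
        bins[int(i)] = bins.get(int(i), 0.0) + float(inten)
    return bins


def match_factor(
    query: Spectrum,
    reference: Spectrum,
    mode: Mode = "reverse",
    weights: tuple[float, float] = (DEFAULT_INTENSITY_EXPONENT, DEFAULT_MZ_EXPONENT),
    bin_width: float = 1.0,
) -> int:
    """Weighted-cosine match factor on the 0–1000 scale, rounded to integer.

    ``weights`` is (intensity exponent a, m/z exponent b).  Scores are
    invariant to overall intensity scaling and to peak order.  Reverse mode
    restricts the comparison to m/z bins occupied by the reference, which
    makes it tolerant to extra peaks in the query.
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("cannot match an empty spectrum")
    a, b = weights
    q_bins = _binned(query, bin_width)
    r_bins = _binned(reference, bin_width)
    if mode == "reverse":
        support = sorted(r_bins)
    elif mode == "forward":
        support = sorted(set(q_bins) | set(r_bins))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    mz_rep = np.array(support, dtype=float) * bin_width
    wq = np.array([q_bins.get(i, 0.0) for i in support]) ** a * mz_rep**b
    wr = np.array([r_bins.get(i, 0.0) for i in support]) ** a * mz_rep**b
    dot = float(wq @ wr)
    nq = float(wq @ wq)
    nr = float(wr @ wr)
    if dot == 0.0 or nq == 0.0 or nr == 0.0:
        return 0
    score = 1000.0 * dot * dot / (nq * nr)
    return int(round(score))


def compare(
    query: Spectrum,
    reference: Spectrum,
    weights: tuple[float, float] = (DEFAULT_INTENSITY_EXPONENT, DEFAULT_MZ_EXPONENT),
    bin_width: float = 1.0,
) -> "MatchResult":
    """Forward and reverse match factors plus the shared-bin count."""
    q_bins = _binned(query, bin_width)
    r_bins = _binned(reference, bin_width)
    return MatchResult(
        forward=match_factor(query, reference, "forward", weights, bin_width),
        reverse=match_factor(query, reference, "reverse", weights, bin_width),
        shared_peaks=len(set(q_bins) & set(r_bins)),
    )


@dataclass(frozen=True)
class MatchResult:
    """Forward/reverse match factors for one query-reference comparison."""

    forward: int
    reverse: int
    shared_peaks: int

    def __post_init__(self) -> None:
        for score in (self.forward, self.reverse):
            if not 0 <= score <= 1000:
                raise ValueError(f"match factor {score} outside [0, 1000]")


def pairwise_matrix(
    library: CompoundLibrary,
    mode: Mode = "reverse",
    weights: tuple[float, float] = (DEFAULT_INTENSITY_EXPONENT, DEFAULT_MZ_EXPONENT),
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """All-against-all match factors over a library's spectra.

    Rows are queries, columns references.  Forward mode gives a symmetric
    matrix; reverse mode is directional (row spectrum matched against the
    column spectrum's peak set), mirroring how spectral search tools report
    comparisons in either direction.
    """
    for entry in library:
        if entry.spectrum is None:
            raise ValueError(f"entry {entry.name!r} has no spectrum")
    names = library.names()
    n = len(names)
    mat = np.zeros((n, n), dtype=int)
    entries = list(library)
    for i in range(n):
        for j in range(n):
            if i == j:
                mat[i, j] = 1000
            elif mode == "forward" and j < i:
                mat[i, j] = mat[j, i]
            else:
                mat[i, j] = match_factor(
                    entries[i].spectrum, entries[j].spectrum, mode, weights, bin_width
                )
    return pd.DataFrame(mat, index=names, columns=names)
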