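"""Pattern-guided identification against Ident-Mix runs.

Each compound in the panel was spiked into exactly two of the k mixtures.
Measuring the k mixture runs therefore gives every compound a binary
presence/absence fingerprint which must match its pair-code *exactly* for a
confirmed identification: present in both code mixtures, absent everywhere
else.  This principle of exclusion is what separates isomers that neither
retention nor spectra can distinguish on their own — of two candidates for
the same peak, only the one whose code matches the peak's across-mixture
occurrence can be right.

The pipeline per library entry:

1. *detect* — in each mixture run, find peaks within the retention window of
   the entry's expectation, above the intensity floor, and (when spectra are
   available) above the reverse-match-factor threshold; the most intense
   qualifying peak supports the call;
2. *match* — compare the presence pattern with the pair-code: ``confirmed``
   on exact match, ``not_found`` when absent everywhere, ``conflict``
   otherwise (extra or missing presences; never silently collapsed into
   not-found);
3. *resolve* — when several entries claim the same peak, reassign it to the
   entry whose code equals the peak's across-mixture occurrence (the
   mannose/glucose swap); entries sharing one code cannot be told apart and
   become ``ambiguous``;
4. *update* — confirmed entries get fresh retention values
   (intensity-weighted mean over the two code mixtures) and the library is
   re-emitted with updated encoded names, ready to identify the samples of
   the same batch.

Because a truly present standard gives a strong signal, the intensity floor
can be set high (default: 5% of the run's base peak), making the binary
readout robust against false positives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .library import CompoundLibrary, LibraryEntry, Spectrum
from .mixdesign import MixDesign, PairCode
from .retention import AlkaneLadder, compute_ri
from .spectra import match_factor

__all__ = [
    "Peak",
    "PeakList",
    "Tolerances",
    "PresencePattern",
    "IdStatus",
    "Identification",
    "Claim",
    "detect_presence",
    "match_pattern",
    "resolve_isomers",
    "identify_batch",
    "write_report",
]


@dataclass(frozen=True)
class Peak:
    """One detected chromatographic peak."""

    rt: float
    intensity: float
    mz: float | None = None
    spectrum: Spectrum | None = None
    ri: float | None = None
    gap_filled: bool = False

    def value(self, mode: str) -> float:
        if mode == "ri":
            if self.ri is None:
                raise ValueError("peak has no retention index; supply a ladder")
            return self.ri
        return self.rt


@dataclass
class PeakList:
    """All peaks of one chromatographic run (one Ident-Mix injection)."""

    label: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def max_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def with_ri(self, ladder: AlkaneLadder) -> "PeakList":
        """Copy with retention indices computed from the run's alkane ladder."""
        if not self.peaks:
            return PeakList(self.label, [])
        ris = compute_ri(np.array([p.rt for p in self.peaks]), ladder)
        return PeakList(
            self.label,
            [replace(p, ri=float(ri)) for p, ri in zip(self.peaks, ris)],
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "rt_seconds": [p.rt for p in self.peaks],
                "intensity": [p.intensity for p in self.peaks],
                "mz": [p.mz if p.mz is not None else "" for p in self.peaks],
                "spectrum_id": ["" for _ in self.peaks],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, label: str) -> "PeakList":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        peaks = [
            Peak(
                rt=float(row["rt_seconds"]),
                intensity=float(row["intensity"]),
                mz=float(row["mz"]) if str(row.get("mz", "")) != "" else None,
            )
            for row in df.to_dict("records")
        ]
        return cls(label, peaks)


@dataclass(frozen=True)
class Tolerances:
    """Matching thresholds for presence detection.

    ``ri_window`` (GC, retention-index units) or ``rt_window`` (LC, seconds)
    bounds the retention deviation; ``spectral_min`` is the minimum reverse
    match factor when both library and peak spectra exist; the intensity
    floor is the larger of ``intensity_min_abs`` and ``intensity_min_frac``
    times the run's base peak — deliberately high, since spiked standards
    always give strong signals.

    ``cluster_tol`` groups peaks *across runs of the same batch* when
    computing a peak's across-mixture occurrence during isomer resolution.
    It is much tighter than the matching window: the window absorbs the
    library-to-batch retention shift, whereas replicate peaks of one
    compound within a batch scatter by well under an RI unit.  Defaults:
    1 RI unit (GC) / 5 s (LC); set it to roughly 3× the observed
    within-batch retention scatter.
    """

    ri_window: float = 10.0
    rt_window: float = 30.0
    spectral_min: int = 650
    intensity_min_frac: float = 0.05
    intensity_min_abs: float = 0.0
    mode: str = "ri"  # "ri" (GC) or "rt" (LC)
    cluster_tol: float | None = None
    include_gap_filled: bool = False

    @property
    def window(self) -> float:
        return self.ri_window if self.mode == "ri" else self.rt_window

    @property
    def occurrence_tol(self) -> float:
        if self.cluster_tol is not None:
            return self.cluster_tol
        return 1.0 if self.mode == "ri" else 5.0


class IdStatus(str, Enum):
    CONFIRMED = "confirmed"
    CONFLICT = "conflict"
    NOT_FOUND = "not_found"
    AMBIGUOUS = "ambiguous"
    UNVALIDATED = "unvalidated"


@dataclass
class PresencePattern:
    """Binary presence readout across the k mixture runs."""

    labels: tuple[str, ...]
    present: frozenset[str]
    #: most intense qualifying peak per present mixture
    support: dict[str, Peak] = field(default_factory=dict)
    support_idx: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.present <= set(self.labels):
            raise ValueError("presence flags outside the run labels")

    def __str__(self) -> str:
        return "".join(lab if lab in self.present else "·" for lab in self.labels)


@dataclass
class Identification:
    """Outcome of identifying one library entry against a batch of runs."""

    entry: LibraryEntry
    status: IdStatus
    observed_pattern: PresencePattern
    matched_peaks: dict[str, Peak] = field(default_factory=dict)
    updated_ri: float | None = None
    updated_rt: float | None = None
    notes: str = ""


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _prepare_runs(
    runs: Mapping[str, PeakList],
    ladders: Mapping[str, AlkaneLadder] | None,
    tol: Tolerances,
) -> dict[str, PeakList]:
    """Attach retention indices where the GC (RI) mode requires them."""
    prepared = {}
    for label, run in runs.items():
        if tol.mode == "ri" and any(p.ri is None for p in run.peaks):
            if ladders is None or label not in ladders:
                raise ValueError(f"run {label!r}: RI mode needs an alkane ladder")
            run = run.with_ri(ladders[label])
        prepared[label] = run
    return prepared


def _expected_value(entry: LibraryEntry, tol: Tolerances) -> float:
    expected = entry.expected_ri if tol.mode == "ri" else entry.expected_rt
    if expected is None:
        raise ValueError(
            f"entry {entry.name!r} has no expected "
            f"{'RI' if tol.mode == 'ri' else 'RT'}"
        )
    return expected


def _qualifying(
    entry: LibraryEntry,
    runs: Mapping[str, PeakList],
    tol: Tolerances,
) -> dict[str, list[int]]:
    """Per run: indices of peaks matching the entry, most intense first."""
    expected = _expected_value(entry, tol)
    out: dict[str, list[int]] = {}
    for label, run in runs.items():
        floor = max(
            tol.intensity_min_abs, tol.intensity_min_frac * run.max_intensity()
        )
        idx = []
        for i, peak in enumerate(run.peaks):
            if peak.gap_filled and not tol.include_gap_filled:
                continue
            if abs(peak.value(tol.mode) - expected) > tol.window:
                continue
            if peak.intensity < floor:
                continue
            if entry.spectrum is not None and peak.spectrum is not None:
                if match_factor(peak.spectrum, entry.spectrum, "reverse") < tol.spectral_min:
                    continue
            idx.append(i)
        idx.sort(key=lambda i: -run.peaks[i].intensity)
        out[label] = idx
    return out


def _pattern_from_qualifying(
    labels: tuple[str, ...],
    runs: Mapping[str, PeakList],
    qualifying: Mapping[str, list[int]],
) -> PresencePattern:
    present = frozenset(lab for lab in labels if qualifying.get(lab))
    support = {lab: runs[lab].peaks[qualifying[lab][0]] for lab in present}
    support_idx = {lab: qualifying[lab][0] for lab in present}
    return PresencePattern(labels=labels, present=present, support=support, support_idx=support_idx)


def detect_presence(
    entry: LibraryEntry,
    runs: Mapping[str, PeakList],
    ladders: Mapping[str, AlkaneLadder] | None = None,
    tolerances: Tolerances = Tolerances(),
) -> PresencePattern:
    """Binary presence of one entry in each mixture run.

    A mixture counts as *present* when some peak lies within the retention
    window of the entry's expectation, clears the intensity floor and, when
    both sides carry spectra, reaches the reverse-match-factor threshold.
    The most intense such peak is recorded as support.
    """
    prepared = _prepare_runs(runs, ladders, tolerances)
    labels = tuple(prepared)
    qualifying = _qualifying(entry, prepared, tolerances)
    return _pattern_from_qualifying(labels, prepared, qualifying)


def match_pattern(observed: PresencePattern, code: PairCode) -> IdStatus:
    """Exclusion matching: exact pattern/code agreement or nothing.

    ``confirmed`` iff the entry is present in both code mixtures and absent
    in every other; ``not_found`` when absent everywhere; ``conflict`` for
    any partial or contaminated pattern (a distinct diagnostic — a presence
    in a non-code mixture means a wrong peak or an interfering compound).
    """
    if not code.mixes <= set(observed.labels):
        raise ValueError(
            f"code {code} uses labels outside the observed runs {observed.labels}"
        )
    if observed.present == code.mixes:
        return IdStatus.CONFIRMED
    if not observed.present:
        return IdStatus.NOT_FOUND
    return IdStatus.CONFLICT


# ---------------------------------------------------------------------------
# Isomer resolution
# ---------------------------------------------------------------------------


@dataclass
class Claim:
    """One entry's candidate peaks while competing for shared signals."""

    entry_name: str
    code: PairCode
    #: per run label: candidate peak indices, most intense first
    qualifying: dict[str, list[int]]


@dataclass
class Resolution:
    """Outcome of :func:`resolve_isomers`."""

    support: dict[str, dict[str, int]]  # entry -> label -> peak index
    #: entry -> label -> surviving candidate peak indices after reassignment
    qualifying: dict[str, dict[str, list[int]]]
    ambiguous: set[str]
    swaps: list[str]


def resolve_isomers(
    claims: list[Claim],
    labels: tuple[str, ...],
    runs: Mapping[str, PeakList],
    occurrence: Callable[[str, int], frozenset[str]],
) -> Resolution:
    """Assign contested peaks to entries using the pair-codes.

    Overlapping retention windows make neighbouring isomers qualify for each
    other's peaks, contaminating their presence patterns.  Every peak claimed
    by more than one entry is therefore inspected with two exclusion rules:

    1. a peak in run L cannot be a compound that was never spiked into L —
       as long as some claimant's code contains L, claimants whose codes do
       not release the peak (this is what lets fully separated coeluters,
       codes {A,C} vs {B,D}, both confirm);
    2. among the remaining claimants, the peak's across-mixture occurrence
       (the set of runs showing a peak at that retention, within the tight
       within-batch clustering tolerance) decides: the claimant whose code
       equals the occurrence keeps the peak, the others fall back to their
       next candidates, and the swap is logged.

    Two claimants with the *same* matching code cannot be separated by the
    pattern and are marked ambiguous.  A contested peak in a run no claimant
    is coded for stays with everyone — an honest conflict is better than a
    guessed swap.
    """
    qual = {c.entry_name: {lab: list(ix) for lab, ix in c.qualifying.items()} for c in claims}
    codes = {c.entry_name: c.code for c in claims}
    ambiguous: set[str] = set()
    swaps: list[str] = []

    contested: dict[tuple[str, int], list[str]] = {}
    for name, q in qual.items():
        for lab, indices in q.items():
            for i in indices:
                contested.setdefault((lab, i), []).append(name)

    def drop(name: str, lab: str, i: int, winner: str, reason: str) -> None:
        qual[name][lab] = [j for j in qual[name][lab] if j != i]
        swaps.append(
            f"run {lab}, peak {i}: assigned to {winner}, "
            f"dropped from {name} ({reason})"
        )

    # claims only ever shrink, so one pass over the contested peaks suffices
    for (lab, i), claimants in sorted(contested.items()):
        if len(claimants) < 2:
            continue
        containing = [n for n in claimants if lab in codes[n].mixes]
        if not containing:
            continue
        for name in claimants:
            if name not in containing:
                drop(name, lab, i, "+".join(containing), "not coded for this mix")
        if len(containing) == 1:
            continue
        occ = occurrence(lab, i)
        matching = [n for n in containing if codes[n].mixes == occ]
        if len(matching) >= 2:
            ambiguous.update(matching)
        elif len(matching) == 1:
            winner = matching[0]
            for name in containing:
                if name != winner:
                    drop(name, lab, i, winner, f"occurrence {sorted(occ)}")
    support = {
        name: {lab: ix[0] for lab, ix in q.items() if ix} for name, q in qual.items()
    }
    return Resolution(support=support, qualifying=qual, ambiguous=ambiguous, swaps=swaps)


# ---------------------------------------------------------------------------
# Batch identification and library update
# ---------------------------------------------------------------------------


def _best_consistent_pair(
    qualifying: Mapping[str, list[int]],
    code_labels: list[str],
    runs: Mapping[str, PeakList],
    tol: Tolerances,
) -> dict[str, int] | None:
    """Most intense pair of mutually consistent peaks across the code mixes.

    The two supporting peaks are replicate injections of the same analyte, so
    their retention must agree within the within-batch clustering tolerance;
    among consistent pairs the one with the largest summed intensity wins.
    Returns label -> peak index, or None when no consistent pair exists.
    """
    lab1, lab2 = code_labels
    best: dict[str, int] | None = None
    best_intensity = -np.inf
    for i in qualifying.get(lab1, []):
        p1 = runs[lab1].peaks[i]
        for j in qualifying.get(lab2, []):
            p2 = runs[lab2].peaks[j]
            if abs(p1.value(tol.mode) - p2.value(tol.mode)) >= tol.occurrence_tol:
                continue
            total = p1.intensity + p2.intensity
            if total > best_intensity:
                best_intensity = total
                best = {lab1: i, lab2: j}
    return best


def _code_for(entry: LibraryEntry, design: MixDesign) -> PairCode | None:
    for key in (entry.name, entry.display_identity, entry.compound_name):
        if key in design.assignment:
            return design.assignment[key]
    if entry.ident_code is not None:
        return PairCode(entry.ident_code)
    return None


def identify_batch(
    library: CompoundLibrary,
    design: MixDesign,
    runs: Mapping[str, PeakList],
    ladders: Mapping[str, AlkaneLadder] | None = None,
    tolerances: Tolerances = Tolerances(),
) -> tuple[list[Identification], CompoundLibrary]:
    """Identify every library entry against one batch of Ident-Mix runs.

    Returns the identifications and a new library in which every confirmed
    entry carries updated retention values — the intensity-weighted mean of
    its supporting peaks across the code's two mixtures — with encoded names
    refreshed accordingly.  Entries without a pair-code are matched by
    retention (and spectrum) alone and flagged ``unvalidated``.
    """
    missing = set(design.labels) - set(runs)
    if missing:
        raise ValueError(f"missing runs for mixture labels {sorted(missing)}")
    for entry in library:
        if entry.ident_code is not None and not entry.ident_code <= set(design.labels):
            raise ValueError(
                f"entry {entry.name!r}: code uses labels outside the design"
            )

    prepared = _prepare_runs(runs, ladders, tolerances)
    labels = tuple(design.labels)

    claims: list[Claim] = []
    qual_by_entry: dict[str, dict[str, list[int]]] = {}
    codes: dict[str, PairCode | None] = {}
    for entry in library:
        q = _qualifying(entry, prepared, tolerances)
        qual_by_entry[entry.name] = q
        code = _code_for(entry, design)
        codes[entry.name] = code
        if code is not None:
            claims.append(Claim(entry_name=entry.name, code=code, qualifying=q))

    def occurrence(lab: str, i: int) -> frozenset[str]:
        ref = prepared[lab].peaks[i].value(tolerances.mode)
        occ = set()
        for other, run in prepared.items():
            for p in run.peaks:
                if p.gap_filled and not tolerances.include_gap_filled:
                    continue
                if abs(p.value(tolerances.mode) - ref) < tolerances.occurrence_tol:
                    occ.add(other)
                    break
        return frozenset(occ)

    resolution = resolve_isomers(claims, labels, prepared, occurrence)

    identifications: list[Identification] = []
    updated_entries: list[LibraryEntry] = []
    for entry in library:
        code = codes[entry.name]
        if code is not None and entry.name in resolution.support:
            sup_idx = resolution.support[entry.name]
            q = {lab: ([i] if (i := sup_idx.get(lab)) is not None else []) for lab in labels}
            pattern = _pattern_from_qualifying(labels, prepared, q)
        else:
            pattern = _pattern_from_qualifying(labels, prepared, qual_by_entry[entry.name])

        notes = []
        if code is None:
            status = IdStatus.UNVALIDATED if pattern.present else IdStatus.NOT_FOUND
            notes.append("no pair-code: matched by retention/spectrum only")
        elif entry.name in resolution.ambiguous:
            status = IdStatus.AMBIGUOUS
            notes.append("another entry with the same pair-code claims this peak")
        else:
            status = match_pattern(pattern, code)
            if status is IdStatus.CONFIRMED:
                # the two code-mix peaks must be replicates of one analyte:
                # their retention must agree within the within-batch tolerance
                pair = _best_consistent_pair(
                    resolution.qualifying[entry.name], sorted(code.mixes),
                    prepared, tolerances,
                )
                if pair is None:
                    status = IdStatus.CONFLICT
                    notes.append(
                        "code-mix peaks disagree in retention beyond the "
                        "within-batch tolerance"
                    )
                else:
                    support = {lab: prepared[lab].peaks[i] for lab, i in pair.items()}
                    pattern = PresencePattern(
                        labels=labels, present=frozenset(pair),
                        support=support, support_idx=pair,
                    )

        ident = Identification(
            entry=entry,
            status=status,
            observed_pattern=pattern,
            matched_peaks=dict(pattern.support),
            notes="; ".join(notes),
        )
        if status is IdStatus.CONFIRMED:
            peaks = [pattern.support[lab] for lab in sorted(code.mixes)]
            weights = np.array([p.intensity for p in peaks], dtype=float)
            if weights.sum() == 0:
                weights = np.ones_like(weights)
            if tolerances.mode == "ri":
                ident.updated_ri = float(
                    np.average([p.ri for p in peaks], weights=weights)
                )
            ident.updated_rt = float(np.average([p.rt for p in peaks], weights=weights))
            updated_entries.append(
                entry.with_retention(ri=ident.updated_ri, rt=ident.updated_rt)
            )
        else:
            updated_entries.append(replace(entry))
        identifications.append(ident)

    updated = CompoundLibrary(
        entries=updated_entries,
        metadata={**library.metadata, "retention_updated": "true"},
    )
    if resolution.swaps:
        updated.metadata["swap_log"] = " | ".join(resolution.swaps)
    return identifications, updated


def write_report(
    identifications: list[Identification],
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> pd.DataFrame:
    """Tabulate identifications; optionally write TSV and JSON versions."""
    rows = []
    for ident in identifications:
        rows.append(
            {
                "name": ident.entry.name,
                "status": ident.status.value,
                "pattern": str(ident.observed_pattern),
                "expected_ri": ident.entry.expected_ri,
                "updated_ri": ident.updated_ri,
                "updated_rt": ident.updated_rt,
                "notes": ident.notes,
            }
        )
    df = pd.DataFrame(rows)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(df.to_dict("records"), indent=2, default=str),
            encoding="utf-8",
        )
    return df
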