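"""Compound library data model, encoded-name codec, and library file IO.

A spectral library here is an ordered collection of standards, each with a
derivatisation state (one metabolite commonly yields several TMS/MeOX
products), expected retention (index and/or time), an optional electron-impact
spectrum, and an optional Ident-Mix pair-code recording which two of the k
pooled mixtures the compound was spiked into.

All of this is carried in a single machine- and human-readable entry name,

    Alanine_(3TMS)_MP_RI:1367_IDENT:B+C

so that every downstream table, chromatogram annotation or msp export keeps
the identification evidence attached to the compound name.  Splitting after
the second underscore recovers the display identity (compound plus
derivatisation product), which is what distinguishes e.g. the two fructose
peaks from one another.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ProductRank",
    "Spectrum",
    "LibraryEntry",
    "CompoundLibrary",
    "NameCodecError",
    "MspFormatError",
    "encode_name",
    "parse_name",
    "read_msp",
    "write_msp",
    "read_library_tsv",
    "write_library_tsv",
]

#: msp convention: base peak of a normalized spectrum has intensity 999.
MSP_BASE_PEAK = 999.0

#: Separator between mixture labels inside the IDENT segment.
IDENT_SEP = "+"


class NameCodecError(ValueError):
    """Raised when an entry cannot be encoded or a name cannot be parsed."""


class MspFormatError(ValueError):
    """Raised on malformed msp input (e.g. a Num Peaks mismatch)."""


class ProductRank(str, Enum):
    """Rank of a derivatisation product of one metabolite.

    MP marks the main (usually most abundant) product; BP a by-product;
    NA is used when the distinction is unknown or meaningless.
    """

    MP = "MP"
    BP = "BP"
    NA = "NA"


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """A centroided mass spectrum as parallel m/z and intensity arrays.

    Peaks are stored sorted by m/z with duplicate m/z values merged
    (intensities summed), so ``mz`` is strictly increasing.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or mz.shape != inten.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size == 0:
            raise ValueError("a spectrum needs at least one peak")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if np.any(np.diff(mz) == 0):
            uniq, inverse = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, inten)
            mz, inten = uniq, summed
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @classmethod
    def from_peaks(cls, peaks: Iterable[tuple[float, float]]) -> "Spectrum":
        arr = np.asarray(list(peaks), dtype=float)
        if arr.size == 0:
            raise ValueError("a spectrum needs at least one peak")
        return cls(arr[:, 0], arr[:, 1])

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return int(self.mz.size)

    def normalized(self, base: float = MSP_BASE_PEAK) -> "Spectrum":
        """Scale intensities so the base peak equals ``base`` (999 for msp)."""
        peak_max = float(self.intensity.max())
        if peak_max == 0:
            return self
        return Spectrum(self.mz, self.intensity * (base / peak_max))

    def isclose(self, other: "Spectrum", rtol: float = 1e-5) -> bool:
        if len(self) != len(other):
            return False
        a, b = self.normalized(), other.normalized()
        return bool(
            np.allclose(a.mz, b.mz, rtol=rtol)
            and np.allclose(a.intensity, b.intensity, rtol=rtol)
        )


# ---------------------------------------------------------------------------
# LibraryEntry and the name codec
# ---------------------------------------------------------------------------


@dataclass
class LibraryEntry:
    """One standard in the library: a single derivatisation product.

    At least one of ``expected_ri`` / ``expected_rt`` must be set: an entry
    without any retention expectation cannot be matched to a chromatogram.
    """

    compound_name: str
    derivatisation_state: str
    product_rank: ProductRank = ProductRank.NA
    expected_ri: float | None = None
    expected_rt: float | None = None
    ident_code: frozenset[str] | None = None
    spectrum: Spectrum | None = None
    compound_class: str | None = None
    #: Verbatim trailing name segments not understood by the codec
    #: (extra identifiers appended by other tools); re-emitted on encode.
    name_extras: tuple[str, ...] = ()
    #: Extra msp headers (Synon:, CAS#, ...) preserved verbatim.
    msp_fields: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "_" in self.compound_name:
            raise NameCodecError(
                f"compound name {self.compound_name!r} contains '_', which "
                "would break the split-after-second-underscore convention"
            )
        if not self.compound_name:
            raise NameCodecError("compound name must be non-empty")
        self.product_rank = ProductRank(self.product_rank)
        if self.expected_ri is None and self.expected_rt is None:
            raise ValueError(
                f"entry {self.compound_name!r}: at least one of expected_ri / "
                "expected_rt must be set"
            )
        if self.ident_code is not None:
            code = frozenset(self.ident_code)
            for label in code:
                if not label or "_" in label or IDENT_SEP in label:
                    raise NameCodecError(f"invalid mixture label {label!r}")
            self.ident_code = code

    @property
    def display_identity(self) -> str:
        """Compound + derivatisation product, e.g. ``Fructose_(MeOX)(5TMS)``."""
        return f"{self.compound_name}_{self.derivatisation_state}"

    @property
    def name(self) -> str:
        return encode_name(self)

    def with_retention(
        self, ri: float | None = None, rt: float | None = None
    ) -> "LibraryEntry":
        """Copy of this entry with updated retention expectation."""
        return replace(
            self,
            expected_ri=ri if ri is not None else self.expected_ri,
            expected_rt=rt if rt is not None else self.expected_rt,
        )


def _round_int(x: float) -> int:
    # round half away from zero, so RI 1366.5 renders as 1367
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def encode_name(entry: LibraryEntry) -> str:
    """Render an entry as its underscore-delimited library name.

    Segment order: compound, derivatisation state, product rank (omitted when
    NA), ``RI:<int>``, ``RT:<int seconds>``, ``IDENT:<labels joined by '+'>``.
    Unset segments are omitted; retention values are rendered as nearest
    integers (they stay float internally).
    """
    parts = [entry.compound_name, entry.derivatisation_state]
    if entry.product_rank is not ProductRank.NA:
        parts.append(entry.product_rank.value)
    if entry.expected_ri is not None:
        parts.append(f"RI:{_round_int(entry.expected_ri)}")
    if entry.expected_rt is not None:
        parts.append(f"RT:{_round_int(entry.expected_rt)}")
    if entry.ident_code:
        parts.append(f"IDENT:{IDENT_SEP.join(sorted(entry.ident_code))}")
    parts.extend(entry.name_extras)
    return "_".join(parts)


def parse_name(name: str, **extra_fields) -> LibraryEntry:
    """Parse an encoded library name back into a :class:`LibraryEntry`.

    The display identity is always the first two underscore-separated fields;
    ``RI:`` / ``RT:`` / ``IDENT:`` segments are recognised by prefix in any
    position after the second field, so names extended with other tools'
    identifiers still parse (unknown segments are kept in ``name_extras``).
    """
    fields_ = name.split("_")
    if len(fields_) < 3:
        raise NameCodecError(
            f"{name!r}: expected at least two underscores "
            "(compound_derivatisation_<segments>)"
        )
    compound, deriv = fields_[0], fields_[1]
    rank = ProductRank.NA
    ri: float | None = None
    rt: float | None = None
    code: frozenset[str] | None = None
    extras: list[str] = []
    for seg in fields_[2:]:
        if seg in (ProductRank.MP.value, ProductRank.BP.value):
            rank = ProductRank(seg)
        elif seg.startswith("RI:"):
            try:
                ri = float(int(seg[3:]))
            except ValueError:
                raise NameCodecError(
                    f"{name!r}: malformed RI segment {seg!r} (not an integer)"
                ) from None
        elif seg.startswith("RT:"):
            try:
                rt = float(int(seg[3:]))
            except ValueError:
                raise NameCodecError(
                    f"{name!r}: malformed RT segment {seg!r} (not an integer)"
                ) from None
        elif seg.startswith("IDENT:"):
            code = frozenset(seg[len("IDENT:"):].split(IDENT_SEP))
        else:
            extras.append(seg)
    return LibraryEntry(
        compound_name=compound,
        derivatisation_state=deriv,
        product_rank=rank,
        expected_ri=ri,
        expected_rt=rt,
        ident_code=code,
        name_extras=tuple(extras),
        **extra_fields,
    )


# ---------------------------------------------------------------------------
# CompoundLibrary
# ---------------------------------------------------------------------------


@dataclass
class CompoundLibrary:
    """Ordered collection of library entries with free-form provenance.

    Encoded names must be unique; the same compound may appear several times
    under different derivatisation states (most metabolites give two peaks).
    """

    entries: list[LibraryEntry] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_unique()

    def _check_unique(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            n = e.name
            if n in seen:
                raise ValueError(f"duplicate encoded name in library: {n!r}")
            seen.add(n)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LibraryEntry]:
        return iter(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def get(self, name: str) -> LibraryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def add(self, entry: LibraryEntry) -> None:
        if entry.name in set(self.names()):
            raise ValueError(f"duplicate encoded name: {entry.name!r}")
        self.entries.append(entry)


# ---------------------------------------------------------------------------
# msp IO (NIST text flavor)
# ---------------------------------------------------------------------------

_PEAK_PAIR = re.compile(r"(\d+\.?\d*(?:[eE][+-]?\d+)?)\s+(\d+\.?\d*(?:[eE][+-]?\d+)?)")
_HEADER = re.compile(r"^([^:]+):\s*(.*)$")


def read_msp(path: str | Path) -> CompoundLibrary:
    """Read a NIST-text msp file into a :class:`CompoundLibrary`.

    Entries are blocks starting with ``Name:`` and ending after ``Num Peaks:``
    plus that many ``mz intensity`` pairs (``;``-terminated pairs and several
    pairs per line are both accepted).  Headers other than ``Name`` and
    ``Num Peaks`` (``Comment:``, ``Synon:``, ``CAS#:`` ...) are preserved
    verbatim on the entry.  The ``Name:`` field must follow the encoded-name
    convention so retention and pair-code information survive the round trip.
    """
    text = Path(path).read_text(encoding="utf-8")
    entries: list[LibraryEntry] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _HEADER.match(line)
        if not m or m.group(1).strip().lower() != "name":
            raise MspFormatError(f"expected 'Name:' header, got {line!r}")
        name = m.group(2).strip()
        headers: dict[str, str] = {}
        num_peaks: int | None = None
        i += 1
        while i < len(lines):
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            m = _HEADER.match(line)
            if m is None:
                break
            key, value = m.group(1).strip(), m.group(2).strip()
            i += 1
            if key.lower() == "num peaks":
                num_peaks = int(value)
                break
            headers[key] = value
        if num_peaks is None:
            raise MspFormatError(f"entry {name!r}: missing 'Num Peaks:' header")
        peaks: list[tuple[float, float]] = []
        while i < len(lines) and len(peaks) < num_peaks:
            line = lines[i].strip()
            if not line:
                break
            if _HEADER.match(line) and not _PEAK_PAIR.match(line):
                break
            for pm in _PEAK_PAIR.finditer(line):
                peaks.append((float(pm.group(1)), float(pm.group(2))))
            i += 1
        if len(peaks) != num_peaks:
            raise MspFormatError(
                f"entry {name!r}: Num Peaks is {num_peaks} but "
                f"{len(peaks)} peaks are listed"
            )
        entry = parse_name(
            name,
            spectrum=Spectrum.from_peaks(peaks),
            msp_fields=headers,
            compound_class=headers.get("Class") or None,
        )
        entries.append(entry)
    return CompoundLibrary(entries=entries)


def write_msp(library: CompoundLibrary, path: str | Path) -> None:
    """Write a library to msp; inverse of :func:`read_msp` up to float format."""
    out: list[str] = []
    for e in library:
        if e.spectrum is None:
            raise ValueError(f"entry {e.name!r} has no spectrum; cannot write msp")
        out.append(f"Name: {e.name}")
        headers = dict(e.msp_fields)
        if e.compound_class and "Class" not in headers:
            headers["Class"] = e.compound_class
        for key, value in headers.items():
            out.append(f"{key}: {value}")
        spec = e.spectrum.normalized()
        out.append(f"Num Peaks: {len(spec)}")
        pairs = [f"{mz:g} {inten:.6g};" for mz, inten in spec.peaks]
        for start in range(0, len(pairs), 5):
            out.append(" ".join(pairs[start : start + 5]))
        out.append("")
    Path(path).write_text("\n".join(out), encoding="utf-8")


# ---------------------------------------------------------------------------
# library TSV IO
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["name", "derivatisation", "rank", "ri", "rt", "ident_code", "class"]


def write_library_tsv(library: CompoundLibrary, path: str | Path) -> None:
    rows = []
    for e in library:
        rows.append(
            {
                "name": e.compound_name,
                "derivatisation": e.derivatisation_state,
                "rank": e.product_rank.value,
                "ri": e.expected_ri,
                "rt": e.expected_rt,
                "ident_code": IDENT_SEP.join(sorted(e.ident_code))
                if e.ident_code
                else "",
                "class": e.compound_class or "",
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library_tsv(path: str | Path) -> CompoundLibrary:
    df = pd.read_csv(path, sep="\t", dtype={"name": str}, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"library TSV missing columns: {missing}")
    entries = []
    for row in df.to_dict("records"):
        ri = float(row["ri"]) if str(row["ri"]) != "" else None
        rt = float(row["rt"]) if str(row["rt"]) != "" else None
        code = (
            frozenset(str(row["ident_code"]).split(IDENT_SEP))
            if str(row["ident_code"])
            else None
        )
        entries.append(
            LibraryEntry(
                compound_name=str(row["name"]),
                derivatisation_state=str(row["derivatisation"]),
                product_rank=ProductRank(str(row["rank"]) or "NA"),
                expected_ri=ri,
                expected_rt=rt,
                ident_code=code,
                compound_class=str(row["class"]) or None,
            )
        )
    return CompoundLibrary(entries=entries)
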