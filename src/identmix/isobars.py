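"""Isobar and isomer statistics over metabolite-database exports.

Most metabolites in the common databases share their molecular mass with at
least one other compound, so mass alone — even exact mass — rarely pins down
an identity.  These routines quantify that ambiguity on a flat table export
(one row per compound with id, name, formula, mass, status, pathways):

* declarative pre-filters with an audit trail (drop entries without formula
  or reaction, inorganics, masses above a cutoff, lipids by the
  two-numbers-and-a-colon name rule, status/pathway whitelists);
* per-compound isobar group sizes at exact or unit (integer-rounded) mass
  resolution;
* the cumulative curve "percentage of compounds with at least t isobars";
* per-5-Da-window maxima showing where along the mass axis the ambiguity
  concentrates.

Working on exported tables keeps the analysis reproducible against a stated
database snapshot rather than a live API.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "FilterRules",
    "filter_records",
    "is_lipid_name",
    "isobar_group_sizes",
    "cumulative_isobar_curve",
    "window_density",
    "read_records_tsv",
]

#: Lipid shorthand such as "PC(16:0/18:1)": two numbers separated by a colon
#: (carbon count : double bonds).  Purely textual; odd names like
#: "Vitamin D3 1:1 complex" are documented false positives.
_LIPID_RE = re.compile(r"\d:\d")

_CARBON_RE = re.compile(r"C(?![a-z])")


@dataclass(frozen=True)
class CompoundRecord:
    """One database row: a compound with mass and minimal annotation."""

    id: str
    name: str
    formula: str | None = None
    mass: float | None = None
    status: str | None = None
    pathways: frozenset[str] = field(default_factory=frozenset)
    has_reaction: bool | None = None

    def __post_init__(self) -> None:
        if self.mass is not None and not self.mass > 0:
            raise ValueError(f"record {self.id!r}: mass must be positive")
        object.__setattr__(self, "pathways", frozenset(self.pathways))


def is_lipid_name(name: str) -> bool:
    """True iff the name contains two numbers separated by a colon."""
    return bool(_LIPID_RE.search(name))


def _is_organic(formula: str | None) -> bool:
    # carbon present in the formula; "C" not followed by a lowercase letter
    # (so Cl, Ca, Co, Cu do not count)
    return bool(formula) and bool(_CARBON_RE.search(formula))


@dataclass
class FilterRules:
    """Declarative record filters, applied in field-declaration order.

    A ``None`` value disables the rule.  The order matters only for the
    audit trail: each rule's removal count refers to records that survived
    all earlier rules.
    """

    require_formula: bool = False
    require_reaction: bool = False
    organic_only: bool = False
    max_mass: float | None = None
    lipid_exclusion: bool = False
    status_whitelist: Sequence[str] | None = None
    pathway_whitelist: Sequence[str] | None = None


def filter_records(
    records: Iterable[CompoundRecord],
    rules: FilterRules,
) -> tuple[list[CompoundRecord], dict[str, int]]:
    """Apply the rules in declared order; return survivors and removal counts.

    The audit dict maps rule name to the number of records it removed; the
    counts plus the survivor count always sum to the input count.
    """
    remaining = list(records)
    audit: dict[str, int] = {}

    def apply(rule_name: str, keep) -> None:
        nonlocal remaining
        kept = [r for r in remaining if keep(r)]
        audit[rule_name] = len(remaining) - len(kept)
        remaining = kept

    if rules.require_formula:
        apply("require_formula", lambda r: bool(r.formula))
    if rules.require_reaction:
        apply("require_reaction", lambda r: bool(r.has_reaction))
    if rules.organic_only:
        apply("organic_only", lambda r: _is_organic(r.formula))
    if rules.max_mass is not None:
        apply("max_mass", lambda r: r.mass is not None and r.mass <= rules.max_mass)
    if rules.lipid_exclusion:
        apply("lipid_exclusion", lambda r: not is_lipid_name(r.name))
    if rules.status_whitelist is not None:
        allowed = {s.lower() for s in rules.status_whitelist}
        known = {r.status.lower() for r in remaining if r.status}
        for status in sorted(allowed - known):
            warnings.warn(
                f"status whitelist entry {status!r} matches no record",
                stacklevel=2,
            )
        apply(
            "status_whitelist",
            lambda r: r.status is not None and r.status.lower() in allowed,
        )
    if rules.pathway_whitelist is not None:
        allowed_pw = set(rules.pathway_whitelist)
        apply("pathway_whitelist", lambda r: bool(r.pathways & allowed_pw))
    return remaining, audit


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def isobar_group_sizes(
    records: Sequence[CompoundRecord],
    resolution: str = "exact",
) -> pd.Series:
    """Per-compound count of records sharing its mass (itself included).

    ``exact`` groups by mass equality after rounding to 4 decimals (database
    exports store fixed-precision values); ``unit`` rounds to the nearest
    integer first (half away from zero), emulating unit-resolution MS.
    """
    missing = [r.id for r in records if r.mass is None]
    if missing:
        raise ValueError(f"records without mass: {missing}")
    masses = np.array([r.mass for r in records], dtype=float)
    if resolution == "exact":
        keys = np.round(masses, 4)
    elif resolution == "unit":
        keys = _round_half_away(masses)
    else:
        raise ValueError(f"unknown resolution {resolution!r}")
    key_series = pd.Series(keys)
    sizes = key_series.map(key_series.value_counts())
    sizes.index = pd.Index([r.id for r in records], name="id")
    sizes.name = f"group_size_{resolution}"
    return sizes.astype(int)


def cumulative_isobar_curve(group_sizes: pd.Series) -> pd.DataFrame:
    """Cumulative percentage of compounds with at least t isobaric partners.

    For each threshold t >= 0 the curve gives the percentage of compounds
    whose group contains at least t *other* records; t = 0 is 100% by
    definition and the curve is non-increasing.
    """
    sizes = np.asarray(group_sizes, dtype=int)
    if sizes.size == 0:
        raise ValueError("no group sizes given")
    partners = sizes - 1
    thresholds = np.arange(0, partners.max() + 2)
    pct = [100.0 * np.mean(partners >= t) for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "cumulative_percent": pct})


def window_density(
    records: Sequence[CompoundRecord],
    window_width: float = 5.0,
) -> pd.DataFrame:
    """Max exact-mass isobar group size per mass window of ``window_width`` Da.

    Windows are half-open [w, w + width) starting at 0, so a mass exactly on
    a boundary belongs to the upper window.  Group sizes are computed over
    the full record set; each window reports the largest group whose members
    fall inside it.  Only populated windows are listed.
    """
    sizes = isobar_group_sizes(records, resolution="exact").to_numpy()
    masses = np.array([r.mass for r in records], dtype=float)
    starts = np.floor(masses / window_width) * window_width
    df = pd.DataFrame({"window_start": starts, "size": sizes})
    out = (
        df.groupby("window_start", sort=True)["size"]
        .max()
        .rename("max_count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Flat-table IO
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {
    "id": "id",
    "name": "name",
    "formula": "formula",
    "mass": "mass",
    "status": "status",
    "pathways": "pathways",
    "has_reaction": "has_reaction",
}


def read_records_tsv(
    path: str | Path,
    schema: dict[str, str] | None = None,
    pathway_sep: str = ";",
) -> list[CompoundRecord]:
    """Read a database export; ``schema`` maps record fields to column names.

    Absent columns simply leave the corresponding field unset, so minimal
    exports (id, name, mass) work out of the box.
    """
    colmap = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def col(fieldname: str, row: dict) -> str | None:
        c = colmap[fieldname]
        v = row.get(c, "")
        return v if v != "" else None

    records = []
    for row in df.to_dict("records"):
        pathways = col("pathways", row)
        reaction = col("has_reaction", row)
        mass = col("mass", row)
        records.append(
            CompoundRecord(
                id=col("id", row) or "",
                name=col("name", row) or "",
                formula=col("formula", row),
                mass=float(mass) if mass is not None else None,
                status=col("status", row),
                pathways=frozenset(pathways.split(pathway_sep)) if pathways else frozenset(),
                has_reaction=reaction.lower() in ("1", "true", "yes")
                if reaction is not None
                else None,
            )
        )
    return records
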