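"""Combinatorial design of Ident-Mixes.

Each compound is spiked into exactly two of k pooled standard mixtures, so
its presence/absence fingerprint across the k runs is an unordered pair of
mixture labels — its *pair-code*.  k mixtures yield C(k,2) codes, so up to
six chemically similar (near-coeluting) compounds can be told apart with
k = 4, ten with k = 5, fifteen with k = 6, while each individual mixture
holds only a 2/k fraction of the panel.

Constraints between similar compounds are expressed as a typed graph:

* DISTINCT    — the two compounds must carry different codes;
* DISJOINT    — codes share no mixture, so the pair is never co-injected
                (e.g. fructose {B,C} vs mannose {A,D});
* OVERLAP_ONE — codes share exactly one mixture, so one run deliberately
                contains both and shows whether they still separate
                (e.g. mannose {A,D} vs galactose {A,C}).

DISJOINT and OVERLAP_ONE each imply DISTINCT.  Code assignment is a seeded
backtracking search, most-constrained compound first, candidate codes ordered
by current mixture load so the design stays balanced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from pathlib import Path
from string import ascii_uppercase

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ConstraintType",
    "PairCode",
    "ConstraintGraph",
    "MixDesign",
    "DesignError",
    "InfeasibleDesignError",
    "ValidationReport",
    "code_capacity",
    "per_mix_fraction",
    "assign_codes",
    "validate_design",
]


class DesignError(ValueError):
    """Invalid design input."""


class InfeasibleDesignError(DesignError):
    """No code assignment can satisfy the constraints."""


class ConstraintType(str, Enum):
    DISTINCT = "DISTINCT"
    DISJOINT = "DISJOINT"
    OVERLAP_ONE = "OVERLAP_ONE"


@dataclass(frozen=True)
class PairCode:
    """Unordered pair of distinct mixture labels."""

    mixes: frozenset[str]

    def __post_init__(self) -> None:
        mixes = frozenset(self.mixes)
        if len(mixes) != 2:
            raise DesignError(f"a pair-code needs exactly 2 labels, got {sorted(mixes)}")
        object.__setattr__(self, "mixes", mixes)

    @classmethod
    def of(cls, a: str, b: str) -> "PairCode":
        return cls(frozenset((a, b)))

    @classmethod
    def from_string(cls, text: str, sep: str = "+") -> "PairCode":
        return cls(frozenset(text.split(sep)))

    def __str__(self) -> str:
        return "+".join(sorted(self.mixes))

    def __contains__(self, label: str) -> bool:
        return label in self.mixes

    def __iter__(self):
        return iter(sorted(self.mixes))

    def shares(self, other: "PairCode") -> int:
        return len(self.mixes & other.mixes)


def _satisfies(a: PairCode, b: PairCode, ctype: ConstraintType) -> bool:
    if ctype is ConstraintType.DISTINCT:
        return a != b
    if ctype is ConstraintType.DISJOINT:
        return a.shares(b) == 0
    return a.shares(b) == 1  # OVERLAP_ONE


class ConstraintGraph:
    """Typed pairwise constraints between compounds (thin networkx wrapper)."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_compound(self, compound: str) -> None:
        self.graph.add_node(compound)

    def add(self, a: str, b: str, ctype: ConstraintType | str) -> None:
        ctype = ConstraintType(ctype)
        if a == b:
            raise DesignError(f"self-constraint on {a!r}")
        if self.graph.has_edge(a, b):
            existing = self.graph.edges[a, b]["ctype"]
            # DISJOINT/OVERLAP_ONE imply DISTINCT: upgrading is fine,
            # mixing the two strict types is contradictory
            if ConstraintType.DISTINCT not in (existing, ctype) and existing != ctype:
                raise DesignError(
                    f"conflicting constraint types for pair ({a!r}, {b!r}): "
                    f"{existing.value} vs {ctype.value}"
                )
            if existing is not ConstraintType.DISTINCT:
                ctype = existing
        self.graph.add_edge(a, b, ctype=ctype)

    def add_distinct(self, *compounds: str) -> None:
        """Mark a group of similar compounds as pairwise DISTINCT."""
        for a, b in combinations(compounds, 2):
            self.add(a, b, ConstraintType.DISTINCT)

    def constraints(self) -> list[tuple[str, str, ConstraintType]]:
        return [(a, b, d["ctype"]) for a, b, d in self.graph.edges(data=True)]

    def neighbors(self, compound: str) -> list[tuple[str, ConstraintType]]:
        if compound not in self.graph:
            return []
        return [
            (other, self.graph.edges[compound, other]["ctype"])
            for other in self.graph.neighbors(compound)
        ]

    def degree(self, compound: str) -> int:
        return self.graph.degree(compound) if compound in self.graph else 0

    def distinct_cliques(self) -> list[list[str]]:
        """Maximal cliques of the DISTINCT-connected subgraph.

        Every typed edge implies DISTINCT, so all edges count.
        """
        return [sorted(c) for c in nx.find_cliques(self.graph)] if self.graph.number_of_edges() else []


def default_labels(k: int) -> list[str]:
    if k > len(ascii_uppercase):
        raise DesignError(f"no default labels for k={k}; pass labels explicitly")
    return list(ascii_uppercase[:k])


@dataclass
class MixDesign:
    """k mixture labels plus the compound → pair-code assignment."""

    labels: list[str]
    assignment: dict[str, PairCode] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels) or len(self.labels) < 2:
            raise DesignError("labels must be >= 2 distinct mixture names")
        label_set = set(self.labels)
        for compound, code in self.assignment.items():
            if not code.mixes <= label_set:
                raise DesignError(
                    f"{compound!r}: code {code} uses labels outside {sorted(label_set)}"
                )

    @property
    def k(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.assignment)

    def code_of(self, compound: str) -> PairCode:
        return self.assignment[compound]

    def compounds_in(self, label: str) -> list[str]:
        return [c for c, code in self.assignment.items() if label in code]

    def loads(self) -> dict[str, int]:
        """Number of compounds spiked into each mixture."""
        counts = {lab: 0 for lab in self.labels}
        for code in self.assignment.values():
            for lab in code.mixes:
                counts[lab] += 1
        return counts

    # ---- serialization ----

    def to_json(self, path: str | Path, constraints: ConstraintGraph | None = None) -> None:
        payload = {
            "k": self.k,
            "labels": self.labels,
            "assignment": {c: sorted(code.mixes) for c, code in self.assignment.items()},
        }
        if constraints is not None:
            payload["constraints"] = [
                [a, b, t.value] for a, b, t in constraints.constraints()
            ]
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> tuple["MixDesign", ConstraintGraph]:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        design = cls(
            labels=list(payload["labels"]),
            assignment={
                c: PairCode(frozenset(pair))
                for c, pair in payload["assignment"].items()
            },
        )
        cg = ConstraintGraph()
        for a, b, t in payload.get("constraints", []):
            cg.add(a, b, ConstraintType(t))
        return design, cg

    def to_table(
        self,
        expected_ri: dict[str, float] | None = None,
        compound_class: dict[str, str] | None = None,
    ) -> pd.DataFrame:
        """Occurrence table: one row per compound, one column per mixture."""
        rows = []
        for compound, code in self.assignment.items():
            row = {
                "class": (compound_class or {}).get(compound, ""),
                "compound": compound,
                "expected_ri": (expected_ri or {}).get(compound, np.nan),
            }
            for lab in self.labels:
                row[lab] = lab if lab in code else ""
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def code_capacity(k: int) -> int:
    """Number of distinct pair-codes with k mixtures: C(k,2) = k(k-1)/2."""
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool) or k < 2:
        raise DesignError(f"need an integer mixture count k >= 2, got {k!r}")
    return k * (k - 1) // 2


def per_mix_fraction(design: MixDesign) -> tuple[dict[str, float], float]:
    """Fraction of the compound panel present in each mixture.

    Returns (per-mix actual fractions, theoretical fraction 2/k).  With every
    compound in exactly two mixtures, a balanced design puts 2/k of the panel
    in each run — a 50% complexity reduction at k = 4.
    """
    n = len(design)
    if n == 0:
        raise DesignError("empty design")
    actual = {lab: load / n for lab, load in design.loads().items()}
    return actual, 2.0 / design.k


def assign_codes(
    compounds: list[str],
    constraints: ConstraintGraph | None = None,
    k: int = 4,
    seed: int = 0,
    labels: list[str] | None = None,
    balance_slack: int = 2,
) -> MixDesign:
    """Assign a pair-code to every compound, honouring the constraint graph.

    Backtracking search: compounds ordered most-constrained-first (constraint
    degree, then seeded random tie-break); at each step candidate codes are
    tried in order of the current load of their two mixtures so the final
    per-mix loads stay within ``balance_slack`` of each other.  Deterministic
    for a given seed.
    """
    if len(set(compounds)) != len(compounds):
        raise DesignError("duplicate compound ids")
    labels = list(labels) if labels is not None else default_labels(k)
    if len(labels) != k:
        raise DesignError(f"got {len(labels)} labels for k={k}")
    capacity = code_capacity(k)
    cg = constraints or ConstraintGraph()

    for clique in cg.distinct_cliques():
        members = [c for c in clique if c in set(compounds)]
        if len(members) > capacity:
            raise InfeasibleDesignError(
                f"{len(members)} mutually similar compounds {members} exceed the "
                f"{capacity} distinct pair-codes available with k={k} mixtures"
            )

    rng = np.random.default_rng(seed)
    order = sorted(
        compounds,
        key=lambda c: (-cg.degree(c), rng.random()),
    )
    all_codes = [PairCode.of(a, b) for a, b in combinations(labels, 2)]
    load = {lab: 0 for lab in labels}
    assignment: dict[str, PairCode] = {}

    def candidates(compound: str) -> list[PairCode]:
        ok = []
        for code in all_codes:
            feasible = True
            for other, ctype in cg.neighbors(compound):
                if other in assignment and not _satisfies(code, assignment[other], ctype):
                    feasible = False
                    break
            if feasible:
                ok.append(code)
        jitter = {code: rng.random() for code in ok}
        ok.sort(key=lambda c: (sum(load[lab] for lab in c.mixes), jitter[c]))
        return ok

    # depth-first search with an explicit stack (panels can be large)
    def backtrack_all() -> bool:
        cand_iters: list = [None] * len(order)
        idx = 0
        while True:
            if idx == len(order):
                return True
            if cand_iters[idx] is None:
                cand_iters[idx] = iter(candidates(order[idx]))
            code = next(cand_iters[idx], None)
            if code is not None:
                assignment[order[idx]] = code
                for lab in code.mixes:
                    load[lab] += 1
                idx += 1
            else:
                cand_iters[idx] = None
                idx -= 1
                if idx < 0:
                    return False
                undone = assignment.pop(order[idx])
                for lab in undone.mixes:
                    load[lab] -= 1

    if not backtrack_all():
        raise InfeasibleDesignError(
            "no pair-code assignment satisfies the constraint graph "
            f"(k={k}, {len(compounds)} compounds, "
            f"{len(cg.constraints())} constraints)"
        )
    design = MixDesign(labels=labels, assignment={c: assignment[c] for c in compounds})
    loads = design.loads()
    if compounds and max(loads.values()) - min(loads.values()) > balance_slack:
        # constraint satisfaction wins over balance; report, don't fail
        pass
    return design


@dataclass
class ValidationReport:
    """Outcome of checking a design against its constraint graph."""

    violations: list[str]
    bad_codes: list[str]
    loads: dict[str, int]

    @property
    def valid(self) -> bool:
        return not self.violations and not self.bad_codes

    def __str__(self) -> str:
        if self.valid:
            return f"design valid; per-mix loads {self.loads}"
        lines = [f"- {v}" for v in self.violations]
        lines += [f"- malformed code for {c}" for c in self.bad_codes]
        return "design INVALID:\n" + "\n".join(lines)


def validate_design(design: MixDesign, constraints: ConstraintGraph) -> ValidationReport:
    """Report every violated constraint and any malformed assignment."""
    violations: list[str] = []
    bad: list[str] = []
    label_set = set(design.labels)
    for compound, code in design.assignment.items():
        if len(code.mixes) != 2 or not code.mixes <= label_set:
            bad.append(compound)
    for a, b, ctype in constraints.constraints():
        if a not in design.assignment or b not in design.assignment:
            violations.append(f"{ctype.value} {a}/{b}: compound missing from design")
            continue
        ca, cb = design.assignment[a], design.assignment[b]
        if not _satisfies(ca, cb, ctype):
            violations.append(
                f"{ctype.value} violated for {a} ({ca}) vs {b} ({cb}): "
                f"codes share {ca.shares(cb)} mixture(s)"
            )
    return ValidationReport(violations=violations, bad_codes=bad, loads=design.loads())
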