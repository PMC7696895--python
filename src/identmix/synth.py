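"""Synthetic ground truth: compound panels, designs, ladders and peak lists.

The generator stands in for a wet-lab batch of Ident-Mix injections: a panel
of standards with known retention indices (including clusters of isomers
whose RIs sit within a narrow spread, like the hexoses), a pair-code design
honouring DISTINCT constraints within each cluster, and one peak list per
mixture run in which each compound appears in exactly its two code mixtures
with Gaussian RI noise, optional per-run dropout, and uniformly scattered
decoy peaks.  Peak retention times are produced through the same monotone
alkane-ladder RI→RT map the identification pipeline inverts, so a zero-noise
batch is recovered exactly.

Defaults mirror a routine GC–MS validation batch: a 105-compound panel over
four mixtures, C10–C36 alkane anchors, sub-unit within-batch retention-index
noise, and log-normal peak intensities.  Everything is deterministic given
the seed.

The bundled ``table2`` preset reproduces the published excerpt of the
Ident-Mix composition — 13 sugars and sugar derivatives with their expected
RIs and mixture occurrences — and is the worked example used throughout the
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .library import CompoundLibrary, LibraryEntry, ProductRank, Spectrum
from .mixdesign import (
    ConstraintGraph,
    DesignError,
    MixDesign,
    PairCode,
    assign_codes,
    code_capacity,
)
from .pattern_id import Peak, PeakList
from .retention import AlkaneLadder, rt_for_ri

__all__ = [
    "SimulationConfig",
    "default_ladder",
    "generate_truth",
    "generate_peaklists",
    "table2_library",
    "table2_design",
]

#: Alkane markers used as RI anchors (C18 replaced by C17 so the anchor does
#: not coelute with compounds around RI 1800).
LADDER_CARBONS = (10, 12, 15, 17, 19, 22, 28, 32, 36)


def default_ladder() -> AlkaneLadder:
    """A plausible temperature-programmed GC ladder over C10–C36.

    The RT map is mildly convex in carbon number (early alkanes elute faster
    per carbon than late ones under a multi-ramp program) and spans ~2–29 min.
    """
    c = np.array(LADDER_CARBONS, dtype=float)
    rt = 120.0 + 52.0 * (c - 10.0) + 0.4 * (c - 10.0) ** 2
    return AlkaneLadder(c, rt)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated Ident-Mix batch.

    ``n_clusters`` isomer clusters of 2–4 compounds each receive pairwise
    DISTINCT constraints and a ``cluster_spread`` RI span (the four hexoses
    span 24 RI units); remaining compounds get unconstrained uniform RIs.
    ``noise_sd`` is the within-batch RI reproducibility, ``dropout_rate`` the
    per-compound-per-mixture probability of a missing peak, ``decoy_rate``
    the expected number of decoy peaks per run per panel compound.
    """

    n_compounds: int = 105
    k: int = 4
    ri_range: tuple[float, float] = (1000.0, 3600.0)
    n_clusters: int = 8
    cluster_spread: float = 25.0
    #: any two compounds within this RI distance count as "similar" and are
    #: constrained to distinct pair-codes (matches the identification window)
    conflict_window: float = 10.0
    noise_sd: float = 0.25
    dropout_rate: float = 0.0
    decoy_rate: float = 0.0
    #: spiked amounts are tuned so every standard gives a clearly detectable
    #: peak, so panel intensities spread only ~2–3-fold (sigma 0.4); decoy
    #: (matrix) peaks are weaker and more variable, see generate_peaklists
    intensity_lognormal: tuple[float, float] = (11.0, 0.4)
    seed: int = 0
    #: keep decoys at least 2·noise_sd away from every true RI, so dropout
    #: effects can be studied without accidental decoy rescues
    clean_decoys: bool = False
    #: attach sparse random spectra to compounds and their peaks
    with_spectra: bool = False
    preset: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.noise_sd < 0 or self.decoy_rate < 0:
            raise ValueError("noise_sd and decoy_rate must be >= 0")


# ---------------------------------------------------------------------------
# The published 13-compound excerpt (pentoses, hexoses, sugar derivatives)
# ---------------------------------------------------------------------------

#: (class, compound, derivatisation, expected RI, code).  Fructose's second
#: derivatisation product elutes at RI 1872 with near-equal intensity; the
#: main-product entry at 1862 represents it here.
_TABLE2_ROWS = [
    ("Pentoses", "Xylose", "(MeOX)(4TMS)", 1651.0, ("A", "C")),
    ("Pentoses", "Ribose", "(MeOX)(4TMS)", 1672.0, ("B", "D")),
    ("Pentoses", "Arabitol", "(5TMS)", 1711.0, ("C", "D")),
    ("Pentoses", "Ribitol", "(5TMS)", 1716.0, ("A", "B")),
    ("Hexoses", "Fructose", "(MeOX)(5TMS)", 1862.0, ("B", "C")),
    ("Hexoses", "Mannose", "(MeOX)(5TMS)", 1876.0, ("A", "D")),
    ("Hexoses", "Galactose", "(MeOX)(5TMS)", 1880.0, ("A", "C")),
    ("Hexoses", "Glucose", "(MeOX)(5TMS)", 1886.0, ("B", "D")),
    ("Sugar Derivatives", "Sorbitol", "(6TMS)", 1926.0, ("A", "D")),
    ("Sugar Derivatives", "Glucuronic acid", "(MeOX)(5TMS)", 1927.0, ("A", "C")),
    ("Sugar Derivatives", "Glucosamine", "(MeOX)(5TMS)", 1932.0, ("A", "B")),
    ("Sugar Derivatives", "Galacturonic acid", "(MeOX)(5TMS)", 1935.0, ("B", "D")),
    ("Sugar Derivatives", "Gluconic acid", "(MeOX)(6TMS)", 1996.0, ("B", "C")),
]

FRUCTOSE_SECOND_PEAK_RI = 1872.0


def table2_library() -> CompoundLibrary:
    """The 13-entry sugar panel with printed RIs and mixture occurrences."""
    entries = [
        LibraryEntry(
            compound_name=name,
            derivatisation_state=deriv,
            product_rank=ProductRank.MP,
            expected_ri=ri,
            ident_code=frozenset(code),
            compound_class=cls,
        )
        for cls, name, deriv, ri, code in _TABLE2_ROWS
    ]
    return CompoundLibrary(
        entries=entries,
        metadata={
            "preset": "table2",
            "fructose_second_peak_ri": str(FRUCTOSE_SECOND_PEAK_RI),
        },
    )


def table2_design() -> MixDesign:
    lib = table2_library()
    return MixDesign(
        labels=list("ABCD"),
        assignment={e.name: PairCode(e.ident_code) for e in lib},
    )


# ---------------------------------------------------------------------------
# Random panels
# ---------------------------------------------------------------------------


def _random_spectrum(rng: np.random.Generator) -> Spectrum:
    n = int(rng.integers(5, 20))
    mz = rng.choice(np.arange(60, 600), size=n, replace=False).astype(float)
    intensity = rng.lognormal(4.0, 1.0, size=n)
    return Spectrum(mz, intensity)


def generate_truth(
    config: SimulationConfig,
) -> tuple[CompoundLibrary, MixDesign]:
    """Ground-truth panel and pair-code design for the given conditions.

    Isomer-cluster members receive pairwise DISTINCT constraints and are
    assigned pattern-distinct codes through the constrained design search;
    everything is deterministic for a given seed.
    """
    if config.preset == "table2":
        return table2_library(), table2_design()
    if config.n_compounds <= 0:
        raise ValueError("n_compounds must be positive")

    rng = np.random.default_rng(config.seed)
    capacity = code_capacity(config.k)
    cluster_sizes = [
        int(rng.integers(2, min(4, capacity) + 1)) for _ in range(config.n_clusters)
    ]
    if sum(cluster_sizes) > config.n_compounds:
        raise DesignError(
            f"{config.n_clusters} clusters need {sum(cluster_sizes)} compounds "
            f"but the panel has only {config.n_compounds}"
        )
    lo, hi = config.ri_range
    names = [f"Compound{i:03d}" for i in range(1, config.n_compounds + 1)]
    classes: dict[str, str] = {}
    ris: dict[str, float] = {}
    constraints = ConstraintGraph()

    # cluster centers kept far enough apart that members of different
    # clusters never count as similar (a panel designer spreads standards
    # that the codes could not disentangle)
    min_center_gap = config.cluster_spread + config.conflict_window
    centers = None
    for _attempt in range(1000):
        cand = np.sort(rng.uniform(lo, hi - config.cluster_spread, config.n_clusters))
        if config.n_clusters < 2 or np.all(np.diff(cand) >= min_center_gap):
            centers = cand
            break
    if centers is None and config.n_clusters:
        raise DesignError(
            f"cannot place {config.n_clusters} isomer clusters with "
            f"{min_center_gap:.0f} RI units of separation in {lo}-{hi}"
        )

    pos = 0
    for ci, size in enumerate(cluster_sizes):
        members = names[pos : pos + size]
        pos += size
        offsets = np.sort(rng.uniform(0, config.cluster_spread, size))
        for m, off in zip(members, offsets):
            ris[m] = float(centers[ci] + off)
            classes[m] = f"cluster{ci + 1:02d}"
        constraints.add_distinct(*members)

    # singletons are rejected where they would crowd a retention
    # neighbourhood beyond the code capacity
    placed = np.sort(np.array(list(ris.values()), dtype=float))
    for m in names[pos:]:
        for _attempt in range(1000):
            r = float(rng.uniform(lo, hi))
            neighbourhood = np.sum(np.abs(placed - r) <= config.conflict_window)
            if neighbourhood <= capacity - 1:
                break
        else:
            raise DesignError(
                f"cannot place {config.n_compounds} compounds in {lo}-{hi} "
                f"without exceeding the capacity of {capacity} similar codes"
            )
        ris[m] = r
        classes[m] = "singleton"
        placed = np.insert(placed, np.searchsorted(placed, r), r)

    # default conflict rule: retention proximity = similarity; any pair
    # within the matching window must carry distinct codes, or their
    # patterns could never be told apart
    by_ri = sorted(names, key=lambda m: ris[m])
    for i, m in enumerate(by_ri):
        j = i + 1
        while j < len(by_ri) and ris[by_ri[j]] - ris[m] <= config.conflict_window:
            constraints.add(m, by_ri[j], "DISTINCT")
            j += 1

    design = assign_codes(
        names, constraints, k=config.k, seed=int(rng.integers(2**31))
    )
    entries = [
        LibraryEntry(
            compound_name=name,
            derivatisation_state="(TMS)",
            product_rank=ProductRank.MP,
            expected_ri=ris[name],
            ident_code=design.assignment[name].mixes,
            compound_class=classes[name],
            spectrum=_random_spectrum(rng) if config.with_spectra else None,
        )
        for name in names
    ]
    library = CompoundLibrary(entries=entries, metadata={"seed": str(config.seed)})
    # design keyed by encoded entry names, matching how libraries are matched
    design = MixDesign(
        labels=design.labels,
        assignment={e.name: design.assignment[e.compound_name] for e in entries},
    )
    return library, design


def generate_peaklists(
    truth: CompoundLibrary,
    design: MixDesign,
    config: SimulationConfig,
) -> tuple[dict[str, PeakList], dict[str, AlkaneLadder]]:
    """Per-mixture peak lists and alkane ladders for one simulated batch.

    Each compound yields a peak in exactly its code's mixtures at
    RI ~ Normal(expected, noise_sd), dropped independently per mixture with
    ``dropout_rate``; decoy peaks are scattered uniformly over the RI range.
    RTs come from the shared monotone ladder map, so the pipeline's RI
    computation inverts the simulation exactly.
    """
    rng = np.random.default_rng(config.seed + 1)
    ladder = default_ladder()
    mu, sigma = config.intensity_lognormal
    lo, hi = config.ri_range
    true_ris = np.array([e.expected_ri for e in truth], dtype=float)

    peaks: dict[str, list[Peak]] = {lab: [] for lab in design.labels}
    for entry in truth:
        code = design.assignment.get(entry.name) or PairCode(entry.ident_code)
        for lab in code:
            if rng.random() < config.dropout_rate:
                continue
            ri = entry.expected_ri + (
                rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            )
            peaks[lab].append(
                Peak(
                    rt=rt_for_ri(ri, ladder),
                    intensity=float(rng.lognormal(mu, sigma)),
                    spectrum=entry.spectrum,
                )
            )
    guard = max(2.0 * config.noise_sd, 1e-6)
    for lab in design.labels:
        n_decoys = int(rng.poisson(config.decoy_rate * len(truth)))
        for _ in range(n_decoys):
            for _attempt in range(100):
                ri = float(rng.uniform(lo, hi))
                if not config.clean_decoys or np.all(np.abs(true_ris - ri) >= guard):
                    break
            peaks[lab].append(
                Peak(
                    rt=rt_for_ri(ri, ladder),
                    # matrix/decoy peaks: weaker and more variable than the
                    # amount-tuned standards
                    intensity=float(rng.lognormal(mu - 2.0, sigma + 0.6)),
                    spectrum=_random_spectrum(rng) if config.with_spectra else None,
                )
            )
    runs = {
        lab: PeakList(lab, sorted(plist, key=lambda p: p.rt))
        for lab, plist in peaks.items()
    }
    ladders = {lab: ladder for lab in design.labels}
    return runs, ladders
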