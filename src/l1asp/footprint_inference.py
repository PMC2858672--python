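"""Nucleosome footprint inference from single-molecule GpC accessibility.

In a methyltransferase-footprinting experiment, a GpC methyltransferase marks
every accessible GpC on intact chromatin; after bisulfite sequencing, an
unmarked (unmethylated) GpC on a clone read indicates protection, typically
by a nucleosome.  This module converts GpC calls into per-molecule
accessibility vectors, segments maximal protected patches into footprints
with spans extended to the midpoints of the flanking accessible sites, and
classifies each molecule's promoter occupancy state:

* ``tetranucleosomal`` — the inactive promoter: a -1 and +1 nucleosome at
  both TSSs (near-complete protection),
* ``dinucleosomal`` — the active promoter: only the two +1 nucleosomes
  remain, with nucleosome-free regions upstream of both TSSs,
* ``open`` — essentially no protection,
* ``other`` — anything ambiguous or uninformative.

Because the enzyme misses accessible sites at rate ``1 - efficiency``,
isolated protected calls are expected noise; window occupancy is therefore
judged only by nucleosome-scale footprints (span within or above the
canonical core-particle range) with a minimum overlap, never by a lone
protected site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .locus_model import DataError, GenomicInterval, LocusModel
from .methylation_analysis import CODE_METH, CODE_MISSING, CODE_UNMETH, CallMatrix

ACCESSIBLE = 1
PROTECTED = 0
MISSING = -1

STATE_NAMES = ("tetranucleosomal", "dinucleosomal", "open", "other")

#: Maps simulator state labels onto classifier state names.
TRUTH_TO_STATE = {"tetra": "tetranucleosomal", "di": "dinucleosomal", "open": "open"}


@dataclass(frozen=True)
class AccessibilityVector:
    """Ordered GpC sites of one molecule with accessibility calls.

    Calls: 1 accessible (enzyme-methylated), 0 protected (unmethylated),
    -1 missing.  CpG columns never appear here.
    """

    molecule_id: str
    positions: tuple[int, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise DataError("accessibility positions must be strictly ascending")
        if self.calls.shape != (len(self.positions),):
            raise DataError("one call required per position")

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions and calls with missing cells dropped (missing is neutral)."""
        mask = self.calls != MISSING
        return np.asarray(self.positions)[mask], self.calls[mask]


def accessibility_calls(matrix: CallMatrix, clone: int | str) -> AccessibilityVector:
    """Extract one molecule's GpC accessibility vector from a call matrix.

    An enzyme-methylated GpC was accessible; an unmethylated one protected.
    CpG columns are dropped.  Raises when the matrix has no GpC column (the
    experiment then carries no accessibility signal).
    """
    if isinstance(clone, str):
        try:
            row = matrix.clone_ids.index(clone)
        except ValueError:
            raise DataError(f"unknown clone id {clone!r}") from None
    else:
        row = clone
    gpc_idx = matrix.column_indices(site_class="gpc")
    if gpc_idx.size == 0:
        raise DataError("call matrix has no GpC columns; not a footprinting experiment")
    calls = np.full(gpc_idx.size, MISSING, dtype=np.int8)
    raw = matrix.calls[row, gpc_idx]
    calls[raw == CODE_METH] = ACCESSIBLE
    calls[raw == CODE_UNMETH] = PROTECTED
    return AccessibilityVector(
        molecule_id=matrix.clone_ids[row],
        positions=tuple(matrix.positions[i] for i in gpc_idx),
        calls=calls,
    )


def iter_accessibility(matrix: CallMatrix) -> Iterator[AccessibilityVector]:
    for i in range(matrix.n_clones):
        yield accessibility_calls(matrix, i)


@dataclass(frozen=True)
class Footprint:
    """A protected patch on one molecule."""

    span: GenomicInterval
    n_protected_sites: int
    classification: str  # nucleosome | sub-nucleosomal | super-nucleosomal
    protected_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_protected_sites < 1:
            raise DataError("a footprint needs at least one protected site")


def _classify_span(length: int, min_len: int, max_len: int) -> str:
    if length < min_len:
        return "sub-nucleosomal"
    if length > max_len:
        return "super-nucleosomal"
    return "nucleosome"


def call_footprints(
    vec: AccessibilityVector,
    amplicon: GenomicInterval,
    k: int = 0,
    min_len: int = 120,
    max_len: int = 200,
) -> list[Footprint]:
    """Segment maximal protected patches into footprints.

    A patch is a maximal run of protected sites, optionally absorbing up to
    ``k`` isolated accessible calls (default 0: no smoothing).  Missing calls
    are neutral: they neither break nor extend a run.  The span extends from
    the midpoint between the previous accessible site and the first protected
    site (or the amplicon start) to the midpoint between the last protected
    site and the next accessible site (or the amplicon end) — a symmetric
    treatment of inter-site uncertainty.  Classification by span length:
    ``nucleosome`` within [min_len, max_len] bp (core particle plus linker
    slack), ``sub-nucleosomal`` below, ``super-nucleosomal`` above.
    """
    if k < 0:
        raise DataError("k must be >= 0")
    if len(vec.positions) < 2:
        raise DataError("need at least 2 informative sites to call footprints")
    pos, calls = vec.observed()
    # Protected runs, merging across <= k absorbed accessible calls per patch.
    patches: list[list[int]] = []  # indices into pos
    absorbed: list[int] = []
    current: list[int] = []
    current_absorbed = 0
    gap_accessible = 0
    for i, call in enumerate(calls):
        if call == PROTECTED:
            if current and gap_accessible:
                if current_absorbed + gap_accessible <= k:
                    current_absorbed += gap_accessible
                else:
                    patches.append(current)
                    absorbed.append(current_absorbed)
                    current, current_absorbed = [], 0
            gap_accessible = 0
            current.append(i)
        else:  # accessible
            if current:
                gap_accessible += 1
    if current:
        patches.append(current)
        absorbed.append(current_absorbed)

    footprints: list[Footprint] = []
    accessible_idx = np.flatnonzero(calls == ACCESSIBLE)
    for patch in patches:
        first, last = patch[0], patch[-1]
        prev_acc = accessible_idx[accessible_idx < first]
        next_acc = accessible_idx[accessible_idx > last]
        start = (
            (int(pos[prev_acc[-1]]) + int(pos[first])) // 2
            if prev_acc.size
            else amplicon.start
        )
        end = (
            (int(pos[last]) + int(pos[next_acc[0]])) // 2
            if next_acc.size
            else amplicon.end
        )
        protected_positions = tuple(
            int(pos[i]) for i in patch if calls[i] == PROTECTED
        )
        span = GenomicInterval(amplicon.chrom, start, end)
        footprints.append(
            Footprint(
                span=span,
                n_protected_sites=len(protected_positions),
                classification=_classify_span(span.length, min_len, max_len),
                protected_sites=protected_positions,
            )
        )
    return footprints


@dataclass(frozen=True)
class PromoterWindows:
    """The four 147-bp windows flanking the two TSSs of the bidirectional promoter."""

    minus1_sense: GenomicInterval
    plus1_sense: GenomicInterval
    plus1_asp: GenomicInterval
    minus1_asp: GenomicInterval

    def as_dict(self) -> dict[str, GenomicInterval]:
        return {
            "minus1_sense": self.minus1_sense,
            "plus1_sense": self.plus1_sense,
            "plus1_asp": self.plus1_asp,
            "minus1_asp": self.minus1_asp,
        }


def promoter_windows(locus: LocusModel, window: int = 147) -> PromoterWindows:
    """-1/+1 windows at each TSS (+1 = downstream in transcription direction).

    The sense TSS transcribes rightwards and the antisense TSS leftwards, so
    both +1 windows sit between the TSSs and both -1 windows outside them.
    """
    chrom = locus.interval.chrom
    t1, t2 = locus.tss_sense, locus.tss_antisense
    return PromoterWindows(
        minus1_sense=GenomicInterval(chrom, max(locus.interval.start, t1 - window), t1 - 1),
        plus1_sense=GenomicInterval(chrom, t1 + 1, t1 + window),
        plus1_asp=GenomicInterval(chrom, t2 - window, t2 - 1),
        minus1_asp=GenomicInterval(chrom, t2 + 1, min(locus.interval.end, t2 + window)),
    )


@dataclass
class ClassifierParams:
    """Tunable thresholds of the promoter-state classifier.

    A window counts as nucleosome-occupied when footprint spans cover at
    least ``min_window_coverage`` bp of it (default two thirds of a 147-bp
    window).  Coverage, rather than any single footprint, is what makes the
    call robust to the two noise channels of the assay: an enzyme miss adds
    a small spurious patch in an open region (little coverage), and a
    conversion failure splits a genuine patch into two pieces whose spans
    still cover the window.
    """

    window: int = 147  # bp flanking each TSS
    min_len: int = 120  # nucleosome-scale footprint span, lower bound
    max_len: int = 200  # upper bound of the 'nucleosome' class
    k: int = 0  # accessible calls absorbable per patch
    tetra_protected_fraction: float = 0.9
    open_protected_fraction: float = 0.1
    min_window_coverage: int = 98  # bp of footprint coverage that makes a window occupied


@dataclass(frozen=True)
class PromoterStateCall:
    """Per-molecule promoter occupancy state with its supporting evidence."""

    molecule_id: str
    state: str
    evidence: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.state not in STATE_NAMES:
            raise DataError(f"unknown state {self.state!r}")


def classify_promoter_state(
    footprints: Sequence[Footprint],
    vec: AccessibilityVector,
    locus: LocusModel,
    params: ClassifierParams | None = None,
) -> PromoterStateCall:
    """Classify one molecule as tetra-/dinucleosomal, open or other.

    Rules, in order:

    1. any -1/+1 window with zero informative GpC call -> ``other``
       ("uninformative window"; the state cannot be decided);
    2. ``tetranucleosomal`` when the protected fraction of informative sites
       is >= ``tetra_protected_fraction`` over the whole promoter, or all
       four windows are occupied.  The fraction clause matters because the
       linkers between abutting nucleosomes may carry no informative GpC, so
       the four footprints can merge into one patch;
    3. ``dinucleosomal`` when both +1 windows are occupied and both -1
       windows contain an accessible site and are unoccupied (the
       nucleosome-free regions upstream of both TSSs);
    4. ``open`` when the protected fraction is <= ``open_protected_fraction``;
    5. ``other`` otherwise.

    A window counts as occupied when footprint spans cover >=
    ``min_window_coverage`` bp of it; an isolated protected site (expected
    enzyme-failure noise) contributes only its own small span and never
    occupies a window on its own.
    """
    p = params or ClassifierParams()
    windows = promoter_windows(locus, p.window)
    pos, calls = vec.observed()
    if pos.size == 0:
        return PromoterStateCall(vec.molecule_id, "other", {"reason": "no informative site"})
    protected_fraction = float((calls == PROTECTED).sum()) / pos.size

    occupied: dict[str, bool] = {}
    has_accessible: dict[str, bool] = {}
    uninformative: list[str] = []
    for name, win in windows.as_dict().items():
        in_win = (pos >= win.start) & (pos <= win.end)
        if not in_win.any():
            uninformative.append(name)
            continue
        coverage = sum(fp.span.overlap_length(win) for fp in footprints)
        occupied[name] = coverage >= p.min_window_coverage
        has_accessible[name] = bool((calls[in_win] == ACCESSIBLE).any())

    evidence = {
        "protected_fraction": protected_fraction,
        "occupied_windows": occupied,
        "accessible_windows": has_accessible,
        "n_footprints": len(footprints),
        "footprints": tuple(footprints),
    }
    if uninformative:
        evidence["reason"] = f"uninformative window: {', '.join(uninformative)}"
        return PromoterStateCall(vec.molecule_id, "other", evidence)

    if protected_fraction >= p.tetra_protected_fraction or all(occupied.values()):
        return PromoterStateCall(vec.molecule_id, "tetranucleosomal", evidence)
    minus = ("minus1_sense", "minus1_asp")
    plus = ("plus1_sense", "plus1_asp")
    if (
        all(occupied[w] for w in plus)
        and all(has_accessible[w] and not occupied[w] for w in minus)
    ):
        return PromoterStateCall(vec.molecule_id, "dinucleosomal", evidence)
    if protected_fraction <= p.open_protected_fraction:
        return PromoterStateCall(vec.molecule_id, "open", evidence)
    return PromoterStateCall(vec.molecule_id, "other", evidence)


def classify_matrix(
    matrix: CallMatrix,
    locus: LocusModel,
    params: ClassifierParams | None = None,
) -> tuple[list[PromoterStateCall], list[list[Footprint]]]:
    """Run footprint calling and state classification over a whole matrix."""
    p = params or ClassifierParams()
    calls = []
    all_fps = []
    for vec in iter_accessibility(matrix):
        fps = call_footprints(vec, locus.interval, k=p.k, min_len=p.min_len, max_len=p.max_len)
        all_fps.append(fps)
        calls.append(classify_promoter_state(fps, vec, locus, p))
    return calls, all_fps


@dataclass(frozen=True)
class OccupancyProfile:
    """Population protection frequency per GpC site."""

    positions: tuple[int, ...]
    frequency: np.ndarray  # protected / (protected + accessible), NaN if uncovered
    n_informative: np.ndarray
    n_molecules: int


def occupancy_profile(matrix: CallMatrix) -> OccupancyProfile:
    """Per-GpC-site protection frequency across molecules (missing excluded)."""
    if matrix.n_clones < 1:
        raise DataError("need at least one molecule")
    gpc = matrix.subset(site_class="gpc")
    protected = (gpc.calls == CODE_UNMETH).sum(axis=0).astype(float)
    accessible = (gpc.calls == CODE_METH).sum(axis=0).astype(float)
    denom = protected + accessible
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, protected / denom, np.nan)
    return OccupancyProfile(
        positions=gpc.positions,
        frequency=freq,
        n_informative=denom.astype(int),
        n_molecules=matrix.n_clones,
    )


def state_population_summary(calls: Sequence[PromoterStateCall]) -> pd.DataFrame:
    """Counts and fractions per promoter state (all four states always listed)."""
    n = len(calls)
    counts = {s: 0 for s in STATE_NAMES}
    for c in calls:
        counts[c.state] += 1
    return pd.DataFrame(
        {
            "state": list(STATE_NAMES),
            "count": [counts[s] for s in STATE_NAMES],
            "fraction": [counts[s] / n if n else 0.0 for s in STATE_NAMES],
        }
    )
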