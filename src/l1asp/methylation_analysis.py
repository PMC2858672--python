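"""Per-molecule methylation calling and strand-level statistics.

Turns bisulfite clone reads of a locus amplicon into a molecules x sites call
matrix (C at an informative site = methylated, T = unmethylated), applies
clone-level conversion QC, and computes the population statistics used to
describe locus methylation: per-site percent methylation, the percent of
fully unmethylated strands (PUR), the per-strand methylation histogram whose
bimodality signals a biphasic fully-methylated / fully-unmethylated mixture,
and between-assay concordance.

Cytosines in GpCpG context never enter the matrix: enzyme-applied GpC marks
and endogenous CpG methylation cannot be distinguished there.  A conversion
failure (unmethylated C read as C) is indistinguishable from true methylation
at the single-cell level and is handled only by clone-level QC, not by any
per-cell correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .locus_model import DataError, LocusModel

CODE_MISSING = -1
CODE_UNMETH = 0
CODE_METH = 1

_CODE_CHAR = {CODE_METH: "M", CODE_UNMETH: "U", CODE_MISSING: "."}
_LOLLIPOP = {CODE_METH: "●", CODE_UNMETH: "○", CODE_MISSING: "·"}


@dataclass(frozen=True)
class CallMatrix:
    """Molecules x informative sites, cells in {methylated, unmethylated, missing}.

    Columns are exactly the locus's informative CpG and GpC positions
    (ascending); GpCpG-excluded sites never appear.  Cells are stored as
    int8 codes (1 methylated, 0 unmethylated, -1 missing).
    """

    clone_ids: tuple[str, ...]
    positions: tuple[int, ...]
    site_classes: tuple[str, ...]  # 'cpg' | 'gpc' per column
    calls: np.ndarray

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.clone_ids), len(self.positions)):
            raise DataError("call matrix shape does not match clone ids / positions")
        if len(self.site_classes) != len(self.positions):
            raise DataError("one site class required per column")
        if any(c not in ("cpg", "gpc") for c in self.site_classes):
            raise DataError("site classes must be 'cpg' or 'gpc'")
        if list(self.positions) != sorted(set(self.positions)):
            raise DataError("positions must be strictly ascending")
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise DataError("duplicate clone ids in call matrix")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def column_indices(self, sites: Sequence[int] | None = None, site_class: str | None = None) -> np.ndarray:
        idx = np.arange(len(self.positions))
        if site_class is not None:
            mask = np.array([c == site_class for c in self.site_classes])
            idx = idx[mask]
        if sites is not None:
            wanted = set(sites)
            missing = wanted - {self.positions[i] for i in idx}
            if missing:
                raise DataError(f"sites not in matrix: {sorted(missing)}")
            idx = np.array([i for i in idx if self.positions[i] in wanted], dtype=int)
        return idx

    def subset(self, sites: Sequence[int] | None = None, site_class: str | None = None) -> "CallMatrix":
        idx = self.column_indices(sites, site_class)
        return CallMatrix(
            clone_ids=self.clone_ids,
            positions=tuple(self.positions[i] for i in idx),
            site_classes=tuple(self.site_classes[i] for i in idx),
            calls=self.calls[:, idx],
        )

    def select_clones(self, keep: Sequence[int]) -> "CallMatrix":
        keep = list(keep)
        return CallMatrix(
            clone_ids=tuple(self.clone_ids[i] for i in keep),
            positions=self.positions,
            site_classes=self.site_classes,
            calls=self.calls[keep, :],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [[_CODE_CHAR[int(v)] for v in row] for row in self.calls],
            index=list(self.clone_ids),
            columns=[str(p) for p in self.positions],
        )
        df.index.name = "clone"
        return df

    def lollipop(self) -> str:
        """Text rendering of the matrix, one clone per line: filled circles
        methylated, open circles unmethylated, middle dots missing."""
        width = max((len(c) for c in self.clone_ids), default=5)
        lines = [
            f"{cid:<{width}} " + "".join(_LOLLIPOP[int(v)] for v in row)
            for cid, row in zip(self.clone_ids, self.calls)
        ]
        return "\n".join(lines)


def call_methylation(read: str, locus: LocusModel, max_foreign_fraction: float = 0.10) -> np.ndarray:
    """Call one clone read against the locus, returning a call-matrix row.

    The read must align ungapped and co-linearly (equal length).  At each
    informative site a C is called methylated and a T unmethylated; anything
    else is missing.  Reads whose non-site positions disagree with the fully
    converted reference at more than ``max_foreign_fraction`` of positions
    are rejected as foreign clones.
    """
    if len(read) != len(locus.reference):
        raise DataError(
            f"read length {len(read)} does not match locus length {len(locus.reference)}"
        )
    read_arr = np.frombuffer(read.upper().encode("ascii"), dtype=np.uint8)
    ref_arr = np.frombuffer(locus.reference.encode("ascii"), dtype=np.uint8)

    start = locus.interval.start
    site_idx = np.array([p - start for p in locus.site_map.informative_sites], dtype=int)
    special = np.zeros(len(read), dtype=bool)
    for p in (
        locus.site_map.cpg_sites + locus.site_map.gpc_sites + locus.site_map.excluded_sites
    ):
        special[p - start] = True

    # Foreign-clone check: away from any site, the read must look like the
    # bisulfite-converted reference (C -> T, everything else unchanged).
    expected = ref_arr.copy()
    expected[expected == ord("C")] = ord("T")
    nonsite = ~special & (ref_arr != ord("N")) & (read_arr != ord("N"))
    n_nonsite = int(nonsite.sum())
    if n_nonsite:
        mismatch = float((read_arr[nonsite] != expected[nonsite]).sum()) / n_nonsite
        if mismatch > max_foreign_fraction:
            raise DataError(
                f"read disagrees with converted reference at {mismatch:.1%} of "
                f"non-site positions (> {max_foreign_fraction:.0%}); foreign clone?"
            )

    row = np.full(site_idx.size, CODE_MISSING, dtype=np.int8)
    bases = read_arr[site_idx] if site_idx.size else np.array([], dtype=np.uint8)
    row[bases == ord("C")] = CODE_METH
    row[bases == ord("T")] = CODE_UNMETH
    return row


def build_call_matrix(
    reads: Iterable[tuple[str, str]], locus: LocusModel
) -> CallMatrix:
    """Call a set of ``(clone_id, read)`` pairs into a :class:`CallMatrix`."""
    ids = []
    rows = []
    for cid, read in reads:
        ids.append(cid)
        try:
            rows.append(call_methylation(read, locus))
        except DataError as exc:
            raise DataError(f"clone {cid!r}: {exc}") from exc
    positions = locus.site_map.informative_sites
    classes = tuple(locus.site_map.site_class(p) for p in positions)
    calls = np.vstack(rows) if rows else np.empty((0, len(positions)), dtype=np.int8)
    return CallMatrix(tuple(ids), positions, classes, calls)


@dataclass(frozen=True)
class CloneQC:
    """Per-clone bisulfite conversion QC."""

    clone_id: str
    conversion_efficiency: float  # NaN when no context-free C is available
    passed: bool


def conversion_efficiency(read: str, locus: LocusModel) -> float:
    """Fraction of context-free cytosines (not CpG/GpC/GpCpG) read as T.

    These cytosines are never methylated in vivo, so any residual C there is
    a conversion failure.  Returns NaN when the locus has no such cytosine.
    """
    if len(read) != len(locus.reference):
        raise DataError("read length does not match locus length")
    start = locus.interval.start
    site_positions = set(
        locus.site_map.cpg_sites + locus.site_map.gpc_sites + locus.site_map.excluded_sites
    )
    read_u = read.upper()
    n_t = n_c = 0
    for i, base in enumerate(locus.reference):
        if base != "C" or (i + start) in site_positions:
            continue
        got = read_u[i]
        if got == "T":
            n_t += 1
        elif got == "C":
            n_c += 1
    if n_t + n_c == 0:
        return float("nan")
    return n_t / (n_t + n_c)


def qc_clones(
    reads: Sequence[tuple[str, str]],
    locus: LocusModel,
    min_conversion: float = 0.95,
) -> tuple[CallMatrix, pd.DataFrame]:
    """Filter clones by conversion efficiency and build the call matrix.

    Clones below ``min_conversion`` are removed (and reported); clones with
    no measurable context-free cytosine pass by default.  Raises when every
    clone fails.
    """
    if not 0.0 <= min_conversion <= 1.0:
        raise DataError("min_conversion must be in [0, 1]")
    records = []
    kept = []
    for cid, read in reads:
        try:
            eff = conversion_efficiency(read, locus)
        except DataError as exc:
            raise DataError(f"clone {cid!r}: {exc}") from exc
        passed = bool(np.isnan(eff) or eff >= min_conversion)
        records.append(
            {"clone_id": cid, "conversion_efficiency": eff, "passed": passed}
        )
        if passed:
            kept.append((cid, read))
    report = pd.DataFrame(records, columns=["clone_id", "conversion_efficiency", "passed"])
    if reads and not kept:
        raise DataError(
            f"all {len(reads)} clones failed conversion QC (min_conversion={min_conversion})"
        )
    return build_call_matrix(kept, locus), report


@dataclass(frozen=True)
class MethylationSummary:
    """Per-site percent methylation plus the unweighted mean over sites."""

    per_site: pd.Series  # % per position; NaN where flagged
    mean: float
    flagged_sites: tuple[int, ...]  # sites with zero informative cells


def percent_methylation(
    matrix: CallMatrix, sites: Sequence[int] | None = None
) -> MethylationSummary:
    """Percent methylation per site: 100 x methylated / (methylated + unmethylated).

    Missing cells are ignored.  The summary over the site subset is the
    unweighted mean of per-site values (the convention of averaging the
    assayed CpG sites of a locus); sites with zero informative cells are
    flagged and excluded from that mean.
    """
    sub = matrix.subset(sites)
    if len(sub.positions) == 0:
        raise DataError("empty site subset")
    meth = (sub.calls == CODE_METH).sum(axis=0).astype(float)
    unmeth = (sub.calls == CODE_UNMETH).sum(axis=0).astype(float)
    denom = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, 100.0 * meth / denom, np.nan)
    per_site = pd.Series(pct, index=list(sub.positions), name="percent_methylation")
    flagged = tuple(p for p, d in zip(sub.positions, denom) if d == 0)
    valid = per_site.dropna()
    mean = float(valid.mean()) if len(valid) else float("nan")
    return MethylationSummary(per_site=per_site, mean=mean, flagged_sites=flagged)


@dataclass(frozen=True)
class PurResult:
    """Percent of fully unmethylated strands over a site subset."""

    percent: float
    n_retained: int
    n_dropped: int  # molecules with a missing cell in the subset


def fully_unmethylated_fraction(
    matrix: CallMatrix, sites: Sequence[int] | None = None
) -> PurResult:
    """Percent of molecules unmethylated at every site of the subset (PUR).

    Molecules with any missing cell in the subset are dropped and counted;
    raises when no molecule remains.
    """
    sub = matrix.subset(sites)
    if len(sub.positions) == 0:
        raise DataError("empty site subset")
    complete = ~(sub.calls == CODE_MISSING).any(axis=1)
    n_retained = int(complete.sum())
    n_dropped = sub.n_clones - n_retained
    if n_retained == 0:
        raise DataError("no molecule with complete calls over the requested sites")
    fully_u = (sub.calls[complete] == CODE_UNMETH).all(axis=1)
    return PurResult(
        percent=100.0 * float(fully_u.sum()) / n_retained,
        n_retained=n_retained,
        n_dropped=n_dropped,
    )


def strand_category_percents(
    matrix: CallMatrix, sites: Sequence[int] | None = None
) -> dict[str, float]:
    """Split complete molecules into fully unmethylated / fully methylated /
    intermediate percentages (they sum to 100)."""
    sub = matrix.subset(sites)
    complete = ~(sub.calls == CODE_MISSING).any(axis=1)
    n = int(complete.sum())
    if n == 0:
        raise DataError("no molecule with complete calls over the requested sites")
    calls = sub.calls[complete]
    fully_u = float((calls == CODE_UNMETH).all(axis=1).sum())
    fully_m = float((calls == CODE_METH).all(axis=1).sum())
    return {
        "fully_unmethylated": 100.0 * fully_u / n,
        "fully_methylated": 100.0 * fully_m / n,
        "intermediate": 100.0 * (n - fully_u - fully_m) / n,
    }


@dataclass(frozen=True)
class StrandDistribution:
    """Histogram of per-molecule percent-methylated-sites.

    ``exact_zero`` / ``exact_hundred`` report the strands at exactly 0% and
    100% separately, since biphasic ("all or none") methylation shows up as
    mass concentrated at the two endpoints.
    """

    per_molecule: np.ndarray  # % methylated per molecule
    bin_edges: np.ndarray
    counts: np.ndarray
    exact_zero: int
    exact_hundred: int
    n_dropped: int  # molecules with no informative call in the subset

    @property
    def n_molecules(self) -> int:
        return int(self.per_molecule.size)


def strand_distribution(
    matrix: CallMatrix,
    sites: Sequence[int] | None = None,
    bin_width: float = 10.0,
) -> StrandDistribution:
    """Distribution of strands by percent of sites methylated (Fig-style histogram)."""
    if matrix.n_clones == 0:
        raise DataError("call matrix has no molecules")
    if not 0 < bin_width <= 100:
        raise DataError("bin_width must be in (0, 100]")
    sub = matrix.subset(sites)
    meth = (sub.calls == CODE_METH).sum(axis=1).astype(float)
    unmeth = (sub.calls == CODE_UNMETH).sum(axis=1).astype(float)
    denom = meth + unmeth
    keep = denom > 0
    per_molecule = 100.0 * meth[keep] / denom[keep]
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    counts, _ = np.histogram(per_molecule, bins=edges)
    return StrandDistribution(
        per_molecule=per_molecule,
        bin_edges=edges,
        counts=counts,
        exact_zero=int((per_molecule == 0.0).sum()),
        exact_hundred=int((per_molecule == 100.0).sum()),
        n_dropped=int((~keep).sum()),
    )


def assay_concordance(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Pearson correlation between two per-sample percent-methylation assays.

    Models the comparison of two quantitative assays reading different site
    subsets of the same samples (e.g. a 2-site primer-extension assay vs a
    4-site pyrosequencing assay).  Requires >= 3 paired samples and
    non-degenerate variance in both vectors.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("assay vectors must be 1-D and of equal length")
    if a.size < 3:
        raise DataError("need at least 3 paired samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DataError("correlation undefined: zero variance in an assay vector")
    r, _ = stats.pearsonr(a, b)
    return float(r)
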