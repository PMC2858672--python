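"""Synthetic data with known ground truth for the whole pipeline.

Emulates the experimental chain end to end: chromatin molecules drawn from a
mixture of nucleosome-occupancy states over a bidirectional L1 promoter
(tetranucleosomal = two +1 and two -1 nucleosomes, dinucleosomal = the two +1
nucleosomes only, open = none), marking of accessible GpC sites by a GpC
methyltransferase with efficiency < 1, endogenous CpG methylation as a
biphasic mixture of fully methylated and fully unmethylated strands,
bisulfite conversion with rate < 1, per-sample cohort tables with group
effects (N > CN > T methylation, inversely coupled expression), and partial
MNase digestion into mono/di/tri/tetranucleosome fragments.

Every random draw flows from a single seeded generator, so one seed fixes the
whole dataset.  Draw counts are independent of parameter values (every GpC
consumes one uniform whether or not it sits in a footprint; every C consumes
one uniform whether or not it is marked), which makes runs at different
efficiencies with the same seed common-random-number comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .locus_model import (
    DataError,
    GeneModel,
    GenomicInterval,
    LocusModel,
    build_locus_model,
)

STATE_ORDER = ("tetra", "di", "open")

#: 16-bp tile used for the synthetic promoter reference.  Per tile: one GpC
#: (pos 3), one context-free C (pos 7, used for conversion QC) and one CpG
#: (pos 10); no GpCpG, and tile junctions create no new context.
_REFERENCE_TILE = "AGCTTACAACGATTAT"


@dataclass(frozen=True)
class MoleculeState:
    """Ground truth for one chromatin molecule."""

    nucleosome_footprints: tuple[GenomicInterval, ...]
    endogenous_meth: Mapping[int, bool]  # cpg position -> methylated
    state_label: str  # tetra | di | open

    def __post_init__(self) -> None:
        expected = {"tetra": 4, "di": 2, "open": 0}[self.state_label]
        if len(self.nucleosome_footprints) != expected:
            raise DataError(
                f"{self.state_label} molecule must have {expected} footprints, "
                f"got {len(self.nucleosome_footprints)}"
            )
        fps = sorted(self.nucleosome_footprints, key=lambda f: f.start)
        for a, b in zip(fps, fps[1:]):
            if b.start <= a.end:
                raise DataError("nucleosome footprints must not overlap")


def _validate_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise DataError(f"{name} must be in [0, 1], got {p}")


@dataclass
class SimulationConfig:
    """Free parameters of the molecule/footprinting simulation.

    The enzyme efficiency and conversion rate defaults (0.85 and 0.99)
    reflect typical wet-lab performance of a 15-minute GpC-methyltransferase
    treatment followed by bisulfite conversion; both are overridable.
    ``endogenous_mixture`` is the probability that a strand is fully CpG
    methylated; ``None`` ties it to the occupancy state (tetra molecules
    fully methylated, di/open fully unmethylated), matching the observed
    coupling between methylation and the tetra->di switch.
    """

    n_molecules: int = 200
    state_mixture: dict[str, float] = field(
        default_factory=lambda: {"tetra": 0.5, "di": 0.5, "open": 0.0}
    )
    enzyme_efficiency: float = 0.85
    conversion_rate: float = 0.99
    endogenous_mixture: float | None = None
    nucleosome_length: int = 147
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise DataError("n_molecules must be >= 0")
        unknown = set(self.state_mixture) - set(STATE_ORDER)
        if unknown:
            raise DataError(f"unknown states in mixture: {sorted(unknown)}")
        for name, p in self.state_mixture.items():
            _validate_prob(f"state_mixture[{name}]", p)
        total = sum(self.state_mixture.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise DataError(f"state mixture must sum to 1, got {total}")
        _validate_prob("enzyme_efficiency", self.enzyme_efficiency)
        _validate_prob("conversion_rate", self.conversion_rate)
        if self.endogenous_mixture is not None:
            _validate_prob("endogenous_mixture", self.endogenous_mixture)
        if self.nucleosome_length < 1:
            raise DataError("nucleosome_length must be >= 1")

    def probabilities(self) -> np.ndarray:
        return np.array([self.state_mixture.get(s, 0.0) for s in STATE_ORDER])


@dataclass(frozen=True)
class GroupSpec:
    """Per-group sampling parameters for a synthetic cohort."""

    n: int
    meth_mean: float
    meth_sd: float
    expr_mean: float
    expr_sd: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise DataError("group size must be >= 0")
        if self.meth_sd < 0 or self.expr_sd < 0:
            raise DataError("standard deviations must be >= 0")


@dataclass
class CohortConfig:
    """Cohort generator emulating N / CN / T group structure.

    Defaults encode the direction of the clinical contrast: normal tissue
    from cancer-free bladders (N) heavily methylated with low alternate
    transcript expression, histologically normal tissue from tumor-bearing
    bladders (CN) intermediate, and tumors (T) hypomethylated with high
    expression.  ``coupling`` is the within-group correlation between the
    latent methylation and expression deviations; negative values mean lower
    methylation goes with higher expression.
    """

    groups: dict[str, GroupSpec] = field(
        default_factory=lambda: {
            "N": GroupSpec(19, 85.0, 8.0, 1.0, 0.5),
            "CN": GroupSpec(30, 45.0, 18.0, 5.0, 2.5),
            "T": GroupSpec(30, 25.0, 15.0, 8.0, 4.0),
        }
    )
    coupling: float = -0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.coupling <= 1.0:
            raise DataError(f"coupling must be in [-1, 1], got {self.coupling}")


def synthetic_promoter_locus(
    nucleosome_length: int = 147,
    linker: int = 20,
    upstream_margin: int = 53,
    downstream_margin: int = 58,
    chrom: str = "L1ASP_synthetic",
) -> LocusModel:
    """Construct the default synthetic bidirectional L1 promoter locus.

    The reference is a deterministic 16-bp tiling giving one informative GpC
    every 16 bp (~9 per 147-bp nucleosome window), one CpG every 16 bp and
    one context-free C every 16 bp for conversion QC.  The sense TSS and the
    antisense TSS are placed so that exactly two nucleosomes plus a
    ``linker``-bp linker fit between them, with room for a -1 nucleosome
    outside each TSS.
    """
    if linker < 0 or upstream_margin < 0 or downstream_margin < 0:
        raise DataError("margins and linker must be >= 0")
    t1 = upstream_margin + nucleosome_length  # sense TSS
    t2 = t1 + 2 * nucleosome_length + linker + 1  # antisense TSS
    length = t2 + nucleosome_length + downstream_margin
    n_tiles = -(-length // len(_REFERENCE_TILE))
    reference = (_REFERENCE_TILE * n_tiles)[:length]
    annotations = {
        "tss_sense": GenomicInterval(chrom, t1, t1, "+"),
        "tss_antisense": GenomicInterval(chrom, t2, t2, "-"),
        # The L1 occupies the 3' end of the locus; the antisense promoter
        # fires out of its 5' UTR toward the host gene.
        "l1": GenomicInterval(chrom, max(1, length - 554), length, "-"),
    }
    return build_locus_model(reference, annotations)


def canonical_footprints(
    locus: LocusModel, state: str, nucleosome_length: int = 147
) -> tuple[GenomicInterval, ...]:
    """True footprint intervals for a molecule in the given occupancy state.

    Tetra: a -1 and +1 nucleosome flanking each TSS.  Di: only the two +1
    nucleosomes (each immediately downstream of its TSS, i.e. between the
    TSSs), leaving nucleosome-free regions upstream of both.  Open: none.
    """
    chrom = locus.interval.chrom
    t1, t2, L = locus.tss_sense, locus.tss_antisense, nucleosome_length
    plus1_sense = GenomicInterval(chrom, t1 + 1, t1 + L)
    plus1_asp = GenomicInterval(chrom, t2 - L, t2 - 1)
    if state == "di":
        return (plus1_sense, plus1_asp)
    if state == "tetra":
        minus1_sense = GenomicInterval(chrom, t1 - L, t1 - 1)
        minus1_asp = GenomicInterval(chrom, t2 + 1, t2 + L)
        return (minus1_sense, plus1_sense, plus1_asp, minus1_asp)
    if state == "open":
        return ()
    raise DataError(f"unknown occupancy state {state!r}")


def _check_geometry(locus: LocusModel, L: int) -> None:
    t1, t2 = locus.tss_sense, locus.tss_antisense
    needed_between = 2 * L
    if t2 - t1 - 1 < needed_between or t1 - L < locus.interval.start or t2 + L > locus.interval.end:
        required = 4 * L + (t2 - t1 - 1 if t2 > t1 else 0)
        raise DataError(
            "locus too short for the tetranucleosome geometry: needs "
            f"{L} bp upstream of the sense TSS, {L} bp downstream of the "
            f"antisense TSS and {needed_between} bp between the TSSs "
            f"(>= {4 * L + needed_between} bp informative span in total)"
        )


def simulate_molecules(
    locus: LocusModel,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[MoleculeState]:
    """Draw molecules from the configured occupancy-state mixture.

    Endogenous CpG methylation follows a biphasic (all-or-none per strand)
    mixture: by default tied to the state (tetra methylated, di/open not),
    or Bernoulli(``endogenous_mixture``) per strand when that is set.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    _check_geometry(locus, cfg.nucleosome_length)
    probs = cfg.probabilities()
    states = rng.choice(len(STATE_ORDER), size=cfg.n_molecules, p=probs)
    full_meth_draws = rng.random(cfg.n_molecules)
    cpg_sites = locus.site_map.cpg_sites
    molecules = []
    for i in range(cfg.n_molecules):
        state = STATE_ORDER[states[i]]
        if cfg.endogenous_mixture is None:
            fully_methylated = state == "tetra"
        else:
            fully_methylated = full_meth_draws[i] < cfg.endogenous_mixture
        molecules.append(
            MoleculeState(
                nucleosome_footprints=canonical_footprints(locus, state, cfg.nucleosome_length),
                endogenous_meth={p: fully_methylated for p in cpg_sites},
                state_label=state,
            )
        )
    return molecules


def simulate_enzyme_treatment(
    mol: MoleculeState,
    locus: LocusModel,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[int, bool]:
    """Mark accessible GpC sites with the GpC methyltransferase.

    Each informative GpC outside every nucleosome footprint is methylated
    with probability ``enzyme_efficiency``; GpCs under a footprint are never
    marked (steric protection is absolute).  Endogenous CpG states are copied
    through; GpCpG (excluded) sites carry no mark.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    gpc = np.asarray(locus.site_map.gpc_sites)
    draws = rng.random(gpc.size)
    protected = np.zeros(gpc.size, dtype=bool)
    for fp in mol.nucleosome_footprints:
        protected |= (gpc >= fp.start) & (gpc <= fp.end)
    marked = ~protected & (draws < cfg.enzyme_efficiency)
    marks: dict[int, bool] = {int(p): bool(m) for p, m in zip(gpc, marked)}
    for pos, meth in mol.endogenous_meth.items():
        marks[pos] = bool(meth)
    return marks


def simulate_bisulfite_reads(
    mol: MoleculeState,
    marks: Mapping[int, bool],
    locus: LocusModel,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> str:
    """Bisulfite-convert one molecule into a top-strand clone read.

    Methylated cytosines (endogenous CpG or enzyme-applied GpC) stay C;
    every other C deaminates to T with probability ``conversion_rate`` (a
    failed conversion leaves a spurious C).  Non-C bases are untouched, so
    the read always has the reference length.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ref = np.frombuffer(locus.reference.encode("ascii"), dtype=np.uint8).copy()
    c_idx = np.flatnonzero(ref == ord("C"))
    draws = rng.random(c_idx.size)
    start = locus.interval.start
    keep = np.fromiter(
        (marks.get(int(i) + start, False) for i in c_idx), dtype=bool, count=c_idx.size
    )
    convert = ~keep & (draws < cfg.conversion_rate)
    ref[c_idx[convert]] = ord("T")
    return ref.tobytes().decode("ascii")


@dataclass(frozen=True)
class SimulatedDataset:
    """Molecules with their enzyme marks and bisulfite clone reads."""

    locus: LocusModel
    molecules: tuple[MoleculeState, ...]
    marks: tuple[Mapping[int, bool], ...]
    reads: tuple[str, ...]
    clone_ids: tuple[str, ...]

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(m.state_label for m in self.molecules)


def simulate_dataset(locus: LocusModel, cfg: SimulationConfig) -> SimulatedDataset:
    """Run the full generative chain: molecules -> enzyme marks -> reads."""
    rng = np.random.default_rng(cfg.seed)
    molecules = simulate_molecules(locus, cfg, rng=rng)
    marks = []
    reads = []
    for mol in molecules:
        mk = simulate_enzyme_treatment(mol, locus, cfg, rng=rng)
        marks.append(mk)
        reads.append(simulate_bisulfite_reads(mol, mk, locus, cfg, rng=rng))
    ids = tuple(f"clone_{i + 1:05d}" for i in range(len(molecules)))
    return SimulatedDataset(locus, tuple(molecules), tuple(marks), tuple(reads), ids)


def simulate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Sample a per-patient cohort table (sample, group, methylation %, expression).

    Within each group, methylation and expression share a latent Gaussian
    with correlation ``coupling``; methylation is clipped to [0, 100] and
    expression floored at 0 (relative units).
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    resid = math.sqrt(max(0.0, 1.0 - cfg.coupling**2))
    for group, spec in cfg.groups.items():
        z = rng.standard_normal(spec.n)
        w = rng.standard_normal(spec.n)
        meth = np.clip(spec.meth_mean + spec.meth_sd * z, 0.0, 100.0)
        expr = np.maximum(
            spec.expr_mean + spec.expr_sd * (cfg.coupling * z + resid * w), 0.0
        )
        for i in range(spec.n):
            rows.append(
                {
                    "sample": f"{group}{i + 1:03d}",
                    "group": group,
                    "methylation": float(meth[i]),
                    "expression": float(expr[i]),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "group", "methylation", "expression"])


def simulate_mnase(
    molecules: Sequence[MoleculeState],
    p_cut: float,
    rng: np.random.Generator | int | None = None,
) -> list[list[int]]:
    """Partially digest molecules at inter-nucleosome linkers.

    Each of the ``n - 1`` linkers of an ``n``-nucleosome molecule is cut
    independently with probability ``p_cut``; a fragment's class is the
    number of nucleosomes it spans (1 = mono, 2 = di, ...).  Returns one list
    of fragment classes per molecule; nucleosome-free molecules yield none.
    """
    _validate_prob("p_cut", p_cut)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: list[list[int]] = []
    for mol in molecules:
        n = len(mol.nucleosome_footprints)
        if n == 0:
            out.append([])
            continue
        cuts = rng.random(n - 1) < p_cut
        fragments = []
        run = 1
        for cut in cuts:
            if cut:
                fragments.append(run)
                run = 1
            else:
                run += 1
        fragments.append(run)
        out.append(fragments)
    return out


def fragment_class_counts(fragments: Sequence[Sequence[int]]) -> dict[int, int]:
    """Aggregate per-molecule fragment classes into population counts."""
    counts: dict[int, int] = {}
    for frags in fragments:
        for f in frags:
            counts[f] = counts.get(f, 0) + 1
    return dict(sorted(counts.items()))


# ---------------------------------------------------------------------------
# Synthetic genome with planted genes and L1 repeats, for ASP scanning.

_GENE_SPACING = 22_000
_EXON_LEN = 200
_INTRON_LEN = 6_500
_N_EXONS = 4

_REPEAT_KINDS = ("candidate", "sense_decoy", "short_decoy", "exonic_decoy")


def make_synthetic_genome(
    n_genes: int,
    n_repeats: int,
    seed: int = 0,
    chrom: str = "chrSim",
) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """Plant genes and L1 repeats on a random chromosome, with a truth manifest.

    Repeats cycle through four kinds: a true candidate (full-length 6.1 kb,
    entirely intronic, antisense to the host), a sense-strand decoy, a short
    (1.5 kb) decoy and an exon-overlapping decoy.  Returns the reference
    sequence, an annotation table (chrom, start, end, strand, feature, name)
    and a manifest listing each repeat with its ``is_candidate`` truth flag.
    Identical seeds give byte-identical outputs.
    """
    if n_genes < 0 or n_repeats < 0:
        raise DataError("counts must be >= 0")
    if n_repeats > 0 and n_genes == 0:
        raise DataError("cannot plant repeats without genes")
    rng = np.random.default_rng(seed)
    length = n_genes * _GENE_SPACING + 4000
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reference = bases[rng.integers(0, 4, size=max(length, 1))].tobytes().decode("ascii")

    ann_rows = []
    genes: list[GeneModel] = []
    for g in range(n_genes):
        start = 2001 + g * _GENE_SPACING
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        for e in range(_N_EXONS):
            es = start + e * (_EXON_LEN + _INTRON_LEN)
            exons.append(GenomicInterval(chrom, es, es + _EXON_LEN - 1, strand))
        gene_iv = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
        name = f"gene{g + 1:03d}"
        genes.append(GeneModel(name, gene_iv, tuple(exons)))
        ann_rows.append((chrom, gene_iv.start, gene_iv.end, strand, "gene", name))
        for k, ex in enumerate(exons):
            ann_rows.append((chrom, ex.start, ex.end, strand, "exon", f"{name}.e{k + 1}"))

    manifest_rows = []
    for j in range(n_repeats):
        gene = genes[j % n_genes]
        kind = _REPEAT_KINDS[j % len(_REPEAT_KINDS)]
        introns = gene.introns()
        anti = "-" if gene.strand == "+" else "+"
        if kind == "candidate":
            intron = introns[1]
            iv = GenomicInterval(chrom, intron.start + 100, intron.start + 100 + 6100 - 1, anti)
        elif kind == "sense_decoy":
            intron = introns[0]
            iv = GenomicInterval(chrom, intron.start + 100, intron.start + 100 + 6100 - 1, gene.strand)
        elif kind == "short_decoy":
            intron = introns[2]
            iv = GenomicInterval(chrom, intron.start + 100, intron.start + 100 + 1500 - 1, anti)
        else:  # exonic_decoy: spills out of intron 1 into exon 2
            intron = introns[0]
            iv = GenomicInterval(chrom, intron.end - 6100 + 101, intron.end + 100, anti)
        name = f"L1.{j + 1:03d}"
        ann_rows.append((chrom, iv.start, iv.end, iv.strand, "L1", name))
        manifest_rows.append(
            {
                "name": name,
                "chrom": chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "host_gene": gene.name,
                "kind": kind,
                "is_candidate": kind == "candidate",
            }
        )

    annotations = pd.DataFrame(
        ann_rows, columns=["chrom", "start", "end", "strand", "feature", "name"]
    )
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["name", "chrom", "start", "end", "strand", "host_gene", "kind", "is_candidate"],
    )
    return reference, annotations, manifest


def genes_from_annotations(annotations: pd.DataFrame) -> list[GeneModel]:
    """Reassemble :class:`GeneModel` objects from an annotation table."""
    genes = []
    gene_rows = annotations[annotations["feature"] == "gene"]
    exon_rows = annotations[annotations["feature"] == "exon"]
    for _, row in gene_rows.iterrows():
        prefix = f"{row['name']}."
        exons = tuple(
            GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), r["strand"])
            for _, r in exon_rows.iterrows()
            if str(r["name"]).startswith(prefix)
        )
        genes.append(
            GeneModel(
                row["name"],
                GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]), row["strand"]),
                exons,
            )
        )
    return genes


def repeats_from_annotations(annotations: pd.DataFrame) -> list[GenomicInterval]:
    """Extract L1 repeat intervals from an annotation table."""
    return [
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), r["strand"])
        for _, r in annotations[annotations["feature"] == "L1"].iterrows()
    ]
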