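"""Pipeline configuration, standard-format I/O and the end-to-end stages.

Ties the generator and analysis modules into a reproducible pipeline:
``run_simulate`` writes a complete seed-stamped synthetic dataset (reference
FASTA, locus annotations, clone FASTA with ground-truth labels, cohort TSV)
and ``run_analyze`` turns a dataset directory into a results bundle (call
matrix, QC, footprints, state calls and summary, occupancy profile,
methylation statistics, cohort statistics, and — when ground truth is
present — a recovery report).  Every TSV carries a provenance header with
the package version, the config hash and the seed, so re-running the same
configuration is byte-identical and a mismatched re-analysis is detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .cohort_stats import group_summary, methylation_expression_correlation
from .footprint_inference import (
    ClassifierParams,
    TRUTH_TO_STATE,
    classify_matrix,
    occupancy_profile,
    state_population_summary,
)
from .locus_model import (
    DataError,
    GenomicInterval,
    LocusModel,
    build_locus_model,
    scan_candidate_asps,
)
from .methylation_analysis import (
    fully_unmethylated_fraction,
    percent_methylation,
    qc_clones,
    strand_distribution,
)
from .synthetic_data import (
    CohortConfig,
    GroupSpec,
    SimulationConfig,
    genes_from_annotations,
    make_synthetic_genome,
    repeats_from_annotations,
    simulate_cohort,
    simulate_dataset,
    synthetic_promoter_locus,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA / TSV / annotation I/O


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into ``(id, sequence)`` pairs; duplicate ids are an error."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    return records


def read_fasta_with_descriptions(path: str | Path) -> list[tuple[str, str, str]]:
    """Like :func:`read_fasta` but keeps the description line."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, rec.description, str(rec.seq).upper()))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str] | tuple[str, str, str]]) -> None:
    """Write ``(id, seq)`` or ``(id, description, seq)`` records, wrapped at 60 columns."""
    seen = set()
    seqs = []
    for rec in records:
        if len(rec) == 2:
            rid, desc, seq = rec[0], "", rec[1]
        else:
            rid, desc, seq = rec
        if rid in seen:
            raise DataError(f"duplicate sequence id {rid!r}")
        seen.add(rid)
        seqs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(seqs, str(path), "fasta")


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a header-rowed TSV (UTF-8, ``#`` comment lines allowed, CRLF ok).

    Ragged rows are an error naming the offending line.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise DataError(f"{path}: empty table")
    width = len(lines[0].split("\t"))
    for i, ln in enumerate(lines[1:], start=2):
        if len(ln.split("\t")) != width:
            raise DataError(f"{path}: ragged row at line {i} (expected {width} columns)")
    return pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")


def write_tsv(
    path: str | Path,
    df: pd.DataFrame,
    header_lines: Sequence[str] = (),
) -> None:
    """Write a TSV with optional ``#``-prefixed provenance header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_annotations(path: str | Path, bed: bool = False) -> pd.DataFrame:
    """Read an annotation TSV (chrom, start, end, strand, feature[, name]).

    Coordinates are 1-based inclusive by default; with ``bed=True`` the
    start/end columns are interpreted as 0-based half-open BED coordinates
    and converted on read.
    """
    df = read_tsv(path)
    required = {"chrom", "start", "end", "strand", "feature"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing annotation columns {sorted(missing)}")
    df = df.copy()
    if bed:
        df["start"] = df["start"].astype(int) + 1
        df["end"] = df["end"].astype(int)
    return df


def annotations_to_intervals(df: pd.DataFrame) -> dict[str, GenomicInterval]:
    """Convert a locus annotation table into the named-interval mapping
    expected by :func:`~l1asp.locus_model.build_locus_model`."""
    out = {}
    for _, row in df.iterrows():
        out[str(row["feature"])] = GenomicInterval(
            str(row["chrom"]), int(row["start"]), int(row["end"]), str(row["strand"])
        )
    return out


def locus_annotation_frame(locus: LocusModel) -> pd.DataFrame:
    rows = [
        (locus.interval.chrom, locus.interval.start, locus.interval.end, locus.interval.strand, "locus"),
        (locus.interval.chrom, locus.tss_sense, locus.tss_sense, "+", "tss_sense"),
        (locus.interval.chrom, locus.tss_antisense, locus.tss_antisense, "-", "tss_antisense"),
        (locus.l1_interval.chrom, locus.l1_interval.start, locus.l1_interval.end, locus.l1_interval.strand, "l1"),
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "feature"])


def site_map_frame(locus: LocusModel) -> pd.DataFrame:
    rows = [(p, "cpg") for p in locus.site_map.cpg_sites]
    rows += [(p, "gpc") for p in locus.site_map.gpc_sites]
    rows += [(p, "excluded") for p in locus.site_map.excluded_sites]
    rows.sort()
    return pd.DataFrame(rows, columns=["position", "class"])


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one validated, hashable object."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    min_conversion: float = 0.95
    roc_direction: str = "low"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_conversion <= 1.0:
            raise DataError("min_conversion must be in [0, 1]")
        if self.roc_direction not in ("low", "high"):
            raise DataError("roc_direction must be 'low' or 'high'")

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = PipelineConfig(**{**self.to_kwargs(), "seed": seed})
        cfg.simulation.seed = seed
        cfg.cohort.seed = seed + 1
        return cfg

    def to_kwargs(self) -> dict:
        return {
            "simulation": dataclasses.replace(self.simulation),
            "cohort": dataclasses.replace(self.cohort),
            "classifier": dataclasses.replace(self.classifier),
            "min_conversion": self.min_conversion,
            "roc_direction": self.roc_direction,
            "seed": self.seed,
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> list[str]:
        return [
            f"l1asp {__version__}",
            f"config_hash {self.config_hash()}",
            f"seed {self.seed}",
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"invalid config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw["simulation"])
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "groups" in c:
                c["groups"] = {k: GroupSpec(**v) for k, v in c["groups"].items()}
            kwargs["cohort"] = CohortConfig(**c)
        if "classifier" in raw:
            kwargs["classifier"] = ClassifierParams(**raw["classifier"])
        for key in ("min_conversion", "roc_direction", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Pipeline stages


def run_simulate(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Write a complete synthetic dataset to ``outdir``.

    Files: reference.fasta, locus.tsv, sites.tsv, clones.fasta (ground-truth
    state in the description line), truth.tsv, cohort.tsv, config.json.
    Re-running with the same config is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = cfg.provenance()
    locus = synthetic_promoter_locus(nucleosome_length=cfg.simulation.nucleosome_length)
    ds = simulate_dataset(locus, cfg.simulation)
    if cfg.simulation.n_molecules == 0:
        logger.warning("n_molecules is 0: writing an empty clone FASTA")

    write_fasta(
        outdir / "reference.fasta",
        [(locus.interval.chrom, str(locus.interval), locus.reference)],
    )
    write_tsv(outdir / "locus.tsv", locus_annotation_frame(locus), prov)
    write_tsv(outdir / "sites.tsv", site_map_frame(locus), prov)
    write_fasta(
        outdir / "clones.fasta",
        [
            (cid, f"state={mol.state_label}", read)
            for cid, mol, read in zip(ds.clone_ids, ds.molecules, ds.reads)
        ],
    )
    write_tsv(
        outdir / "truth.tsv",
        pd.DataFrame({"clone_id": ds.clone_ids, "state": ds.state_labels}),
        prov,
    )
    write_tsv(outdir / "cohort.tsv", simulate_cohort(cfg.cohort), prov)
    with open(outdir / "config.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"config": cfg.to_dict(), "hash": cfg.config_hash(), "version": __version__},
            fh,
            indent=2,
            sort_keys=True,
            default=str,
        )
        fh.write("\n")
    logger.info("simulated %d clones into %s", len(ds.clone_ids), outdir)
    return outdir


def _load_locus(indir: Path) -> LocusModel:
    ref_records = read_fasta(indir / "reference.fasta")
    if len(ref_records) != 1:
        raise DataError(f"{indir / 'reference.fasta'}: expected exactly one reference record")
    reference = ref_records[0][1]
    ann = annotations_to_intervals(read_annotations(indir / "locus.tsv"))
    return build_locus_model(reference, ann)


def run_analyze(cfg: PipelineConfig, indir: str | Path, outdir: str | Path) -> dict:
    """Analyze a dataset directory end to end; returns the results in memory.

    Stages: locus loading, clone QC + methylation calling, footprint calling
    and promoter-state classification, occupancy profile, strand statistics,
    cohort statistics (when cohort.tsv is present) and ground-truth recovery
    (when truth.tsv is present).  Stage failures abort with the stage name.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = cfg.provenance()
    results: dict = {}

    def stage(name):
        logger.info("stage: %s", name)

    stage("locus")
    try:
        locus = _load_locus(indir)
    except FileNotFoundError as exc:
        raise DataError(f"stage locus: missing input {exc.filename}") from exc

    stage("methylation-calling")
    try:
        clones = [
            (cid, seq) for cid, _desc, seq in read_fasta_with_descriptions(indir / "clones.fasta")
        ]
    except FileNotFoundError as exc:
        raise DataError(f"stage methylation-calling: missing input {exc.filename}") from exc
    matrix, qc_report = qc_clones(clones, locus, cfg.min_conversion)
    n_dropped = int((~qc_report["passed"]).sum())
    if n_dropped:
        logger.info("dropped %d clones failing conversion QC", n_dropped)
    write_tsv(outdir / "qc.tsv", qc_report, prov)
    frame = matrix.to_frame().reset_index()
    write_tsv(outdir / "callmatrix.tsv", frame, prov)
    (outdir / "lollipop.txt").write_text(matrix.lollipop() + "\n", encoding="utf-8")
    results["matrix"] = matrix
    results["qc"] = qc_report

    stage("methylation-statistics")
    cpg_summary = percent_methylation(matrix.subset(site_class="cpg"))
    meth_df = cpg_summary.per_site.rename_axis("position").reset_index()
    write_tsv(outdir / "methylation.tsv", meth_df, prov)
    pur = fully_unmethylated_fraction(matrix.subset(site_class="cpg"))
    dist = strand_distribution(matrix.subset(site_class="cpg"))
    dist_df = pd.DataFrame(
        {
            "bin_start": dist.bin_edges[:-1],
            "bin_end": dist.bin_edges[1:],
            "count": dist.counts,
        }
    )
    write_tsv(outdir / "strand_distribution.tsv", dist_df, prov)
    write_tsv(
        outdir / "strand_summary.tsv",
        pd.DataFrame(
            [
                {
                    "pur_percent": pur.percent,
                    "n_retained": pur.n_retained,
                    "n_dropped": pur.n_dropped,
                    "exact_zero": dist.exact_zero,
                    "exact_hundred": dist.exact_hundred,
                    "mean_cpg_methylation": cpg_summary.mean,
                }
            ]
        ),
        prov,
    )
    results["pur"] = pur
    results["cpg_summary"] = cpg_summary

    stage("footprinting")
    calls, fps = classify_matrix(matrix, locus, cfg.classifier)
    fp_rows = []
    for cid, mol_fps in zip(matrix.clone_ids, fps):
        for fp in mol_fps:
            fp_rows.append(
                {
                    "clone_id": cid,
                    "chrom": fp.span.chrom,
                    "start": fp.span.start,
                    "end": fp.span.end,
                    "n_protected_sites": fp.n_protected_sites,
                    "class": fp.classification,
                }
            )
    write_tsv(
        outdir / "footprints.tsv",
        pd.DataFrame(
            fp_rows,
            columns=["clone_id", "chrom", "start", "end", "n_protected_sites", "class"],
        ),
        prov,
    )
    state_df = pd.DataFrame(
        {
            "clone_id": [c.molecule_id for c in calls],
            "state": [c.state for c in calls],
            "protected_fraction": [c.evidence.get("protected_fraction", np.nan) for c in calls],
        }
    )
    write_tsv(outdir / "states.tsv", state_df, prov)
    summary = state_population_summary(calls)
    write_tsv(outdir / "state_summary.tsv", summary, prov)
    prof = occupancy_profile(matrix)
    write_tsv(
        outdir / "occupancy.tsv",
        pd.DataFrame(
            {
                "position": prof.positions,
                "protected_frequency": prof.frequency,
                "n_informative": prof.n_informative,
            }
        ),
        prov,
    )
    results["states"] = calls
    results["state_summary"] = summary

    truth_path = indir / "truth.tsv"
    if truth_path.exists():
        stage("truth-recovery")
        truth = read_tsv(truth_path).set_index("clone_id")["state"]
        rows = []
        correct = 0
        n = 0
        for call in calls:
            if call.molecule_id not in truth.index:
                continue
            expected = TRUTH_TO_STATE.get(truth[call.molecule_id], "other")
            ok = call.state == expected
            correct += ok
            n += 1
            rows.append(
                {"clone_id": call.molecule_id, "truth": expected, "called": call.state, "correct": ok}
            )
        acc = correct / n if n else float("nan")
        write_tsv(outdir / "recovery.tsv", pd.DataFrame(rows), prov + [f"accuracy {acc:.4f}"])
        results["accuracy"] = acc

    cohort_path = indir / "cohort.tsv"
    if cohort_path.exists():
        stage("cohort-statistics")
        cohort = read_tsv(cohort_path)
        gs = group_summary(cohort, "methylation")
        write_tsv(outdir / "stats_groups.tsv", gs.per_group, prov)
        write_tsv(outdir / "stats_contrasts.tsv", gs.contrasts, prov)
        corr = methylation_expression_correlation(cohort)
        write_tsv(
            outdir / "stats_correlation.tsv",
            pd.DataFrame(
                [{"spearman_rho": corr.rho, "p": corr.p, "sign": corr.sign, "n": corr.n}]
            ),
            prov,
        )
        results["group_summary"] = gs
        results["correlation"] = corr

    return results


def run_scan(
    annotations: pd.DataFrame,
    outdir: str | Path,
    min_full_length: int = 6000,
    provenance: Sequence[str] = (),
) -> pd.DataFrame:
    """Scan an annotation table for candidate antisense-L1 promoters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = genes_from_annotations(annotations)
    repeats = repeats_from_annotations(annotations)
    candidates = scan_candidate_asps(genes, repeats, min_full_length)
    df = pd.DataFrame(
        [
            {
                "chrom": c.l1.chrom,
                "start": c.l1.start,
                "end": c.l1.end,
                "strand": c.l1.strand,
                "host_gene": c.host_gene,
                "transcript_strand": c.transcript.strand,
                "predicted_tss": c.transcript.tss,
            }
            for c in candidates
        ],
        columns=[
            "chrom", "start", "end", "strand", "host_gene", "transcript_strand", "predicted_tss",
        ],
    )
    write_tsv(outdir / "asp_candidates.tsv", df, provenance)
    return df
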