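"""End-to-end scan pipeline: load/merge -> scan -> cluster -> recall -> LD.

The pipeline mirrors the analyst's workflow for a lethal-haplotype
scan: merge genotype datasets on their shared variants, run the
homozygote-deficit scan with FDR control, cluster flagged variants into
adjacent candidate blocks, re-call any flagged variant for which raw
intensities are available (then re-test it, so calling artifacts clear
themselves), shortlist variants in strong LD with each block member,
and write a reproducible report with full provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from lethscan.errors import LethscanError
from lethscan.hwe import (
    CandidateBlock,
    DeficitTestResult,
    ScanConfig,
    cluster_adjacent,
    population_summary,
    scan_deficit,
)
from lethscan.io import (
    GenotypeMatrix,
    VariantQualityFilter,
    merge_on_common_variants,
    read_plink_text,
    read_vcf,
    write_report,
)
from lethscan.ld import LDConfig, LDStat, shortlist_linked
from lethscan.recall import IntensityPanel, recall_variant

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable description of one pipeline run."""

    ped_map_pairs: list[tuple[str, str]] = field(default_factory=list)
    vcf_paths: list[str] = field(default_factory=list)
    population_path: str | None = None
    quality_filter: VariantQualityFilter | None = None
    scan: ScanConfig = field(default_factory=ScanConfig)
    ld: LDConfig = field(default_factory=LDConfig)
    intensity_paths: dict[str, str] = field(default_factory=dict)  # "chrom:pos" -> TSV
    call_threshold: float = 0.95
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where outputs land must not change them
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ScanReport:
    """Everything one pipeline run produced."""

    results: list[DeficitTestResult]
    blocks: list[CandidateBlock]
    singletons: list[DeficitTestResult]  # flagged but isolated -> discarded
    summary: pd.DataFrame | None
    shortlists: dict[str, list[LDStat]]  # block label -> linked variants
    recall_changes: pd.DataFrame
    provenance: dict


def _load_population(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample_id"], df["population"]))


def _read_intensity_tsv(path: str, variant) -> IntensityPanel:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "x", "y"}
    if not required <= set(df.columns):
        raise LethscanError(f"{path}: intensity TSV needs columns {sorted(required)}")
    return IntensityPanel(
        variant=variant,
        samples=df["sample_id"].tolist(),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
    )


def load_inputs(config: PipelineConfig) -> GenotypeMatrix:
    """Read all configured inputs and merge them on shared variants."""
    matrices: list[GenotypeMatrix] = []
    for ped, map_ in config.ped_map_pairs:
        matrices.append(read_plink_text(ped, map_))
    for path in config.vcf_paths:
        matrices.append(read_vcf(path, config.quality_filter))
    if not matrices:
        raise LethscanError("pipeline config lists no input datasets")
    matrix = matrices[0] if len(matrices) == 1 else merge_on_common_variants(matrices)
    if config.population_path:
        pop = _load_population(config.population_path)
        matrix.population = {s: pop.get(s, "unassigned") for s in matrix.samples}
    return matrix


def _results_frame(results: list[DeficitTestResult], block_of: dict[int, str]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "chrom": r.variant.chrom,
                "pos": r.variant.pos,
                "id": r.variant.id,
                "nAA": r.counts.n_AA,
                "nAB": r.counts.n_AB,
                "nBB": r.counts.n_BB,
                "nmiss": r.counts.n_missing,
                "maf": r.q,
                "expected_minor_hom": r.expected_minor_hom,
                "observed_minor_hom": r.observed_minor_hom,
                "p_hwe": r.p_hwe,
                "q_value": r.q_value,
                "tested": r.tested,
                "flagged": r.flagged,
                "block_id": block_of.get(r.index, ""),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, matrix: GenotypeMatrix | None = None) -> ScanReport:
    """Run the full scan workflow; see the module docstring for stages.

    ``matrix`` may be passed directly (e.g. a simulated cohort) instead
    of configuring input files.  With ``out_dir`` set, writes scan.tsv,
    blocks.tsv, table1.tsv, linked_<block>.tsv, recall_changes.tsv,
    report.json and the effective config beside the outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    if matrix is None:
        matrix = load_inputs(config)
    logger.info("scanning %d variants x %d samples", matrix.n_variants, matrix.n_samples)

    results = scan_deficit(matrix, config.scan)

    # recall-then-rescan: any flagged variant with intensities available
    changes_frames = []
    if config.intensity_paths:
        for r in results:
            key = f"{r.variant.chrom}:{r.variant.pos}"
            if r.flagged and key in config.intensity_paths:
                panel = _read_intensity_tsv(config.intensity_paths[key], r.variant)
                matrix, changes = recall_variant(
                    matrix, panel, seed=config.seed, call_threshold=config.call_threshold
                )
                if not changes.empty:
                    changes = changes.assign(chrom=r.variant.chrom, pos=r.variant.pos)
                    changes_frames.append(changes)
        if changes_frames:
            results = scan_deficit(matrix, config.scan)  # re-test after recalling
    recall_changes = (
        pd.concat(changes_frames, ignore_index=True)
        if changes_frames
        else pd.DataFrame(columns=["sample_id", "old_call", "new_call", "posterior", "chrom", "pos"])
    )

    blocks = cluster_adjacent(results, config.scan)
    in_block = {m.index for b in blocks for m in b.members}
    singletons = [r for r in results if r.flagged and r.index not in in_block]

    shortlists: dict[str, list[LDStat]] = {}
    for b in blocks:
        label = f"{b.chrom}_{b.members[0].variant.pos}"
        best = min(b.members, key=lambda m: m.q_value)
        shortlists[label] = shortlist_linked(matrix, best.variant, config.ld)

    summary = None
    block_indices = sorted(in_block)
    if block_indices:
        summary = population_summary(matrix, block_indices)

    from lethscan import __version__

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_samples": matrix.n_samples,
        "n_variants": matrix.n_variants,
    }
    report = ScanReport(
        results=results,
        blocks=blocks,
        singletons=singletons,
        summary=summary,
        shortlists=shortlists,
        recall_changes=recall_changes,
        provenance=provenance,
    )
    if config.out_dir:
        _write_outputs(report, config)
    return report


def _write_outputs(report: ScanReport, config: PipelineConfig) -> None:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    block_of: dict[int, str] = {}
    for b in report.blocks:
        label = f"{b.chrom}_{b.members[0].variant.pos}"
        for m in b.members:
            block_of[m.index] = label
    scan_df = _results_frame(report.results, block_of)
    write_report(scan_df, os.path.join(out, "scan.tsv"), "tsv", allow_empty=True)

    block_rows = [
        {
            "block_id": f"{b.chrom}_{b.members[0].variant.pos}",
            "chrom": b.chrom,
            "start": b.members[0].variant.pos,
            "end": b.members[-1].variant.pos,
            "size": b.size,
            "span_bp": b.span_bp,
            "min_q_value": b.min_q_value,
        }
        for b in report.blocks
    ]
    write_report(pd.DataFrame(block_rows), os.path.join(out, "blocks.tsv"), "tsv", allow_empty=True)

    if report.summary is not None:
        write_report(report.summary, os.path.join(out, "table1.tsv"), "tsv", allow_empty=True)
    for label, stats in report.shortlists.items():
        rows = [
            {
                "chrom": s.partner_variant.chrom,
                "pos": s.partner_variant.pos,
                "id": s.partner_variant.id,
                "r2": s.r2,
                "dprime": s.D_prime,
                "p11": s.hap_freqs[0],
                "p12": s.hap_freqs[1],
                "p21": s.hap_freqs[2],
                "p22": s.hap_freqs[3],
                "n_used": s.n_used,
            }
            for s in stats
        ]
        write_report(
            pd.DataFrame(rows), os.path.join(out, f"linked_{label}.tsv"), "tsv", allow_empty=True
        )
    write_report(
        report.recall_changes, os.path.join(out, "recall_changes.tsv"), "tsv", allow_empty=True
    )
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(
            {
                "provenance": report.provenance,
                "n_flagged": int(sum(r.flagged for r in report.results)),
                "n_blocks": len(report.blocks),
                "n_singletons_discarded": len(report.singletons),
                "blocks": block_rows,
            },
            fh,
            indent=1,
        )
        fh.write("\n")
    with open(os.path.join(out, "config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, default=str)
        fh.write("\n")


def format_table1(report: ScanReport) -> pd.DataFrame:
    """Per-population genotype table for the candidate block variants.

    One row per population x block variant: sample size, observed
    (minor hom, het, major hom), rounded expected minor homozygotes
    under HWE, exact-test p and significance star — the classic
    reporting layout for a candidate lethal haplotype.
    """
    if report.summary is None or report.summary.empty:
        logger.warning("no candidate blocks: empty population table")
        return pd.DataFrame()
    return report.summary.copy()
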