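"""Genotype I/O: PLINK text (PED/MAP), VCF, dataset merging, reports.

Genotype calls are stored as an int8 samples x variants array counting
copies of ``allele_B`` (0, 1, 2) with :data:`MISSING` (-1) for no-calls.
Coordinates are 1-based ``chrom:pos``, the convention of both VCF and
the array annotation files this package consumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lethscan.errors import (
    AlleleConflictError,
    FormatError,
    LethscanError,
    MergeError,
    TriallelicError,
)

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1


@dataclass(frozen=True)
class VariantDef:
    """A biallelic variant: 1-based coordinates plus its two allele labels."""

    chrom: str
    pos: int
    id: str
    allele_A: str
    allele_B: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.allele_A == self.allele_B:
            raise ValueError(
                f"variant {self.chrom}:{self.pos} has identical alleles "
                f"{self.allele_A!r}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class GenotypeMatrix:
    """Samples x variants genotype calls with map coordinates.

    Parameters
    ----------
    variants
        Variant definitions sorted by (chrom, pos); duplicates rejected.
    samples
        Sample identifiers, unique.
    calls
        ``(n_samples, n_variants)`` int8 array of allele_B copy counts,
        :data:`MISSING` for no-calls.
    population
        Optional sample id -> population/breed label mapping.
    """

    variants: list[VariantDef]
    samples: list[str]
    calls: np.ndarray
    population: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) among variants")
        if keys != sorted(keys, key=lambda k: (k[0], k[1])):
            raise ValueError("variants must be sorted by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, chrom: str, pos: int) -> int:
        """Index of the variant at ``chrom:pos``; KeyError if absent."""
        for i, v in enumerate(self.variants):
            if v.chrom == chrom and v.pos == pos:
                return i
        raise KeyError(f"no variant at {chrom}:{pos}")

    def subset_variants(self, indices: list[int]) -> "GenotypeMatrix":
        variants = [self.variants[i] for i in indices]
        return GenotypeMatrix(
            variants=variants,
            samples=list(self.samples),
            calls=self.calls[:, indices].copy(),
            population=dict(self.population) if self.population else None,
        )


@dataclass(frozen=True)
class VariantQualityFilter:
    """Site-level hard filter: mean depth and Phred quality, both strict >."""

    min_depth: float = 10.0
    min_qual: float = 20.0

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_qual < 0:
            raise ValueError("filter thresholds must be >= 0")


def _sorted_variant_order(variants: list[VariantDef]) -> list[int]:
    return sorted(range(len(variants)), key=lambda i: variants[i].key)


def read_plink_text(ped_path: str, map_path: str) -> GenotypeMatrix:
    """Read a PLINK text fileset (.ped + .map) into a GenotypeMatrix.

    The PED format carries two allele columns per MAP variant after six
    mandatory columns (family, individual, father, mother, sex,
    phenotype); allele code "0" means missing.  ``allele_A``/``allele_B``
    are assigned per variant from the observed alleles in lexicographic
    order, so calls count copies of the lexicographically later allele.
    The family id is kept as the sample's population label.
    """
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 columns")
            chrom, vid, _cm, pos = fields[0], fields[1], fields[2], fields[3]
            map_rows.append((chrom, vid, int(pos)))

    n_var = len(map_rows)
    sample_ids: list[str] = []
    population: dict[str, str] = {}
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_var:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_var} columns "
                    f"for {n_var} MAP variants, got {len(fields)}"
                )
            fam, iid = fields[0], fields[1]
            sample_ids.append(iid)
            population[iid] = fam
            allele_pairs.append(
                [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(n_var)]
            )

    calls = np.full((len(sample_ids), n_var), MISSING, dtype=np.int8)
    variants: list[VariantDef] = []
    for j, (chrom, vid, pos) in enumerate(map_rows):
        observed = sorted(
            {a for pair in allele_pairs for a in (pair[j][0], pair[j][1]) if a != "0"}
        )
        if len(observed) > 2:
            raise TriallelicError(
                f"variant {vid} ({chrom}:{pos}) has alleles {observed}"
            )
        if len(observed) == 0:
            observed = ["A", "B"]  # all-missing column keeps placeholder labels
        elif len(observed) == 1:
            # monomorphic: invent a distinct placeholder for allele_B
            observed = [observed[0], observed[0] + "*"]
        a_ref, a_alt = observed[0], observed[1]
        variants.append(VariantDef(chrom, pos, vid, a_ref, a_alt))
        for i, pairs in enumerate(allele_pairs):
            a1, a2 = pairs[j]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == a_alt) + (a2 == a_alt)

    order = _sorted_variant_order(variants)
    return GenotypeMatrix(
        variants=[variants[k] for k in order],
        samples=sample_ids,
        calls=calls[:, order],
        population=population,
    )


def write_plink_text(matrix: GenotypeMatrix, ped_path: str, map_path: str) -> None:
    """Write a GenotypeMatrix as a PLINK text fileset (round-trip safe)."""
    with open(map_path, "w") as fh:
        for v in matrix.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\n")
    pop = matrix.population or {}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(matrix.samples):
            fam = pop.get(sid, "FAM")
            cols = [fam, sid, "0", "0", "0", "-9"]
            for j, v in enumerate(matrix.variants):
                g = matrix.calls[i, j]
                if g == MISSING:
                    cols += ["0", "0"]
                elif g == 0:
                    cols += [v.allele_A, v.allele_A]
                elif g == 1:
                    cols += [v.allele_A, v.allele_B]
                else:
                    cols += [v.allele_B, v.allele_B]
            fh.write(" ".join(cols) + "\n")


def read_vcf(
    vcf_path: str, filter: VariantQualityFilter | None = None
) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, optionally hard-filtering sites.

    Only biallelic records are kept (multi-allelic records are skipped
    with a logged count).  With a filter, a record is dropped unless its
    mean per-sample FORMAT/DP over non-missing samples is strictly
    greater than ``min_depth`` and its QUAL strictly greater than
    ``min_qual``.  Half-calls and ``./.`` become :data:`MISSING`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(vcf_path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot read VCF header of {vcf_path}: {exc}") from exc

    samples = list(vcf.samples)
    variants: list[VariantDef] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    n_filtered = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if filter is not None:
            depths = rec.format("DP")
            if depths is not None:
                d = np.asarray(depths, dtype=float).ravel()
                d = d[(d >= 0) & np.isfinite(d)]
                mean_dp = float(d.mean()) if d.size else 0.0
            else:
                mean_dp = 0.0
            qual = rec.QUAL if rec.QUAL is not None else 0.0
            if not (mean_dp > filter.min_depth and qual > filter.min_qual):
                n_filtered += 1
                continue
        # gt_types: 0=hom ref, 1=het, 2=hom alt (cyvcf2 gts012), 3=unknown
        vcf_like = rec.genotype.array()  # (n_samples, ploidy+1)
        alleles = vcf_like[:, :-1]
        col = np.where(
            (alleles < 0).any(axis=1), MISSING, (alleles > 0).sum(axis=1)
        ).astype(np.int8)
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        variants.append(VariantDef(rec.CHROM, rec.POS, vid, rec.REF, rec.ALT[0]))
        columns.append(col)
    if n_multi:
        logger.info("skipped %d multi-allelic records in %s", n_multi, vcf_path)
    if n_filtered:
        logger.info("dropped %d records failing quality filter", n_filtered)
    if not variants:
        logger.warning("no records survived in %s", vcf_path)
        return GenotypeMatrix(
            variants=[],
            samples=samples,
            calls=np.empty((len(samples), 0), dtype=np.int8),
        )
    calls = np.column_stack(columns).astype(np.int8)
    order = _sorted_variant_order(variants)
    return GenotypeMatrix(
        variants=[variants[k] for k in order], samples=samples, calls=calls[:, order]
    )


def merge_on_common_variants(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge datasets on their shared (chrom, pos) variants.

    Allele coding is harmonized to the first matrix: where a later
    matrix labels the same site with alleles swapped, its codes are
    flipped 0<->2.  Incompatible allele sets raise
    :class:`AlleleConflictError`; palindromic strand ambiguity is not
    resolved.  Samples are concatenated (ids must be disjoint) and
    population labels preserved.
    """
    if len(matrices) < 2:
        raise MergeError("need at least two matrices to merge")
    all_ids = [s for m in matrices for s in m.samples]
    if len(set(all_ids)) != len(all_ids):
        raise MergeError("sample ids overlap across matrices")

    common = set(v.key for v in matrices[0].variants)
    for m in matrices[1:]:
        common &= {v.key for v in m.variants}
    if not common:
        raise MergeError("no shared (chrom, pos) variants across matrices")

    ref = matrices[0]
    ref_idx = [i for i, v in enumerate(ref.variants) if v.key in common]
    out_variants = [ref.variants[i] for i in ref_idx]

    blocks = [ref.calls[:, ref_idx]]
    for m in matrices[1:]:
        lookup = {v.key: j for j, v in enumerate(m.variants)}
        cols = []
        for v in out_variants:
            j = lookup[v.key]
            w = m.variants[j]
            col = m.calls[:, j]
            if (w.allele_A, w.allele_B) == (v.allele_A, v.allele_B):
                cols.append(col)
            elif (w.allele_A, w.allele_B) == (v.allele_B, v.allele_A):
                flipped = col.copy()
                nz = flipped != MISSING
                flipped[nz] = 2 - flipped[nz]
                cols.append(flipped)
            else:
                raise AlleleConflictError(
                    f"variant {v.chrom}:{v.pos}: alleles "
                    f"{{{v.allele_A},{v.allele_B}}} vs {{{w.allele_A},{w.allele_B}}}"
                )
        blocks.append(np.column_stack(cols).astype(np.int8))

    population: dict[str, str] = {}
    for m in matrices:
        if m.population:
            population.update(m.population)
    return GenotypeMatrix(
        variants=out_variants,
        samples=all_ids,
        calls=np.vstack(blocks),
        population=population or None,
    )


def write_report(
    rows, path: str, format: str = "tsv", allow_empty: bool = False
) -> None:
    """Write tabular records as TSV (header + tab-delimited) or JSON array.

    Column order is taken from the input (first record for dict rows),
    so repeated calls on the same rows are byte-identical.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame(rows)
    if df.empty and not allow_empty:
        raise LethscanError("refusing to write an empty report (allow_empty=False)")
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        records = df.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1, default=str)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
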