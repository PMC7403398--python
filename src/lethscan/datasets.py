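"""Published genotype counts for the candidate lethal haplotype.

Genotype counts at the two adjacent candidate SNPs (6:38278097,
rs68661802 and 6:38278874, rs68663106; EquCab2.0 coordinates, intronic
in *LY49B*) as reported across horse breed panels.  Counts are ordered
(minor homozygotes, heterozygotes, major homozygotes); the per-breed n
used downstream is the genotype sum.  These printed counts are the
desk-scale input for reproducing the published expectation and
carrier-frequency numbers without access to the restricted raw data.
"""

from __future__ import annotations

from lethscan.hwe import GenotypeCounts

#: The two candidate SNPs, 1-based EquCab2.0 coordinates.
CANDIDATE_SNPS = (("6", 38_278_097, "rs68661802"), ("6", 38_278_874, "rs68663106"))

#: breed -> (counts at SNP 6:38278097, counts at 6:38278874)
TABLE1_COUNTS: dict[str, tuple[GenotypeCounts, GenotypeCounts]] = {
    "Australian Thoroughbred": (
        GenotypeCounts(n_AA=90, n_AB=66, n_BB=0),
        GenotypeCounts(n_AA=90, n_AB=66, n_BB=0),
    ),
    "Japanese Thoroughbred": (
        GenotypeCounts(n_AA=253, n_AB=117, n_BB=0),
        GenotypeCounts(n_AA=253, n_AB=117, n_BB=0),
    ),
    "Swedish Warmblood": (
        GenotypeCounts(n_AA=304, n_AB=75, n_BB=0),
        GenotypeCounts(n_AA=306, n_AB=74, n_BB=0),
    ),
    "Coldblooded Trotter": (
        GenotypeCounts(n_AA=388, n_AB=258, n_BB=0),
        GenotypeCounts(n_AA=393, n_AB=226, n_BB=22),
    ),
    "Quarter Horse": (
        GenotypeCounts(n_AA=40, n_AB=97, n_BB=0),
        GenotypeCounts(n_AA=40, n_AB=97, n_BB=0),
    ),
    "Exmoor Pony": (
        GenotypeCounts(n_AA=279, n_AB=1, n_BB=0),
        GenotypeCounts(n_AA=282, n_AB=1, n_BB=0),
    ),
}


def pooled_thoroughbred_counts(snp: int = 0) -> GenotypeCounts:
    """Australian + Japanese Thoroughbred counts pooled at one SNP."""
    a = TABLE1_COUNTS["Australian Thoroughbred"][snp]
    b = TABLE1_COUNTS["Japanese Thoroughbred"][snp]
    return GenotypeCounts(
        n_AA=a.n_AA + b.n_AA, n_AB=a.n_AB + b.n_AB, n_BB=a.n_BB + b.n_BB
    )
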