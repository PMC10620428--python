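"""Cis-instrument selection for drug-target MR.

The selection flow mirrors standard drug-proxy practice: take every
variant inside the target gene's gene/promoter/enhancer intervals,
keep those associated with the biomarker at a Bonferroni-corrected
threshold (alpha divided by the cumulative region SNP count n), greedily
LD-clump the survivors (r² and distance cut-offs combined with AND), and
drop palindromic (A/T, C/G) variants unconditionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .exceptions import ConfigurationError, EmptyRegionError, LDMatrixError
from .io import GenomicRegion, LDMatrix, VariantAssociation

logger = logging.getLogger(__name__)

PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))


@dataclass
class SelectionConfig:
    """Tuning knobs of the selection flow.

    alpha is the family-wise error budget spread over the region SNPs;
    r2_max and window_bp define clumping (a variant is discarded only if
    both linked to and near an index); strict_ld errors on pairs missing
    from the LD matrix instead of treating them as unlinked.
    """

    alpha: float = 0.05
    r2_max: float = 0.1
    window_bp: int = 1_000_000
    exclude_palindromic: bool = True
    strict_ld: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0 <= self.r2_max <= 1:
            raise ConfigurationError("r2_max must be in [0, 1]")
        if self.window_bp <= 0:
            raise ConfigurationError("window_bp must be positive")


@dataclass
class InstrumentSelectionReport:
    """Counts at each stage of the selection flow plus the kept set."""

    target_gene: str
    n_region_snps: int
    p_threshold: float
    n_significant: int
    n_post_clump: int
    n_post_palindrome: int
    kept_rsids: list = field(default_factory=list)
    instruments: list = field(default_factory=list, repr=False)


def is_palindromic(assoc: VariantAssociation) -> bool:
    return assoc.alleles in PALINDROMIC_PAIRS


def extract_region_snps(assocs: list[VariantAssociation],
                        regions: list[GenomicRegion],
                        target_gene: str) -> list[VariantAssociation]:
    """Variants inside any of the target's intervals (union, deduplicated).

    The count of the returned set is the Bonferroni denominator n.
    """
    target_regions = [r for r in regions if r.target_gene == target_gene]
    if not target_regions:
        raise ConfigurationError(
            f"no regions in catalog for target gene {target_gene!r}")
    kept, seen = [], set()
    for a in assocs:
        if a.rsid in seen:
            continue
        if any(r.contains(a.chrom, a.pos) for r in target_regions):
            kept.append(a)
            seen.add(a.rsid)
    return kept


def bonferroni_threshold(alpha: float, n: int) -> float:
    """alpha / n; significance filtering keeps strictly p < threshold."""
    if n < 1:
        raise EmptyRegionError(
            "no region SNPs: Bonferroni denominator is zero")
    return alpha / n


def ld_clump(candidates: list[VariantAssociation], ld: LDMatrix,
             config: SelectionConfig | None = None
             ) -> list[VariantAssociation]:
    """Greedy LD clumping.

    Repeatedly take the smallest-p unclaimed variant as an index
    (p-value ties broken by rsid) and discard every unclaimed variant
    with r² ≥ r2_max to the index AND within window_bp of it.  Output is
    sorted by genomic position.
    """
    config = config or SelectionConfig()
    if config.strict_ld:
        missing = [a.rsid for a in candidates if a.rsid not in ld]
        if missing:
            raise LDMatrixError(
                f"candidates absent from LD matrix: {missing}")
    else:
        absent = [a.rsid for a in candidates if a.rsid not in ld]
        if absent:
            logger.warning(
                "treating %d variant(s) absent from LD matrix as unlinked: %s",
                len(absent), absent)
    pool = sorted(candidates, key=lambda a: (a.pval, a.rsid))
    kept: list[VariantAssociation] = []
    while pool:
        index = pool.pop(0)
        kept.append(index)
        pool = [
            a for a in pool
            if not (ld.lookup(index.rsid, a.rsid, default=0.0) >= config.r2_max
                    and _distance(index, a) <= config.window_bp)
        ]
    return sorted(kept, key=lambda a: (a.chrom, a.pos))


def _distance(a: VariantAssociation, b: VariantAssociation) -> float:
    if a.chrom != b.chrom:
        return float("inf")
    return abs(a.pos - b.pos)


def drop_palindromic(assocs: list[VariantAssociation]
                     ) -> list[VariantAssociation]:
    """Remove A/T and C/G variants unconditionally (no EAF rescue)."""
    return [a for a in assocs if not is_palindromic(a)]


def select_instruments(assocs: list[VariantAssociation],
                       regions: list[GenomicRegion],
                       target_gene: str,
                       ld: LDMatrix,
                       config: SelectionConfig | None = None
                       ) -> InstrumentSelectionReport:
    """Run the full selection flow and record counts at every stage."""
    config = config or SelectionConfig()
    region_snps = extract_region_snps(assocs, regions, target_gene)
    n = len(region_snps)
    threshold = bonferroni_threshold(config.alpha, n)  # raises when n == 0
    significant = [a for a in region_snps if a.pval < threshold]
    clumped = ld_clump(significant, ld, config)
    final = drop_palindromic(clumped) if config.exclude_palindromic \
        else clumped
    logger.info("target %s: n=%d, p<%.3g, %d significant, %d post-clump, "
                "%d post-palindrome", target_gene, n, threshold,
                len(significant), len(clumped), len(final))
    return InstrumentSelectionReport(
        target_gene=target_gene,
        n_region_snps=n,
        p_threshold=threshold,
        n_significant=len(significant),
        n_post_clump=len(clumped),
        n_post_palindrome=len(final),
        kept_rsids=[a.rsid for a in final],
        instruments=final,
    )
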