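"""Synthetic two-sample GWAS summary statistics with known truth.

The generator emulates the statistical structure a drug-target MR
analysis assumes: k weak-to-moderate cis instruments whose exposure
effects (log-biomarker per allele) are measured with small error in a
very large GWAS, outcome effects generated directly on the log-odds
scale as θ·β_X plus configurable pleiotropy, a configurable fraction
of palindromic variants, and block-structured LD for the selection
flow.  Defaults are pitched at the scale of an 18-variant cis proxy
for CRP analysed against a large case-control outcome GWAS (per-variant
exposure effects around 0.08 log-units with SE 0.005, outcome SEs
around 0.04 log-odds, causal slope 0.58 — an OR per unit biomarker
decrease of about 0.56).

No individual-level genotypes are simulated; outcome effects live
directly on the summary-statistic scale, which is exactly what the
estimators consume.  Every randomized operation takes its seed from
the config — there is no global random state.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .io import (
    GenomicRegion,
    LDMatrix,
    VariantAssociation,
    read_ld_matrix,
    read_regions,
    read_sumstats,
    write_ld_matrix,
    write_regions,
    write_sumstats,
)

PLEIOTROPY_REGIMES = ("none", "balanced", "directional", "inside_violating")

_NONPAL_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PAL_PAIRS = (("A", "T"), ("C", "G"))


@dataclass
class SimulationConfig:
    """Generative parameters for a two-sample summary-statistic study."""

    k: int = 18
    theta_true: float = 0.58
    beta_x_scale: float = 0.08
    se_x: float = 0.005
    se_y: float = 0.04
    pleiotropy: str = "none"
    pleiotropy_scale: float = 0.0
    pleiotropy_frac: float = 1.0
    palindrome_frac: float = 0.0
    outcome_flip_frac: float = 0.25
    n_decoys: int = 30
    ld_blocks: tuple = field(default_factory=tuple)  # ((size, r2), ...)
    seed: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ConfigurationError(
                f"unknown pleiotropy regime {self.pleiotropy!r}; "
                f"choose one of {PLEIOTROPY_REGIMES}")
        if min(self.beta_x_scale, self.se_x, self.se_y) <= 0:
            raise ConfigurationError("scales must be positive")
        if not 0 <= self.palindrome_frac <= 1:
            raise ConfigurationError("palindrome_frac must be in [0, 1]")
        if not 0 < self.pleiotropy_frac <= 1:
            raise ConfigurationError("pleiotropy_frac must be in (0, 1]")


def _alleles(rng, n, n_palindromic):
    """Allele pairs: the first ``n_palindromic`` are A/T or C/G."""
    pairs = []
    for j in range(n):
        pool = _PAL_PAIRS if j < n_palindromic else _NONPAL_PAIRS
        pairs.append(pool[rng.integers(len(pool))])
    return pairs


def _pleiotropy_effects(config, bx_true, rng):
    """Per-variant direct effects α_j on the outcome.

    ``pleiotropy_frac`` < 1 restricts the direct effects to a random
    subset of instruments (the rest stay valid), the standard
    contaminated design for studying robust-estimator breakdown.
    """
    mag = config.pleiotropy_scale
    if config.pleiotropy == "none" or mag == 0:
        return np.zeros(config.k)
    if config.pleiotropy == "balanced":
        alpha = rng.normal(0.0, mag, config.k)
    elif config.pleiotropy == "directional":
        # directional on the biomarker-increasing orientation: after
        # estimation-time orientation every direct effect has mean +mag
        alpha = np.sign(bx_true) * rng.normal(mag, mag / 2, config.k)
    else:  # inside_violating: direct effects track instrument strength
        alpha = mag * bx_true / config.beta_x_scale \
            + rng.normal(0.0, mag / 4, config.k)
    if config.pleiotropy_frac < 1:
        n_invalid = int(round(config.pleiotropy_frac * config.k))
        valid = rng.permutation(config.k)[n_invalid:]
        alpha[valid] = 0.0
    return alpha


def simulate_two_sample(config: SimulationConfig
                        ) -> tuple[list[VariantAssociation],
                                   list[VariantAssociation], dict]:
    """Exposure and outcome associations for k instruments, plus truth.

    True exposure effects have magnitude uniform on
    [0.5, 1.5]·beta_x_scale with random sign; observed betas add
    Gaussian noise at the stated SEs.  Outcome betas are
    θ·β_X(true) + α_j + noise with α_j set by the pleiotropy regime.
    A fraction of outcome records is stored on the swapped allele
    orientation (beta negated) to exercise harmonisation; this is
    lossless by construction.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k
    sign = rng.choice([-1.0, 1.0], k)
    bx_true = sign * rng.uniform(0.5, 1.5, k) * config.beta_x_scale
    alpha = _pleiotropy_effects(config, bx_true, rng)
    bx_obs = bx_true + rng.normal(0.0, config.se_x, k)
    by_true = config.theta_true * bx_true + alpha
    by_obs = by_true + rng.normal(0.0, config.se_y, k)

    n_pal = int(round(config.palindrome_frac * k))
    pairs = _alleles(rng, k, n_pal)
    flip = rng.random(k) < config.outcome_flip_frac

    exposure, outcome = [], []
    for j in range(k):
        ea, oa = pairs[j]
        pval = float(2 * stats.norm.sf(abs(bx_obs[j]) / config.se_x))
        exposure.append(VariantAssociation(
            rsid=f"rs{j + 1}", chrom="1", pos=1_000_000 + 50_000 * j,
            effect_allele=ea, other_allele=oa,
            beta=float(bx_obs[j]), se=config.se_x,
            pval=max(pval, 1e-300),
            eaf=float(rng.uniform(0.05, 0.95))))
        o_ea, o_oa, o_beta = (oa, ea, -by_obs[j]) if flip[j] \
            else (ea, oa, by_obs[j])
        o_p = float(2 * stats.norm.sf(abs(by_obs[j]) / config.se_y))
        outcome.append(VariantAssociation(
            rsid=f"rs{j + 1}", chrom="1", pos=1_000_000 + 50_000 * j,
            effect_allele=o_ea, other_allele=o_oa,
            beta=float(o_beta), se=config.se_y,
            pval=max(o_p, 1e-300),
            eaf=float(rng.uniform(0.05, 0.95))))
    truth = {
        "theta_true": config.theta_true,
        "beta_x_true": bx_true.tolist(),
        "pleiotropy_effects": alpha.tolist(),
        "palindromic_rsids": [f"rs{j + 1}" for j in range(n_pal)],
        "config": asdict(config),
    }
    return exposure, outcome, truth


@dataclass
class RegionScenario:
    """A planted selection scenario with its expected outcome."""

    exposure: list
    outcome: list
    regions: list
    ld: LDMatrix
    truth: dict


def simulate_region_scenario(config: SimulationConfig) -> RegionScenario:
    """Plant a selection scenario whose post-selection set is known.

    ``config.k`` significant variants are placed inside the target's
    gene/promoter regions; LD blocks (from ``config.ld_blocks``) group
    the first variants into clumps whose lowest-p member survives;
    ``palindrome_frac`` of the remaining singletons are A/T or C/G and
    are dropped last.  ``n_decoys`` non-significant variants sit inside
    the regions (inflating the Bonferroni denominator) and the same
    number sit outside.  The truth record states the expected counts
    at every selection stage and the expected kept rsids.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k
    target = "GENE1"
    chrom = "1"
    gene_lo = 1_000_001
    gene_hi = gene_lo - 1 + max(1_000_000, 120_000 * (config.k + 2))
    regions = [
        GenomicRegion(target, "gene", chrom, gene_lo, gene_hi),
        GenomicRegion(target, "promoter", chrom, gene_lo - 20_000,
                      gene_lo - 1),
    ]

    block_sizes = [int(s) for s, _ in config.ld_blocks]
    if sum(block_sizes) > k:
        raise ConfigurationError("ld_blocks cover more variants than k")
    n_in_blocks = sum(block_sizes)
    n_single = k - n_in_blocks
    n_pal = int(round(config.palindrome_frac * k))
    if n_pal > n_single:
        raise ConfigurationError(
            "not enough singleton variants to host the palindromes")

    # significant variants: blocks first (members 10 kb apart), then
    # singletons 100 kb apart — all inside the gene region
    pos, block_of = [], []
    cursor = gene_lo + 500
    for b, size in enumerate(block_sizes):
        for _ in range(size):
            pos.append(cursor)
            block_of.append(b)
            cursor += 10_000
        cursor += 90_000
    for _ in range(n_single):
        pos.append(cursor)
        block_of.append(None)
        cursor += 100_000
    if cursor > gene_hi:
        raise ConfigurationError("too many variants for the gene region")

    # z-scores large and distinct: p-values far below any Bonferroni cut
    z = 12.0 + rng.permutation(k).astype(float)
    sign = rng.choice([-1.0, 1.0], k)
    bx = sign * z * config.se_x
    theta = config.theta_true
    by = theta * bx + rng.normal(0.0, config.se_y, k)

    # palindromes among the singletons (dropped after clumping)
    singleton_idx = [j for j in range(k) if block_of[j] is None]
    pal_idx = set(singleton_idx[:n_pal])
    exposure, outcome = [], []
    for j in range(k):
        ea, oa = _PAL_PAIRS[j % 2] if j in pal_idx \
            else _NONPAL_PAIRS[j % len(_NONPAL_PAIRS)]
        pval = float(2 * stats.norm.sf(abs(bx[j]) / config.se_x))
        exposure.append(VariantAssociation(
            rsid=f"sig{j + 1}", chrom=chrom, pos=pos[j],
            effect_allele=ea, other_allele=oa, beta=float(bx[j]),
            se=config.se_x, pval=max(pval, 1e-300)))
        outcome.append(VariantAssociation(
            rsid=f"sig{j + 1}", chrom=chrom, pos=pos[j],
            effect_allele=ea, other_allele=oa, beta=float(by[j]),
            se=config.se_y, pval=0.5))

    # decoys: weak associations (|z| <= 2 so they never pass Bonferroni),
    # half inside the region, half outside it
    for d in range(config.n_decoys):
        zd = rng.uniform(-2.0, 2.0)
        pd_ = float(2 * stats.norm.sf(abs(zd)))
        exposure.append(VariantAssociation(
            rsid=f"dec{d + 1}", chrom=chrom,
            pos=gene_lo + 1000 + 7_919 * d % (gene_hi - gene_lo - 2000),
            effect_allele="A", other_allele="G",
            beta=float(zd * config.se_x), se=config.se_x, pval=pd_))
    for d in range(config.n_decoys):
        zd = rng.uniform(-2.0, 2.0)
        pd_ = float(2 * stats.norm.sf(abs(zd)))
        exposure.append(VariantAssociation(
            rsid=f"out{d + 1}", chrom=chrom, pos=5_000_000 + 10_000 * d,
            effect_allele="A", other_allele="G",
            beta=float(zd * config.se_x), se=config.se_x, pval=pd_))

    # LD: block members share the stated r2, everything else unlinked
    region_rsids = [a.rsid for a in exposure if a.rsid[0] != "o"]
    mat = np.eye(len(region_rsids))
    ridx = {r: i for i, r in enumerate(region_rsids)}
    for b, (size, r2) in enumerate(config.ld_blocks):
        members = [f"sig{j + 1}" for j in range(k) if block_of[j] == b]
        for a in members:
            for c in members:
                if a != c:
                    mat[ridx[a], ridx[c]] = float(r2)
    ld = LDMatrix(rsids=region_rsids, r2=mat)

    # expected selection outcome (blocks assumed tighter than r2_max=0.1
    # and 1 Mb: only the smallest-p member of each survives)
    survivors = []
    for b in range(len(block_sizes)):
        members = [j for j in range(k) if block_of[j] == b]
        survivors.append(min(members, key=lambda j: exposure[j].pval))
    survivors += singleton_idx
    post_clump = sorted(survivors, key=lambda j: pos[j])
    kept = [j for j in post_clump if j not in pal_idx]
    truth = {
        "target_gene": target,
        "theta_true": theta,
        "expected_counts": {
            "n_region_snps": k + config.n_decoys,
            "n_significant": k,
            "n_post_clump": len(post_clump),
            "n_post_palindrome": len(kept),
        },
        "expected_kept_rsids": sorted(f"sig{j + 1}" for j in kept),
        "config": asdict(config),
    }
    return RegionScenario(exposure=exposure, outcome=outcome,
                          regions=regions, ld=ld, truth=truth)


def write_fixture_bundle(path, scenario: RegionScenario) -> None:
    """Write a scenario as plain-text files plus a truth JSON."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_sumstats(path / "exposure.tsv", scenario.exposure)
    write_sumstats(path / "outcome.tsv", scenario.outcome)
    write_regions(path / "regions.bed", scenario.regions)
    write_ld_matrix(path / "ld.tsv", scenario.ld)
    truth = dict(scenario.truth)
    truth["config"] = {k: list(v) if isinstance(v, tuple) else v
                       for k, v in truth["config"].items()}
    with open(path / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def read_fixture_bundle(path) -> RegionScenario:
    path = Path(path)
    with open(path / "truth.json") as fh:
        truth = json.load(fh)
    return RegionScenario(
        exposure=read_sumstats(path / "exposure.tsv"),
        outcome=read_sumstats(path / "outcome.tsv"),
        regions=read_regions(path / "regions.bed"),
        ld=read_ld_matrix(path / "ld.tsv"),
        truth=truth,
    )
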