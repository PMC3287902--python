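"""Hyper-LD diagnostics: genome-scale adjusted-correlation scans and null panels.

In a finite sample of N individuals, the correlation between two common SNPs
in linkage equilibrium is approximately normal with mean 0 and variance 1/N,
so about 1% of pairs exceed 2.33/sqrt(N) by chance alone (0.088 at N = 697).
Because the score test's noncentrality accumulates r_tauj * h_j over every
causal SNP, many such weak correlations — genuine long-range LD or pure
chance — can dominate a test SNP's power.  This module counts them: threshold
scans with a same-chromosome distance exclusion, per-SNP counts against MAF,
causal-partner histograms, and a MAF-matched linkage-equilibrium null panel
for side-by-side comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CovariateTable, DegenerateInputError, GenotypeMatrix
from .power import model_residual_variance
from .score_test import residualize
from .synthetic_data import TraitModel, simulate_genotypes_independent

log = logging.getLogger(__name__)

DEFAULT_MIN_DISTANCE_BP = 10_000_000
HISTOGRAM_BINS = ["0", "1", "2", "3", "4", "5", "6", "7", ">7"]


def chance_correlation_threshold(n_individuals: int, tail: float = 0.01) -> float:
    """Correlation magnitude exceeded by chance with probability ``tail``
    between independent common SNPs: z_{1-tail} / sqrt(N)."""
    if n_individuals < 2:
        raise ValueError("need at least two individuals")
    return float(stats.norm.ppf(1 - tail) / np.sqrt(n_individuals))


def _normalized_residuals(
    g: GenotypeMatrix, z: CovariateTable, snp_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm residualised genotype columns; flags degenerate columns."""
    x_res = residualize(g.imputed(snp_ids), z)
    norms = np.sqrt((x_res**2).sum(axis=0))
    degenerate = norms == 0
    norms[degenerate] = 1.0
    return x_res / norms, degenerate


def correlation_scan(
    g: GenotypeMatrix,
    z: CovariateTable,
    targets: list[str] | None = None,
    partners: list[str] | None = None,
    threshold: float = 0.1,
    min_distance_bp: int = DEFAULT_MIN_DISTANCE_BP,
    signed: bool = True,
    block_size: int = 512,
) -> pd.DataFrame:
    """All (target, partner) pairs whose adjusted correlation exceeds the
    threshold, excluding same-chromosome pairs closer than ``min_distance_bp``.

    ``signed=True`` keeps pairs with r > threshold; ``signed=False`` uses |r|.
    Different chromosomes count as infinitely distant.  The kernel works in
    column blocks so peak memory scales with block_size x panel width, not
    with the number of emitted pairs' search space.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    target_ids = g.snp_ids if targets is None else list(targets)
    partner_ids = g.snp_ids if partners is None else list(partners)
    xt, deg_t = _normalized_residuals(g, z, target_ids)
    xp, deg_p = _normalized_residuals(g, z, partner_ids)
    for ids, deg in ((target_ids, deg_t), (partner_ids, deg_p)):
        for sid in np.array(ids)[deg]:
            log.info("skipping degenerate SNP %s in correlation scan", sid)
    by_id = {s.snp_id: s for s in g.snps}
    t_chrom = np.array([by_id[s].chromosome for s in target_ids])
    t_pos = np.array([by_id[s].position_bp for s in target_ids], dtype=np.int64)
    p_chrom = np.array([by_id[s].chromosome for s in partner_ids])
    p_pos = np.array([by_id[s].position_bp for s in partner_ids], dtype=np.int64)
    rows: list[tuple[str, str, float]] = []
    for start in range(0, len(target_ids), block_size):
        stop = min(start + block_size, len(target_ids))
        r_block = xt[:, start:stop].T @ xp  # block x partners
        keep = (r_block > threshold) if signed else (np.abs(r_block) > threshold)
        keep[deg_t[start:stop], :] = False
        keep[:, deg_p] = False
        same_chrom = t_chrom[start:stop, np.newaxis] == p_chrom[np.newaxis, :]
        close = same_chrom & (
            np.abs(t_pos[start:stop, np.newaxis] - p_pos[np.newaxis, :])
            < min_distance_bp
        )
        keep &= ~close  # excludes self-pairs too (distance zero)
        for bi, pj in zip(*np.nonzero(keep)):
            rows.append(
                (target_ids[start + bi], partner_ids[pj], float(r_block[bi, pj]))
            )
    return pd.DataFrame(rows, columns=["target", "partner", "r"])


@dataclass
class CorrelationCountRow:
    """Per-target tallies from a correlation scan."""

    snp_id: str
    maf: float
    n_correlated: int
    n_correlated_causal: int
    cumulative_effect: float | None = None


def count_correlated(
    scan: pd.DataFrame,
    targets: list[str],
    g: GenotypeMatrix,
    causal_ids: list[str] | None = None,
    direct_effects: dict[str, float] | None = None,
) -> list[CorrelationCountRow]:
    """Per-target partner counts (all partners and causal partners), with the
    target MAF for count-vs-MAF reporting.  When per-causal direct effects are
    supplied the cumulative effect sum(r * h) over emitted causal partners is
    attached."""
    causal = set(causal_ids or [])
    grouped: dict[str, list[tuple[str, float]]] = {t: [] for t in targets}
    for target, partner, r in scan.itertuples(index=False):
        if target in grouped:
            grouped[target].append((partner, r))
    rows = []
    for t in targets:
        partners = grouped[t]
        n_causal = sum(1 for p, _ in partners if p in causal)
        cume = None
        if direct_effects is not None:
            cume = float(
                sum(r * direct_effects[p] for p, r in partners if p in causal)
            )
        col, mask = g.column(t)
        from .data_model import compute_maf

        rows.append(
            CorrelationCountRow(t, compute_maf(col, mask), len(partners), n_causal, cume)
        )
    return rows


def causal_count_histogram(rows: list[CorrelationCountRow]) -> pd.Series:
    """Distribution of the number of correlated causal SNPs per target SNP,
    binned 0..7 and >7."""
    counts = pd.Series(0, index=HISTOGRAM_BINS, dtype=int)
    for row in rows:
        key = str(row.n_correlated_causal) if row.n_correlated_causal <= 7 else ">7"
        counts[key] += 1
    return counts


def null_panel_comparison(
    g: GenotypeMatrix,
    z: CovariateTable,
    causal_ids: list[str],
    threshold: float = 0.1,
    min_distance_bp: int = DEFAULT_MIN_DISTANCE_BP,
    seed: int = 0,
    signed: bool = True,
) -> tuple[pd.Series, pd.Series, list[CorrelationCountRow], list[CorrelationCountRow]]:
    """Observed panel vs a MAF-matched linkage-equilibrium null panel.

    Simulates an independent HWE panel with the observed panel's MAFs (and the
    same map, so the distance exclusion applies identically), runs the same
    scan / count / histogram pipeline on both, and returns
    (observed histogram, null histogram, observed rows, null rows).  Any
    excess of observed over null counts is attributable to genuine LD.
    """
    mafs = g.mafs()
    null = simulate_genotypes_independent(mafs, g.n_individuals, seed=seed)
    # carry over the observed map and causal flags so exclusions match
    null = GenotypeMatrix(
        null.values,
        g.individual_ids,
        g.snps,
        null.missing_mask,
    )
    out = []
    for panel in (g, null):
        scan = correlation_scan(
            panel, z, threshold=threshold, min_distance_bp=min_distance_bp, signed=signed
        )
        rows = count_correlated(scan, panel.snp_ids, panel, causal_ids)
        out.append((causal_count_histogram(rows), rows))
    return out[0][0], out[1][0], out[0][1], out[1][1]


@dataclass
class CumulativeEffectReport:
    """Why a test SNP has power: its correlated causal partners and their sum."""

    test_snp: str
    table: pd.DataFrame  # causal partners above threshold: r, h, product
    cumulative_all_causal: float  # sum r * h over ALL causal SNPs
    lam: float
    rank_among_direct_effects: int  # 1 = larger than every causal |h_j|


def cumulative_effect_report(
    test_snp: str,
    g: GenotypeMatrix,
    z: CovariateTable,
    model: TraitModel,
    r_threshold: float = 0.1,
) -> CumulativeEffectReport:
    """Decompose a test SNP's noncentrality over causal SNPs.

    Lists the causal SNPs with adjusted correlation above the threshold
    (no distance exclusion: every causal SNP contributes to power wherever it
    sits), the cumulative effect over all causal SNPs, and where that
    cumulative effect ranks among the causal SNPs' own direct effects — the
    diagnosis of a test SNP whose power is borrowed entirely through weak
    correlations.
    """
    from .power import noncentrality

    nb = noncentrality(test_snp, g, z, model)
    records = [
        {"snp_id": sid, "r": r, "h": h, "product": prod}
        for sid, r, h, prod in nb.per_causal
        if r > r_threshold
    ]
    table = pd.DataFrame(records, columns=["snp_id", "r", "h", "product"])
    abs_h = sorted((abs(h) for _, _, h, _ in nb.per_causal), reverse=True)
    rank = 1 + sum(1 for h in abs_h if h > abs(nb.cumulative))
    return CumulativeEffectReport(test_snp, table, nb.cumulative, nb.lam, rank)


def null_correlation_sample(
    n_pairs: int,
    n_individuals: int,
    maf_range: tuple[float, float] = (0.2, 0.5),
    seed: int = 0,
) -> np.ndarray:
    """Sample correlations between independent HWE SNP pairs.

    Each pair is two independent Binomial(2, maf) genotype vectors with maf
    drawn uniformly from ``maf_range``; returns the n_pairs sample Pearson
    correlations.  The empirical distribution approaches N(0, 1/N) for common
    SNPs, the reference law for the chance-correlation tail.
    """
    rng = np.random.default_rng(seed)
    mafs_a = rng.uniform(*maf_range, size=n_pairs)
    mafs_b = rng.uniform(*maf_range, size=n_pairs)
    a = rng.binomial(2, mafs_a[np.newaxis, :], size=(n_individuals, n_pairs)).astype(float)
    b = rng.binomial(2, mafs_b[np.newaxis, :], size=(n_individuals, n_pairs)).astype(float)
    a -= a.mean(axis=0)
    b -= b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    if (denom == 0).any():
        raise DegenerateInputError("monomorphic draw; widen maf_range or change seed")
    return (a * b).sum(axis=0) / denom
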