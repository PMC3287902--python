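"""Analytical and Monte-Carlo power of the score test with multiple causal SNPs.

Under the additive trait model the score statistic at a test SNP tau follows a
noncentral 1-df chi-square with noncentrality

    lambda = (N - 1) * ( sum_j r_tauj * h_j )^2,

summing over causal SNPs j, where r_tauj is the covariate-adjusted sample
correlation between the genotype vectors at tau and j, and h_j is the direct
effect of SNP j: the signed square root of the proportion of residual trait
variance it explains, h_j = beta_j * sqrt(s_jj / s_yy).  The cumulative sum is
the reason weak correlations matter: ten causal SNPs each at r = 0.1 with
equal h give lambda = (N-1) h^2 — one hundred, not ten, times the lambda of a
single such SNP.  Analytical power is the upper-tail mass of that noncentral
chi-square beyond the central 1-df critical value; Monte-Carlo power is the
rejection rate over replicate trait simulations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import CovariateTable, DegenerateInputError, GenotypeMatrix
from .score_test import _chi2_matrix, residualize
from .synthetic_data import TraitModel, simulate_traits


def adjusted_covariance(xa: np.ndarray, xb: np.ndarray, z: CovariateTable) -> float:
    """s_ab = <residual(xa), residual(xb)> / (N - 1); the sample covariance of
    the two columns after both are residualised on the covariates."""
    res = residualize(np.column_stack([xa, xb]), z)
    return float(res[:, 0] @ res[:, 1]) / (res.shape[0] - 1)


def adjusted_correlation(xa: np.ndarray, xb: np.ndarray, z: CovariateTable) -> float:
    """Covariate-adjusted sample correlation; symmetric in its arguments."""
    res = residualize(np.column_stack([xa, xb]), z)
    va = float(res[:, 0] @ res[:, 0])
    vb = float(res[:, 1] @ res[:, 1])
    if va == 0.0 or vb == 0.0:
        raise DegenerateInputError("zero-variance column in adjusted_correlation")
    return float(res[:, 0] @ res[:, 1]) / np.sqrt(va * vb)


def direct_effect(beta_j: float, x_j: np.ndarray, z: CovariateTable, s_yy: float) -> float:
    """h_j = beta_j * sqrt(s_jj / s_yy); h_j^2 is the fraction of residual
    trait variance explained by causal SNP j."""
    if s_yy <= 0:
        raise ValueError("s_yy must be positive")
    s_jj = adjusted_covariance(x_j, x_j, z)
    return float(beta_j) * np.sqrt(s_jj / s_yy)


def model_residual_variance(model: TraitModel, g: GenotypeMatrix, z: CovariateTable) -> float:
    """Model-implied residual trait variance: noise variance plus the
    covariate-adjusted variance of the genetic component,
    s_yy = sigma^2 + beta' S beta with S the adjusted covariance matrix of the
    causal genotype columns.  Cross-causal covariances are included — no
    independence among causal SNPs is assumed."""
    causal = model.causal_ids()
    if not causal:
        return model.error_sd**2
    x_res = residualize(g.imputed(causal), z)
    s = (x_res.T @ x_res) / (g.n_individuals - 1)
    beta = model.betas()
    return float(model.error_sd**2 + beta @ s @ beta)


@dataclass
class NoncentralityBreakdown:
    """lambda for one test SNP, decomposed over causal SNPs."""

    test_snp: str
    n_individuals: int
    per_causal: list[tuple[str, float, float, float]]  # (snp_id, r_tj, h_j, r*h)
    cumulative: float  # sum over causal SNPs of r_tauj * h_j
    lam: float  # (N - 1) * cumulative^2


def lambda_from_effects(
    n_individuals: int, correlations: np.ndarray, direct_effects: np.ndarray
) -> float:
    """Noncentrality from explicit per-causal correlations and direct effects:
    lambda = (N - 1) * (sum r_j h_j)^2."""
    r = np.asarray(correlations, dtype=float)
    h = np.asarray(direct_effects, dtype=float)
    if r.shape != h.shape:
        raise ValueError("correlations and direct_effects must align")
    return (n_individuals - 1) * float(r @ h) ** 2


def noncentrality(
    test_snp: str, g: GenotypeMatrix, z: CovariateTable, model: TraitModel
) -> NoncentralityBreakdown:
    """Noncentrality parameter at one test SNP with per-causal contributions.

    Uses the model's true effect sizes and the panel's adjusted correlations;
    the per-causal products expose which causal SNPs drive the power (the
    hyper-LD diagnosis).
    """
    causal = model.causal_ids()
    n = g.n_individuals
    cols = [test_snp] + causal
    x_res = residualize(g.imputed(cols), z)
    norms2 = (x_res**2).sum(axis=0)
    if norms2[0] <= 0:
        raise DegenerateInputError(f"test SNP {test_snp!r} degenerate after adjustment")
    s_yy = model_residual_variance(model, g, z)
    per_causal = []
    for k, snp_id in enumerate(causal, start=1):
        s_jj = norms2[k] / (n - 1)
        if norms2[k] == 0:
            r = 0.0
            h = 0.0
        else:
            r = float(x_res[:, 0] @ x_res[:, k]) / np.sqrt(norms2[0] * norms2[k])
            h = model.snp_effects[snp_id] * np.sqrt(s_jj / s_yy)
        per_causal.append((snp_id, r, h, r * h))
    cumulative = float(sum(p[3] for p in per_causal))
    return NoncentralityBreakdown(
        test_snp, n, per_causal, cumulative, (n - 1) * cumulative**2
    )


def analytical_power(lam: float, alpha: float = 0.05) -> float:
    """Upper-tail probability of a noncentral chi-square (1 df, noncentrality
    lam) beyond the central 1-df critical value at level alpha."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    crit = stats.chi2.ppf(1 - alpha, df=1)
    if lam == 0:
        return alpha
    return float(stats.ncx2.sf(crit, df=1, nc=lam))


@dataclass
class PowerResult:
    """Analytical and (optionally) simulated power at one test SNP."""

    test_snp: str
    alpha: float
    lam: float
    analytical_power: float
    simulated_power: float | None = None
    n_replicates: int | None = None
    cumulative_effect: float | None = None


def simulated_power(
    g: GenotypeMatrix,
    z: CovariateTable,
    model: TraitModel,
    test_snp: str,
    n_replicates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the score test at one SNP over replicate traits."""
    results = power_analysis(
        g, z, model, alpha=alpha, n_replicates=n_replicates, seed=seed,
        test_snps=[test_snp],
    )
    if results[0].simulated_power is None:
        raise DegenerateInputError(f"test SNP {test_snp!r} degenerate")
    return results[0].simulated_power


def power_analysis(
    g: GenotypeMatrix,
    z: CovariateTable,
    model: TraitModel,
    alpha: float = 0.05,
    n_replicates: int | None = 100,
    seed: int = 0,
    test_snps: list[str] | None = None,
) -> list[PowerResult]:
    """Analytical (and, when n_replicates is set, Monte-Carlo) power at every
    test SNP.  Replicate traits share one simulation per call, genotypes held
    fixed, mirroring the replicate-phenotype design."""
    ids = g.snp_ids if test_snps is None else list(test_snps)
    results = []
    rejection: dict[str, float] = {}
    if n_replicates:
        traits = simulate_traits(g, z, model, n_replicates, seed=seed)
        from .score_test import residualize_panel

        panel = residualize_panel(g, z, traits, ids)
        chi2 = _chi2_matrix(panel.residual_genotypes, panel.residual_traits, panel.s_yy)
        crit = stats.chi2.ppf(1 - alpha, df=1)
        degenerate = np.isnan(chi2).all(axis=1)
        rejection = {
            snp: (None if degenerate[j] else float((chi2[j] > crit).mean()))
            for j, snp in enumerate(ids)
        }
    for snp in ids:
        try:
            nb = noncentrality(snp, g, z, model)
        except DegenerateInputError:
            continue
        results.append(
            PowerResult(
                snp,
                alpha,
                nb.lam,
                analytical_power(nb.lam, alpha),
                rejection.get(snp) if n_replicates else None,
                n_replicates if n_replicates else None,
                cumulative_effect=nb.cumulative,
            )
        )
    return results


def compare_power(
    panel_results: list[tuple[float, float]] | list[PowerResult],
) -> tuple[float, list[tuple[float, float, float]]]:
    """Percent of variance in simulated power explained by analytical power.

    Returns (100 * squared Pearson correlation, residual table of
    (analytical, simulated, simulated - analytical) per SNP).
    """
    pairs = []
    for item in panel_results:
        if isinstance(item, PowerResult):
            if item.simulated_power is None:
                continue
            pairs.append((item.analytical_power, item.simulated_power))
        else:
            pairs.append((float(item[0]), float(item[1])))
    if len(pairs) < 2:
        raise ValueError("need at least two SNPs with both power values")
    a = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs])
    if np.ptp(a) == 0 or np.ptp(s) == 0:
        raise DegenerateInputError("constant power vector; R^2 undefined")
    r = np.corrcoef(a, s)[0, 1]
    residuals = [(float(ai), float(si), float(si - ai)) for ai, si in pairs]
    return float(100.0 * r**2), residuals
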