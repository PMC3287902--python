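"""Covariate-adjusted single-SNP score test and rare-variant collapsing.

The test statistic for a test SNP tau is u = <X_res, Y_res>, the inner product
of the genotype and trait vectors after both are residualised on the design
Z = (1, Z_1, ..., Z_K).  Under the null its variance is estimated as
v = s_YY * ||X_res||^2 with s_YY the sample variance of the residual trait
values (divisor N - 1), and u^2/v is referred to a 1-df chi-square.  With
intercept-only adjustment this reduces to the classical identity
u^2/v = (N - 1) * r^2 for the Pearson correlation r of X and Y.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import CovariateTable, DegenerateInputError, GenotypeMatrix, TraitVector

log = logging.getLogger(__name__)

#: relative tolerance below which a residualised genotype is considered constant
DEGENERATE_TOL = 1e-12


class CollinearityError(ValueError):
    """The covariate design [1 | Z] is rank deficient."""


@dataclass
class ResidualizedPanel:
    """Genotypes and traits after projection off the covariate design."""

    design: np.ndarray  # N x (K+1), [1 | Z]
    residual_genotypes: np.ndarray  # N x M
    residual_traits: np.ndarray  # N x R (one column per trait replicate)
    s_yy: np.ndarray  # R, per-replicate sample variance of residual traits


def _design_matrix(z: CovariateTable, n: int) -> np.ndarray:
    design = np.column_stack([np.ones(n), z.values]) if z.values.size else np.ones((n, 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(
            "covariate design is rank deficient; collinear columns: "
            + ", ".join(z.collinear_columns())
        )
    return design


def residualize(columns: np.ndarray, z: CovariateTable) -> np.ndarray:
    """Residuals of each column after least-squares projection onto span(1, Z)."""
    columns = np.atleast_2d(np.asarray(columns, dtype=float))
    if columns.shape[0] == 1 and columns.size > 1:
        columns = columns.T  # a single vector was passed
    design = _design_matrix(z, columns.shape[0])
    coef, *_ = np.linalg.lstsq(design, columns, rcond=None)
    return columns - design @ coef


def residualize_panel(
    g: GenotypeMatrix,
    z: CovariateTable,
    traits: list[TraitVector],
    snp_ids: list[str] | None = None,
) -> ResidualizedPanel:
    """Residualise the whole panel once; missing genotypes are mean-imputed
    per SNP beforehand so N stays constant."""
    x = g.imputed(snp_ids)
    y = np.column_stack([t.values for t in traits])
    design = _design_matrix(z, g.n_individuals)
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    x_res = x - design @ coef_x
    y_res = y - design @ coef_y
    s_yy = (y_res**2).sum(axis=0) / (g.n_individuals - 1)
    return ResidualizedPanel(design, x_res, y_res, s_yy)


@dataclass
class ScoreTestResult:
    """Score statistic u, its variance estimate v, u^2/v and the 1-df p-value."""

    snp_id: str
    u: float
    v: float
    chi2: float
    p_value: float


def _chi2_matrix(x_res: np.ndarray, y_res: np.ndarray, s_yy: np.ndarray) -> np.ndarray:
    """u^2/v for every (SNP, replicate) pair; degenerate SNPs yield NaN rows."""
    xnorm2 = (x_res**2).sum(axis=0)
    u = x_res.T @ y_res  # M x R
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = u**2 / (xnorm2[:, np.newaxis] * s_yy[np.newaxis, :])
    scale = np.abs(x_res).max(axis=0) ** 2 * x_res.shape[0]
    chi2[xnorm2 <= DEGENERATE_TOL * np.maximum(scale, 1.0)] = np.nan
    return chi2


def score_test(
    g: GenotypeMatrix, z: CovariateTable, y: TraitVector, test_snp: str
) -> ScoreTestResult:
    """Score test of association between the trait and one test SNP."""
    x_res = residualize(g.imputed([test_snp]), z)[:, 0]
    y_res = residualize(y.values, z)[:, 0]
    return _score_from_residuals(test_snp, x_res, y_res, y.values)


def _score_from_residuals(
    snp_id: str, x_res: np.ndarray, y_res: np.ndarray, y_raw: np.ndarray
) -> ScoreTestResult:
    n = x_res.shape[0]
    xnorm2 = float(x_res @ x_res)
    if xnorm2 <= DEGENERATE_TOL * max(np.abs(x_res).max() ** 2 * n, 1.0):
        raise DegenerateInputError(
            f"SNP {snp_id!r} is constant after covariate adjustment"
        )
    s_yy = float(y_res @ y_res) / (n - 1)
    u = float(x_res @ y_res)
    v = s_yy * xnorm2
    # trait (numerically) inside the covariate span: no residual variation left
    if np.sqrt(float(y_res @ y_res)) <= 1e-10 * np.linalg.norm(y_raw):
        return ScoreTestResult(snp_id, 0.0, v, 0.0, 1.0)
    chi2 = u**2 / v
    return ScoreTestResult(snp_id, u, v, chi2, float(stats.chi2.sf(chi2, df=1)))


def collapsed_score_test(
    g: GenotypeMatrix,
    z: CovariateTable,
    y: TraitVector,
    snp_ids: list[str],
    weights: list[float] | None = None,
) -> ScoreTestResult:
    """Score test on a pseudo-genotype: the (weighted) sum of several SNPs.

    Collapsing rare variants raises the effective minor allele frequency of
    the tested unit; the resulting pseudo-SNP behaves exactly like a single
    SNP in both the test and the power formulas.
    """
    if not snp_ids:
        raise ValueError("at least one SNP required for collapsing")
    w = np.ones(len(snp_ids)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (len(snp_ids),):
        raise ValueError("weights must align with snp_ids")
    pseudo = g.imputed(snp_ids) @ w
    label = "+".join(snp_ids)
    x_res = residualize(pseudo, z)[:, 0]
    y_res = residualize(y.values, z)[:, 0]
    return _score_from_residuals(label, x_res, y_res, y.values)


def scan(
    g: GenotypeMatrix,
    z: CovariateTable,
    y: TraitVector,
    snp_ids: list[str] | None = None,
) -> list[ScoreTestResult]:
    """Score test at every SNP (or a subset), in input order.

    Degenerate SNPs (constant after adjustment, e.g. monomorphic) are skipped
    with a logged reason rather than failing the scan.
    """
    ids = g.snp_ids if snp_ids is None else list(snp_ids)
    panel = residualize_panel(g, z, [y], ids)
    chi2 = _chi2_matrix(panel.residual_genotypes, panel.residual_traits, panel.s_yy)[:, 0]
    xnorm2 = (panel.residual_genotypes**2).sum(axis=0)
    u = panel.residual_genotypes.T @ panel.residual_traits[:, 0]
    results = []
    for j, snp_id in enumerate(ids):
        if np.isnan(chi2[j]):
            log.info("skipping degenerate SNP %s (constant after adjustment)", snp_id)
            continue
        v = float(panel.s_yy[0] * xnorm2[j])
        results.append(
            ScoreTestResult(
                snp_id,
                float(u[j]),
                v,
                float(chi2[j]),
                float(stats.chi2.sf(chi2[j], df=1)),
            )
        )
    return results
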