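"""Containers and I/O for genotype panels, SNP metadata, covariates and traits.

Genotypes are minor-allele counts (0/1/2), the additive coding of the
quantitative-trait model: each copy of the minor allele shifts the trait by the
SNP's effect size.  Readers normalise to that coding (flipping a VCF site when
the ALT allele is the in-sample major allele), and the module provides the two
standard QC primitives the downstream statistics depend on: per-SNP minor
allele frequency and Hardy-Weinberg equilibrium tests, applied per population
with a panel-level filter.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

log = logging.getLogger(__name__)

MISSING = -9  # sentinel inside the integer genotype array; mask is authoritative


class EmptyInputError(ValueError):
    """Input contained no usable records."""


class ParseError(ValueError):
    """A token in a text input could not be interpreted."""


class DegenerateInputError(ValueError):
    """Operation undefined for this input (e.g. all-missing column)."""


@dataclass(frozen=True)
class SnpRecord:
    """Per-SNP metadata: identity, genomic position, frequency and true effect.

    ``beta`` is the allele effect size in trait units per minor-allele copy;
    a nonzero ``beta`` forces ``is_causal``.
    """

    snp_id: str
    chromosome: str
    position_bp: int
    maf: float = float("nan")
    is_causal: bool = False
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not math.isnan(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")
        if self.position_bp < 1:
            raise ValueError(f"{self.snp_id}: position must be 1-based positive")
        if self.beta != 0.0 and not self.is_causal:
            object.__setattr__(self, "is_causal", True)


@dataclass
class GenotypeMatrix:
    """N individuals x M SNPs of minor-allele counts with a missingness mask."""

    values: np.ndarray
    individual_ids: list[str]
    snps: list[SnpRecord]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, m = self.values.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match rows")
        if len(self.snps) != m:
            raise ValueError("snps length does not match columns")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, m), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, m):
            raise ValueError("missing_mask shape mismatch")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.isin(observed, (0, 1, 2)).all():
            raise ValueError("non-missing genotypes must be 0, 1 or 2")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def column(self, snp_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(values, missing_mask)`` for one SNP."""
        j = self.snp_index(snp_id)
        return self.values[:, j], self.missing_mask[:, j]

    def imputed(self, snp_ids: list[str] | None = None) -> np.ndarray:
        """Float genotype matrix with missing entries replaced per-SNP by the
        column mean of the observed entries (keeps N constant downstream)."""
        idx = (
            slice(None)
            if snp_ids is None
            else [self.snp_index(s) for s in snp_ids]
        )
        x = self.values[:, idx].astype(float)
        mask = self.missing_mask[:, idx]
        if mask.any():
            obs = np.where(mask, 0.0, x)
            cnt = (~mask).sum(axis=0)
            if (cnt == 0).any():
                raise DegenerateInputError("a column is entirely missing")
            means = obs.sum(axis=0) / cnt
            x = np.where(mask, means[np.newaxis, :], x)
        return x

    def mafs(self) -> np.ndarray:
        return np.array(
            [compute_maf(self.values[:, j], self.missing_mask[:, j])
             for j in range(self.n_snps)]
        )

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(chromosome labels, base-pair positions) as arrays."""
        chrom = np.array([s.chromosome for s in self.snps])
        pos = np.array([s.position_bp for s in self.snps], dtype=np.int64)
        return chrom, pos


@dataclass
class CovariateTable:
    """Numeric covariate design (categoricals expanded to indicators).

    ``values`` is N x K with one indicator column per non-reference level of
    each categorical factor; ``raw`` optionally keeps the pre-expansion table
    for round-tripping to disk.
    """

    values: np.ndarray
    names: list[str]
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("covariate values must be 2-D")
        if self.values.shape[1] != len(self.names):
            raise ValueError("names length does not match columns")

    @classmethod
    def empty(cls, n_individuals: int) -> "CovariateTable":
        return cls(np.empty((n_individuals, 0)), [])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CovariateTable":
        expanded = pd.get_dummies(df, drop_first=True, dtype=float)
        return cls(expanded.to_numpy(dtype=float), list(expanded.columns), raw=df)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    def collinear_columns(self) -> list[str]:
        """Names of columns that make [1 | covariates] rank deficient."""
        design = np.column_stack([np.ones(self.n_individuals), self.values])
        from scipy.linalg import qr

        _, r, piv = qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps if diag.size else 0.0
        dropped = piv[np.flatnonzero(diag <= tol)] if diag.size else []
        extra = list(piv[design.shape[1]:]) if r.shape[0] < design.shape[1] else []
        labels = ["(intercept)"] + list(self.names)
        return [labels[i] for i in sorted(set(dropped) | set(extra))]


@dataclass
class TraitVector:
    """One replicate of quantitative trait values."""

    values: np.ndarray
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trait values must be 1-D")
        if not np.isfinite(self.values).all():
            raise ValueError("trait values must be finite")


# ---------------------------------------------------------------------------
# MAF and Hardy-Weinberg tests
# ---------------------------------------------------------------------------

def compute_maf(column: np.ndarray, missing_mask: np.ndarray | None = None) -> float:
    """Minor allele frequency of one genotype column, missing entries excluded.

    Returns ``min(c, 1-c)`` with ``c`` the frequency of the coded allele.
    """
    column = np.asarray(column)
    if missing_mask is not None:
        column = column[~np.asarray(missing_mask, dtype=bool)]
    if column.size == 0:
        raise DegenerateInputError("all genotypes missing: MAF undefined")
    c = float(column.sum()) / (2.0 * column.size)
    return min(c, 1.0 - c)


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """(hom for allele coded 0, het, hom for allele coded 2)."""
    return (
        int(np.count_nonzero(column == 0)),
        int(np.count_nonzero(column == 1)),
        int(np.count_nonzero(column == 2)),
    )


def hwe_chisq_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> tuple[float, float]:
    """One-df goodness-of-fit chi-square test of HWE. Returns (statistic, p)."""
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise DegenerateInputError("no genotypes")
    p = (2 * n_hom_minor + n_het) / (2.0 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    observed = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def hwe_exact_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional test of HWE.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts no more likely than the observed one (the standard
    two-sided exact test used in GWAS QC).
    """
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise DegenerateInputError("no genotypes")
    rare = min(2 * n_hom_major + n_het, 2 * n_hom_minor + n_het)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = n - hets - homs_rare
    # log multiplicity of each table sharing the allele margin; the common
    # normalising constant cancels when probabilities are renormalised.
    lg = math.lgamma
    logw = np.array(
        [
            lg(n + 1) - lg(a + 1) - lg(h + 1) - lg(b + 1) + h * math.log(2.0)
            for a, h, b in zip(homs_rare, hets, homs_common)
        ]
    )
    logp = logw - logsumexp(logw)
    obs = logp[np.flatnonzero(hets == n_het)[0]]
    keep = logp <= obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def hwe_test(
    column: np.ndarray,
    missing_mask: np.ndarray | None = None,
    population_labels: np.ndarray | None = None,
    method: str = "exact",
) -> float:
    """Smallest per-population HWE p-value for one genotype column.

    Populations are tested separately (stratified panels are not expected to be
    in HWE jointly); a monomorphic population contributes p = 1.
    """
    if method not in ("exact", "chisq"):
        raise ValueError("method must be 'exact' or 'chisq'")
    column = np.asarray(column)
    mask = (
        np.zeros(column.shape, dtype=bool)
        if missing_mask is None
        else np.asarray(missing_mask, dtype=bool)
    )
    labels = (
        np.zeros(column.shape[0])
        if population_labels is None
        else np.asarray(population_labels)
    )
    p_min = 1.0
    for lev in np.unique(labels):
        sel = (labels == lev) & ~mask
        sub = column[sel]
        if sub.size == 0:
            raise DegenerateInputError(f"population {lev!r} has no observed genotypes")
        a, h, b = _genotype_counts(sub)
        if h == 0 and (a == 0 or b == 0):
            log.debug("monomorphic column in population %r: HWE p = 1", lev)
            p = 1.0
        elif method == "exact":
            p = hwe_exact_p(a, h, b)
        else:
            p = hwe_chisq_p(a, h, b)[1]
        p_min = min(p_min, p)
    return p_min


def hwe_filter(
    g: GenotypeMatrix,
    population_labels: np.ndarray | None = None,
    threshold: float = 1e-4,
    method: str = "exact",
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop SNPs whose minimum per-population HWE p-value is below ``threshold``.

    Survivor order is preserved.  Returns (filtered panel, removed SNP ids).
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    keep, removed = [], []
    for j, snp in enumerate(g.snps):
        p = hwe_test(g.values[:, j], g.missing_mask[:, j], population_labels, method)
        (removed if p < threshold else keep).append(
            snp.snp_id if p < threshold else j
        )
    filtered = GenotypeMatrix(
        g.values[:, keep],
        g.individual_ids,
        [g.snps[j] for j in keep],
        g.missing_mask[:, keep],
    )
    if removed:
        log.info("HWE filter removed %d SNPs at p < %g", len(removed), threshold)
    return filtered, removed


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _default_snps(snp_ids: list[str]) -> list[SnpRecord]:
    return [SnpRecord(s, "0", j + 1) for j, s in enumerate(snp_ids)]


def read_genotypes_vcf(path: str) -> GenotypeMatrix:
    """Read diallelic sites from a VCF as minor-allele counts.

    Multi-allelic sites are skipped with a warning.  If the ALT allele is the
    in-sample major allele the coding is flipped so 2 means two minor alleles;
    an exact 0.5 tie keeps ALT as the minor allele.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc
    individual_ids = list(vcf.samples)
    columns, masks, snps = [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            log.warning(
                "skipping multi-allelic site %s:%d", variant.CHROM, variant.POS
            )
            continue
        gt = np.asarray(variant.gt_types)  # 0/1/2 ALT copies, 3 = missing
        mask = gt == 3
        counts = np.where(mask, 0, gt)
        observed = counts[~mask]
        if observed.size == 0:
            alt_freq = 0.0
        else:
            alt_freq = observed.sum() / (2.0 * observed.size)
        if alt_freq > 0.5:  # ALT is major: flip; ties keep ALT as minor
            counts = np.where(mask, 0, 2 - counts)
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        maf = min(alt_freq, 1.0 - alt_freq)
        snps.append(SnpRecord(snp_id, str(variant.CHROM), variant.POS, maf))
        columns.append(counts)
        masks.append(mask)
    if not columns:
        raise EmptyInputError(f"no diallelic sites in {path!r}")
    return GenotypeMatrix(
        np.column_stack(columns).astype(np.int16),
        individual_ids,
        snps,
        np.column_stack(masks),
    )


def read_genotypes_tsv(path: str) -> GenotypeMatrix:
    """Read a genotype TSV: header of SNP ids, one row per individual, 0/1/2/NA."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise EmptyInputError(f"no genotype data in {path!r}")
    values = np.zeros(df.shape, dtype=np.int16)
    mask = np.zeros(df.shape, dtype=bool)
    arr = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            tok = arr[i, j]
            if tok is None or (isinstance(tok, float) and math.isnan(tok)) or tok == "NA":
                mask[i, j] = True
            elif tok in ("0", "1", "2"):
                values[i, j] = int(tok)
            else:
                raise ParseError(
                    f"bad genotype {tok!r} at individual {df.index[i]!r}, "
                    f"SNP {df.columns[j]!r}"
                )
    return GenotypeMatrix(
        values, [str(i) for i in df.index], _default_snps(list(df.columns)), mask
    )


def write_genotypes_tsv(g: GenotypeMatrix, path: str, header_lines: list[str] | None = None) -> None:
    tokens = g.values.astype(object)
    tokens[g.missing_mask] = "NA"
    df = pd.DataFrame(tokens, index=g.individual_ids, columns=g.snp_ids)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label="individual_id")


def read_snp_table(path: str) -> list[SnpRecord]:
    """SNP metadata TSV: snp_id, chromosome, position_bp and optional beta/maf."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, comment="#")
    required = {"snp_id", "chromosome", "position_bp"}
    if not required.issubset(df.columns):
        raise ParseError(f"SNP table must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SnpRecord(
                str(row.snp_id),
                str(row.chromosome),
                int(row.position_bp),
                maf=float(getattr(row, "maf", float("nan"))),
                beta=float(getattr(row, "beta", 0.0)),
            )
        )
    return records


def write_snp_table(snps: list[SnpRecord], path: str) -> None:
    pd.DataFrame(
        [dataclasses.asdict(s) for s in snps]
    ).to_csv(path, sep="\t", index=False)


def attach_snp_table(g: GenotypeMatrix, snps: list[SnpRecord]) -> GenotypeMatrix:
    """Replace a panel's metadata with records read from a SNP table."""
    by_id = {s.snp_id: s for s in snps}
    missing = [s for s in g.snp_ids if s not in by_id]
    if missing:
        raise KeyError(f"SNP table lacks {len(missing)} panel SNPs, e.g. {missing[0]!r}")
    return GenotypeMatrix(
        g.values, g.individual_ids, [by_id[s] for s in g.snp_ids], g.missing_mask
    )


def read_covariates_tsv(path: str) -> CovariateTable:
    """Covariate TSV with a header of names; non-numeric columns are treated as
    categorical and expanded to indicator columns (first level dropped)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] == 0:
        raise EmptyInputError(f"no covariate rows in {path!r}")
    return CovariateTable.from_dataframe(df)


def write_covariates_tsv(z: CovariateTable, individual_ids: list[str], path: str) -> None:
    df = z.raw if z.raw is not None else pd.DataFrame(z.values, columns=z.names)
    df = df.copy()
    df.index = individual_ids
    df.to_csv(path, sep="\t", index_label="individual_id")


def read_traits_tsv(path: str) -> list[TraitVector]:
    """Trait TSV: one column per replicate."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise EmptyInputError(f"no trait data in {path!r}")
    return [
        TraitVector(df.iloc[:, j].to_numpy(dtype=float), replicate_id=j)
        for j in range(df.shape[1])
    ]


def write_traits_tsv(traits: list[TraitVector], individual_ids: list[str], path: str) -> None:
    df = pd.DataFrame(
        {f"rep_{t.replicate_id}": t.values for t in traits}, index=individual_ids
    )
    df.to_csv(path, sep="\t", index_label="individual_id")
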