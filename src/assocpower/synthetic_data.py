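"""Simulators for genotype panels, covariates and replicate quantitative traits.

The generators mirror the statistical structure assumed by the analytic power
formulas: unrelated individuals, Hardy-Weinberg genotypes, an additive trait

    Y = mu + sum_k alpha_k Z_k + sum_j beta_j X_j + eps,   eps ~ N(0, sigma^2),

and a replicate design in which genotypes and covariates are held fixed while
the noise is redrawn, so rejection frequency across replicates estimates power
at fixed genotype correlations.  Two genotype generators are provided: fully
independent SNPs (the linkage-equilibrium null used to show that weak
correlations arise by chance alone) and haplotype-block panels with genuine LD.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CovariateTable, GenotypeMatrix, SnpRecord, TraitVector

#: default synthetic map: 1 Mb spacing, 1,000 SNPs per synthetic chromosome,
#: so a 10 Mb distance-exclusion rule is exercisable on simulated panels.
SNP_SPACING_BP = 1_000_000
SNPS_PER_CHROMOSOME = 1_000


@dataclass
class TraitModel:
    """Additive quantitative-trait model.

    Parameters
    ----------
    mu : baseline mean trait value.
    covariate_effects : effects alpha_k, aligned with the covariate table's
        expanded columns (trait units per covariate unit).
    snp_effects : map snp_id -> beta_j, trait units per minor-allele copy.
    error_sd : standard deviation of the residual noise (> 0).
    """

    mu: float = 0.0
    covariate_effects: np.ndarray = field(default_factory=lambda: np.zeros(0))
    snp_effects: dict[str, float] = field(default_factory=dict)
    error_sd: float = 1.0

    def __post_init__(self) -> None:
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)
        if self.error_sd <= 0:
            raise ValueError("error_sd must be positive")

    def causal_ids(self) -> list[str]:
        return [s for s, b in self.snp_effects.items() if b != 0.0]

    def betas(self) -> np.ndarray:
        return np.array([self.snp_effects[s] for s in self.causal_ids()])


@dataclass
class LdBlock:
    """A haplotype block: H haplotypes over L loci with sampling frequencies."""

    haplotypes: np.ndarray  # H x L of 0/1 alleles
    frequencies: np.ndarray  # H, summing to 1

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be H x L")
        if self.frequencies.shape != (self.haplotypes.shape[0],):
            raise ValueError("one frequency per haplotype required")
        if (self.frequencies < 0).any() or abs(self.frequencies.sum() - 1.0) > 1e-8:
            raise ValueError("haplotype frequencies must be nonnegative and sum to 1")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def size(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.frequencies @ self.haplotypes


def snp_layout(n_snps: int, prefix: str = "snp") -> list[tuple[str, str, int]]:
    """Deterministic synthetic map: (snp_id, chromosome, position)."""
    out = []
    for j in range(n_snps):
        chrom = f"chr{1 + j // SNPS_PER_CHROMOSOME}"
        pos = SNP_SPACING_BP * (j % SNPS_PER_CHROMOSOME) + 1
        out.append((f"{prefix}{j}", chrom, pos))
    return out


def simulate_genotypes_independent(
    mafs: np.ndarray, n_individuals: int, seed: int, prefix: str = "snp"
) -> GenotypeMatrix:
    """Independent HWE SNPs: entry for SNP j ~ Binomial(2, maf_j)."""
    mafs = np.asarray(mafs, dtype=float)
    if ((mafs < 0) | (mafs > 0.5)).any():
        raise ValueError("every maf must lie in [0, 0.5]")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.binomial(2, mafs[np.newaxis, :], size=(n_individuals, mafs.size))
    snps = [
        SnpRecord(sid, chrom, pos, maf=float(m))
        for (sid, chrom, pos), m in zip(snp_layout(mafs.size, prefix), mafs)
    ]
    return GenotypeMatrix(
        values.astype(np.int16),
        [f"ind{i}" for i in range(n_individuals)],
        snps,
    )


def simulate_genotypes_ld(
    blocks: list[LdBlock], n_individuals: int, seed: int, prefix: str = "snp"
) -> GenotypeMatrix:
    """Haplotype-block panel: two haplotypes drawn independently per block per
    individual; blocks are mutually independent, so LD exists only within."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    columns = []
    freqs = []
    for block in blocks:
        h1 = rng.choice(block.haplotypes.shape[0], size=n_individuals, p=block.frequencies)
        h2 = rng.choice(block.haplotypes.shape[0], size=n_individuals, p=block.frequencies)
        columns.append(block.haplotypes[h1] + block.haplotypes[h2])
        freqs.extend(block.allele_frequencies())
    values = np.concatenate(columns, axis=1)
    snps = [
        SnpRecord(sid, chrom, pos, maf=float(min(p, 1 - p)))
        for (sid, chrom, pos), p in zip(snp_layout(values.shape[1], prefix), freqs)
    ]
    return GenotypeMatrix(
        values.astype(np.int16),
        [f"ind{i}" for i in range(n_individuals)],
        snps,
    )


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

@dataclass
class CovariateSpec:
    """One covariate: kind is 'uniform_int' (low, high inclusive), 'binary'
    (probability of 1) or 'categorical' (levels with probabilities)."""

    name: str
    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in ("uniform_int", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "binary" and not (0.0 <= self.params["p"] <= 1.0):
            raise ValueError("binary probability must be in [0, 1]")
        if self.kind == "categorical":
            probs = np.asarray(self.params["probs"], dtype=float)
            if abs(probs.sum() - 1.0) > 1e-8 or (probs < 0).any():
                raise ValueError("categorical probabilities must sum to 1")
            if len(self.params["levels"]) != probs.size:
                raise ValueError("levels and probs must align")


def default_covariate_spec() -> list[CovariateSpec]:
    """Age / Sex / Smoke / Population covariates, with Population taking seven
    equally likely levels (a seven-population study design)."""
    return [
        CovariateSpec("Age", "uniform_int", {"low": 20, "high": 70}),
        CovariateSpec("Sex", "binary", {"p": 0.5}),
        CovariateSpec("Smoke", "binary", {"p": 0.3}),
        CovariateSpec(
            "Population",
            "categorical",
            {"levels": [f"pop{i + 1}" for i in range(7)], "probs": [1 / 7] * 7},
        ),
    ]


def simulate_covariates(
    n_individuals: int, spec: list[CovariateSpec] | None = None, seed: int = 0
) -> CovariateTable:
    if spec is None:
        spec = default_covariate_spec()
    rng = np.random.default_rng(seed)
    cols: dict[str, object] = {}
    for cv in spec:
        if cv.kind == "uniform_int":
            cols[cv.name] = rng.integers(
                cv.params["low"], cv.params["high"] + 1, size=n_individuals
            ).astype(float)
        elif cv.kind == "binary":
            cols[cv.name] = rng.binomial(1, cv.params["p"], size=n_individuals).astype(float)
        else:
            draws = rng.choice(
                cv.params["levels"], size=n_individuals, p=cv.params["probs"]
            )
            cols[cv.name] = pd.Categorical(draws, categories=cv.params["levels"])
    df = pd.DataFrame(cols, index=[f"ind{i}" for i in range(n_individuals)])
    return CovariateTable.from_dataframe(df)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_traits(
    g: GenotypeMatrix,
    z: CovariateTable,
    model: TraitModel,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[TraitVector]:
    """Replicate trait vectors under the additive model: genotypes and
    covariates fixed, the normal noise term redrawn per replicate."""
    n = g.n_individuals
    if z.n_individuals != n:
        raise ValueError("covariate table and genotype panel disagree on N")
    if z.values.shape[1] != model.covariate_effects.size:
        raise ValueError(
            f"model has {model.covariate_effects.size} covariate effects but the "
            f"table has {z.values.shape[1]} expanded columns"
        )
    unknown = [s for s in model.snp_effects if s not in g.snp_ids]
    if unknown:
        raise ValueError(f"model SNPs absent from panel: {unknown}")
    fixed = np.full(n, model.mu)
    if model.covariate_effects.size:
        fixed = fixed + z.values @ model.covariate_effects
    causal = model.causal_ids()
    if causal:
        fixed = fixed + g.imputed(causal) @ model.betas()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, model.error_sd, size=(n_replicates, n))
    return [TraitVector(fixed + noise[r], replicate_id=r) for r in range(n_replicates)]


# ---------------------------------------------------------------------------
# Flat key=value configuration
# ---------------------------------------------------------------------------

def read_config(path: str) -> dict[str, str]:
    """Flat ``key = value`` configuration file; '#' starts a comment."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            cfg[key] = val
    return cfg


def panel_from_config(cfg: dict[str, str], seed: int):
    """Build (genotypes, covariates, model, traits) from a flat config.

    Recognised keys (all optional): n_individuals, n_snps, maf_min, maf_max,
    rare_fraction (fraction of SNPs given a MAF putting < 30 minor-allele
    copies in the sample), n_causal, beta, error_sd, mu, n_replicates.
    """
    n = int(cfg.get("n_individuals", 697))
    m = int(cfg.get("n_snps", 500))
    maf_min = float(cfg.get("maf_min", 0.05))
    maf_max = float(cfg.get("maf_max", 0.5))
    rare_fraction = float(cfg.get("rare_fraction", 0.0))
    n_causal = int(cfg.get("n_causal", 10))
    beta = float(cfg.get("beta", 0.3))
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_min, maf_max, size=m)
    n_rare = int(round(rare_fraction * m))
    if n_rare:
        # "rare" = fewer than 30 expected minor-allele copies in the sample
        mafs[rng.choice(m, size=n_rare, replace=False)] = rng.uniform(
            1.0 / (2 * n), 30.0 / (2 * n), size=n_rare
        )
    g = simulate_genotypes_independent(mafs, n, seed=int(rng.integers(2**31)))
    z = simulate_covariates(n, seed=int(rng.integers(2**31)))
    causal = rng.choice(g.snp_ids, size=min(n_causal, m), replace=False)
    model = TraitModel(
        mu=float(cfg.get("mu", 0.0)),
        covariate_effects=np.zeros(z.values.shape[1]),
        snp_effects={s: beta for s in causal},
        error_sd=float(cfg.get("error_sd", 1.0)),
    )
    traits = simulate_traits(
        g, z, model, int(cfg.get("n_replicates", 100)), seed=int(rng.integers(2**31))
    )
    return g, z, model, traits
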