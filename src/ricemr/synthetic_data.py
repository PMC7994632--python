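"""Simulator for multi-population, multi-environment F1 hybrid rice panels.

The generator stands in for unreleased hybrid-rice diversity panels: it
draws LD-structured biallelic genotypes, builds the three yield component
traits (GPP, KGW, TP) from sparse major-effect SNPs plus a rescaled
polygenic background, and composes yield per plant (YD) as a noisy weighted
combination of the components plus a few direct-effect loci.  The causal
architecture is returned alongside the data (:class:`TruthRecord`) so every
downstream stage — mixed-model GWAS, meta-analysis, instrument selection,
Mendelian randomization, allele pyramiding — can be checked against ground
truth.

Genotype model
--------------
Each line is the sum of two haplotypes.  Along a haplotype, successive
alleles copy the previous SNP's allele with probability ``ld_rho`` and are
otherwise fresh Bernoulli draws at that SNP's own frequency, giving a
first-order LD decay that is cheap, seedable and analytically tractable
(see :func:`expected_adjacent_r2`).

Trait model
-----------
For component trait t in dataset d::

    t = intercept_t + sum_j beta_tj * dosage_j + polygenic_t + shift_(d,t) + e

The polygenic term is built from a random subset of non-causal SNPs with
small Gaussian effects, rescaled so that (together with the major-effect
term) the realized genetic fraction of variance equals the requested
heritability; the residual noise variance is then solved from h^2.  Yield::

    YD = intercept_YD + w_GPP*GPP + w_KGW*KGW + w_TP*TP
         + sum_j delta_j * dosage_j + e_YD

Environments of one population share genotypes and differ only by additive
trait shifts and independent noise draws.

Exclusion-restriction modes
---------------------------
``exclusivity="disjoint"`` (default) guarantees no SNP is causal for two
component traits.  ``"strict"`` additionally projects each component trait
orthogonal to the other components' causal-SNP dosages within each
population, enforcing the Mendelian-randomization exclusion restriction
in-sample rather than only in expectation (a rank-k projection with k much
smaller than n, so the trait's own architecture is essentially untouched).
``"none"`` applies no constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    TRAITS,
    GenotypeMatrix,
    PhenotypeTable,
    SnpRecord,
    ValidationError,
)

import pandas as pd

__all__ = [
    "TruthRecord",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_study",
    "default_truth",
    "expected_adjacent_r2",
]

COMPONENTS = ("GPP", "KGW", "TP")


class ParameterError(ValueError):
    """A simulation parameter lies outside its stated domain."""


@dataclass
class TruthRecord:
    """Ground-truth causal parameters of one simulated study.

    component_effects map each component trait to (snp_index, effect) pairs
    in trait units per ALT dosage; yield_weights are (w_GPP, w_KGW, w_TP);
    direct_yield_effects act on YD in grams per dosage.  ``heritability``
    is the target genetic fraction of variance per component trait.
    """

    component_effects: dict[str, list[tuple[int, float]]]
    yield_weights: tuple[float, float, float]
    direct_yield_effects: list[tuple[int, float]]
    heritability: dict[str, float]
    env_shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0
    intercepts: dict[str, float] = field(
        default_factory=lambda: {"GPP": 150.0, "KGW": 25.0, "TP": 10.0, "YD": 0.0}
    )
    #: residual SD used for a component trait when its genetic variance is
    #: zero (h^2 solving is then impossible); and the YD residual SD.
    base_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"GPP": 15.0, "KGW": 1.2, "TP": 1.2}
    )
    yield_noise_sd: float = 3.0
    #: fraction of genetic variance carried by the polygenic background.
    polygenic_fraction: float = 0.35
    n_polygenic: int = 1000

    def __post_init__(self) -> None:
        for t, h2 in self.heritability.items():
            if not 0.0 <= h2 <= 1.0:
                raise ParameterError(f"h2({t}) = {h2} outside [0, 1]")
        if not all(np.isfinite(self.yield_weights)):
            raise ParameterError("yield_weights must be finite")
        if not 0.0 <= self.polygenic_fraction < 1.0:
            raise ParameterError("polygenic_fraction must lie in [0, 1)")

    def causal_indices(self, trait: str) -> list[int]:
        return [i for i, _ in self.component_effects.get(trait, [])]


@dataclass
class SimulatedStudy:
    """Genotypes per dataset, long phenotype table, and the truth record."""

    genotypes: dict[str, GenotypeMatrix]
    phenotypes: PhenotypeTable
    truth: TruthRecord

    def dataset_ids(self) -> list[str]:
        return list(self.genotypes)


def simulate_genotypes(
    n_lines: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.0,
    seed: int = 0,
    line_prefix: str = "L",
) -> GenotypeMatrix:
    """Draw an LD-structured biallelic dosage panel.

    Two haplotypes per line follow a first-order copying process along the
    SNP order: allele j equals allele j-1 with probability ``ld_rho``,
    otherwise a fresh Bernoulli at SNP j's frequency (drawn uniformly in
    ``maf_range``).  Deterministic given ``seed``.
    """
    if n_lines < 2 or n_snps < 1:
        raise ParameterError("need n_lines >= 2 and n_snps >= 1")
    low, high = maf_range
    if not (0.0 < low < high <= 0.5):
        raise ParameterError(f"degenerate maf_range {maf_range}")
    if not 0.0 <= ld_rho < 1.0:
        raise ParameterError(f"ld_rho {ld_rho} outside [0, 1)")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(low, high, size=n_snps)
    hap = np.empty((2 * n_lines, n_snps), dtype=np.int8)
    hap[:, 0] = rng.random(2 * n_lines) < freqs[0]
    for j in range(1, n_snps):
        fresh = rng.random(2 * n_lines) < freqs[j]
        copy = rng.random(2 * n_lines) < ld_rho
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    dosage = (hap[0::2] + hap[1::2]).astype(float)
    width = len(str(n_lines))
    line_ids = [f"{line_prefix}{i + 1:0{width}d}" for i in range(n_lines)]
    # synthetic positions: one chromosome-sized axis, 1 kb spacing over 12 chromosomes
    per_chrom = -(-n_snps // 12)
    snps = []
    for j in range(n_snps):
        chrom = j // per_chrom + 1
        pos = (j % per_chrom + 1) * 1000
        snps.append(SnpRecord(SnpRecord.auto_id(chrom, pos), chrom, pos, "A", "G"))
    return GenotypeMatrix(line_ids, snps, dosage)


def expected_adjacent_r2(f_prev: float, f_here: float, ld_rho: float) -> float:
    """Closed-form adjacent-SNP haplotype r^2 for the copying process.

    With marginal frequency ``f_prev`` at the previous SNP, the next allele
    copies it with probability rho, else is Bernoulli(``f_here``); dosage
    correlation equals haplotype correlation because the two haplotypes of
    a line are independent.
    """
    f2 = ld_rho * f_prev + (1 - ld_rho) * f_here  # marginal at the next SNP
    cov = ld_rho * f_prev * (1 - f_prev)
    denom = np.sqrt(f_prev * (1 - f_prev) * f2 * (1 - f2))
    return float((cov / denom) ** 2) if denom > 0 else 0.0


def _component_architecture(
    truth: TruthRecord, n_snps: int, rng: np.random.Generator
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per trait: (effect vector over all SNPs, polygenic effect vector)."""
    causal_all = {i for t in COMPONENTS for i in truth.causal_indices(t)}
    causal_all |= {i for i, _ in truth.direct_yield_effects}
    non_causal = np.array(sorted(set(range(n_snps)) - causal_all))
    arch: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for t in COMPONENTS:
        beta = np.zeros(n_snps)
        for i, eff in truth.component_effects.get(t, []):
            if not 0 <= i < n_snps:
                raise ParameterError(f"causal snp_index {i} outside panel of {n_snps}")
            beta[i] = eff
        poly = np.zeros(n_snps)
        n_poly = min(truth.n_polygenic, len(non_causal))
        if n_poly > 0 and truth.polygenic_fraction > 0:
            chosen = rng.choice(non_causal, size=n_poly, replace=False)
            poly[chosen] = rng.standard_normal(n_poly)
        arch[t] = (beta, poly)
    return arch


def _orthogonalize(y: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project y orthogonal to span([1, basis columns])."""
    X = np.column_stack([np.ones(len(y)), basis])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def simulate_study(
    truth: TruthRecord,
    populations: Mapping[str, int],
    environments: Sequence[str] = ("E1",),
    n_snps: int = 5000,
    maf_range: tuple[float, float] = (0.1, 0.5),
    ld_rho: float = 0.0,
    exclusivity: str = "disjoint",
) -> SimulatedStudy:
    """Simulate genotypes and phenotypes for populations x environments.

    Each population gets its own genotype panel (shared across its
    environments); each (population, environment) pair is one dataset with
    id ``"{pop}:{env}"``.  Deterministic given ``truth.seed``.
    """
    if exclusivity not in ("none", "disjoint", "strict"):
        raise ParameterError(f"unknown exclusivity mode {exclusivity!r}")
    if exclusivity in ("disjoint", "strict"):
        seen: set[int] = set()
        for t in COMPONENTS:
            idx = set(truth.causal_indices(t))
            if idx & seen:
                raise ParameterError(
                    "exclusivity-compatible simulation requires disjoint causal "
                    f"SNP sets; overlap at {sorted(idx & seen)}"
                )
            seen |= idx
    rng = np.random.default_rng(truth.seed)
    arch = _component_architecture(truth, n_snps, rng)
    w = dict(zip(COMPONENTS, truth.yield_weights))

    genotypes: dict[str, GenotypeMatrix] = {}
    records: list[tuple[str, str, str, float]] = []
    for pop, n_lines in populations.items():
        g = simulate_genotypes(
            n_lines,
            n_snps,
            maf_range,
            ld_rho,
            seed=int(rng.integers(2**31)),
            line_prefix=f"{pop}_L",
        )
        D = np.nan_to_num(g.dosage)  # generator never emits missing, but be safe
        Dc = D - D.mean(axis=0)
        components: dict[str, dict[str, np.ndarray]] = {e: {} for e in environments}
        for t in COMPONENTS:
            beta, poly = arch[t]
            h2 = truth.heritability.get(t, 0.0)
            g_major = Dc @ beta
            var_major = float(np.var(g_major))
            g_poly = Dc @ poly
            var_poly_raw = float(np.var(g_poly))
            pf = truth.polygenic_fraction
            if var_major > 0 and pf > 0 and var_poly_raw > 0:
                target_poly = var_major * pf / (1 - pf)
                g_poly *= np.sqrt(target_poly / var_poly_raw)
            elif var_major == 0 and h2 > 0 and var_poly_raw > 0:
                # purely polygenic trait: give the genetic part unit variance
                g_poly /= np.sqrt(var_poly_raw)
            else:
                g_poly = np.zeros(n_lines)
            g_total = g_major + g_poly
            var_g = float(np.var(g_total))
            if var_g > 0 and h2 > 0:
                noise_sd = np.sqrt(var_g * (1 - h2) / h2)
            elif var_g > 0 and h2 == 0:
                raise ParameterError(
                    f"trait {t}: nonzero genetic effects but h2 = 0 is inconsistent"
                )
            else:
                noise_sd = truth.base_noise_sd.get(t, 1.0)
            for env in environments:
                dataset = f"{pop}:{env}"
                shift = truth.env_shifts.get((dataset, t), 0.0)
                e = noise_sd * rng.standard_normal(n_lines) if noise_sd > 0 else 0.0
                y = truth.intercepts.get(t, 0.0) + g_total + shift + e
                components[env][t] = y
        if exclusivity == "strict":
            for env in environments:
                for t in COMPONENTS:
                    others = [
                        i
                        for t2 in COMPONENTS
                        if t2 != t
                        for i in truth.causal_indices(t2)
                    ]
                    if others:
                        mu = components[env][t].mean()
                        resid = _orthogonalize(components[env][t] - mu, D[:, others])
                        components[env][t] = mu + resid
        direct = np.zeros(n_lines)
        for i, eff in truth.direct_yield_effects:
            direct += eff * Dc[:, i]
        for env in environments:
            dataset = f"{pop}:{env}"
            e_y = (
                truth.yield_noise_sd * rng.standard_normal(n_lines)
                if truth.yield_noise_sd > 0
                else 0.0
            )
            yd = (
                truth.intercepts.get("YD", 0.0)
                + sum(w[t] * components[env][t] for t in COMPONENTS)
                + direct
                + truth.env_shifts.get((dataset, "YD"), 0.0)
                + e_y
            )
            genotypes[dataset] = g
            for t in COMPONENTS:
                records += [
                    (lid, dataset, t, float(v))
                    for lid, v in zip(g.line_ids, components[env][t])
                ]
            records += [(lid, dataset, "YD", float(v)) for lid, v in zip(g.line_ids, yd)]

    frame = pd.DataFrame(records, columns=PhenotypeTable.COLUMNS)
    return SimulatedStudy(genotypes, PhenotypeTable(frame), truth)


def default_truth(
    n_snps: int = 5000,
    seed: int = 0,
    n_causal_per_trait: int = 8,
    n_direct: int = 3,
    heritability: float = 0.5,
) -> TruthRecord:
    """A realistic default causal architecture for a hybrid-rice panel.

    Component trait scales target SDs of roughly 30 grains (GPP), 2.5 g
    (KGW) and 2.5 tillers (TP); each major causal SNP explains a few
    percent of trait variance, in line with effect sizes seen in hybrid
    rice association panels.  Yield weights are the linearization of
    YD = GPP * TP * KGW/1000 around (150 grains, 25 g, 10 tillers):
    (0.25, 1.5, 3.75) with intercept -75 g, giving mean yield near 37 g per
    plant.  Causal loci for different traits are spread far apart along the
    genome so LD never couples two traits' instruments.
    """
    rng = np.random.default_rng(seed)
    trait_sd = {"GPP": 30.0, "KGW": 2.5, "TP": 2.5}
    n_loci = n_causal_per_trait * len(COMPONENTS) + n_direct
    slots = np.linspace(0, n_snps - 1, n_loci + 2)[1:-1].astype(int)
    rng.shuffle(slots)
    effects: dict[str, list[tuple[int, float]]] = {}
    cursor = 0
    for t in COMPONENTS:
        idx = slots[cursor : cursor + n_causal_per_trait]
        cursor += n_causal_per_trait
        mags = 0.4 * trait_sd[t] * rng.uniform(0.85, 1.15, size=len(idx))
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        effects[t] = [(int(i), float(m * s)) for i, m, s in zip(idx, mags, signs)]
    direct_idx = slots[cursor : cursor + n_direct]
    direct = [
        (int(i), float(1.5 * s))
        for i, s in zip(direct_idx, rng.choice([-1.0, 1.0], size=n_direct))
    ]
    return TruthRecord(
        component_effects=effects,
        yield_weights=(0.25, 1.5, 3.75),
        direct_yield_effects=direct,
        heritability={t: heritability for t in COMPONENTS},
        env_shifts={},
        seed=seed,
        intercepts={"GPP": 150.0, "KGW": 25.0, "TP": 10.0, "YD": -75.0},
    )
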