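"""Fixed- and random-effects meta-analysis of GWAS summary statistics.

The primary model is the inverse-variance-weighted fixed-effect estimator
(METAL convention): each study is weighted by the inverse of its squared
standard error.  Cochran's Q assesses heterogeneity, with
I^2 = max(0, (Q - df) / Q); when I^2 >= 50% the SNP is re-combined under a
DerSimonian-Laird random-effects model.  Genome-wide significance for the
meta scan defaults to P < 1e-6.

Alleles are aligned on A1/A2 before combining: a study whose A1 matches the
reference A2 has its beta sign-flipped; an unresolvable mismatch drops the
SNP with a log entry.  SNPs present in only a subset of studies are
combined over that subset (METAL behavior).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import AssocStat, SnpRecord, ValidationError

__all__ = ["MetaStat", "meta_fixed", "meta_random", "cochran_q", "run_meta_gwas"]

log = logging.getLogger("ricemr.meta")

#: heterogeneity level at which the random-effects model takes over.
I2_SWITCH = 0.5


@dataclass(frozen=True)
class MetaStat:
    """Meta-analytic per-SNP summary with heterogeneity fields."""

    snp: SnpRecord
    trait: str
    beta: float
    se: float
    p: float
    k: int
    Q: float
    df: int
    i2: float
    model: str  # "fixed" | "random"

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"{self.snp.snp_id}: meta SE must be > 0")
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"{self.snp.snp_id}: meta P outside (0, 1]")
        if self.model not in ("fixed", "random"):
            raise ValidationError(f"unknown meta model {self.model!r}")


def cochran_q(
    betas: Sequence[float], ses: Sequence[float]
) -> tuple[float, int, float, float]:
    """Cochran's Q about the fixed-effect mean; returns (Q, df, p, i2).

    For a single study Q = 0, df = 0 and p is reported as 1 (undefined-as-1
    convention).  i2 = max(0, (Q - df)/Q), 0 when Q = 0.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape:
        raise ValidationError("betas and ses differ in length")
    if (s <= 0).any():
        raise ValidationError("all standard errors must be > 0")
    k = len(b)
    w = 1.0 / s**2
    mu = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - mu) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(Q, df)) if df >= 1 else 1.0
    i2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return Q, df, p, i2


def _check_homogeneous(stats_: Sequence[AssocStat]) -> None:
    if not stats_:
        raise ValidationError("empty study list")
    ids = {s.snp.snp_id for s in stats_}
    if len(ids) > 1:
        raise ValidationError(f"mixed snp ids in one combination: {sorted(ids)}")
    traits = {s.trait for s in stats_}
    if len(traits) > 1:
        raise ValidationError(f"mixed traits in one combination: {sorted(traits)}")


def meta_fixed(stats_: Sequence[AssocStat]) -> MetaStat:
    """Inverse-variance-weighted fixed-effect combination of >= 1 studies."""
    _check_homogeneous(stats_)
    b = np.array([s.beta for s in stats_])
    se = np.array([s.se for s in stats_])
    w = 1.0 / se**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_meta = float(1.0 / np.sqrt(np.sum(w)))
    p = float(np.clip(2 * stats.norm.sf(abs(beta) / se_meta), np.nextafter(0, 1), 1.0))
    Q, df, _, i2 = cochran_q(b, se)
    return MetaStat(stats_[0].snp, stats_[0].trait, beta, se_meta, p,
                    len(stats_), Q, df, i2, "fixed")


def meta_random(stats_: Sequence[AssocStat]) -> MetaStat:
    """DerSimonian-Laird random-effects combination of >= 2 studies.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w; studies are then re-weighted by 1/(se^2 + tau^2).  When
    Q <= df this collapses to the fixed-effect result.
    """
    _check_homogeneous(stats_)
    if len(stats_) < 2:
        raise ValidationError("random-effects model needs k >= 2 studies")
    b = np.array([s.beta for s in stats_])
    se = np.array([s.se for s in stats_])
    w = 1.0 / se**2
    Q, df, _, i2 = cochran_q(b, se)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    beta = float(np.sum(w_star * b) / np.sum(w_star))
    se_meta = float(1.0 / np.sqrt(np.sum(w_star)))
    p = float(np.clip(2 * stats.norm.sf(abs(beta) / se_meta), np.nextafter(0, 1), 1.0))
    return MetaStat(stats_[0].snp, stats_[0].trait, beta, se_meta, p,
                    len(stats_), Q, df, i2, "random")


def _align(ref: AssocStat, other: AssocStat) -> AssocStat | None:
    """Flip ``other``'s beta if its effect allele is ``ref``'s other allele;
    return None when alleles cannot be reconciled."""
    ra, ro = ref.snp.allele_alt, ref.snp.allele_ref
    oa, oo = other.snp.allele_alt, other.snp.allele_ref
    if (oa, oo) == (ra, ro):
        return other
    if (oa, oo) == (ro, ra):
        return AssocStat(ref.snp, other.trait, other.dataset_id,
                         -other.beta, other.se, other.p, other.n)
    return None


_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def run_meta_gwas(
    per_dataset_stats: Sequence[Sequence[AssocStat]],
    trait: str,
    alpha: float = 1e-6,
) -> tuple[list[MetaStat], list[MetaStat]]:
    """Combine per-dataset scans into meta statistics for one trait.

    Per SNP: fixed-effect IVW; if I^2 >= 50% the DerSimonian-Laird
    random-effects estimate replaces it (the ``model`` field records
    which).  Returns (all meta stats in genome order, significant subset
    with p strictly below ``alpha``).
    """
    by_snp: dict[str, list[AssocStat]] = {}
    order: list[str] = []
    for table in per_dataset_stats:
        for s in table:
            if s.trait and s.trait != trait:
                raise ValidationError(
                    f"summary table for trait {s.trait!r} passed to meta of {trait!r}"
                )
            if s.snp.snp_id not in by_snp:
                by_snp[s.snp.snp_id] = []
                order.append(s.snp.snp_id)
            by_snp[s.snp.snp_id].append(s)

    out: list[MetaStat] = []
    for snp_id in order:
        group = by_snp[snp_id]
        ref = group[0]
        if frozenset((ref.snp.allele_ref, ref.snp.allele_alt)) in _AMBIGUOUS:
            warnings.warn(
                f"{snp_id}: strand-ambiguous alleles "
                f"{ref.snp.allele_ref}/{ref.snp.allele_alt}; passing through",
                stacklevel=2,
            )
        aligned: list[AssocStat] = []
        dropped = False
        for s in group:
            a = _align(ref, s)
            if a is None:
                log.warning("%s: allele mismatch not resolvable by flipping; "
                            "SNP dropped", snp_id)
                dropped = True
                break
            aligned.append(a)
        if dropped:
            continue
        aligned = [
            AssocStat(ref.snp, trait, a.dataset_id, a.beta, a.se, a.p, a.n)
            for a in aligned
        ]
        m = meta_fixed(aligned)
        if m.i2 >= I2_SWITCH and m.k >= 2:
            m = meta_random(aligned)
        out.append(m)
    significant = [m for m in out if m.p < alpha]
    log.info("meta %s: %d SNPs combined, %d significant at p<%g",
             trait, len(out), len(significant), alpha)
    return out, significant
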