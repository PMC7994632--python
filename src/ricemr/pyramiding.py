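"""Superior-allele assignment and allele-pyramiding summaries.

At each significant locus the genotype *class* (hom-ref / het / hom-alt)
with the highest mean of the defining trait is the superior genotype —
classes, not a dosage regression, because heterozygous classes matter in
F1 hybrids.  Lines are then scored by how many loci carry their superior
class, and mean yield is summarized per superior-allele count; groups with
fewer than ``min_lines`` (default 3) lines are omitted.  Pairwise group
comparisons use Fisher's least significant difference on the one-way-ANOVA
pooled error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, ValidationError

__all__ = [
    "SuperiorAllele",
    "SuperiorAlleleMap",
    "PyramidSummary",
    "assign_superior_alleles",
    "pyramid_summary",
    "lsd_test",
]

log = logging.getLogger("ricemr.pyramiding")

CLASS_NAMES = {0: "hom_ref", 1: "het", 2: "hom_alt"}


@dataclass(frozen=True)
class SuperiorAllele:
    """The best genotype class at one locus for its defining trait."""

    snp_id: str
    superior_class: int  # dosage 0, 1 or 2
    class_means: dict[int, float]
    class_counts: dict[int, int]

    @property
    def superior_name(self) -> str:
        return CLASS_NAMES[self.superior_class]


SuperiorAlleleMap = dict[str, SuperiorAllele]


@dataclass
class PyramidSummary:
    """Mean yield per superior-allele count plus LSD comparisons."""

    groups: pd.DataFrame  # columns: superior_allele_count, n_lines, mean_yield
    lsd: pd.DataFrame  # pairwise comparisons across retained groups
    omitted: pd.DataFrame  # groups dropped for having < min_lines lines


def assign_superior_alleles(
    g: GenotypeMatrix, pheno: np.ndarray, snps: Sequence[str]
) -> SuperiorAlleleMap:
    """Per SNP, the genotype class with the maximal trait mean.

    Classes with zero lines are excluded from the argmax; exact ties go to
    the lower dosage class (deterministic convention).  Monomorphic SNPs
    in the phenotyped lines are skipped with a log entry.
    """
    pheno = np.asarray(pheno, dtype=float)
    out: SuperiorAlleleMap = {}
    for snp_id in snps:
        d = g.column(snp_id)
        ok = ~(np.isnan(d) | np.isnan(pheno))
        means: dict[int, float] = {}
        counts: dict[int, int] = {}
        for cls in (0, 1, 2):
            mask = ok & (d == cls)
            n = int(mask.sum())
            if n:
                counts[cls] = n
                means[cls] = float(pheno[mask].mean())
        if len(counts) < 2:
            log.info("assign_superior_alleles: %s monomorphic in phenotyped "
                     "lines; skipped", snp_id)
            continue
        best = max(sorted(means), key=lambda c: (means[c], -c))
        out[snp_id] = SuperiorAllele(snp_id, best, means, counts)
    return out


def pyramid_summary(
    g: GenotypeMatrix,
    superior: SuperiorAlleleMap,
    yield_pheno: np.ndarray,
    min_lines: int = 3,
    alpha: float = 0.05,
) -> PyramidSummary:
    """Group lines by their count of superior genotype classes and report
    mean yield per group, omitting groups with fewer than ``min_lines``
    lines; LSD comparisons run across the retained groups."""
    y = np.asarray(yield_pheno, dtype=float)
    counts = np.zeros(g.n_lines, dtype=int)
    for snp_id, sup in superior.items():
        counts += (g.column(snp_id) == sup.superior_class).astype(int)
    ok = ~np.isnan(y)
    rows = []
    group_values: dict[int, np.ndarray] = {}
    for c in sorted(set(counts[ok])):
        vals = y[ok & (counts == c)]
        rows.append((c, len(vals), float(vals.mean())))
        group_values[c] = vals
    frame = pd.DataFrame(rows, columns=["superior_allele_count", "n_lines", "mean_yield"])
    retained = frame[frame["n_lines"] >= min_lines].reset_index(drop=True)
    omitted = frame[frame["n_lines"] < min_lines].reset_index(drop=True)
    for c in omitted["superior_allele_count"]:
        log.info("pyramid_summary: omitting count=%d group (<%d lines)", c, min_lines)
    kept_groups = [group_values[c] for c in retained["superior_allele_count"]]
    labels = [str(c) for c in retained["superior_allele_count"]]
    if len(kept_groups) >= 2 and all(len(v) >= 2 for v in kept_groups):
        try:
            lsd = lsd_test(kept_groups, alpha=alpha, labels=labels)
        except ValidationError:
            log.info("pyramid_summary: zero pooled variance; LSD table empty")
            lsd = pd.DataFrame(
                columns=["group_a", "group_b", "mean_diff", "t", "p", "significant"]
            )
    else:
        if retained.empty:
            import warnings

            warnings.warn("no superior-allele-count group has enough lines",
                          stacklevel=2)
        lsd = pd.DataFrame(
            columns=["group_a", "group_b", "mean_diff", "t", "p", "significant"]
        )
    return PyramidSummary(retained, lsd, omitted)


def lsd_test(
    groups: Sequence[np.ndarray],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons on the one-way-ANOVA pooled error.

    t = |mean_a - mean_b| / sqrt(MSE (1/n_a + 1/n_b)) with df = N - k;
    pairs are flagged significant at ``alpha``.
    """
    groups = [np.asarray(v, dtype=float) for v in groups]
    if len(groups) < 2:
        raise ValidationError("LSD needs at least two groups")
    if any(len(v) < 2 for v in groups):
        raise ValidationError("every group needs n >= 2")
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    N = sum(len(v) for v in groups)
    k = len(groups)
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in groups)
    df = N - k
    mse = sse / df
    if mse == 0.0:
        raise ValidationError("zero pooled variance; LSD undefined")
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            va, vb = groups[a], groups[b]
            diff = float(va.mean() - vb.mean())
            t = abs(diff) / np.sqrt(mse * (1.0 / len(va) + 1.0 / len(vb)))
            p = float(2 * stats.t.sf(t, df))
            rows.append((labels[a], labels[b], diff, float(t), p, p < alpha))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_diff", "t", "p", "significant"]
    )
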