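"""Per-dataset mixed-linear-model association scan (EMMAX-style).

The model is y = Xb + g + e with g ~ N(0, A sigma_g^2), e ~ N(0, I
sigma_e^2) and A the genomic relationship matrix built from standardized
dosages.  Variance components are estimated once under the null by REML —
profiled down to a one-dimensional optimization over h^2 = sigma_g^2 /
(sigma_g^2 + sigma_e^2) in the GRM eigenbasis — and then held fixed for
every SNP's generalized-least-squares test (the EMMAX approximation, which
matches GCTA --mlma defaults).  P-values use the two-sided normal
reference, matching GCTA output and the normal theory of the meta stage.

Missing dosages are mean-imputed per SNP (both in the GRM and in the scan);
lines with a missing phenotype are dropped for that trait before fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io_formats import AssocStat, GenotypeMatrix, ValidationError

__all__ = [
    "VarianceComponents",
    "GrmEigen",
    "qc_filter",
    "compute_grm",
    "fit_null_lmm",
    "mlma_scan",
]

log = logging.getLogger("ricemr.gwas")


@dataclass
class VarianceComponents:
    """REML genetic / residual variance components of the null model."""

    sigma_g2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValidationError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def qc_filter(
    g: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.20
) -> GenotypeMatrix:
    """Retain SNPs with MAF strictly above ``maf_min`` and missing fraction
    strictly below ``missing_max``; the line set is unchanged.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValidationError(f"maf_min {maf_min} outside [0, 0.5)")
    if not 0.0 <= missing_max <= 1.0:
        raise ValidationError(f"missing_max {missing_max} outside [0, 1]")
    keep = (g.maf() > maf_min) & (g.missing_rate() < missing_max)
    if not keep.any():
        warnings.warn("QC removed every SNP; returning an empty panel", stacklevel=2)
    log.info("qc_filter: %d -> %d SNPs (maf>%g, miss<%g)",
             g.n_snps, int(keep.sum()), maf_min, missing_max)
    return g.subset_snps(keep)


def _imputed_standardized(g: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed, column-standardized dosage matrix Z with
    Z_ij = (d_ij - 2 f_j) / sqrt(2 f_j (1 - f_j))."""
    f = g.alt_freq()
    mono = (f <= 0.0) | (f >= 1.0) | ~np.isfinite(f)
    if mono.any():
        bad = [g.snps[i].snp_id for i in np.flatnonzero(mono)[:5]]
        raise ValidationError(f"monomorphic SNP(s) in panel, e.g. {bad}")
    D = g.dosage.copy()
    miss = np.isnan(D)
    if miss.any():
        D[miss] = np.broadcast_to(2 * f, D.shape)[miss]
    return (D - 2 * f) / np.sqrt(2 * f * (1 - f))


def compute_grm(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden-style GRM: Z Z^T / m over standardized dosages."""
    Z = _imputed_standardized(g)
    return (Z @ Z.T) / g.n_snps


@dataclass
class GrmEigen:
    """Eigendecomposition of a GRM, shared between the REML fit and the scan."""

    values: np.ndarray  # ascending
    vectors: np.ndarray  # columns

    @classmethod
    def from_grm(cls, grm: np.ndarray, tol: float = 1e-8) -> "GrmEigen":
        grm = np.asarray(grm, dtype=float)
        if not np.allclose(grm, grm.T, atol=1e-10):
            raise ValidationError("GRM is not symmetric")
        vals, vecs = np.linalg.eigh(grm)
        if vals.min() < -tol * max(1.0, vals.max()):
            raise ValidationError(
                f"GRM not positive semi-definite (min eigenvalue {vals.min():.3g})"
            )
        return cls(np.maximum(vals, 0.0), vecs)


def _as_eigen(grm: np.ndarray | GrmEigen) -> GrmEigen:
    return grm if isinstance(grm, GrmEigen) else GrmEigen.from_grm(np.asarray(grm))


def _reml_neg_loglik(h2: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray) -> float:
    v = h2 * d + (1.0 - h2)
    w = 1.0 / v
    XtWX = (Xt * w[:, None]).T @ Xt
    XtWy = (Xt * w[:, None]).T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yt - Xt @ beta
    n, p = Xt.shape
    rss = float(resid @ (w * resid))
    sigma2 = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    return 0.5 * (
        (n - p) * np.log(sigma2) + np.sum(np.log(v)) + logdet_xwx + (n - p)
    )


def fit_null_lmm(
    y: np.ndarray,
    grm: np.ndarray | GrmEigen,
    covariates: np.ndarray | None = None,
) -> VarianceComponents:
    """REML variance components via GRM eigendecomposition and a 1-D
    profile optimization over h^2 on [0, 1].

    With a flat likelihood (e.g. an identity GRM, where sigma_g and sigma_e
    are not separately identifiable) the convention is h^2 = 0 with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValidationError("phenotype vector contains missing values; drop lines first")
    eig = _as_eigen(grm)
    U, d = eig.vectors, eig.values
    X = np.ones((len(y), 1))
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    yt, Xt = U.T @ y, U.T @ X
    obj = lambda h2: _reml_neg_loglik(h2, yt, Xt, d)
    res = optimize.minimize_scalar(obj, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    h2 = float(res.x)
    ll_opt, ll_zero = -res.fun, -obj(0.0)
    if ll_opt - ll_zero < 1e-6:
        if abs(ll_opt - ll_zero) < 1e-6 and h2 > 1e-3:
            warnings.warn(
                "REML likelihood is flat in h2 (variance components not "
                "identifiable); returning h2 = 0",
                stacklevel=2,
            )
        h2 = 0.0
    # profile scale at the optimum
    v = h2 * d + (1.0 - h2)
    w = 1.0 / v
    XtWX = (Xt * w[:, None]).T @ Xt
    beta = np.linalg.solve(XtWX, (Xt * w[:, None]).T @ yt)
    resid = yt - Xt @ beta
    n, p = Xt.shape
    sigma2 = float(resid @ (w * resid)) / (n - p)
    return VarianceComponents(sigma_g2=sigma2 * h2, sigma_e2=sigma2 * (1.0 - h2))


def mlma_scan(
    g: GenotypeMatrix,
    y: np.ndarray,
    vc: VarianceComponents,
    grm: np.ndarray | GrmEigen | None = None,
    trait: str = "",
    dataset_id: str = "",
    covariates: np.ndarray | None = None,
) -> list[AssocStat]:
    """Per-SNP GLS association under V = sigma_g^2 GRM + sigma_e^2 I.

    Variance components stay fixed at the null estimates for every SNP
    (EMMAX convention); the system is solved in the GRM eigenbasis.  SNPs
    with zero dosage variance are skipped with a log entry.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValidationError("phenotype vector contains missing values; drop lines first")
    eig = _as_eigen(compute_grm(g) if grm is None else grm)
    U, d = eig.vectors, eig.values
    v = vc.sigma_g2 * d + vc.sigma_e2
    w = 1.0 / v

    f = g.alt_freq()
    D = g.dosage.copy()
    miss = np.isnan(D)
    if miss.any():
        D[miss] = np.broadcast_to(2 * f, D.shape)[miss]
    var0 = D.var(axis=0)
    testable = var0 > 0
    skipped = np.flatnonzero(~testable)
    for i in skipped[:10]:
        log.info("mlma_scan: skipping zero-variance SNP %s", g.snps[i].snp_id)
    if len(skipped) > 10:
        log.info("mlma_scan: ... and %d more zero-variance SNPs", len(skipped) - 10)

    X = np.ones((len(y), 1))
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    if X.shape[1] > 1:  # residualize covariates out under V, then test dosage
        Xt = U.T @ X
        XtWX = (Xt * w[:, None]).T @ Xt
        yt_full = U.T @ y
        beta_c = np.linalg.solve(XtWX, (Xt * w[:, None]).T @ yt_full)
        y = y - X[:, 1:] @ beta_c[1:]

    Gt = U.T @ D[:, testable]
    yt = U.T @ y
    ot = U.T @ np.ones(len(y))

    s_oo = float(ot @ (w * ot))
    s_oy = float(ot @ (w * yt))
    s_ox = (w * ot) @ Gt
    s_xy = (w * yt) @ Gt
    s_xx = w @ (Gt * Gt)
    det = s_oo * s_xx - s_ox**2
    beta = (s_oo * s_xy - s_ox * s_oy) / det
    se = np.sqrt(s_oo / det)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    n = len(y)
    out: list[AssocStat] = []
    for k, j in enumerate(np.flatnonzero(testable)):
        out.append(
            AssocStat(
                snp=g.snps[j],
                trait=trait,
                dataset_id=dataset_id,
                beta=float(beta[k]),
                se=float(se[k]),
                p=float(p[k]),
                n=n,
            )
        )
    return out
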