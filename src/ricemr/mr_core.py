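"""Two-sample Mendelian-randomization estimators and sensitivity analyses.

All estimators operate on an :class:`~ricemr.instruments.InstrumentSet`
through per-SNP Wald ratios beta_Y / beta_X with first-order delta-method
standard errors se_Y / |beta_X| (exposure-side uncertainty ignored, the
standard two-sample construction), hence inverse-variance weights
w = beta_X^2 / se_Y^2.

* IVW — the weighted mean of Wald ratios, with a multiplicative
  random-effects scale max(1, sqrt(Q / (k - 1))) on its SE so that
  over-dispersed instrument sets get honestly wider intervals while
  homogeneous sets keep the fixed-effect SE.
* Weighted median — the ratio at standardized cumulative weight 1/2,
  consistent while valid instruments carry more than half the weight; its
  SE comes from a seeded parametric bootstrap of the ratios.
* MR-Egger — weighted regression of outcome betas on exposure betas with a
  free intercept after orienting every instrument to beta_X > 0; a nonzero
  intercept flags directional pleiotropy.  Coefficient SEs are scaled by
  max(1, sqrt(RSS_w / (k - 2))).

95% CIs are estimate +/- 1.959964 * SE and p-values are two-sided normal
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .instruments import Instrument, InstrumentSet
from .io_formats import ValidationError
from .meta_gwas import cochran_q

__all__ = [
    "WaldRatio",
    "MrResult",
    "wald_ratios",
    "ivw",
    "weighted_median",
    "mr_egger",
    "heterogeneity",
    "split_by_ratio_sign",
]

Z95 = 1.959964


@dataclass(frozen=True)
class WaldRatio:
    """Per-SNP causal estimate: outcome effect over exposure effect."""

    snp_id: str
    ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se_ratio**2


@dataclass(frozen=True)
class MrResult:
    """A causal-effect estimate in outcome units per exposure unit."""

    method: str  # "ivw" | "weighted_median" | "mr_egger"
    estimate: float
    se: float
    p: float
    k: int
    scale_factor: float = 1.0
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def ci_low(self) -> float:
        return self.estimate - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z95 * self.se

    @property
    def intercept_ci(self) -> tuple[float, float] | None:
        if self.intercept is None:
            return None
        return (self.intercept - Z95 * self.intercept_se,
                self.intercept + Z95 * self.intercept_se)


def _two_sided_p(est: float, se: float) -> float:
    return float(np.clip(2 * stats.norm.sf(abs(est) / se), np.nextafter(0, 1), 1.0))


def wald_ratios(s: InstrumentSet) -> list[WaldRatio]:
    """First-order Wald ratios; a zero exposure effect is degenerate."""
    out = []
    for ins in s.instruments:
        if ins.beta_x == 0.0:
            raise ValidationError(
                f"{ins.snp.snp_id}: beta_x = 0, Wald ratio undefined"
            )
        out.append(
            WaldRatio(ins.snp.snp_id, ins.beta_y / ins.beta_x,
                      ins.se_y / abs(ins.beta_x))
        )
    return out


def ivw(s: InstrumentSet) -> MrResult:
    """Inverse-variance-weighted estimate over >= 1 instruments.

    The SE is the fixed-effect 1/sqrt(sum w) inflated by
    max(1, sqrt(Q/(k-1))) — the multiplicative random-effects convention —
    with the factor fixed at 1 when k = 1.
    """
    if s.k == 0:
        raise ValidationError("IVW needs at least one instrument")
    wr = wald_ratios(s)
    r = np.array([x.ratio for x in wr])
    w = np.array([x.weight for x in wr])
    est = float(np.sum(w * r) / np.sum(w))
    se0 = float(1.0 / np.sqrt(np.sum(w)))
    if s.k > 1:
        Q, df, _, _ = cochran_q(r, [x.se_ratio for x in wr])
        scale = max(1.0, float(np.sqrt(Q / df)))
    else:
        scale = 1.0
    se = se0 * scale
    return MrResult("ivw", est, se, _two_sided_p(est, se), s.k, scale)


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="stable")
    r_s, w_s = r[order], w[order] / w.sum()
    s = np.cumsum(w_s) - w_s / 2.0
    if 0.5 <= s[0]:
        return float(r_s[0])
    if 0.5 >= s[-1]:
        return float(r_s[-1])
    return float(np.interp(0.5, s, r_s))


def weighted_median(s: InstrumentSet, n_boot: int = 10000, seed: int = 0) -> MrResult:
    """Weighted-median estimate over >= 3 instruments.

    The point estimate interpolates the sorted Wald ratios at standardized
    cumulative weight 0.5 (clamped to the extreme ratios outside the
    range); the SE is the standard deviation of the estimate over
    ``n_boot`` parametric bootstrap draws ratio* ~ N(ratio, se_ratio) with
    the weights held fixed.
    """
    if s.k < 3:
        raise ValidationError(f"weighted median needs k >= 3 instruments, got {s.k}")
    wr = wald_ratios(s)
    r = np.array([x.ratio for x in wr])
    se_r = np.array([x.se_ratio for x in wr])
    w = np.array([x.weight for x in wr])
    est = _weighted_median_point(r, w)

    rng = np.random.default_rng(seed)
    draws = rng.normal(r, se_r, size=(n_boot, s.k))
    order = np.argsort(draws, axis=1, kind="stable")
    r_s = np.take_along_axis(draws, order, axis=1)
    w_s = (w / w.sum())[order]
    cum = np.cumsum(w_s, axis=1) - w_s / 2.0
    # vectorized interpolation of each bootstrap row at cumulative weight 0.5
    j = np.clip((cum < 0.5).sum(axis=1), 1, s.k - 1)
    rows = np.arange(n_boot)
    x0, x1 = cum[rows, j - 1], cum[rows, j]
    y0, y1 = r_s[rows, j - 1], r_s[rows, j]
    t = np.clip((0.5 - x0) / np.where(x1 > x0, x1 - x0, 1.0), 0.0, 1.0)
    boots = y0 + t * (y1 - y0)
    boots = np.where(0.5 <= cum[:, 0], r_s[:, 0], boots)
    boots = np.where(0.5 >= cum[:, -1], r_s[:, -1], boots)
    se = float(boots.std(ddof=1))
    if se == 0.0:
        se = float(np.min(se_r) / np.sqrt(s.k))  # degenerate identical-ratio case
    return MrResult("weighted_median", est, se, _two_sided_p(est, se), s.k)


def mr_egger(s: InstrumentSet) -> MrResult:
    """MR-Egger weighted regression with intercept over >= 3 instruments.

    Instruments are oriented so every exposure beta is positive (outcome
    beta flipped jointly); outcome betas are regressed on exposure betas
    with weights 1/se_Y^2.  Coefficient SEs from the WLS information
    matrix are scaled by max(1, sqrt(RSS_w / (k - 2))).
    """
    if s.k < 3:
        raise ValidationError(f"MR-Egger needs k >= 3 instruments, got {s.k}")
    bx = np.array([i.beta_x for i in s.instruments])
    by = np.array([i.beta_y for i in s.instruments])
    sy = np.array([i.se_y for i in s.instruments])
    if (bx == 0).any():
        raise ValidationError("beta_x = 0 instrument cannot be oriented")
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    if np.allclose(bx, bx[0]):
        raise ValidationError("all exposure betas equal after orientation; "
                              "Egger design is singular")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    XtW = X.T * w
    info = XtW @ X
    coef = np.linalg.solve(info, XtW @ by)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, float(np.sqrt(rss_w / (s.k - 2))))
    cov = np.linalg.inv(info) * scale**2
    se_i, se_s = np.sqrt(np.diag(cov))
    intercept, slope = float(coef[0]), float(coef[1])
    return MrResult(
        "mr_egger",
        slope,
        float(se_s),
        _two_sided_p(slope, se_s),
        s.k,
        scale,
        intercept=intercept,
        intercept_se=float(se_i),
        intercept_p=_two_sided_p(intercept, se_i),
    )


def heterogeneity(s: InstrumentSet) -> tuple[float, int, float, float]:
    """Cochran's Q over the Wald ratios about the IVW center:
    (Q, df, p, i2)."""
    if s.k < 2:
        raise ValidationError("heterogeneity needs k >= 2 instruments")
    wr = wald_ratios(s)
    return cochran_q([x.ratio for x in wr], [x.se_ratio for x in wr])


def split_by_ratio_sign(s: InstrumentSet) -> tuple[InstrumentSet, InstrumentSet]:
    """Partition instruments by the sign of their Wald ratio (zero counts
    as positive); each subset is analyzed independently downstream."""
    pos: list[Instrument] = []
    neg: list[Instrument] = []
    for ins in s.instruments:
        if ins.beta_x == 0.0:
            raise ValidationError(f"{ins.snp.snp_id}: beta_x = 0")
        (pos if ins.beta_y / ins.beta_x >= 0 else neg).append(ins)
    return s.subset(pos), s.subset(neg)
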