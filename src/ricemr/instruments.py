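"""Mendelian-randomization instrument selection and SE reconstruction.

A valid instrument for exposure trait X on outcome Y must (i) reach
genome-wide significance for X in the meta-GWAS (P < 1e-6 by default),
(ii) be unassociated with confounders — addressed by design in simulation,
not directly testable — and (iii) act on Y only through X, operationalized
as P > 0.05 for every *other* component trait in its meta table.  Surviving
candidates are greedily LD-pruned: scanning in order of ascending exposure
p-value (snp_id as the deterministic tie-break), a SNP is kept only if its
dosage r^2 with every already-kept SNP is at most ``r2_max`` (0.01).

:func:`derive_se` reconstructs a standard error from a printed (beta, p)
pair under the two-sided normal reference — the bridge from published
per-SNP effect tables, which omit SEs, to the MR estimators that need
them.  Instruments selected from meta tables carry the meta SEs directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GenotypeMatrix, SnpRecord, ValidationError
from .meta_gwas import MetaStat

__all__ = [
    "Instrument",
    "InstrumentSet",
    "derive_se",
    "ld_r2",
    "select_instruments",
    "read_instruments",
    "write_instruments",
]

INSTRUMENT_COLUMNS = [
    "SNP", "CHR", "POS", "BETA_X", "SE_X", "P_X", "BETA_Y", "SE_Y", "P_Y",
]

log = logging.getLogger("ricemr.instruments")


@dataclass(frozen=True)
class Instrument:
    """A SNP with exposure-trait and outcome-trait effect estimates."""

    snp: SnpRecord
    beta_x: float
    se_x: float
    p_x: float
    beta_y: float
    se_y: float
    p_y: float

    def __post_init__(self) -> None:
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValidationError(f"{self.snp.snp_id}: instrument SEs must be > 0")


@dataclass
class InstrumentSet:
    """All instruments for one exposure -> outcome pair."""

    exposure: str
    outcome: str
    instruments: list[Instrument]

    def __post_init__(self) -> None:
        ids = [i.snp.snp_id for i in self.instruments]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate snp ids in instrument set")

    @property
    def k(self) -> int:
        return len(self.instruments)

    def subset(self, keep: Sequence[Instrument]) -> "InstrumentSet":
        return InstrumentSet(self.exposure, self.outcome, list(keep))


def derive_se(beta: float, p: float) -> float:
    """SE = |beta| / PHI^-1(1 - p/2), the exact inverse of the two-sided
    normal p-value computed from (beta, se)."""
    if not (0.0 < p < 1.0):
        raise ValidationError(f"p = {p} outside the open interval (0, 1)")
    if beta == 0.0:
        raise ValidationError("beta = 0 with p < 1 has no finite standard error")
    z = stats.norm.isf(p / 2.0)
    return float(abs(beta) / z)


def ld_r2(g: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two dosage vectors over jointly
    non-missing lines."""
    a = g.column(snp_a)
    b = g.column(snp_b)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValidationError(f"fewer than 2 complete lines for {snp_a}/{snp_b}")
    a, b = a[ok], b[ok]
    if a.var() == 0 or b.var() == 0:
        raise ValidationError(
            f"LD undefined: zero dosage variance for {snp_a}/{snp_b}"
        )
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pooled_within_r2(panels: Sequence[GenotypeMatrix], snp_a: str, snp_b: str) -> float:
    """Pooled within-population LD r^2 across one or more panels.

    Dosages are centered within each panel before pooling, so
    allele-frequency differences between populations (stratification) are
    not mistaken for linkage, while the estimate still uses every line.
    """
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for g in panels:
        try:
            a, b = g.column(snp_a), g.column(snp_b)
        except KeyError:
            continue
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 2:
            continue
        xs.append(a[ok] - a[ok].mean())
        ys.append(b[ok] - b[ok].mean())
    if not xs:
        raise ValidationError(f"no panel can estimate LD for {snp_a}/{snp_b}")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    vx, vy = float(x @ x), float(y @ y)
    if vx == 0.0 or vy == 0.0:
        raise ValidationError(
            f"LD undefined: zero pooled dosage variance for {snp_a}/{snp_b}"
        )
    return float((x @ y) ** 2 / (vx * vy))


def select_instruments(
    exposure_meta: Sequence[MetaStat],
    other_traits_meta: Mapping[str, Sequence[MetaStat]],
    outcome_meta: Sequence[MetaStat],
    g: GenotypeMatrix | Sequence[GenotypeMatrix],
    p_sig: float = 1e-6,
    p_excl: float = 0.05,
    r2_max: float = 0.01,
) -> InstrumentSet:
    """Select MR instruments from meta-GWAS tables.

    Keeps SNPs with exposure p strictly below ``p_sig`` whose p strictly
    exceeds ``p_excl`` in *every* other component trait's table, then
    greedily LD-prunes (ascending exposure p), and attaches the outcome
    effect from ``outcome_meta``.  ``g`` may be a single panel or one panel
    per population; with several panels the pruning criterion is the
    pooled within-population r^2 (see :func:`_pooled_within_r2`).  Returns an empty
    set with a warning when nothing survives.
    """
    panels = [g] if isinstance(g, GenotypeMatrix) else list(g)
    exposure = exposure_meta[0].trait if exposure_meta else ""
    outcome = outcome_meta[0].trait if outcome_meta else "YD"
    other_lut = {
        t: {m.snp.snp_id: m for m in table} for t, table in other_traits_meta.items()
    }
    outcome_lut = {m.snp.snp_id: m for m in outcome_meta}

    sig = [m for m in exposure_meta if m.p < p_sig]
    log.info("select_instruments %s: %d genome-wide significant (p<%g)",
             exposure, len(sig), p_sig)

    exclusive = []
    for m in sig:
        ok = True
        for t, lut in other_lut.items():
            o = lut.get(m.snp.snp_id)
            if o is None:
                log.warning("%s absent from %s meta table; exclusivity assumed",
                            m.snp.snp_id, t)
                continue
            if not o.p > p_excl:
                ok = False
                break
        if ok:
            exclusive.append(m)
    log.info("select_instruments %s: %d pass exclusivity (p>%g in other traits)",
             exposure, len(exclusive), p_excl)

    exclusive.sort(key=lambda m: (m.p, m.snp.snp_id))
    kept: list[MetaStat] = []
    for m in exclusive:
        if all(
            _pooled_within_r2(panels, m.snp.snp_id, k.snp.snp_id) <= r2_max
            for k in kept
        ):
            kept.append(m)
    log.info("select_instruments %s: %d after LD pruning (r2<=%g)",
             exposure, len(kept), r2_max)

    instruments: list[Instrument] = []
    for m in kept:
        o = outcome_lut.get(m.snp.snp_id)
        if o is None:
            log.warning("%s has no outcome estimate; dropped", m.snp.snp_id)
            continue
        instruments.append(
            Instrument(m.snp, m.beta, m.se, m.p, o.beta, o.se, o.p)
        )
    instruments.sort(key=lambda i: (i.snp.chrom, i.snp.pos))
    if not instruments:
        warnings.warn(
            f"no instruments survive selection for exposure {exposure!r}",
            stacklevel=2,
        )
    return InstrumentSet(exposure, outcome, instruments)


def write_instruments(s: InstrumentSet, path: str) -> None:
    """Write an instrument TSV (SNP/CHR/POS/BETA_X/SE_X/P_X/BETA_Y/SE_Y/P_Y)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(INSTRUMENT_COLUMNS) + "\n")
        for i in s.instruments:
            fh.write(
                "\t".join(
                    [
                        i.snp.snp_id,
                        str(i.snp.chrom),
                        str(i.snp.pos),
                        repr(float(i.beta_x)),
                        repr(float(i.se_x)),
                        repr(float(i.p_x)),
                        repr(float(i.beta_y)),
                        repr(float(i.se_y)),
                        repr(float(i.p_y)),
                    ]
                )
                + "\n"
            )


def read_instruments(
    path: str,
    exposure: str = "",
    outcome: str = "YD",
    derive_missing_se: bool = False,
) -> InstrumentSet:
    """Read an instrument TSV.

    With ``derive_missing_se`` the SE_X/SE_Y columns may be absent or empty
    (the layout of published beta/p tables) and are back-derived from
    (beta, p) via :func:`derive_se`.
    """
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    needed = [c for c in INSTRUMENT_COLUMNS if not c.startswith("SE_")]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValidationError(f"instrument TSV lacks columns {missing}")
    instruments = []
    for row in frame.itertuples(index=False):
        bx, px = float(row.BETA_X), float(row.P_X)
        by, py = float(row.BETA_Y), float(row.P_Y)
        se_x = getattr(row, "SE_X", float("nan"))
        se_y = getattr(row, "SE_Y", float("nan"))
        if not se_x > 0:
            if not derive_missing_se:
                raise ValidationError(f"{row.SNP}: missing SE_X (pass derive_missing_se)")
            se_x = derive_se(bx, px)
        if not se_y > 0:
            if not derive_missing_se:
                raise ValidationError(f"{row.SNP}: missing SE_Y (pass derive_missing_se)")
            se_y = derive_se(by, py)
        snp = SnpRecord(str(row.SNP), int(row.CHR), int(row.POS))
        instruments.append(Instrument(snp, bx, float(se_x), px, by, float(se_y), py))
    return InstrumentSet(exposure, outcome, instruments)
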