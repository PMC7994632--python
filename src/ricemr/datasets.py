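"""Bundled instrument tables for the rice yield worked example.

These are published per-SNP effect estimates from a hybrid-rice meta-GWAS:
for each instrumental SNP, the effect (beta) and p-value on one component
trait (the exposure) and on yield per plant (the outcome).  Published
tables print beta and p only, so the standard errors all MR estimators
need are back-derived with :func:`ricemr.instruments.derive_se` under the
two-sided normal reference.  Because the printed p-values are rounded,
back-derived SEs — and everything downstream — carry a small rounding
error; it is negligible except where p is printed very close to 1
(e.g. p = 0.997), which inflates the relative error of that SNP's SE.

Exposures: GPP (grains per panicle, 6 instruments), KGW (kilo-grain
weight, 11 instruments), TP (tillers per plant, 3 instruments); the
outcome is always YD (yield per plant, grams).
"""

from __future__ import annotations

from .instruments import Instrument, InstrumentSet, derive_se
from .io_formats import SnpRecord

__all__ = ["load_reference_instruments", "GPP_TABLE", "KGW_TABLE", "TP_TABLE"]

# (snp_id, chrom, pos, beta_exposure, p_exposure, beta_yield, p_yield)
GPP_TABLE = [
    ("chr03_29979498", 3, 29_979_498, -18.724, 1.12e-07, -0.633, 0.543),
    ("chr03_898774", 3, 898_774, 18.953, 2.92e-07, 1.254, 0.299),
    ("chr05_7226049", 5, 7_226_049, -7.242, 2.25e-08, -1.329, 0.005),
    ("chr08_25257522", 8, 25_257_522, -16.559, 8.58e-07, 1.178, 0.553),
    ("chr09_12464309", 9, 12_464_309, -7.538, 4.49e-07, -0.974, 0.066),
    ("chr12_22633431", 12, 22_633_431, 15.738, 3.01e-07, 1.439, 0.158),
]

KGW_TABLE = [
    ("chr01_3547491", 1, 3_547_491, 0.706, 7.14e-08, -0.036, 0.948),
    ("chr01_5524333", 1, 5_524_333, 1.018, 6.56e-07, 0.310, 0.840),
    ("chr02_1118809", 2, 1_118_809, 0.786, 1.56e-09, 1.030, 0.082),
    ("chr02_334316", 2, 334_316, -1.474, 2.38e-07, 0.948, 0.505),
    ("chr02_7792121", 2, 7_792_121, -1.256, 9.21e-08, 0.029, 0.980),
    ("chr03_17810847", 3, 17_810_847, 0.651, 4.74e-07, 0.711, 0.394),
    ("chr03_33060865", 3, 33_060_865, -0.505, 2.03e-08, -0.978, 0.027),
    ("chr04_13785932", 4, 13_785_932, 0.739, 3.16e-07, 0.623, 0.406),
    ("chr05_16393143", 5, 16_393_143, 0.466, 4.71e-07, 0.029, 0.955),
    ("chr07_23215227", 7, 23_215_227, 0.952, 1.09e-07, -0.308, 0.715),
    ("chr08_25464238", 8, 25_464_238, -0.875, 2.01e-09, -0.004, 0.997),
]

TP_TABLE = [
    ("chr02_21604477", 2, 21_604_477, -1.279, 8.25e-07, -1.977, 0.043),
    ("chr06_1578700", 6, 1_578_700, -0.639, 4.52e-07, -1.691, 3.21e-04),
    ("chr11_26492375", 11, 26_492_375, -0.507, 7.04e-08, -0.720, 0.043),
]

_TABLES = {"GPP": GPP_TABLE, "KGW": KGW_TABLE, "TP": TP_TABLE}


def load_reference_instruments() -> dict[str, InstrumentSet]:
    """The bundled instrument sets (exposure -> InstrumentSet, outcome YD).

    Standard errors for both exposure and outcome effects are back-derived
    from the printed (beta, p) pairs via the two-sided normal quantile.
    """
    out: dict[str, InstrumentSet] = {}
    for trait, table in _TABLES.items():
        instruments = [
            Instrument(
                snp=SnpRecord(snp_id, chrom, pos),
                beta_x=bx,
                se_x=derive_se(bx, px),
                p_x=px,
                beta_y=by,
                se_y=derive_se(by, py),
                p_y=py,
            )
            for snp_id, chrom, pos, bx, px, by, py in table
        ]
        out[trait] = InstrumentSet(trait, "YD", instruments)
    return out
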