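"""End-to-end orchestration: simulate -> GWAS per dataset -> meta per trait
-> instrument selection per exposure -> MR -> pyramiding (-> annotation).

Every stage writes its TSV artifacts plus structured log lines recording
parameters and SNP-count transitions (the attrition trail: significant ->
exclusive -> LD-pruned -> instruments), and the run ends with a manifest
of all artifacts and their SHA-256 checksums.  Given fixed seeds the
manifest is a pure function of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import annotation, mr_core
from .gwas_lmm import GrmEigen, compute_grm, fit_null_lmm, mlma_scan, qc_filter
from .instruments import InstrumentSet, select_instruments, write_instruments
from .io_formats import (
    TRAITS,
    GenotypeMatrix,
    concat_lines,
    read_gff3,
    write_genotypes,
    write_phenotypes,
    write_summary_stats,
)
from .meta_gwas import MetaStat, run_meta_gwas
from .pyramiding import assign_superior_alleles, pyramid_summary
from .synthetic_data import COMPONENTS, SimulatedStudy, default_truth, simulate_study

__all__ = ["PipelineConfig", "run_pipeline", "mr_report", "report_frame"]

log = logging.getLogger("ricemr.pipeline")


@dataclass
class PipelineConfig:
    """All thresholds and sizes of one pipeline run.

    QC is per population: the default MAF floors mirror the convention of
    using 5% for a small panel and 1% for a large deeply-imputed one.
    """

    populations: dict[str, int] = field(default_factory=lambda: {"P1": 500, "P2": 500})
    environments: list[str] = field(default_factory=lambda: ["E1", "E2"])
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    n_causal_per_trait: int = 6
    n_direct: int = 3
    heritability: float = 0.5
    exclusivity: str = "disjoint"
    seed: int = 0
    maf_min: dict[str, float] = field(default_factory=lambda: {"P1": 0.05, "P2": 0.01})
    missing_max: float = 0.20
    meta_alpha: float = 1e-6
    p_excl: float = 0.05
    r2_max: float = 0.01
    n_boot: int = 2000
    min_lines: int = 3
    gff: str | None = None
    curated_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.meta_alpha < 1.0:
            raise ValueError("meta_alpha must lie in (0, 1)")
        if not 0.0 <= self.p_excl <= 1.0:
            raise ValueError("p_excl must lie in [0, 1]")
        if not 0.0 <= self.r2_max <= 1.0:
            raise ValueError("r2_max must lie in [0, 1]")

    def to_file(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["maf_range"] = list(self.maf_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "maf_range" in data:
            data["maf_range"] = tuple(data["maf_range"])
        return cls(**data)


def mr_report(
    s: InstrumentSet, n_boot: int = 10000, seed: int = 0, split_by_sign: bool = False
) -> dict[str, Any]:
    """All applicable MR estimators for one instrument set.

    Returns a nested dict: overall results under the exposure name; with
    ``split_by_sign`` and both signs present, additional ``(positive)`` /
    ``(negative)`` subgroup entries, each analyzed independently.
    """
    def one(sub: InstrumentSet, tag: str) -> dict[str, Any]:
        entry: dict[str, Any] = {"k": sub.k}
        if sub.k == 0:
            return entry
        entry["ivw"] = mr_core.ivw(sub)
        if sub.k >= 2:
            Q, df, p, i2 = mr_core.heterogeneity(sub)
            entry["heterogeneity"] = {"Q": Q, "df": df, "p": p, "i2": i2}
        if sub.k >= 3:
            entry["weighted_median"] = mr_core.weighted_median(sub, n_boot, seed)
            entry["mr_egger"] = mr_core.mr_egger(sub)
        return entry

    report = {s.exposure: one(s, s.exposure)}
    if split_by_sign and s.k:
        pos, neg = mr_core.split_by_ratio_sign(s)
        if pos.k and neg.k:
            report[f"{s.exposure} (positive)"] = one(pos, "positive")
            report[f"{s.exposure} (negative)"] = one(neg, "negative")
    return report


def report_frame(report: dict[str, Any]):
    """Flatten an :func:`mr_report` dict to a tidy table
    (trait, method, estimate, ci_low, ci_high, p)."""
    import pandas as pd

    rows = []
    for trait, entry in report.items():
        for method in ("ivw", "weighted_median", "mr_egger"):
            res = entry.get(method)
            if res is None:
                continue
            rows.append((trait, res.method, res.estimate, res.ci_low, res.ci_high, res.p))
            if res.intercept is not None:
                lo, hi = res.intercept_ci
                rows.append((trait, "mr_egger(intercept)", res.intercept, lo, hi,
                             res.intercept_p))
    return pd.DataFrame(
        rows, columns=["trait", "method", "estimate", "ci_low", "ci_high", "p"]
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, workdir: str) -> dict[str, str]:
    """Run the full chain under ``workdir``; returns {relative path: sha256}.

    Stage errors abort with the stage name; partial outputs stay on disk.
    """
    wd = Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(wd / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ricemr")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        return _run(config, wd)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()


def _run(config: PipelineConfig, wd: Path) -> dict[str, str]:
    stage = "simulate"
    try:
        truth = default_truth(
            n_snps=config.n_snps,
            seed=config.seed,
            n_causal_per_trait=config.n_causal_per_trait,
            n_direct=config.n_direct,
            heritability=config.heritability,
        )
        study = simulate_study(
            truth,
            populations=config.populations,
            environments=config.environments,
            n_snps=config.n_snps,
            maf_range=config.maf_range,
            ld_rho=config.ld_rho,
            exclusivity=config.exclusivity,
        )
        artifacts: list[Path] = []
        for pop in config.populations:
            first_ds = f"{pop}:{config.environments[0]}"
            p = wd / f"genotypes_{pop}.tsv"
            write_genotypes(study.genotypes[first_ds], p)
            artifacts.append(p)
        p = wd / "phenotypes.tsv"
        write_phenotypes(study.phenotypes, p)
        artifacts.append(p)
        p = wd / "truth.json"
        p.write_text(json.dumps(dataclasses.asdict(_jsonable_truth(truth)), indent=1))
        artifacts.append(p)

        stage = "gwas"
        per_trait: dict[str, list[list]] = {t: [] for t in TRAITS}
        qc_panels: dict[str, GenotypeMatrix] = {}
        for pop in config.populations:
            first_ds = f"{pop}:{config.environments[0]}"
            g_qc = qc_filter(
                study.genotypes[first_ds],
                maf_min=config.maf_min.get(pop, 0.05),
                missing_max=config.missing_max,
            )
            qc_panels[pop] = g_qc
            eig = GrmEigen.from_grm(compute_grm(g_qc))
            for env in config.environments:
                ds = f"{pop}:{env}"
                for trait in TRAITS:
                    y = study.phenotypes.values_for(ds, trait, g_qc.line_ids)
                    keep = ~np.isnan(y)
                    if not keep.all():
                        g_fit = g_qc.subset_lines(
                            [l for l, k in zip(g_qc.line_ids, keep) if k]
                        )
                        e_fit = GrmEigen.from_grm(compute_grm(g_fit))
                        y_fit = y[keep]
                    else:
                        g_fit, e_fit, y_fit = g_qc, eig, y
                    vc = fit_null_lmm(y_fit, e_fit)
                    log.info("gwas %s %s: n=%d h2=%.3f", ds, trait, len(y_fit), vc.h2)
                    stats = mlma_scan(g_fit, y_fit, vc, e_fit, trait=trait, dataset_id=ds)
                    p = wd / f"gwas_{pop}_{env}_{trait}.tsv"
                    write_summary_stats(stats, p)
                    artifacts.append(p)
                    per_trait[trait].append(stats)

        stage = "meta"
        meta: dict[str, list[MetaStat]] = {}
        sig: dict[str, list[MetaStat]] = {}
        for trait in TRAITS:
            meta[trait], sig[trait] = run_meta_gwas(
                per_trait[trait], trait, alpha=config.meta_alpha
            )
            p = wd / f"meta_{trait}.tsv"
            _write_meta(meta[trait], p)
            artifacts.append(p)

        stage = "instruments"
        pooled = concat_lines([qc_panels[pop] for pop in config.populations])
        instrument_sets: dict[str, InstrumentSet] = {}
        for trait in COMPONENTS:
            others = {t: meta[t] for t in COMPONENTS if t != trait}
            iset = select_instruments(
                meta[trait], others, meta["YD"], list(qc_panels.values()),
                p_sig=config.meta_alpha, p_excl=config.p_excl, r2_max=config.r2_max,
            )
            instrument_sets[trait] = iset
            p = wd / f"instruments_{trait}.tsv"
            write_instruments(iset, p)
            artifacts.append(p)

        stage = "mr"
        frames = []
        for trait, iset in instrument_sets.items():
            if iset.k == 0:
                log.warning("mr: no instruments for %s; skipped", trait)
                continue
            rep = mr_report(iset, n_boot=config.n_boot, seed=config.seed,
                            split_by_sign=True)
            frames.append(report_frame(rep))
        p = wd / "mr_results.tsv"
        if frames:
            import pandas as pd

            pd.concat(frames, ignore_index=True).to_csv(p, sep="\t", index=False)
        else:
            p.write_text("trait\tmethod\testimate\tci_low\tci_high\tp\n")
        artifacts.append(p)

        stage = "pyramid"
        pooled_ids = pooled.line_ids
        env0 = config.environments[0]

        def pooled_trait(trait: str) -> np.ndarray:
            # mean over environments per line, pooled across populations
            vals = []
            for pop, g_qc in qc_panels.items():
                per_env = np.array([
                    study.phenotypes.values_for(f"{pop}:{e}", trait, g_qc.line_ids)
                    for e in config.environments
                ])
                vals.append(np.nanmean(per_env, axis=0))
            return np.concatenate(vals)

        yield_vals = pooled_trait("YD")
        superior = {}
        for trait in COMPONENTS:
            iset = instrument_sets[trait]
            ids = [i.snp.snp_id for i in iset.instruments
                   if i.snp.snp_id in set(pooled.snp_ids)]
            superior.update(assign_superior_alleles(pooled, pooled_trait(trait), ids))
        direct_ids = [m.snp.snp_id for m in sig["YD"] if m.snp.snp_id in set(pooled.snp_ids)]
        superior.update(assign_superior_alleles(pooled, yield_vals, direct_ids))
        summary = pyramid_summary(pooled, superior, yield_vals,
                                  min_lines=config.min_lines)
        p = wd / "pyramid_summary.tsv"
        summary.groups.to_csv(p, sep="\t", index=False)
        artifacts.append(p)
        p = wd / "pyramid_lsd.tsv"
        summary.lsd.to_csv(p, sep="\t", index=False)
        artifacts.append(p)

        if config.gff:
            stage = "annotate"
            genes = read_gff3(config.gff)
            rows = []
            for trait in COMPONENTS:
                for ins in instrument_sets[trait].instruments:
                    for gene, dist in annotation.candidate_genes(
                        ins.snp, genes, curated_ids=set(config.curated_genes)
                    ):
                        rows.append((trait, ins.snp.snp_id, gene.gene_id, dist))
            import pandas as pd

            p = wd / "candidate_genes.tsv"
            pd.DataFrame(rows, columns=["trait", "snp", "gene_id", "distance_bp"]).to_csv(
                p, sep="\t", index=False
            )
            artifacts.append(p)

        stage = "manifest"
        manifest = {str(a.relative_to(wd)): _sha256(a) for a in artifacts}
        (wd / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed ({exc}); partial outputs in {wd}"
        ) from exc


def _jsonable_truth(truth):
    # dataclasses.asdict cannot serialize tuple-keyed env_shifts to JSON
    t = dataclasses.replace(
        truth, env_shifts={f"{d}|{tr}": v for (d, tr), v in truth.env_shifts.items()}
    )
    return t


def _read_meta(path: str | Path) -> list[MetaStat]:
    import pandas as pd

    from .io_formats import SnpRecord

    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for r in frame.itertuples(index=False):
        snp = SnpRecord(str(r.SNP), int(r.CHR), int(r.POS), str(r.A2), str(r.A1))
        out.append(
            MetaStat(snp, getattr(r, "TRAIT", ""), float(r.BETA), float(r.SE),
                     float(r.P), int(r.K), float(r.Q), int(r.DF), float(r.I2),
                     str(r.MODEL))
        )
    return out


def _write_meta(stats: list[MetaStat], path: Path) -> None:
    cols = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "P", "K", "Q", "DF",
            "I2", "MODEL"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for m in stats:
            fh.write(
                "\t".join(
                    [
                        m.snp.snp_id, str(m.snp.chrom), str(m.snp.pos),
                        m.snp.allele_alt, m.snp.allele_ref,
                        repr(float(m.beta)), repr(float(m.se)),
                        repr(float(m.p)), str(m.k),
                        repr(float(m.Q)), str(m.df), repr(float(m.i2)), m.model,
                    ]
                )
                + "\n"
            )
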