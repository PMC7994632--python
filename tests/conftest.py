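"""Shared fixtures and the simulation -> GWAS -> meta -> instruments chain
used by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from ricemr.gwas_lmm import GrmEigen, compute_grm, fit_null_lmm, mlma_scan, qc_filter
from ricemr.instruments import select_instruments
from ricemr.io_formats import TRAITS, GenotypeMatrix, SnpRecord
from ricemr.meta_gwas import run_meta_gwas
from ricemr.synthetic_data import COMPONENTS, default_truth, simulate_study


def toy_matrix(dosage, ids=None):
    """A GenotypeMatrix from a literal dosage array, SNPs 1 kb apart."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ids = ids or [f"L{i + 1}" for i in range(n)]
    snps = [
        SnpRecord(SnpRecord.auto_id(1, 1000 * (j + 1)), 1, 1000 * (j + 1))
        for j in range(m)
    ]
    return GenotypeMatrix(ids, snps, dosage)


def run_mr_chain(
    seed: int,
    n_lines: int = 1000,
    n_snps: int = 5000,
    environments=("E1",),
    heritability: float = 0.8,
    polygenic_fraction: float = 0.0,
    n_causal_per_trait: int = 6,
    exclusivity: str = "strict",
):
    """Simulate a two-population study and run it through GWAS, meta and
    instrument selection; returns (truth, study, meta tables, instrument
    sets, QC'd panels)."""
    truth = default_truth(
        n_snps=n_snps,
        seed=seed,
        n_causal_per_trait=n_causal_per_trait,
        heritability=heritability,
    )
    truth.polygenic_fraction = polygenic_fraction
    study = simulate_study(
        truth,
        {"P1": n_lines, "P2": n_lines},
        list(environments),
        n_snps=n_snps,
        exclusivity=exclusivity,
    )
    per_trait: dict[str, list] = {t: [] for t in TRAITS}
    panels: dict[str, GenotypeMatrix] = {}
    eigs: dict[str, GrmEigen] = {}
    for ds, g in study.genotypes.items():
        pop = ds.split(":")[0]
        if pop not in panels:
            panels[pop] = qc_filter(g)
            eigs[pop] = GrmEigen.from_grm(compute_grm(panels[pop]))
        gq, eig = panels[pop], eigs[pop]
        for t in TRAITS:
            y = study.phenotypes.values_for(ds, t, gq.line_ids)
            vc = fit_null_lmm(y, eig)
            per_trait[t].append(mlma_scan(gq, y, vc, eig, trait=t, dataset_id=ds))
    meta = {t: run_meta_gwas(per_trait[t], t)[0] for t in TRAITS}
    isets = {}
    for t in COMPONENTS:
        others = {o: meta[o] for o in COMPONENTS if o != t}
        isets[t] = select_instruments(meta[t], others, meta["YD"], list(panels.values()))
    return truth, study, meta, isets, list(panels.values())


@pytest.fixture(scope="session")
def reference_sets():
    from ricemr.datasets import load_reference_instruments

    return load_reference_instruments()
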