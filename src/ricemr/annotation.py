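"""Candidate-gene lookup around significant SNPs.

Genes within ``window_bp`` (default +/-200 kb) of a SNP are candidates;
distance is 0 inside the gene body, else the distance to the nearer gene
boundary.  When a user-supplied list of curated (cloned, trait-relevant)
gene ids intersects the window those genes rank first, mirroring the
convention that a known cloned gene beats mere proximity; otherwise genes
are returned nearest-first.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .io_formats import GeneModel, SnpRecord

__all__ = ["candidate_genes"]


def candidate_genes(
    snp: SnpRecord,
    genes: Sequence[GeneModel],
    window_bp: int = 200_000,
    curated_ids: Iterable[str] | None = None,
) -> list[tuple[GeneModel, int]]:
    """Genes within ``window_bp`` of ``snp``, curated ids first, then by
    distance (gene_id as the deterministic tie-break)."""
    curated = set(curated_ids or ())
    hits: list[tuple[GeneModel, int]] = []
    for gene in genes:
        if gene.chrom != snp.chrom:
            continue
        if gene.start <= snp.pos <= gene.end:
            dist = 0
        else:
            dist = min(abs(snp.pos - gene.start), abs(snp.pos - gene.end))
        if dist <= window_bp:
            hits.append((gene, dist))
    hits.sort(key=lambda gd: (gd[0].gene_id not in curated, gd[1], gd[0].gene_id))
    return hits
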