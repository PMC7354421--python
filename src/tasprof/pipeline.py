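"""End-to-end profiling convenience: reads -> hits -> evidence -> report."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .calling import CallReport, GeneCall, ThresholdConfig, call_strains, genotype_gene
from .catalog import Catalog
from .mapping import ReadHit, coverage_profiles, index_catalog, map_reads
from .markers import MarkerSet, markers_for_catalog

__all__ = ["genotype_all", "profile_sample"]


def genotype_all(
    hits: Iterable[ReadHit],
    catalog: Catalog,
    markers: MarkerSet,
    min_allele_depth: int = 1,
) -> dict[str, GeneCall]:
    """Coverage profiles plus genotyping for every catalog gene."""
    profiles = coverage_profiles(hits, catalog, markers)
    return {
        gene_id: genotype_gene(profile, markers, min_allele_depth)
        for gene_id, profile in profiles.items()
    }


def profile_sample(
    catalog: Catalog,
    reads: Iterable[tuple[str, str]] | str | Path | None = None,
    hits: Iterable[ReadHit] | None = None,
    markers: MarkerSet | None = None,
    cfg: ThresholdConfig = ThresholdConfig(),
    k: int = 21,
    min_identity: float = 0.95,
    min_aligned_len: int = 50,
) -> CallReport:
    """Profile one sample from reads (internal aligner) or prepared hits."""
    if (reads is None) == (hits is None):
        raise ValueError("provide exactly one of reads / hits")
    if markers is None:
        markers = markers_for_catalog(catalog)
    if hits is None:
        index = index_catalog(catalog, k=k)
        hits = map_reads(reads, index, min_identity, min_aligned_len)
    calls = genotype_all(hits, catalog, markers)
    return call_strains(calls, catalog, cfg)
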