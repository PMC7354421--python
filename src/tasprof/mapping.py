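"""Read alignment against the gene catalog and per-gene coverage.

The built-in aligner is a deliberately simple ungapped seed-and-extend:
exact k-mer seeds locate candidate placements of a read on a catalog
gene (both strands) and each placement is scored by Hamming comparison
over the read/gene overlap.  Catalog genes are short (~300 bp) and the
markers that matter downstream are dominated by substitutions, so an
ungapped model suffices; alignments from any external gapped aligner can
be brought in through :func:`import_sam` instead.

Per gene, hits are reduced to a :class:`CoverageProfile`: breadth of
coverage (bp and % of gene length), per-position depth, and the bases
observed at marker positions -- the evidence the calling layer consumes.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .catalog import Catalog
from .markers import MarkerSet

__all__ = [
    "ReadHit",
    "CoverageProfile",
    "SeedIndex",
    "index_catalog",
    "map_reads",
    "import_sam",
    "coverage_profiles",
    "read_fastq",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadHit:
    """One read aligned to one catalog gene (0-based half-open interval)."""

    read_id: str
    gene_id: str
    gene_start: int
    gene_end: int
    strand: str  # '+' or '-'
    mismatches: tuple[tuple[int, str], ...]  # (gene position, read base)

    def __post_init__(self) -> None:
        if self.gene_end <= self.gene_start:
            raise ValueError("empty hit interval")

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatches)

    @property
    def span(self) -> int:
        return self.gene_end - self.gene_start


@dataclass
class CoverageProfile:
    """Mapping evidence accumulated on one catalog gene."""

    gene_id: str
    gene_len: int
    depth: np.ndarray
    #: marker position -> {base: observation count}
    allele_observations: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def covered_bp(self) -> int:
        return int(np.count_nonzero(self.depth))

    @property
    def covered_pct(self) -> float:
        return 100.0 * self.covered_bp / self.gene_len


@dataclass
class SeedIndex:
    """Exact k-mer index over catalog genes (forward strand)."""

    k: int
    seeds: dict[str, list[tuple[str, int]]]
    genes: dict[str, str]  # gene_id -> sequence

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.seeds.get(kmer, [])


def index_catalog(catalog: Catalog, k: int = 21) -> SeedIndex:
    """Build a k-mer -> (gene, offset) multimap; short genes indexed whole."""
    if k < 11:
        raise ValueError(f"seed length must be >= 11, got {k}")
    seeds: dict[str, list[tuple[str, int]]] = {}
    genes: dict[str, str] = {}
    for rec in catalog:
        seq = rec.sequence
        genes[rec.gene_id] = seq
        if len(seq) < k:
            seeds.setdefault(seq, []).append((rec.gene_id, 0))
            continue
        for off in range(len(seq) - k + 1):
            seeds.setdefault(seq[off : off + k], []).append((rec.gene_id, off))
    return SeedIndex(k=k, seeds=seeds, genes=genes)


# ---------------------------------------------------------------------------
# FASTQ input


class FastqError(ValueError):
    pass


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a plain or gzipped FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FastqError(f"malformed FASTQ record at index {idx} in {path}")
            if not seq or len(qual) != len(seq):
                raise FastqError(f"malformed FASTQ record at index {idx} in {path}")
            yield header[1:].split()[0], seq.upper()
            idx += 1


# ---------------------------------------------------------------------------
# seed-and-extend mapping


def _placements(seq: str, index: SeedIndex) -> set[tuple[str, int]]:
    """Candidate (gene, read-start-on-gene) placements from seed hits."""
    k = index.k
    out: set[tuple[str, int]] = set()
    if len(seq) < k:
        for gene_id, off in index.lookup(seq):
            out.add((gene_id, off))
        return out
    for rpos in range(len(seq) - k + 1):
        for gene_id, off in index.lookup(seq[rpos : rpos + k]):
            out.add((gene_id, off - rpos))
    return out


def _evaluate(
    seq: str, gene: str, start: int
) -> tuple[int, int, tuple[tuple[int, str], ...]] | None:
    """Ungapped comparison of a read placed at ``start`` on ``gene``.

    Returns (span, n_mismatch, mismatches) over the read/gene overlap,
    or None when there is no overlap.
    """
    g0 = max(start, 0)
    g1 = min(start + len(seq), len(gene))
    if g1 <= g0:
        return None
    mism = tuple(
        (g, seq[g - start])
        for g in range(g0, g1)
        if seq[g - start] != gene[g]
    )
    return g1 - g0, len(mism), mism


def map_reads(
    reads: Iterable[tuple[str, str]] | str | Path,
    index: SeedIndex,
    min_identity: float = 0.95,
    min_aligned_len: int = 50,
) -> list[ReadHit]:
    """Map reads to catalog genes, reporting the single best hit per read.

    Best = fewest mismatches, then longest span, then lexicographically
    smallest gene id (then '+' strand).  Reads whose best placement fails
    the identity or length thresholds yield no hit.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    hits: list[ReadHit] = []
    for read_id, seq in reads:
        best: tuple | None = None
        for oriented, strand in ((seq, "+"), (revcomp(seq), "-")):
            for gene_id, start in _placements(oriented, index):
                ev = _evaluate(oriented, index.genes[gene_id], start)
                if ev is None:
                    continue
                span, n_mm, mism = ev
                key = (n_mm, -span, gene_id, strand)
                if best is None or key < best[0]:
                    best = (key, gene_id, start, span, mism, strand)
        if best is None:
            continue
        _, gene_id, start, span, mism, strand = best
        if span < min_aligned_len:
            continue
        if (span - len(mism)) / span < min_identity:
            continue
        g0 = max(start, 0)
        hits.append(
            ReadHit(
                read_id=read_id,
                gene_id=gene_id,
                gene_start=g0,
                gene_end=g0 + span,
                strand=strand,
                mismatches=mism,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# SAM import


def import_sam(path: str | Path, catalog: Catalog) -> list[ReadHit]:
    """Convert mapped SAM records into :class:`ReadHit` objects.

    Reference names must be catalog gene ids.  Unmapped, secondary and
    supplementary records are skipped; intervals come from the CIGAR
    walk and mismatches from comparing the query sequence to the catalog
    gene at aligned positions.
    """
    genes = {rec.gene_id: rec.sequence for rec in catalog}
    hits: list[ReadHit] = []
    unknown: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            ref = rec.reference_name
            if ref not in genes:
                unknown.add(ref)
                continue
            gene = genes[ref]
            mism: list[tuple[int, str]] = []
            qseq = rec.query_sequence
            if qseq:
                for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                    if qseq[qpos].upper() != gene[rpos]:
                        mism.append((rpos, qseq[qpos].upper()))
            hits.append(
                ReadHit(
                    read_id=rec.query_name,
                    gene_id=ref,
                    gene_start=rec.reference_start,
                    gene_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=tuple(mism),
                )
            )
    if unknown:
        raise ValueError(
            f"SAM references not present in catalog: {sorted(unknown)}"
        )
    return hits


# ---------------------------------------------------------------------------
# coverage profiles


def coverage_profiles(
    hits: Iterable[ReadHit],
    catalog: Catalog,
    markers: MarkerSet | None = None,
) -> dict[str, CoverageProfile]:
    """Aggregate hits into per-gene coverage and marker-allele evidence.

    Every catalog gene gets a profile (zeroed when unmapped).  When a
    ``markers`` set is given, each hit covering a marker position records
    the read base there: the listed mismatch base if any, otherwise the
    reference base.
    """
    profiles = {
        rec.gene_id: CoverageProfile(
            gene_id=rec.gene_id,
            gene_len=len(rec.sequence),
            depth=np.zeros(len(rec.sequence), dtype=np.int32),
        )
        for rec in catalog
    }
    seqs = {rec.gene_id: rec.sequence for rec in catalog}
    marker_pos: dict[str, list[int]] = {}
    if markers is not None:
        for (gene_id, pos), _m in markers.markers.items():
            marker_pos.setdefault(gene_id, []).append(pos)

    for hit in hits:
        if hit.gene_id not in profiles:
            raise ValueError(f"hit references unknown gene {hit.gene_id!r}")
        prof = profiles[hit.gene_id]
        prof.depth[hit.gene_start : hit.gene_end] += 1
        positions = marker_pos.get(hit.gene_id)
        if not positions:
            continue
        mism = dict(hit.mismatches)
        for pos in positions:
            if hit.gene_start <= pos < hit.gene_end:
                base = mism.get(pos, seqs[hit.gene_id][pos])
                obs = prof.allele_observations.setdefault(pos, {})
                obs[base] = obs.get(base, 0) + 1
    return profiles
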