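"""Reference catalog of toxin-antitoxin (TAS) gene variants.

A catalog is an ordered collection of nucleotide gene variants, each
labelled with the taxonomy of the bacterium it came from (genus, species,
strain) and the TAS family of the gene (MazEF, RelBE, HicAB, ...).  The
profiler uses the catalog both as the alignment reference and as the
lookup table that turns gene-level evidence into strain calls.

Catalog construction mirrors the usual curation steps for a marker-gene
panel: parse sequences plus taxonomy metadata, drop duplicates (exact or
by greedy identity clustering), and exclude genes that also occur on
plasmids -- a plasmid-borne gene can move horizontally between taxa and
is therefore useless as a taxonomic marker.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneRecord",
    "Catalog",
    "PlasmidFilterParams",
    "CatalogError",
    "parse_gene_fasta",
    "write_gene_fasta",
    "deduplicate",
    "filter_plasmid_genes",
    "catalog_census",
]

_VALID_BASES = set("ACGTN")

#: sentinel used when a record has no strain designation
UNKNOWN_STRAIN = "unknown-strain"


class CatalogError(ValueError):
    """Malformed catalog input (bad header, duplicate id, bad sequence)."""


@dataclass(frozen=True)
class GeneRecord:
    """One nucleotide gene variant with its taxonomy labels."""

    gene_id: str
    genus: str
    species: str
    strain: str
    tas_family: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CatalogError(f"record {self.gene_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise CatalogError(
                f"record {self.gene_id!r}: invalid bases {sorted(bad)}"
            )
        for name in ("gene_id", "genus", "species", "strain", "tas_family"):
            if not getattr(self, name):
                raise CatalogError(f"record {self.gene_id!r}: empty {name}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Catalog:
    """Ordered collection of :class:`GeneRecord` with provenance notes."""

    records: list[GeneRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise CatalogError(f"duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def by_id(self) -> dict[str, GeneRecord]:
        return {rec.gene_id: rec for rec in self.records}

    def strain_species(self) -> dict[str, str]:
        """Map each strain label to its species label."""
        return {rec.strain: rec.species for rec in self.records}


@dataclass(frozen=True)
class PlasmidFilterParams:
    """Thresholds for excluding plasmid-borne genes.

    A catalog gene is dropped when a local alignment against any plasmid
    reaches ``min_identity`` (matches / alignment columns, gaps counted)
    over a span covering ``min_query_coverage`` of the gene length.
    """

    min_identity: float = 0.70
    min_query_coverage: float = 0.80

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_query_coverage"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


# ---------------------------------------------------------------------------
# parsing / serialization


def _clean_sequence(raw: str) -> str:
    return str(raw).upper().replace("U", "T")


def parse_gene_fasta(
    path: str | Path,
    delimiter: str = "|",
    metadata: str | Path | None = None,
) -> Catalog:
    """Read a catalog from multi-FASTA.

    Taxonomy travels in the headers as
    ``gene_id|genus|species|strain|tas_family`` (``delimiter``-separated),
    or in a sidecar TSV (``metadata``) with columns
    gene_id/genus/species/strain/tas_family keyed by the plain FASTA id.
    """
    path = Path(path)
    meta: dict[str, dict[str, str]] | None = None
    if metadata is not None:
        table = pd.read_csv(metadata, sep="\t", dtype=str)
        required = ["gene_id", "genus", "species", "strain", "tas_family"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise CatalogError(f"metadata TSV missing columns {missing}")
        meta = {row.gene_id: row._asdict() for row in table.itertuples(index=False)}

    records: list[GeneRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description
        if meta is not None:
            gene_id = entry.id
            if gene_id not in meta:
                raise CatalogError(f"no metadata row for FASTA record {gene_id!r}")
            fields = meta[gene_id]
            rec = GeneRecord(
                gene_id=gene_id,
                genus=fields["genus"],
                species=fields["species"],
                strain=fields["strain"],
                tas_family=fields["tas_family"],
                sequence=_clean_sequence(str(entry.seq)),
            )
        else:
            parts = header.split(delimiter)
            if len(parts) != 5:
                raise CatalogError(
                    f"header {header!r}: expected 5 {delimiter!r}-separated "
                    f"fields, got {len(parts)}"
                )
            gene_id, genus, species, strain, family = (p.strip() for p in parts)
            rec = GeneRecord(
                gene_id=gene_id,
                genus=genus,
                species=species,
                strain=strain or UNKNOWN_STRAIN,
                tas_family=family,
                sequence=_clean_sequence(str(entry.seq)),
            )
        if rec.gene_id in seen:
            raise CatalogError(f"duplicate gene_id {rec.gene_id!r} in {path}")
        seen.add(rec.gene_id)
        records.append(rec)
    return Catalog(records, provenance=[f"parsed {len(records)} records from {path}"])


def write_gene_fasta(catalog: Catalog, path: str | Path, delimiter: str = "|") -> None:
    """Write the catalog as multi-FASTA with pipe-delimited headers."""
    entries = [
        SeqRecord(
            Seq(rec.sequence),
            id=delimiter.join(
                [rec.gene_id, rec.genus, rec.species, rec.strain, rec.tas_family]
            ),
            description="",
        )
        for rec in catalog
    ]
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# deduplication


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Gap columns count toward the denominator, matching the BLAST-style
    convention used throughout the package.
    """
    from .markers import pairwise_align

    aln_a, aln_b, _ = pairwise_align(a, b)
    matches = sum(x == y for x, y in zip(aln_a, aln_b))
    return matches / len(aln_a)


def deduplicate(catalog: Catalog, identity: float = 1.0) -> Catalog:
    """Collapse (near-)duplicate sequences to one representative.

    ``identity == 1.0`` removes exact duplicates only.  Lower values run
    CD-HIT-style greedy clustering: sequences are sorted longest-first,
    each becomes a new cluster representative unless its global-alignment
    identity to an earlier representative reaches the threshold.
    Representative metadata is kept; removed ids are logged in provenance.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"identity must be in (0, 1], got {identity}")

    # exact (taxonomy, sequence) repeats are always removed first
    kept: list[GeneRecord] = []
    removed: list[str] = []
    seen_tuples: set[tuple] = set()
    for rec in catalog:
        key = (rec.genus, rec.species, rec.strain, rec.tas_family, rec.sequence)
        if key in seen_tuples:
            removed.append(rec.gene_id)
        else:
            seen_tuples.add(key)
            kept.append(rec)

    if identity >= 1.0:
        # exact sequence duplicates collapse regardless of taxonomy
        reps: dict[str, GeneRecord] = {}
        order: list[GeneRecord] = []
        for rec in kept:
            if rec.sequence in reps:
                removed.append(rec.gene_id)
            else:
                reps[rec.sequence] = rec
                order.append(rec)
        kept = order
    else:
        by_len = sorted(kept, key=lambda r: (-len(r), r.gene_id))
        reps_list: list[GeneRecord] = []
        clustered: set[str] = set()
        for rec in by_len:
            placed = False
            for rep in reps_list:
                if rec.sequence == rep.sequence or (
                    alignment_identity(rep.sequence, rec.sequence) >= identity
                ):
                    placed = True
                    break
            if placed:
                clustered.add(rec.gene_id)
                removed.append(rec.gene_id)
            else:
                reps_list.append(rec)
        kept = [rec for rec in kept if rec.gene_id not in clustered]

    note = (
        f"deduplicate(identity={identity}): kept {len(kept)}, "
        f"removed {sorted(removed)}"
    )
    return Catalog(kept, provenance=[*catalog.provenance, note])


# ---------------------------------------------------------------------------
# plasmid filter

_LOCAL_ALIGNER = PairwiseAligner(
    mode="local",
    match_score=2,
    mismatch_score=-3,
    open_gap_score=-5,
    extend_gap_score=-2,
)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _best_local_hit(gene: str, plasmid: str) -> tuple[float, float]:
    """(identity, query coverage) of the best-scoring local alignment."""
    best = (0.0, 0.0)
    for target in (plasmid, _revcomp(plasmid)):
        alns = _LOCAL_ALIGNER.align(gene, target)
        if len(alns) == 0 or alns.score <= 0:
            continue
        aln = alns[0]
        q_blocks, _ = aln.aligned[0], aln.aligned[1]
        if len(q_blocks) == 0:
            continue
        matches = 0
        columns = 0
        prev_q = prev_t = None
        for (qs, qe), (ts, te) in zip(aln.aligned[0], aln.aligned[1]):
            if prev_q is not None:
                columns += (qs - prev_q) + (ts - prev_t)  # internal gap columns
            for q, t in zip(gene[qs:qe], target[ts:te]):
                matches += q == t
            columns += qe - qs
            prev_q, prev_t = qe, te
        identity = matches / columns if columns else 0.0
        span = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
        coverage = span / len(gene)
        if (identity, coverage) > best:
            best = (identity, coverage)
    return best


def filter_plasmid_genes(
    catalog: Catalog,
    plasmids: Sequence[str] | Iterable[str],
    params: PlasmidFilterParams = PlasmidFilterParams(),
) -> tuple[Catalog, list[str]]:
    """Exclude genes with a strong local hit to any plasmid sequence.

    Returns the retained catalog (input order preserved) and the excluded
    gene ids.  An empty plasmid collection is a vacuous filter.
    """
    plasmids = list(plasmids)
    if not plasmids:
        return Catalog(list(catalog.records), list(catalog.provenance)), []
    excluded: list[str] = []
    retained: list[GeneRecord] = []
    for rec in catalog:
        hit = False
        for plasmid in plasmids:
            identity, coverage = _best_local_hit(rec.sequence, plasmid)
            if identity >= params.min_identity and coverage >= params.min_query_coverage:
                hit = True
                break
        if hit:
            excluded.append(rec.gene_id)
        else:
            retained.append(rec)
    note = (
        f"plasmid filter (identity>={params.min_identity}, "
        f"coverage>={params.min_query_coverage}): excluded {sorted(excluded)}"
    )
    return Catalog(retained, provenance=[*catalog.provenance, note]), excluded


# ---------------------------------------------------------------------------
# census


def catalog_census(catalog: Catalog) -> pd.DataFrame:
    """Per-genus counts of distinct species, distinct strains, and genes.

    Ends with a ``Total`` row holding distinct counts over the whole
    catalog (so strains shared in name across genera are still counted
    once per (genus, species, strain) triple).
    """
    rows = []
    per_genus: dict[str, list[GeneRecord]] = collections.defaultdict(list)
    for rec in catalog:
        per_genus[rec.genus].append(rec)
    for genus in sorted(per_genus):
        recs = per_genus[genus]
        rows.append(
            {
                "genus": genus,
                "n_species": len({r.species for r in recs}),
                "n_strains": len({(r.species, r.strain) for r in recs}),
                "n_genes": len(recs),
            }
        )
    df = pd.DataFrame(rows, columns=["genus", "n_species", "n_strains", "n_genes"])
    if len(catalog):
        total = {
            "genus": "Total",
            "n_species": len({(r.genus, r.species) for r in catalog}),
            "n_strains": len({(r.genus, r.species, r.strain) for r in catalog}),
            "n_genes": len(catalog),
        }
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return df
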