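"""Synthetic catalogs, genomes and shotgun read sets with known truth.

The generator emulates the benchmarking setup used to tune the
profiler: a hierarchy of genera -> species -> strains in which species
sequences diverge from a genus/family ancestor by a substitution
fraction (default 10%) and sibling strains differ by a fixed handful of
substitutions per gene (default 3).  Strain genomes are built by
embedding the strain's catalog genes at random non-overlapping positions
in random background sequence, and reads are drawn uniformly from the
genomes (both strands) with a per-base substitution error probability --
a DWGSIM-style model with fixed-length reads and constant quality.

Everything is driven by a seeded :class:`numpy.random.Generator`; a
fixed seed yields byte-identical catalogs and FASTQ output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .catalog import Catalog, GeneRecord
from .mapping import revcomp

__all__ = [
    "SimDesign",
    "TruthSet",
    "make_synthetic_catalog",
    "build_genomes",
    "simulate_reads",
    "write_fastq",
    "write_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one simulation study.

    ``coverage`` (fold, typical range 3-7) and ``n_reads`` are mutually
    exclusive ways to size a read set.  ``strain_divergence`` is an
    absolute number of substitutions per gene between sibling strains;
    ``species_divergence`` is a substitution fraction between a species
    and its genus ancestor.
    """

    n_genera: int = 3
    species_per_genus: int = 3
    strains_per_species: int = 2
    genes_per_strain: int = 3
    gene_len: int = 306
    species_divergence: float = 0.10
    strain_divergence: int = 3
    genome_len: int = 6000
    coverage: float | None = 5.0
    n_reads: int | None = None
    read_len: int = 100
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.coverage is None) == (self.n_reads is None):
            raise ValueError("specify exactly one of coverage / n_reads")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        for name in (
            "n_genera",
            "species_per_genus",
            "strains_per_species",
            "genes_per_strain",
            "gene_len",
            "genome_len",
            "read_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(data, fh)
            else:
                json.dump(data, fh, indent=2)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimDesign":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class TruthSet:
    """Known composition of one simulated sample."""

    species: frozenset[str]
    strains: frozenset[str]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> tuple[str, list[int]]:
    """Substitute ``n_subs`` distinct positions, each to a different base."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode(), sorted(int(p) for p in positions)


def make_synthetic_catalog(
    design: SimDesign, rng: np.random.Generator | None = None
) -> tuple[Catalog, dict[str, dict[str, list[int]]]]:
    """Generate a catalog with controlled species/strain divergence.

    Per (genus, family) an ancestral gene is drawn at random; each
    species substitutes ``round(gene_len * species_divergence)``
    positions of it, and each strain substitutes ``strain_divergence``
    further positions of its species sequence.  Returns the catalog and
    the ground-truth mutated positions per gene
    (``{gene_id: {"species": [...], "strain": [...]}}``).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    n_species_subs = round(design.gene_len * design.species_divergence)
    records: list[GeneRecord] = []
    truth: dict[str, dict[str, list[int]]] = {}
    for gi in range(design.n_genera):
        genus = f"Genus{gi + 1:02d}"
        ancestors = [
            _random_seq(rng, design.gene_len)
            for _ in range(design.genes_per_strain)
        ]
        used_per_family: list[set[str]] = [set() for _ in ancestors]
        for si in range(design.species_per_genus):
            species = f"{genus} species{si + 1:02d}"
            species_seqs: list[tuple[str, list[int]]] = []
            for fi, anc in enumerate(ancestors):
                for _attempt in range(100):
                    seq, pos = _mutate(rng, anc, n_species_subs)
                    if seq not in used_per_family[fi]:
                        break
                else:
                    raise RuntimeError("could not generate distinct species sequence")
                used_per_family[fi].add(seq)
                species_seqs.append((seq, pos))
            for ti in range(design.strains_per_species):
                strain = f"{genus.lower()}_sp{si + 1:02d}_st{ti + 1:02d}"
                for fi, (sp_seq, sp_pos) in enumerate(species_seqs):
                    for _attempt in range(100):
                        seq, st_pos = _mutate(rng, sp_seq, design.strain_divergence)
                        if seq != sp_seq or design.strain_divergence == 0:
                            break
                    else:
                        raise RuntimeError("could not generate distinct strain gene")
                    gene_id = f"{strain}_fam{fi + 1:02d}"
                    records.append(
                        GeneRecord(
                            gene_id=gene_id,
                            genus=genus,
                            species=species,
                            strain=strain,
                            tas_family=f"fam{fi + 1:02d}",
                            sequence=seq,
                        )
                    )
                    truth[gene_id] = {"species": sp_pos, "strain": st_pos}
    return Catalog(records, provenance=["synthetic catalog"]), truth


def build_genomes(
    catalog: Catalog,
    strains: list[str],
    design: SimDesign,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Embed each strain's genes in random background sequence.

    Genes are placed left-to-right at random non-overlapping offsets
    with at least one read length of background flanking between them,
    so desk-scale genomes preserve the gene-recovery task of full
    genomes.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    genomes: dict[str, str] = {}
    for strain in strains:
        genes = [rec.sequence for rec in catalog if rec.strain == strain]
        total_gene = sum(len(g) for g in genes)
        slack = design.genome_len - total_gene
        n_gaps = len(genes) + 1
        if slack < n_gaps * design.read_len:
            raise ValueError(
                f"genome_len {design.genome_len} too small for "
                f"{len(genes)} genes of strain {strain!r}"
            )
        # draw gap lengths summing to the slack
        cuts = np.sort(
            rng.choice(slack - n_gaps * design.read_len + 1, size=n_gaps - 1)
        )
        gaps = np.diff(np.concatenate([[0], cuts, [slack - n_gaps * design.read_len]]))
        gaps = gaps + design.read_len
        parts: list[str] = []
        for gap, gene in zip(gaps, genes):
            parts.append(_random_seq(rng, int(gap)))
            parts.append(gene)
        parts.append(_random_seq(rng, int(gaps[-1])))
        genomes[strain] = "".join(parts)
    return genomes


def simulate_reads(
    genomes: dict[str, str],
    design: SimDesign,
    abundances: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], TruthSet]:
    """Draw uniform fixed-length reads from labeled genomes.

    With ``coverage`` set, each genome yields
    ``round(coverage * genome_len / read_len)`` reads; with ``n_reads``,
    the total is split by abundance x genome length.  Each base is
    flipped to a uniformly random different base with probability
    ``error_rate``; strand is uniform.  Read names encode the source
    genome, start and strand.  Returns FASTQ tuples (name, seq, qual)
    and the truth composition.
    """
    if not genomes:
        raise ValueError("no genomes to simulate from")
    if rng is None:
        rng = np.random.default_rng(design.seed + 2)
    if abundances is None:
        abundances = {label: 1.0 for label in genomes}
    for label, seq in genomes.items():
        if design.read_len > len(seq):
            raise ValueError(f"read_len exceeds genome {label!r}")

    counts: dict[str, int] = {}
    if design.coverage is not None:
        for label, seq in genomes.items():
            counts[label] = round(design.coverage * len(seq) / design.read_len)
    else:
        weights = np.array(
            [abundances[label] * len(genomes[label]) for label in genomes], float
        )
        weights /= weights.sum()
        alloc = np.floor(weights * design.n_reads).astype(int)
        remainder = design.n_reads - alloc.sum()
        order = np.argsort(-(weights * design.n_reads - alloc))
        alloc[order[:remainder]] += 1
        counts = dict(zip(genomes, (int(x) for x in alloc)))

    reads: list[tuple[str, str, str]] = []
    qual = "I" * design.read_len
    for label in genomes:
        genome = genomes[label]
        n = counts[label]
        starts = rng.integers(0, len(genome) - design.read_len + 1, size=n)
        strands = rng.integers(0, 2, size=n)
        for i in range(n):
            start = int(starts[i])
            seq = genome[start : start + design.read_len]
            if design.error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                flips = np.nonzero(
                    rng.random(design.read_len) < design.error_rate
                )[0]
                for pos in flips:
                    arr[pos] = rng.choice(_BASES[_BASES != arr[pos]])
                seq = arr.tobytes().decode()
            strand = "+" if strands[i] == 0 else "-"
            if strand == "-":
                seq = revcomp(seq)
            reads.append((f"{label}:{start}:{strand}:{i}", seq, qual))
    return reads, TruthSet(species=frozenset(), strains=frozenset(genomes))


def truth_from_catalog(catalog: Catalog, strains: set[str] | frozenset[str]) -> TruthSet:
    """Resolve a strain set to a full truth composition via the catalog."""
    species_of = catalog.strain_species()
    return TruthSet(
        species=frozenset(species_of[s] for s in strains),
        strains=frozenset(strains),
    )


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_truth(
    truth: TruthSet, catalog: Catalog, path: str | Path, sample: str = "sample1"
) -> None:
    """Truth table as TSV: sample, genus, species, strain, abundance."""
    meta = {rec.strain: (rec.genus, rec.species) for rec in catalog}
    with open(path, "w") as fh:
        fh.write("sample\tgenus\tspecies\tstrain\tabundance\n")
        for strain in sorted(truth.strains):
            genus, species = meta.get(strain, ("NA", "NA"))
            fh.write(f"{sample}\t{genus}\t{species}\t{strain}\t1.0\n")
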