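"""Strain calling: threshold rules over per-gene marker evidence.

A gene contributes evidence only when it is well covered (breadth in bp
and as % of its length) and shows enough *significant SNPs*: marker
positions where every mapped read agrees on one allele.  The strains
whose catalog alleles match all significant SNPs of a gene are
*consistent* with it.  A strain is reported when enough admissible genes
support it; when several strains remain indistinguishable on all
supporting genes they are reported jointly as a "+"-joined group whose
size is the call's *uniqueness*.

Seven thresholds govern the process (:class:`ThresholdConfig`); the
defaults are the operating point found by grid-search optimization:
uniqueness 1, breadth 170 bp and 98%, 3 significant SNPs, and TAS counts
5 (species), 1 (summary report), 2 (short report).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .catalog import Catalog
from .mapping import CoverageProfile
from .markers import MarkerSet

__all__ = [
    "ThresholdConfig",
    "GeneCall",
    "CallReport",
    "genotype_gene",
    "call_strains",
]

#: admissible parameter ranges explored by the optimizer
PARAM_RANGES = {
    "uniqueness_max": (1, 15),
    "min_marker_coverage_bp": (30, 280),
    "min_gene_coverage_pct": (40, 100),
    "min_significant_snps": (0, 20),
    "min_tas_species": (2, 15),
    "min_tas_summary": (1, 10),
    "min_tas_short": (1, 10),
}


@dataclass(frozen=True, order=True)
class ThresholdConfig:
    """The seven tunable detection thresholds."""

    uniqueness_max: int = 1
    min_marker_coverage_bp: int = 170
    min_gene_coverage_pct: float = 98.0
    min_significant_snps: int = 3
    min_tas_species: int = 5
    min_tas_summary: int = 1
    min_tas_short: int = 2

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(data, fh)
            else:
                json.dump(data, fh, indent=2)

    @classmethod
    def from_file(cls, path: str | Path) -> "ThresholdConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class GeneCall:
    """Genotyping outcome for one catalog gene."""

    gene_id: str
    covered_bp: int
    covered_pct: float
    significant_snp_count: int
    significant_positions: tuple[int, ...]
    consistent_strains: frozenset[str]

    def admissible(self, cfg: ThresholdConfig) -> bool:
        return (
            self.covered_bp >= cfg.min_marker_coverage_bp
            and self.covered_pct >= cfg.min_gene_coverage_pct
            and self.significant_snp_count >= cfg.min_significant_snps
        )


@dataclass
class CallReport:
    """The two strain reports plus the species list.

    ``summary_rows`` / ``short_rows``: one row per detected strain or
    "+"-joined strain group, with its uniqueness, significant-SNP tally,
    number of supporting genes, and mean breadth over them.
    """

    summary_rows: pd.DataFrame
    short_rows: pd.DataFrame
    species_rows: pd.DataFrame

    @property
    def detected(self) -> set[str]:
        """Strain/group labels present in both reports."""
        return set(self.summary_rows["label"]) & set(self.short_rows["label"])

    @property
    def detected_strains(self) -> set[str]:
        """Union of individual strains over the detected labels."""
        return {s for label in self.detected for s in label.split("+")}

    @property
    def detected_species(self) -> set[str]:
        return set(self.species_rows["species"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary_rows.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        self.short_rows.to_csv(outdir / "short_results.tsv", sep="\t", index=False)
        self.species_rows.to_csv(outdir / "species.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotyping


def genotype_gene(
    profile: CoverageProfile,
    markers: MarkerSet,
    min_allele_depth: int = 1,
) -> GeneCall:
    """Call significant SNPs on one gene and the strains they allow.

    A marker position is a significant SNP when it is covered at depth
    >= ``min_allele_depth`` and all observed reads agree on one base
    (only substitution markers qualify: indel alleles are not observable
    under ungapped mapping).  The consistent strains are those whose
    catalog variant carries the observed allele at every significant
    SNP; with no significant SNPs, every strain of the gene's variant
    group remains consistent.
    """
    if min_allele_depth < 1:
        raise ValueError("min_allele_depth must be >= 1")
    gene_id = profile.gene_id
    consistent = set(markers.group_strains(gene_id))
    significant: list[int] = []
    for marker in markers.for_gene(gene_id):
        if marker.position >= profile.gene_len:
            raise ValueError(
                f"marker at {marker.position} beyond gene {gene_id!r} "
                f"(length {profile.gene_len})"
            )
        if marker.kind != "substitution":
            continue
        obs = profile.allele_observations.get(marker.position, {})
        if len(obs) != 1:
            continue  # uncovered or discordant
        allele, count = next(iter(obs.items()))
        if count < min_allele_depth:
            continue
        significant.append(marker.position)
        carriers = markers.carriers.get((gene_id, marker.position), {})
        carrier_strains = {
            markers.strain_of[g] for g in carriers.get(allele, set())
        }
        consistent &= carrier_strains
    return GeneCall(
        gene_id=gene_id,
        covered_bp=profile.covered_bp,
        covered_pct=profile.covered_pct,
        significant_snp_count=len(significant),
        significant_positions=tuple(sorted(significant)),
        consistent_strains=frozenset(consistent),
    )


# ---------------------------------------------------------------------------
# calling


def call_strains(
    calls: Mapping[str, GeneCall],
    catalog: Catalog,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> CallReport:
    """Apply the threshold rule to per-gene calls and build the reports.

    1. a gene is *admissible* when breadth (bp and %) and significant-SNP
       count clear their thresholds;
    2. a strain's supporting genes are the admissible genes it is
       consistent with; it enters the summary report with
       >= ``min_tas_summary`` of them and the short report with
       >= ``min_tas_short``;
    3. the intersection of consistent strains over the supporting genes
       is the reported group; its size is the uniqueness, and rows with
       uniqueness > ``uniqueness_max`` are suppressed;
    4. a species is reported when it owns >= ``min_tas_species``
       admissible genes or one of its strains is detected.
    """
    species_of_strain = catalog.strain_species()
    species_of_gene = {rec.gene_id: rec.species for rec in catalog}

    admissible = {g: c for g, c in calls.items() if c.admissible(cfg)}

    support: dict[str, list[GeneCall]] = {}
    for call in admissible.values():
        for strain in call.consistent_strains:
            support.setdefault(strain, []).append(call)

    summary: dict[str, dict] = {}
    short: dict[str, dict] = {}
    reported_strains: set[str] = set()
    for strain, genes in sorted(support.items()):
        n = len(genes)
        if n < cfg.min_tas_summary and n < cfg.min_tas_short:
            continue
        group: set[str] = set.intersection(
            *(set(c.consistent_strains) for c in genes)
        )
        uniqueness = len(group)
        if uniqueness > cfg.uniqueness_max:
            continue
        label = "+".join(sorted(group))
        mean_cov = round(sum(c.covered_pct for c in genes) / n, 2)
        if n >= cfg.min_tas_summary:
            summary.setdefault(label, {
                "label": label,
                "uniqueness": uniqueness,
                "significant_snps": sum(c.significant_snp_count for c in genes),
                "n_genes": n,
                "mean_coverage_pct": mean_cov,
            })
        if n >= cfg.min_tas_short:
            short.setdefault(label, {
                "label": label,
                "n_genes": n,
                "mean_coverage_pct": mean_cov,
                "snp_positions": ";".join(
                    f"{c.gene_id}:"
                    + ",".join(str(p + 1) for p in c.significant_positions)
                    for c in sorted(genes, key=lambda c: c.gene_id)
                ),
            })
        if label in summary and label in short:
            reported_strains |= group

    admissible_per_species: dict[str, int] = {}
    for gene_id in admissible:
        sp = species_of_gene[gene_id]
        admissible_per_species[sp] = admissible_per_species.get(sp, 0) + 1
    species: set[str] = {
        sp
        for sp, n in admissible_per_species.items()
        if n >= cfg.min_tas_species
    }
    species |= {species_of_strain[s] for s in reported_strains if s in species_of_strain}

    summary_df = pd.DataFrame(
        list(summary.values()),
        columns=["label", "uniqueness", "significant_snps", "n_genes",
                 "mean_coverage_pct"],
    )
    short_df = pd.DataFrame(
        list(short.values()),
        columns=["label", "n_genes", "mean_coverage_pct", "snp_positions"],
    )
    species_df = pd.DataFrame(
        [{"species": sp} for sp in sorted(species)], columns=["species"]
    )
    return CallReport(
        summary_rows=summary_df, short_rows=short_df, species_rows=species_df
    )
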