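"""Genotyping and the seven-parameter threshold rule."""

import itertools

import numpy as np
import pytest

from tasprof.calling import GeneCall, ThresholdConfig, call_strains, genotype_gene
from tasprof.catalog import Catalog
from tasprof.mapping import CoverageProfile, ReadHit, coverage_profiles
from tasprof.markers import markers_for_catalog

from conftest import make_record


def two_strain_catalog(n_snps=3, length=300, seed=3):
    """Two strains of one species differing at n_snps positions per gene."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    records = []
    for fam in ("MazEF", "RelBE", "HicAB"):
        seq = bases[rng.integers(0, 4, size=length)]
        records.append(make_record(
            f"{fam}_s1", seq.tobytes().decode(), strain="s1", family=fam))
        mutated = seq.copy()
        for pos in rng.choice(length, size=n_snps, replace=False):
            mutated[pos] = bases[(np.nonzero(bases == mutated[pos])[0][0] + 1) % 4]
        records.append(make_record(
            f"{fam}_s2", mutated.tobytes().decode(), strain="s2", family=fam))
    return Catalog(records)


def full_coverage_hits(catalog, strain):
    """Error-free full-length hits over every gene of one strain."""
    return [
        ReadHit(f"read_{rec.gene_id}", rec.gene_id, 0, len(rec.sequence), "+", ())
        for rec in catalog
        if rec.strain == strain
    ]


class TestGenotypeGene:
    def test_concordant_full_coverage(self):
        cat = two_strain_catalog()
        ms = markers_for_catalog(cat)
        profs = coverage_profiles(full_coverage_hits(cat, "s1"), cat, ms)
        call = genotype_gene(profs["MazEF_s1"], ms)
        assert call.significant_snp_count == len(ms.for_gene("MazEF_s1"))
        assert call.significant_snp_count >= 3
        assert call.consistent_strains == {"s1"}

    def test_uncovered_marker_not_significant(self):
        cat = two_strain_catalog()
        ms = markers_for_catalog(cat)
        profs = coverage_profiles([], cat, ms)
        call = genotype_gene(profs["MazEF_s1"], ms)
        assert call.significant_snp_count == 0
        # no evidence: both strains remain consistent
        assert call.consistent_strains == {"s1", "s2"}

    def test_discordant_position_excluded(self):
        cat = two_strain_catalog()
        ms = markers_for_catalog(cat)
        gene = "MazEF_s1"
        pos = ms.for_gene(gene)[0].position
        L = len(cat.by_id[gene].sequence)
        hits = [
            ReadHit("r1", gene, 0, L, "+", ()),
            ReadHit("r2", gene, 0, L, "+", ((pos, "N"),)),
        ]
        profs = coverage_profiles(hits, cat, ms)
        call = genotype_gene(profs[gene], ms)
        assert pos not in call.significant_positions
        assert call.significant_snp_count == len(ms.for_gene(gene)) - 1

    def test_allele_depth_threshold(self):
        cat = two_strain_catalog()
        ms = markers_for_catalog(cat)
        gene = "MazEF_s1"
        L = len(cat.by_id[gene].sequence)
        profs = coverage_profiles([ReadHit("r1", gene, 0, L, "+", ())], cat, ms)
        assert genotype_gene(profs[gene], ms, min_allele_depth=1).significant_snp_count > 0
        assert genotype_gene(profs[gene], ms, min_allele_depth=2).significant_snp_count == 0

    def test_truth_table_two_marker_gene(self):
        """Enumerate allele observations on a 2-marker toy gene."""
        cat = Catalog([
            make_record("v1", "AAAAAAAAAA", strain="s1"),
            make_record("v2", "ACAAAAAAGA", strain="s2"),
        ])
        ms = markers_for_catalog(cat)
        assert {m.position for m in ms.for_gene("v1")} == {1, 8}
        # observations: None (uncovered), 'ref', 'alt', 'mixed'
        def build_profile(obs1, obs2):
            observations = {}
            for pos, obs in ((1, obs1), (8, obs2)):
                if obs == "ref":
                    observations[pos] = {"A": 2}
                elif obs == "alt":
                    observations[pos] = {"C" if pos == 1 else "G": 2}
                elif obs == "mixed":
                    observations[pos] = {"A": 1, "C": 1}
            return CoverageProfile(
                gene_id="v1", gene_len=10,
                depth=np.ones(10, dtype=np.int32),
                allele_observations=observations,
            )

        for obs1, obs2 in itertools.product(
            (None, "ref", "alt", "mixed"), repeat=2
        ):
            call = genotype_gene(build_profile(obs1, obs2), ms)
            expected_sig = sum(o in ("ref", "alt") for o in (obs1, obs2))
            assert call.significant_snp_count == expected_sig
            # hand truth table for consistency
            expected = {"s1", "s2"}
            if "ref" in (obs1, obs2):
                expected &= {"s1"}
            if "alt" in (obs1, obs2):
                expected &= {"s2"}
            assert call.consistent_strains == expected

    def test_marker_beyond_gene_is_error(self):
        cat = Catalog([
            make_record("v1", "AAAAAAAAAA", strain="s1"),
            make_record("v2", "ACAAAAAAAA", strain="s2"),
        ])
        ms = markers_for_catalog(cat)
        short = CoverageProfile(gene_id="v1", gene_len=1,
                                depth=np.zeros(1, dtype=np.int32))
        with pytest.raises(ValueError, match="beyond"):
            genotype_gene(short, ms)


def call_for(gene_id, covered_bp, covered_pct, snps, strains):
    return GeneCall(
        gene_id=gene_id, covered_bp=covered_bp, covered_pct=covered_pct,
        significant_snp_count=snps,
        significant_positions=tuple(range(snps)),
        consistent_strains=frozenset(strains),
    )


class TestCallStrains:
    def setup_method(self):
        self.catalog = two_strain_catalog()

    def test_default_detection(self):
        calls = {
            "MazEF_s1": call_for("MazEF_s1", 300, 100.0, 3, {"s1"}),
            "RelBE_s1": call_for("RelBE_s1", 300, 100.0, 3, {"s1"}),
        }
        report = call_strains(calls, self.catalog, ThresholdConfig())
        assert report.detected == {"s1"}
        assert report.detected_species == {"B. longum"}

    def test_breadth_bp_threshold(self):
        calls = {
            "MazEF_s1": call_for("MazEF_s1", 160, 100.0, 3, {"s1"}),
            "RelBE_s1": call_for("RelBE_s1", 300, 100.0, 3, {"s1"}),
        }
        report = call_strains(calls, self.catalog, ThresholdConfig())
        # one admissible gene meets summary (>=1) but not short (>=2)
        assert set(report.summary_rows["label"]) == {"s1"}
        assert report.detected == set()

    def test_indistinguishable_strains_grouped_or_suppressed(self):
        calls = {
            "MazEF_s1": call_for("MazEF_s1", 300, 100.0, 3, {"s1", "s2"}),
            "RelBE_s1": call_for("RelBE_s1", 300, 100.0, 3, {"s1", "s2"}),
        }
        strict = call_strains(calls, self.catalog, ThresholdConfig())
        assert strict.detected == set()  # uniqueness 2 > uniqueness_max 1
        loose = call_strains(
            calls, self.catalog,
            ThresholdConfig(uniqueness_max=2),
        )
        assert loose.detected == {"s1+s2"}
        row = loose.summary_rows.set_index("label").loc["s1+s2"]
        assert row["uniqueness"] == 2

    def test_species_via_admissible_gene_count(self):
        # five admissible genes of one species, no strain resolvable
        catalog = Catalog([
            make_record(f"g{i}", "A" * 200 + "C" * 100, strain=f"st{i}",
                        family=f"F{i}")
            for i in range(5)
        ])
        calls = {
            f"g{i}": call_for(f"g{i}", 300, 100.0, 3, set())
            for i in range(5)
        }
        report = call_strains(calls, catalog, ThresholdConfig())
        assert report.detected == set()
        assert report.detected_species == {"B. longum"}

    def test_report_consistency_short_subset_of_summary(self):
        calls = {
            "MazEF_s1": call_for("MazEF_s1", 300, 100.0, 3, {"s1"}),
            "RelBE_s1": call_for("RelBE_s1", 300, 100.0, 3, {"s1"}),
            "HicAB_s2": call_for("HicAB_s2", 300, 100.0, 3, {"s2"}),
        }
        report = call_strains(calls, self.catalog, ThresholdConfig())
        assert set(report.short_rows["label"]) <= set(report.summary_rows["label"])


def random_config(rng):
    return ThresholdConfig(
        uniqueness_max=int(rng.integers(1, 16)),
        min_marker_coverage_bp=int(rng.integers(30, 281)),
        min_gene_coverage_pct=float(rng.integers(40, 101)),
        min_significant_snps=int(rng.integers(0, 21)),
        min_tas_species=int(rng.integers(2, 16)),
        min_tas_summary=int(rng.integers(1, 11)),
        min_tas_short=int(rng.integers(1, 11)),
    )


def tighten(cfg, rng):
    return ThresholdConfig(
        uniqueness_max=int(rng.integers(1, cfg.uniqueness_max + 1)),
        min_marker_coverage_bp=int(rng.integers(cfg.min_marker_coverage_bp, 281)),
        min_gene_coverage_pct=float(rng.integers(int(cfg.min_gene_coverage_pct), 101)),
        min_significant_snps=int(rng.integers(cfg.min_significant_snps, 21)),
        min_tas_species=int(rng.integers(cfg.min_tas_species, 16)),
        min_tas_summary=int(rng.integers(cfg.min_tas_summary, 11)),
        min_tas_short=int(rng.integers(cfg.min_tas_short, 11)),
    )


def test_threshold_monotonicity_random_pairs():
    """Tightening any threshold never enlarges the detected strain set."""
    rng = np.random.default_rng(99)
    catalog = two_strain_catalog()
    strains = ["s1", "s2"]
    genes = [rec.gene_id for rec in catalog]
    for _ in range(60):
        calls = {}
        for g in genes:
            consistent = {s for s in strains if rng.random() < 0.7}
            calls[g] = call_for(
                g,
                int(rng.integers(0, 301)),
                float(rng.integers(0, 101)),
                int(rng.integers(0, 8)),
                consistent,
            )
        loose = random_config(rng)
        tight = tighten(loose, rng)
        rep_loose = call_strains(calls, catalog, loose)
        rep_tight = call_strains(calls, catalog, tight)
        assert rep_tight.detected_strains <= rep_loose.detected_strains
        assert rep_tight.detected_species <= rep_loose.detected_species
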