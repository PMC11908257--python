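import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrgcat.build import revcomp
from nrgcat.errors import ConfigError, IntegrityError, SchemaError
from nrgcat.mock import MockTruth, SpeciesSpec, make_genomes, simulate_reads
from nrgcat.model import Lifestyle, PhageAnnotation, TaxonomyLabel
from nrgcat.profiler import (
    Alignment,
    CatalogIndex,
    GeneProfile,
    MapOptions,
    ReadHit,
    cazy_matrix,
    compose,
    map_reads,
    mycobiome,
    phage_contig_filter,
    phageome,
    quantify,
    read_sam_hits,
    species_transcriptome,
    tpm,
    write_sam,
)

from .conftest import mutate_exact, random_seq


def _exhaustive_oracle(read, genes, min_identity=0.90):
    """Scan every gene, offset, and strand; return the full alignment set."""
    hits = []
    lr = len(read)
    for strand in ("+", "-"):
        oriented = read if strand == "+" else revcomp(read)
        for nid, seq in genes.items():
            for start in range(0, len(seq) - lr + 1):
                matches = sum(
                    a == b for a, b in zip(oriented, seq[start : start + lr])
                )
                if matches / lr >= min_identity:
                    hits.append((nid, start, strand, matches))
    return sorted(hits, key=lambda h: (-h[3], h[0], h[1], h[2]))


class TestMapReads:
    def _catalog(self, rng, n_genes=3, length=500):
        return {f"n{i}": random_seq(rng, length) for i in range(n_genes)}

    def test_error_free_read_maps_perfectly(self, rng):
        genes = self._catalog(rng)
        index = CatalogIndex(genes)
        read = genes["n1"][100:250]
        hits = list(map_reads([("r1", read)], index))
        assert len(hits) == 1
        best = hits[0].alignments[0]
        assert best.nrg_id == "n1" and best.pos == 100
        assert best.matches == 150  # identity 1.0

    def test_shared_gene_reports_both(self, rng):
        shared = random_seq(rng, 400)
        genes = {"nA": shared + random_seq(rng, 100),
                 "nB": shared + random_seq(rng, 200)}
        index = CatalogIndex(genes)
        hits = list(map_reads([("r1", shared[50:200])], index))
        alns = hits[0].alignments
        assert {a.nrg_id for a in alns} == {"nA", "nB"}
        assert alns[0].matches == alns[1].matches

    def test_reverse_strand_mapping(self, rng):
        genes = self._catalog(rng)
        index = CatalogIndex(genes)
        read = revcomp(genes["n2"][10:170])
        hits = list(map_reads([("r1", read)], index))
        best = hits[0].alignments[0]
        assert best.nrg_id == "n2" and best.strand == "-"

    def test_low_identity_dropped(self, rng):
        genes = self._catalog(rng)
        index = CatalogIndex(genes)
        read = mutate_exact(genes["n0"][0:150], 30, rng)  # identity 0.80
        assert list(map_reads([("r1", read)], index)) == []

    def test_short_read_warns_once(self, rng):
        index = CatalogIndex(self._catalog(rng))
        with pytest.warns(UserWarning):
            hits = list(map_reads([("r1", "ACGT"), ("r2", "ACGT")], index))
        assert hits == []

    def test_exhaustive_oracle_equivalence(self, rng):
        genes = self._catalog(rng, n_genes=3, length=400)
        # duplicate a block so multi-mapping occurs
        genes["n2"] = genes["n0"][:200] + genes["n2"][200:]
        index = CatalogIndex(genes)
        reads = []
        py_rng = random.Random(99)
        for i in range(300):
            src = py_rng.choice(list(genes))
            start = py_rng.randrange(0, len(genes[src]) - 150 + 1)
            read = genes[src][start : start + 150]
            if py_rng.random() < 0.3:
                # <=6 substitutions: each destroys at most seed_length
                # 20-mer windows, so at least one of the 131 windows stays
                # intact and exhaustive seeding retains full sensitivity
                read = mutate_exact(read, py_rng.randrange(0, 7), py_rng)
            if py_rng.random() < 0.5:
                read = revcomp(read)
            reads.append((f"r{i:03d}", read))
        opts = MapOptions(n_seeds=0)  # exhaustive seeding
        got = {
            h.read_id: [(a.nrg_id, a.pos, a.strand, a.matches)
                        for a in h.alignments]
            for h in map_reads(reads, index, opts)
        }
        for rid, read in reads:
            expected = _exhaustive_oracle(read, genes)[:10]
            assert got.get(rid, []) == expected, rid


class TestQuantify:
    def test_unique_reads_depth(self):
        hits = [ReadHit(f"r{i}", 100, [Alignment("g1", 0, "+", 100)])
                for i in range(10)]
        profile = quantify(hits, {"g1": 1000})
        assert profile.reads["g1"] == 10
        assert profile.depth["g1"] == pytest.approx(1.0)

    def test_tie_split(self):
        hits = [ReadHit("r1", 100, [Alignment("g1", 0, "+", 100),
                                    Alignment("g2", 5, "+", 100)])]
        profile = quantify(hits, {"g1": 1000, "g2": 1000})
        assert profile.reads["g1"] == pytest.approx(0.5)
        assert profile.reads["g2"] == pytest.approx(0.5)

    def test_best_score_only(self):
        hits = [ReadHit("r1", 100, [Alignment("g1", 0, "+", 100),
                                    Alignment("g2", 5, "+", 95)])]
        profile = quantify(hits, {"g1": 1000, "g2": 1000})
        assert profile.reads["g1"] == 1.0
        assert "g2" not in profile.reads

    def test_unknown_nrg_integrity_error(self):
        hits = [ReadHit("r1", 100, [Alignment("ghost", 0, "+", 100)])]
        with pytest.raises(IntegrityError):
            quantify(hits, {"g1": 1000})

    def test_zero_read_genes_omitted(self):
        profile = quantify([], {"g1": 1000})
        assert profile.reads == {} and profile.depth == {}


SP_A = TaxonomyLabel.species("A sp", "A")
SP_B = TaxonomyLabel.species("B sp", "B")


class TestCompose:
    def test_single_species(self):
        profile = GeneProfile("s", depth={"g1": 2.0, "g2": 1.0})
        comp = compose(profile, {"g1": SP_A, "g2": SP_A})
        assert comp.shares[SP_A] == pytest.approx(1.0)

    def test_two_taxa_equal_depth(self):
        profile = GeneProfile("s", depth={"g1": 1.5, "g2": 1.5})
        comp = compose(profile, {"g1": SP_A, "g2": SP_B})
        assert comp.shares[SP_A] == pytest.approx(0.5)
        assert comp.shares[SP_B] == pytest.approx(0.5)

    def test_unassigned_bucket(self):
        profile = GeneProfile("s", depth={"g1": 1.0, "g2": 3.0})
        comp = compose(profile, {"g1": SP_A})
        assert comp.shares[TaxonomyLabel.unassigned()] == pytest.approx(0.75)

    def test_shares_sum_to_one(self, rng):
        depth = {f"g{i}": rng.random() for i in range(50)}
        taxonomy = {f"g{i}": (SP_A if i % 3 == 0 else SP_B) for i in range(40)}
        comp = compose(GeneProfile("s", depth=depth), taxonomy)
        assert sum(comp.shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_depth_flagged(self):
        comp = compose(GeneProfile("s"), {})
        assert comp.empty and comp.shares == {}


class TestTpm:
    def test_single_gene(self):
        expr = tpm(GeneProfile("s", reads={"g1": 7.0}), {"g1": 900})
        assert expr.tpm["g1"] == pytest.approx(1e6)

    def test_length_correction_closed_form(self):
        profile = GeneProfile("s", reads={"g1": 10.0, "g2": 10.0})
        expr = tpm(profile, {"g1": 1000, "g2": 2000})
        assert expr.tpm["g1"] == pytest.approx(2e6 / 3, rel=1e-9)
        assert expr.tpm["g2"] == pytest.approx(1e6 / 3, rel=1e-9)

    def test_sums_to_million(self, rng):
        profile = GeneProfile(
            "s", reads={f"g{i}": rng.random() * 50 for i in range(30)})
        expr = tpm(profile, {f"g{i}": 500 + 17 * i for i in range(30)})
        assert sum(expr.tpm.values()) == pytest.approx(1e6, abs=1e-3)

    def test_empty_flagged(self):
        assert tpm(GeneProfile("s"), {}).empty

    @given(reads=st.dictionaries(
        st.sampled_from([f"g{i}" for i in range(12)]),
        st.floats(0.5, 1e5), min_size=1))
    @settings(max_examples=50, deadline=None)
    def test_tpm_normalization_property(self, reads):
        lengths = {f"g{i}": 300 + 97 * i for i in range(12)}
        expr = tpm(GeneProfile("s", reads=reads), lengths)
        assert sum(expr.tpm.values()) == pytest.approx(1e6, abs=1e-3)


class TestMycobiome:
    FUNGI = {"Candida albicans", "Pichia kudriavzevii"}

    def _comp(self, fungal_share):
        ca = TaxonomyLabel.species("Candida albicans", "Candida")
        shares = {SP_A: 1.0 - fungal_share}
        if fungal_share:
            shares[ca] = fungal_share
        comp = compose(
            GeneProfile("s", depth={"g1": shares[SP_A]}), {"g1": SP_A})
        comp.shares = shares
        return comp

    def test_detected_above_threshold(self):
        assert mycobiome(self._comp(2e-4), self.FUNGI).detected

    def test_exactly_threshold_not_detected(self):
        assert not mycobiome(self._comp(1e-4), self.FUNGI).detected

    def test_no_fungi(self):
        result = mycobiome(self._comp(0.0), self.FUNGI)
        assert result.total_share == 0.0 and not result.detected

    def test_within_fungi_renormalized(self):
        ca = TaxonomyLabel.species("Candida albicans", "Candida")
        pk = TaxonomyLabel.species("Pichia kudriavzevii", "Pichia")
        comp = self._comp(0.0)
        comp.shares = {SP_A: 0.99, ca: 0.0075, pk: 0.0025}
        result = mycobiome(comp, self.FUNGI)
        assert result.within["Candida albicans"] == pytest.approx(0.75)

    def test_empty_fungal_list_rejected(self):
        with pytest.raises(ConfigError):
            mycobiome(self._comp(0.1), [])


class TestPhageome:
    def test_ratio(self):
        profile = GeneProfile("s", depth={"v": 2.0, "t": 1.0, "b": 7.0})
        phage = {"v": PhageAnnotation(Lifestyle.VIRULENT),
                 "t": PhageAnnotation(Lifestyle.TEMPERATE)}
        result = phageome(profile, phage)
        assert result.ratio == pytest.approx(2.0)
        assert result.phage_share == pytest.approx(0.3)

    def test_no_phage_undefined(self):
        result = phageome(GeneProfile("s", depth={"b": 1.0}), {})
        assert result.phage_share == 0.0 and not result.ratio_defined

    def test_only_temperate_ratio_zero(self):
        profile = GeneProfile("s", depth={"t": 1.0})
        result = phageome(profile, {"t": PhageAnnotation(Lifestyle.TEMPERATE)})
        assert result.ratio == 0.0 and result.ratio_defined


class TestPhageContigFilter:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["contig_id", "viral_gene_count", "is_prophage",
                           "host_gene_count", "completeness", "host_score",
                           "host_genus"])

    def test_accept(self):
        table = self._table([["c1", 2, "no", 3, 95.0, 1500, "Lactobacillus"]])
        accepted, hosts = phage_contig_filter(table)
        assert accepted == ["c1"] and hosts == {"c1": "Lactobacillus"}

    def test_single_viral_gene_rejected(self):
        table = self._table([["c1", 1, "no", 0, 99.0, None, ""]])
        assert phage_contig_filter(table)[0] == []

    def test_strict_host_and_completeness(self):
        table = self._table([["c1", 5, "no", 10, 95.0, None, ""],
                             ["c2", 5, "no", 9, 90.0, None, ""]])
        assert phage_contig_filter(table)[0] == []

    def test_host_below_score_not_recorded(self):
        table = self._table([["c1", 2, "no", 3, 95.0, 1399, "Lactobacillus"]])
        accepted, hosts = phage_contig_filter(table)
        assert accepted == ["c1"] and hosts == {}

    def test_missing_column_schema_error(self):
        with pytest.raises(SchemaError):
            phage_contig_filter(pd.DataFrame({"viral_gene_count": [2]}))


class TestSpeciesTranscriptome:
    def _setup(self, reads_a):
        taxonomy = {"g1": SP_A, "g2": SP_A, "g3": SP_B}
        profile = GeneProfile(
            "s", reads={"g1": reads_a * 0.6, "g2": reads_a * 0.4, "g3": 50.0})
        expr = tpm(profile, {"g1": 1000, "g2": 1000, "g3": 1000})
        return profile, expr, taxonomy

    def test_emitted_above_methods_threshold(self):
        profile, expr, taxonomy = self._setup(150_000)
        result = species_transcriptome(profile, expr, taxonomy, "A sp",
                                       min_reads=100_000)
        assert result.emitted
        assert result.table["tpm_species"].sum() == pytest.approx(1e6)

    def test_refused_under_figure_threshold(self):
        profile, expr, taxonomy = self._setup(150_000)
        result = species_transcriptome(profile, expr, taxonomy, "A sp",
                                       min_reads=250_000)
        assert not result.emitted and result.n_reads == pytest.approx(150_000)

    def test_absent_species_refused_with_zero(self):
        profile, expr, taxonomy = self._setup(150_000)
        profile.reads.pop("g3")
        result = species_transcriptome(profile, expr, taxonomy, "B sp")
        assert not result.emitted and result.n_reads == 0

    def test_unknown_species_error(self):
        profile, expr, taxonomy = self._setup(10)
        with pytest.raises(ConfigError):
            species_transcriptome(profile, expr, taxonomy, "Nope sp")


class TestCazyMatrix:
    def test_single_gene(self):
        expr = {"s1": tpm(GeneProfile("s1", reads={"g1": 10.0}), {"g1": 1000})}
        matrix, contrib = cazy_matrix(expr, {"g1": {"GH33"}}, {"g1": SP_A})
        assert matrix.loc["s1", "GH33"] == pytest.approx(1e6)
        row = contrib.iloc[0]
        assert row["taxon"] == "A sp" and row["contribution"] == pytest.approx(1.0)

    def test_two_taxa_contributions(self):
        profile = GeneProfile("s1", reads={"g1": 75.0, "g2": 25.0})
        expr = {"s1": tpm(profile, {"g1": 1000, "g2": 1000})}
        matrix, contrib = cazy_matrix(
            expr, {"g1": {"GH13"}, "g2": {"GH13"}}, {"g1": SP_A, "g2": SP_B})
        by_taxon = dict(zip(contrib["taxon"], contrib["contribution"]))
        assert by_taxon["A sp"] == pytest.approx(0.75)
        assert by_taxon["B sp"] == pytest.approx(0.25)

    def test_multifamily_full_tpm_each(self):
        profile = GeneProfile("s1", reads={"g1": 10.0})
        expr = {"s1": tpm(profile, {"g1": 1000})}
        matrix, _ = cazy_matrix(
            expr, {"g1": {"GH13", "CBM48"}}, {"g1": SP_A})
        assert matrix.loc["s1", "GH13"] == pytest.approx(1e6)
        assert matrix.loc["s1", "CBM48"] == pytest.approx(1e6)


class TestSamInterchange:
    def test_sam_path_equals_internal_path(self, rng, tmp_path):
        genes = {f"n{i}": random_seq(rng, 600) for i in range(4)}
        genes["n3"] = genes["n0"][:300] + genes["n3"][300:]
        index = CatalogIndex(genes)
        py_rng = random.Random(5)
        reads = []
        for i in range(400):
            src = py_rng.choice(list(genes))
            start = py_rng.randrange(0, 451)
            reads.append((f"r{i:03d}", genes[src][start : start + 150]))
        hits = list(map_reads(reads, index))
        lengths = {nid: len(s) for nid, s in genes.items()}
        internal = quantify(hits, lengths, "s")

        sam = tmp_path / "aln.sam"
        write_sam(hits, lengths, sam)
        imported = quantify(read_sam_hits(sam), lengths, "s")
        assert set(internal.reads) == set(imported.reads)
        for nid in internal.reads:
            assert internal.reads[nid] == pytest.approx(imported.reads[nid])
            assert internal.depth[nid] == pytest.approx(imported.depth[nid])


class TestEndToEndRecovery:
    """Profiler recovery on a species-resolvable panel (divergences well
    above the clustering threshold), scaled down from the documented
    200k-read setting."""

    def _run(self, error_rate, n_reads=40_000):
        from nrgcat.build import build_catalog
        from nrgcat.mock import cds_from_genomes
        from nrgcat.profiler import species_shares

        specs = [SpeciesSpec(f"Sp {i}", f"Gen{i}", 20_000, 19) for i in range(8)]
        genomes = make_genomes(specs, seed=77)
        catalog, _ = build_catalog(cds_from_genomes(genomes))
        proportions = {"Sp 0": 0.30, "Sp 1": 0.20, "Sp 2": 0.15, "Sp 3": 0.10,
                       "Sp 4": 0.10, "Sp 5": 0.08, "Sp 6": 0.04, "Sp 7": 0.03}
        truth = MockTruth(proportions, genomes, seed=77)
        reads = simulate_reads(truth, n_reads, 150, error_rate, seed=78)
        index = CatalogIndex.from_catalog(catalog)
        hits = map_reads(zip(reads.ids, reads.sequences), index)
        profile = quantify(hits, catalog.lengths(), "s")
        observed = species_shares(profile, catalog)
        return proportions, observed

    def test_error_free_within_one_point(self):
        expected, observed = self._run(0.0)
        for sp, e in expected.items():
            assert abs(observed.get(sp, 0.0) - e) <= 0.01

    def test_with_errors_within_two_points(self):
        expected, observed = self._run(0.002)
        for sp, e in expected.items():
            assert abs(observed.get(sp, 0.0) - e) <= 0.02
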