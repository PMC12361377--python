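"""Synthetic community generator: determinism, planted structure, capture."""

import json

import numpy as np
import pytest

import sagmetab as sm


class TestGenerateCompleteGenomes:
    def test_same_seed_byte_identical_outputs(self, catalog, tmp_path):
        cfg = sm.CommunityConfig(n_genomes_per_habitat=8, seed=1)
        for sub in ("a", "b"):
            res = sm.simulate_community(cfg, catalog)
            sm.write_community(res, tmp_path / sub)
        for name in ("annotations.tsv", "quality.tsv", "metadata.tsv",
                     "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes(), name
        gffs = sorted(p.name for p in (tmp_path / "a" / "gff").iterdir())
        for name in gffs:
            assert (tmp_path / "a" / "gff" / name).read_bytes() == \
                (tmp_path / "b" / "gff" / name).read_bytes()

    def test_full_carriage_forces_truth_positive(self, catalog):
        cfg = sm.CommunityConfig(
            n_genomes_per_habitat=12, seed=2,
            guilds=(sm.GuildSpec("g", ("sulfide_oxidation",), 1.0, 0.0),),
            background_carriage=0.0,
        )
        truth, _ = sm.generate_complete_genomes(cfg, catalog)
        assert all(t.pathways["sulfide_oxidation"]
                   for t in truth.genomes.values())

    def test_zero_background_and_no_guild_forces_negative(self, catalog):
        cfg = sm.CommunityConfig(
            n_genomes_per_habitat=12, seed=3,
            guilds=(sm.GuildSpec("g", ("rdsr",), 0.5, 0.0,
                                 habitats=("lake",)),),
            background_carriage=0.0,
        )
        truth, _ = sm.generate_complete_genomes(cfg, catalog)
        sediment = [t for t in truth.genomes.values()
                    if t.habitat == "sediment"]
        assert sediment and not any(t.pathways["rdsr"] for t in sediment)

    def test_carriers_contain_every_required_gene(self, catalog):
        cfg = sm.CommunityConfig(n_genomes_per_habitat=20, seed=4)
        truth, genomes = sm.generate_complete_genomes(cfg, catalog)
        profiles = {g: genomes[g].ko_counts() for g in genomes}
        matrix = sm.call_all(profiles, catalog)
        for gid, t in truth.genomes.items():
            for pid, truly in t.pathways.items():
                assert bool(matrix.loc[gid, pid] >= 1) == truly

    def test_captured_genes_exist_in_truth_inventory(self, small_community):
        res = small_community
        for gid, genome in res.captured_genomes.items():
            inventory = res.truth.genomes[gid].inventory
            for gene in genome.genes():
                if gene.ko is None or "_x" in gene.gene_id:
                    continue       # unannotated / injected contaminant
                assert gene.ko in inventory

    def test_unresolvable_guild_pathway_names_the_id(self, catalog):
        cfg = sm.CommunityConfig(
            guilds=(sm.GuildSpec("g", ("no_such_pathway",), 0.5, 0.0),))
        with pytest.raises(sm.ConfigError, match="no_such_pathway"):
            sm.generate_complete_genomes(cfg, catalog)

    def test_multi_copy_genomes_occur_when_configured(self, catalog):
        cfg = sm.CommunityConfig(n_genomes_per_habitat=30, seed=6,
                                 multi_copy_fraction=0.5)
        truth, _ = sm.generate_complete_genomes(cfg, catalog)
        max_copies = max(
            max(t.inventory.values(), default=1)
            for t in truth.genomes.values())
        assert max_copies >= 2


class TestApplyCapture:
    def test_full_completeness_is_identity(self, catalog):
        cfg = sm.CommunityConfig(n_genomes_per_habitat=5, seed=7,
                                 contamination_rate=0.0)
        truth, genomes = sm.generate_complete_genomes(cfg, catalog)
        rng = np.random.default_rng(0)
        captured, _, _ = sm.apply_capture(
            genomes, {g: 1.0 for g in genomes}, truth, cfg, rng)
        for gid in genomes:
            assert [x.gene_id for x in captured[gid].genes()] == \
                [x.gene_id for x in genomes[gid].genes()]

    def test_half_completeness_retains_half_the_genes(self, catalog):
        from sagmetab.reduction import Contig, ContigGenome, Gene

        genome = ContigGenome("g", (Contig("c", tuple(
            Gene(f"g{j}", f"K{j}", j * 10 + 1, j * 10 + 9)
            for j in range(100))),))
        cfg = sm.CommunityConfig(n_genomes_per_habitat=1, seed=0,
                                 contamination_rate=0.0)
        truth = sm.TruthTable({"g": sm.simulate.GenomeTruth(
            "g", "genus_001", "lake", (), {}, {f"K{j}": 1 for j in range(100)})})
        captured, records, ann = sm.apply_capture(
            {"g": genome}, {"g": 0.5}, truth, cfg, np.random.default_rng(1))
        assert captured["g"].n_genes == 50
        assert len(ann) == 50
        assert records["g"].completeness == 0.5

    def test_sample_mean_completeness_near_configured(self, catalog):
        cfg = sm.CommunityConfig(seed=8)
        draws = sm.draw_completeness(cfg, 1000, np.random.default_rng(8))
        assert abs(draws.mean() - 0.387) < 0.02

    def test_capture_marginals_match_completeness(self, catalog):
        """Per-gene retention probability equals the drawn completeness."""
        cfg = sm.CommunityConfig(n_genomes_per_habitat=260, seed=9,
                                 contamination_rate=0.0)
        truth, genomes = sm.generate_complete_genomes(cfg, catalog)
        rng = np.random.default_rng(9)
        gids = sorted(genomes)
        completeness = dict(zip(gids, sm.draw_completeness(cfg, len(gids), rng)))
        captured, _, _ = sm.apply_capture(genomes, completeness, truth,
                                          cfg, rng)
        kept = expected = 0.0
        n_genes = 0
        for gid in gids:
            kept += captured[gid].n_genes
            expected += completeness[gid] * genomes[gid].n_genes
            n_genes += genomes[gid].n_genes
        # aggregate retention within binomial error of the drawn completeness
        sigma = np.sqrt(n_genes * 0.25)
        assert abs(kept - expected) < 5 * sigma

    def test_contamination_exercises_ingest_filter(self, catalog, tmp_path):
        cfg = sm.CommunityConfig(n_genomes_per_habitat=150, seed=10,
                                 contamination_rate=0.004)
        res = sm.simulate_community(cfg, catalog)
        mean_contam = res.quality["contamination_pct"].mean()
        assert 0.1 < mean_contam < 1.0      # ~0.4% on average
        assert (res.quality["contamination_pct"] < 5.0).all()

    def test_planted_guild_pairs_cooccur_above_background(self, catalog):
        cfg = sm.CommunityConfig(
            n_genomes_per_habitat=150, seed=11, multi_copy_fraction=0.0,
            guilds=(
                sm.GuildSpec("A", ("sulfide_oxidation", "hydrogenase"),
                             0.35, 0.05),
                sm.GuildSpec("B", ("urease", "methane_oxidation"),
                             0.35, 0.05),
            ),
        )
        truth, genomes = sm.generate_complete_genomes(cfg, catalog)
        profiles = {g: genomes[g].ko_counts() for g in genomes}
        m = (sm.call_all(profiles, catalog) >= 1)

        def jaccard(a, b):
            return (m[a] & m[b]).sum() / max(1, (m[a] | m[b]).sum())

        within = min(jaccard("sulfide_oxidation", "hydrogenase"),
                     jaccard("urease", "methane_oxidation"))
        across = max(jaccard("sulfide_oxidation", "urease"),
                     jaccard("hydrogenase", "methane_oxidation"))
        assert within > across


class TestRoundTrip:
    def test_written_files_load_through_the_readers(self, small_community,
                                                    tmp_path, catalog):
        sm.write_community(small_community, tmp_path)
        ingest = sm.load_annotations(tmp_path / "annotations.tsv",
                                     tmp_path / "quality.tsv")
        assert set(ingest.records) == set(small_community.records)
        for gid, rec in ingest.records.items():
            assert rec.completeness == pytest.approx(
                small_community.records[gid].completeness, abs=1e-4)
            assert rec.habitat == small_community.records[gid].habitat
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth) == set(ingest.records)

    def test_gff_round_trip_preserves_structure(self, small_community,
                                                tmp_path):
        sm.write_community(small_community, tmp_path)
        gid = sorted(small_community.captured_genomes)[0]
        genome = sm.read_gff3(tmp_path / "gff" / f"{gid}.gff3", gid)
        orig = small_community.captured_genomes[gid]
        assert [c.contig_id for c in genome.contigs] == \
            [c.contig_id for c in orig.contigs]
        assert [g.gene_id for g in genome.genes()] == \
            [g.gene_id for g in orig.genes()]
        assert genome.ko_counts() == orig.ko_counts()

    def test_invalid_config_rejected(self):
        with pytest.raises(sm.ConfigError):
            sm.CommunityConfig(mean_completeness=1.5)
        with pytest.raises(sm.ConfigError):
            sm.CommunityConfig(n_contigs_range=(5, 2))
        with pytest.raises(sm.ConfigError):
            sm.GuildSpec("g", ("x",), carrier_fraction=0.1,
                         background_fraction=0.2)
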