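"""Synthetic bundle generation: determinism, planted class structure, and
round-tripping through the package's own readers."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from symsieve import conservation as cons
from symsieve import expression as expr
from symsieve import motifs as mot
from symsieve import orthology as ortho
from symsieve import simulate as sim
from symsieve.species import SpeciesGroups


def _dir_digest(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def _small_config(seed=0, **kw):
    defaults = dict(
        seed=seed, n_ubiquitous=8, n_trait_specific=6, n_trait_biased=6,
        n_negative_only=4, n_treatments=20, n_background_genes=20,
        promoter_length=400,
    )
    defaults.update(kw)
    return sim.SimConfig(**defaults)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        a = sim.emit_fixture_bundle(_small_config(seed=5), tmp_path / "a")
        b = sim.emit_fixture_bundle(_small_config(seed=5), tmp_path / "b")
        assert _dir_digest(a) == _dir_digest(b)

    def test_different_seeds_differ(self, tmp_path):
        a = sim.emit_fixture_bundle(_small_config(seed=5), tmp_path / "a")
        b = sim.emit_fixture_bundle(_small_config(seed=6), tmp_path / "b")
        assert _dir_digest(a) != _dir_digest(b)

    def test_refuses_nonempty_directory_without_force(self, tmp_path):
        sim.emit_fixture_bundle(_small_config(), tmp_path / "a")
        with pytest.raises(FileExistsError):
            sim.emit_fixture_bundle(_small_config(), tmp_path / "a")
        sim.emit_fixture_bundle(_small_config(), tmp_path / "a", force=True)


class TestFamilyConstruction:
    def test_zero_dropout_trait_families_pass_the_strictest_filter(self):
        config = _small_config(dropout_rate=0.0, n_trait_specific=10)
        families = sim.simulate_families(config)
        groups = config.groups
        clusters = ortho.parse_cluster_trees(
            sim.families_to_newick(families), groups
        )
        task6 = ortho.task_filter(clusters, groups, 6)
        trait = [f for f, i in families.items() if i["class"] == "trait_specific"]
        kept_stems = {c.members[0][1].split(".")[0] for c in task6}
        assert set(trait) <= kept_stems

    def test_exact_single_dropout_passes_task5_not_task6(self):
        config = _small_config(dropout_exact=1)
        families = sim.simulate_families(config)
        groups = config.groups
        clusters = ortho.parse_cluster_trees(
            sim.families_to_newick(families), groups
        )
        stems = lambda cs: {c.members[0][1].split(".")[0] for c in cs}  # noqa: E731
        trait = {f for f, i in families.items() if i["class"] != "ubiquitous"
                 and i["class"] != "negative_only"}
        assert trait <= stems(ortho.task_filter(clusters, groups, 5))
        assert not (trait & stems(ortho.task_filter(clusters, groups, 6)))

    def test_class_membership_structure(self):
        config = _small_config()
        families = sim.simulate_families(config)
        groups = config.groups
        neg = groups.codes("C")
        pos = {t.code for t in groups.positive_clustered}
        for info in families.values():
            codes = set(info["members"])
            if info["class"] == "ubiquitous":
                assert codes == groups.codes("clustered")
            elif info["class"] == "negative_only":
                assert codes <= neg
            else:
                assert codes <= pos and len(codes) >= config.min_positive_present


class TestHitTables:
    def test_trait_specific_families_have_no_negative_rows(self, tmp_path):
        config = _small_config()
        families = sim.simulate_families(config)
        tables = sim.simulate_hit_tables(config, families)
        path = tmp_path / "task3.tsv"
        path.write_text("\n".join(tables["task3"]) + "\n")
        hits = cons.ingest_hit_table(path, groups=config.groups)
        truth_map = {
            fam: info["class"] for fam, info in families.items()
        }
        by_query = hits.assign(
            fam=hits["subject"].str.split("_").str[1].str.split(".").str[0]
        )
        neg = config.groups.codes("C")
        for _, row in by_query.iterrows():
            if truth_map[row["fam"].replace("_d", "")] == "trait_specific":
                assert row["species"] not in neg

    def test_trait_biased_gap_matches_configured_model(self, tmp_path):
        config = sim.SimConfig(
            seed=2, n_ubiquitous=0, n_trait_specific=0, n_trait_biased=30,
            n_negative_only=0,
        )
        families = sim.simulate_families(config)
        tables = sim.simulate_hit_tables(config, families)
        path = tmp_path / "task3.tsv"
        path.write_text("\n".join(tables["task3"]) + "\n")
        best = cons.best_hit_reduce(
            cons.ingest_hit_table(path, groups=config.groups)
        )
        records = cons.build_conservation_records(best, config.groups)
        model = config.evalue_model["trait_biased"]
        expected_gap = model["C"][0] - model["A"][0]  # −10 − (−130) = 120
        assert records["ratio_CA"].mean() == pytest.approx(expected_gap, abs=15)

    def test_decoy_hits_are_worse_than_the_best_hit(self, tmp_path):
        config = _small_config(decoy_rate=1.0)
        families = sim.simulate_families(config)
        tables = sim.simulate_hit_tables(config, families)
        path = tmp_path / "t.tsv"
        path.write_text("\n".join(tables["task9"]) + "\n")
        hits = cons.ingest_hit_table(path, groups=config.groups)
        decoys = hits[hits["subject"].str.endswith("_d")]
        assert len(decoys) > 0
        merged = decoys.merge(
            cons.best_hit_reduce(hits), on=["query", "species"], suffixes=("", "_best")
        )
        assert (merged["evalue"] > merged["evalue_best"]).all()

    def test_missing_species_knob_feeds_best_hit_reduction(self, tmp_path):
        config = _small_config(hit_dropout=0.5, n_ubiquitous=20)
        families = sim.simulate_families(config)
        tables = sim.simulate_hit_tables(config, families)
        path = tmp_path / "t.tsv"
        path.write_text("\n".join(tables["task9"]) + "\n")
        best = cons.best_hit_reduce(cons.ingest_hit_table(path, groups=config.groups))
        per_query_b = best[best["species"].isin(config.groups.codes("B"))]
        counts = per_query_b.groupby("query").size()
        assert counts.min() < len(config.groups.group_b)  # some dropout happened


class TestExpressionSimulation:
    def test_noise_free_planted_fold_is_exact(self):
        config = _small_config(noise_sigma=0.0, planted_fold=4.0,
                               induced_fraction=1.0, bad_probeset_rate=0.0,
                               criterion_probs={"AM": 1.0})
        families = sim.simulate_families(config)
        values, probesets, columns, meta_rows, truth = sim.simulate_expression(
            config, families
        )
        import pandas as pd

        matrix = pd.DataFrame(values, index=probesets, columns=columns)
        criteria = [c for c in expr.load_criteria() if c.name == "AM"]
        ratios = expr.compute_ratios(matrix, criteria)
        meta = pd.DataFrame(meta_rows).set_index("probeset_id")
        planted_probes = meta["gene_id"].isin(
            {t["gene_id"] for t in truth.values() if "AM" in t["induced_criteria"]}
        )
        assert np.allclose(ratios.loc[planted_probes.values, "AM"], 4.0)

    def test_unplanted_fold_passes_threshold_almost_never(self):
        config = sim.SimConfig(
            seed=8, n_ubiquitous=0, n_trait_specific=500, n_trait_biased=500,
            n_negative_only=0, dropout_rate=0.0, planted_fold=1.0,
            induced_fraction=1.0, criterion_probs={"AM": 1.0},
            bad_probeset_rate=0.0, n_treatments=15,
        )
        families = sim.simulate_families(config)
        values, probesets, columns, meta_rows, _ = sim.simulate_expression(
            config, families
        )
        import pandas as pd

        matrix = pd.DataFrame(values, index=probesets, columns=columns)
        criteria = [c for c in expr.load_criteria() if c.name == "AM"]
        ratios = expr.compute_ratios(matrix, criteria)
        meta = pd.DataFrame(meta_rows).set_index("probeset_id")
        _, flags = expr.gene_level_flags(ratios, meta, threshold=3)
        assert flags["AM"].mean() <= 0.01

    def test_curation_removes_exactly_the_planted_bad_probesets(self, tmp_path):
        bundle = sim.emit_fixture_bundle(
            _small_config(bad_probeset_rate=0.3), tmp_path / "b"
        )
        truth = sim.load_truth(bundle)
        matrix = expr.read_expression_matrix(bundle / "expression.tsv")
        meta = expr.read_probeset_meta(bundle / "probeset_meta.tsv")
        _, _, log = expr.curate_probesets(matrix, meta)
        assert sorted(log["probeset_id"]) == truth["planted_bad_probesets"]


class TestPromoterSimulation:
    def test_planting_rate_shows_up_as_presence(self):
        config = sim.SimConfig(seed=3, plant_rate=0.5, induced_fraction=1.0)
        families = sim.simulate_families(config)
        truth = sim.assign_expression_truth(config, families)
        promoters, planted = sim.simulate_promoters(config, truth)
        fg = [t["gene_id"] for t in truth.values()
              if {"LCM", "AM"} & set(t["induced_criteria"])]
        assert len(fg) > 30
        n_with_myc1 = sum(
            any(s["motif"] == "Myc1" for s in planted.get(g, [])) for g in fg
        )
        rate = n_with_myc1 / len(fg)
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / len(fg))

    def test_gcc_palindrome_plantings_are_proximally_biased(self):
        config = sim.SimConfig(seed=4, plant_rate=1.0, induced_fraction=1.0)
        families = sim.simulate_families(config)
        truth = sim.assign_expression_truth(config, families)
        promoters, planted = sim.simulate_promoters(config, truth)
        gcc = mot.Motif("GCCGGC", "GCC-palindrome")
        fg = {
            t["gene_id"]: promoters[t["gene_id"]]
            for t in truth.values()
            if {"LCM", "AM"} & set(t["induced_criteria"])
        }
        hits, _ = mot.scan_motif(fg, gcc)
        _, p = mot.positional_distribution(hits, config.promoter_length, 6)
        assert p < 0.05

    def test_motif_longer_than_promoter_is_an_error(self):
        config = _small_config(promoter_length=8)
        with pytest.raises(ValueError, match="longer"):
            sim.simulate_promoters(config, {})


class TestBundleRoundTrip:
    def test_bundle_loads_through_every_reader(self, tmp_path):
        bundle = sim.emit_fixture_bundle(_small_config(), tmp_path / "b")
        groups = SpeciesGroups.from_yaml(bundle / "groups.yaml")
        clusters = ortho.parse_cluster_trees(bundle / "clusters.nwk", groups)
        assert len(clusters) == 24
        proteomes = ortho.read_proteomes(
            {t.code: bundle / "proteomes" / f"{t.code}.fasta"
             for t in groups.clustered_species}
        )
        assert len(proteomes) > 0
        for name in ("task3", "task9"):
            cons.ingest_hit_table(bundle / "hits" / f"{name}.tsv", groups=groups)
        expr.read_expression_matrix(bundle / "expression.tsv")
        expr.read_probeset_meta(bundle / "probeset_meta.tsv")
        mot.read_promoters(bundle / "promoters.fasta")

    def test_truth_manifest_round_trips(self, tmp_path):
        config = _small_config()
        bundle = sim.emit_fixture_bundle(config, tmp_path / "b")
        truth = sim.load_truth(bundle)
        assert truth["config"]["seed"] == config.seed
        classes = {i["class"] for i in truth["families"].values()}
        assert classes == set(sim.FAMILY_CLASSES)

    def test_missing_file_fails_with_its_name(self, tmp_path):
        bundle = sim.emit_fixture_bundle(_small_config(), tmp_path / "b")
        (bundle / "expression.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="expression.tsv"):
            sim.load_truth(bundle)

    def test_cluster_class_map_agrees_with_pipeline_ids(self, tmp_path):
        config = _small_config()
        bundle = sim.emit_fixture_bundle(config, tmp_path / "b")
        truth = sim.load_truth(bundle)
        class_map = sim.cluster_class_map(truth)
        groups = SpeciesGroups.from_yaml(bundle / "groups.yaml")
        clusters = ortho.parse_cluster_trees(bundle / "clusters.nwk", groups)
        task3 = ortho.task_filter(clusters, groups, config.min_positive_present)
        for cl in task3:
            fam = cl.members[0][1].split(".")[0]
            assert class_map[cl.cluster_id] == truth["families"][fam]["class"]
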