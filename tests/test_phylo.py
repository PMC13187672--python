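import numpy as np
import pytest

from darkinhib.modality import PAPER_DEFAULT
from darkinhib.phylo import (
    LEVEL_COLORS,
    TreeError,
    coverage_summary,
    export_itol_annotation,
    genus_annotations,
    parse_itol_annotation,
    read_tree,
)
from darkinhib.types import Level


@pytest.fixture()
def newick(tmp_path):
    def _write(text, name="tree.nwk"):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return _write


class TestReadTree:
    def test_three_tip_topology(self, newick):
        tree = read_tree(newick("(A,(B,C));"))
        assert len(tree.leaf_nodes()) == 3
        internal = [n for n in tree if not n.is_leaf()]
        assert len(internal) == 2

    def test_underscore_tips_normalised(self, newick):
        tree = read_tree(newick("(Phaseolus_vulgaris,Pisum_sativum);"))
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert "Phaseolus vulgaris" in labels

    def test_duplicate_tips_rejected(self, newick):
        with pytest.raises(TreeError, match="duplicate"):
            read_tree(newick("(Pisum_sativum,Pisum_sativum);"))

    def test_malformed_newick_raises(self, newick):
        with pytest.raises(TreeError):
            read_tree(newick("(A,(B,C);"))


class TestGenusAnnotations:
    def test_genus_mean_and_level(self, fixture_dataset):
        anns = {a.genus: a for a in genus_annotations(fixture_dataset.summaries)}
        # Pisum has printed means 0.0, 0.0, 2.0 -> mean 2/3 -> low
        assert anns["Pisum"].n_species_with_data == 3
        assert anns["Pisum"].mean_di_percent == pytest.approx(2.0 / 3.0)
        assert anns["Pisum"].level is Level.LOW
        # single-species genus equals the species mean exactly
        assert anns["Nuphar"].mean_di_percent == 84.0
        assert anns["Nuphar"].level is Level.VERY_HIGH

    def test_two_species_genus_average(self, fixture_dataset):
        from darkinhib.types import SpeciesSummary, Taxonomy

        summaries = [
            SpeciesSummary(Taxonomy("Fab", "Xgenus alpha"), mean_di_percent=80.0),
            SpeciesSummary(Taxonomy("Fab", "Xgenus beta"), mean_di_percent=92.0),
        ]
        (ann,) = genus_annotations(summaries)
        assert ann.mean_di_percent == 86.0
        assert ann.level is Level.VERY_HIGH

    def test_absent_genus_not_annotated(self, fixture_dataset):
        genera = {a.genus for a in genus_annotations(fixture_dataset.summaries)}
        assert "Quercus" not in genera

    def test_palette_is_bijective(self):
        assert len(set(LEVEL_COLORS.values())) == len(Level)


class TestCoverage:
    def test_fixture_coverage(self, fixture_dataset):
        cov = coverage_summary(fixture_dataset.summaries)
        assert cov.n_orders_covered == 14
        assert cov.reference_order_count == 64
        assert cov.n_species == 157
        assert cov.order_fraction == pytest.approx(14 / 64)

    def test_empty_summaries(self):
        cov = coverage_summary([])
        assert cov.n_orders_covered == 0 and cov.n_species == 0


class TestItolExport:
    def test_export_and_roundtrip(self, fixture_dataset, newick, tmp_path):
        tree = read_tree(
            newick("((Phaseolus_vulgaris,Pisum_sativum),Oryza_sativa);")
        )
        anns = [
            a for a in genus_annotations(fixture_dataset.summaries)
            if a.genus in ("Phaseolus", "Pisum", "Oryza", "Quercusfake")
        ]
        out = tmp_path / "itol.txt"
        export = export_itol_annotation(tree, anns, out)
        assert export.n_records == 3
        records = parse_itol_annotation(out)
        got = {(r[0].split()[0], r[1]) for r in records}
        expected = {(a.genus, a.color) for a in anns if a.genus != "Quercusfake"}
        assert got == expected

    def test_unmatched_genus_in_sidecar(self, fixture_dataset, newick, tmp_path):
        tree = read_tree(newick("(Pisum_sativum,Oryza_sativa);"))
        anns = [
            a for a in genus_annotations(fixture_dataset.summaries)
            if a.genus in ("Pisum", "Phaseolus")
        ]
        out = tmp_path / "itol.txt"
        export = export_itol_annotation(tree, anns, out)
        assert export.unmatched == ["Phaseolus"]
        sidecar = out.with_suffix(out.suffix + ".unmatched.txt")
        assert "Phaseolus" in sidecar.read_text()

    def test_zero_matches_is_error(self, fixture_dataset, newick, tmp_path):
        tree = read_tree(newick("(Quercus_robur,Fagus_sylvatica);"))
        anns = genus_annotations(fixture_dataset.summaries)[:5]
        with pytest.raises(TreeError, match="normaliz"):
            export_itol_annotation(tree, anns, tmp_path / "itol.txt")

    def test_pruning_preserves_annotation_values(self, fixture_dataset, newick):
        # annotations are computed from summaries alone; pruning the tree
        # cannot change them
        full = read_tree(newick("((Phaseolus_vulgaris,Pisum_sativum),Oryza_sativa);"))
        anns_before = {
            a.genus: a.mean_di_percent
            for a in genus_annotations(fixture_dataset.summaries)
        }
        anns_after = {
            a.genus: a.mean_di_percent
            for a in genus_annotations(fixture_dataset.summaries)
        }
        assert anns_before == anns_after
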