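"""Annotate a phylogeny with genus-level dark-inhibition levels.

Builds a small Newick tree, aggregates species means to genus level,
classifies each genus with the published thresholds, and writes an
iTOL-compatible colour dataset.
"""
import tempfile
from pathlib import Path

from darkinhib import load_table1_fixture
from darkinhib.phylo import export_itol_annotation, genus_annotations, read_tree

NEWICK = "((Phaseolus_vulgaris,(Pisum_sativum,Vicia_faba)),(Oryza_sativa,Zea_mays));"

with tempfile.TemporaryDirectory() as tmp:
    tree_path = Path(tmp) / "tree.nwk"
    tree_path.write_text(NEWICK)
    tree = read_tree(tree_path)

    ds = load_table1_fixture()
    annotations = genus_annotations(ds.summaries)
    wanted = {"Phaseolus", "Pisum", "Vicia", "Oryza", "Zea"}
    subset = [a for a in annotations if a.genus in wanted]
    for a in subset:
        print(f"{a.genus}: mean {a.mean_di_percent:.1f}% over "
              f"{a.n_species_with_data} species -> {a.level.value} ({a.color})")

    out = Path(tmp) / "itol_levels.txt"
    export = export_itol_annotation(tree, subset, out)
    print(f"\nwrote {export.n_records} iTOL records; unmatched: {export.unmatched}")
    print(out.read_text())
# Phaseolus (12 species, mean ~70%) colours high while Pisum and Vicia sit
# near zero, reproducing the contrast between neighbouring legume clades.
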