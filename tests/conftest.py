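import dendropy
import pytest

from barcodeval.seqio import Alignment, SequenceRecord, TaxonEntry, TaxonMap
from barcodeval.synth import make_dataset, well_separated_profiles


def make_taxa(design: dict[str, int], outgroups: int = 0) -> TaxonMap:
    """TaxonMap with ``n`` individuals per species, ids '<sp>_<i>'."""
    entries = []
    for sp, n in design.items():
        for i in range(1, n + 1):
            entries.append(TaxonEntry(f"{sp}_{i}", sp, f"{sp}_{i}", False))
    for k in range(outgroups):
        lab = f"og{k + 1}"
        entries.append(TaxonEntry(f"{lab}_1", lab, f"{lab}_1", True))
    return TaxonMap(entries)


def aln_from(rows: dict[str, str]) -> Alignment:
    return Alignment([SequenceRecord(k, v) for k, v in rows.items()])


def parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


@pytest.fixture(scope="session")
def small_separated_dataset():
    """8 species (2 singletons) + 2 outgroups, 2 regions, wide barcoding gap."""
    return make_dataset(
        n_species=8,
        n_per_species=3,
        profiles=well_separated_profiles(2),
        singleton_species=2,
        outgroups=2,
        seed=42,
        enforce_separation=True,
    )
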