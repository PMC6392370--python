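"""Synthetic multi-locus barcode datasets with known truth.

The generator emulates the statistical structure of a real barcode study in
a taxonomically dense genus: a pure-birth species tree, star-like
within-species subtrees, K80 sequence evolution with a chosen
transition/transversion ratio, branch-proportional deletion events, and
optional conserved anchor motifs flanking an internal spacer so sub-region
extraction can be tested against embedded truth.

Calibration convention: after simulation the species tree is rescaled so
that the expected tip-to-tip path between individuals of *different*
species equals the profile's interspecific depth, while within-species tip
depths are exponential with mean ``intraspecific_depth / 2`` (a conspecific
pair then has expected path length ``intraspecific_depth``). Distances the
pipeline estimates from the simulated sequences therefore center on the
profile's intra/inter targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from barcodeval.seqio import (
    Alignment,
    SequenceRecord,
    TaxonEntry,
    TaxonMap,
    write_fasta,
    write_newick,
    write_taxon_map,
    tree_to_newick,
)
from barcodeval.trees import _k80_pmatrix

_BASES = "ACGT"


@dataclass(frozen=True)
class RegionSimProfile:
    """Simulation parameters of one barcode region.

    Depths are expected substitutions/site; ``indel_rate`` is the expected
    number of deletion events accumulated along one root-to-tip path;
    ``core_length_range`` is used only when anchor motifs are set and gives
    the length (bp) of the protected internal spacer between them.
    """

    name: str
    length_mean: float
    length_sd: float
    interspecific_depth: float
    intraspecific_depth: float
    kappa: float = 2.0
    indel_rate: float = 0.0
    indel_length_range: tuple[int, int] = (1, 10)
    motif_5p: str | None = None
    motif_3p: str | None = None
    core_length_range: tuple[int, int] = (222, 246)

    def __post_init__(self):
        if self.length_mean <= 0 or self.length_sd < 0:
            raise ValueError("invalid length parameters")
        if min(self.interspecific_depth, self.intraspecific_depth,
               self.kappa, self.indel_rate) < 0:
            raise ValueError("rates and depths must be >= 0")
        if self.kappa == 0:
            raise ValueError("kappa must be positive")


# Default anchor motifs shared with the extraction defaults.
from barcodeval.seqio import DEFAULT_MOTIF_5P, DEFAULT_MOTIF_3P  # noqa: E402


def default_profiles() -> list[RegionSimProfile]:
    """Profiles emulating the three evaluated regions.

    Length and distance targets follow the published per-region summaries:
    ITS-like (L≈550, intra 0.0103, inter 0.0705, many short indels, anchor
    motifs embedded around a 222–246 bp spacer), matK-like (L≈850, intra
    0.0016, inter 0.0474, few indels), ITS2-like (L≈235, intra 0.0159,
    inter 0.1026).
    """
    return [
        RegionSimProfile(
            name="ITS", length_mean=550, length_sd=12,
            interspecific_depth=0.0705, intraspecific_depth=0.0103,
            indel_rate=0.15, indel_length_range=(1, 22),
            motif_5p=DEFAULT_MOTIF_5P, motif_3p=DEFAULT_MOTIF_3P,
        ),
        RegionSimProfile(
            name="matK", length_mean=850, length_sd=4,
            interspecific_depth=0.0474, intraspecific_depth=0.0016,
            indel_rate=0.06, indel_length_range=(1, 12),
        ),
        RegionSimProfile(
            name="ITS2", length_mean=235, length_sd=6,
            interspecific_depth=0.1026, intraspecific_depth=0.0159,
            indel_rate=0.08, indel_length_range=(1, 10),
        ),
    ]


def well_separated_profiles(n_regions: int = 2) -> list[RegionSimProfile]:
    """Idealized profiles with a wide barcoding gap (for ground-truth runs)."""
    names = ["regA", "regB", "regC"][:n_regions]
    return [
        RegionSimProfile(
            name=nm, length_mean=600, length_sd=5,
            interspecific_depth=0.15, intraspecific_depth=0.004,
        )
        for nm in names
    ]


# ---------------------------------------------------------------------------
# tree simulation


def simulate_species_tree(n_species: int, birth_rate: float = 1.0,
                          seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric species tree with ``n_species`` tips.

    Forward simulation from two lineages; after the n-th lineage appears a
    final Exp(n*rate) hold time is added (the memoryless residual of
    observing exactly n extant tips), so the expected tree height is
    sum_{k=2..n} 1/(k*rate). Tips are labeled species01, species02, ...
    in simulation order.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    first, second = dendropy.Node(), dendropy.Node()
    root.add_child(first)
    root.add_child(second)
    # active lineages and the time their subtending branch started
    active = [(first, 0.0), (second, 0.0)]
    now = 0.0
    while len(active) < n_species:
        k = len(active)
        now += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.edge.length = now - born
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        active.extend([(a, now), (b, now)])
    now += rng.exponential(1.0 / (n_species * birth_rate))
    width = max(2, len(str(n_species)))
    for idx, (node, born) in enumerate(active):
        node.edge.length = now - born
        node.taxon = tns.require_taxon(label=f"species{idx + 1:0{width}d}")
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def _mean_pairwise_tip_distance(tree: dendropy.Tree) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    dists = [
        pdm.patristic_distance(taxa[i], taxa[j])
        for i in range(len(taxa))
        for j in range(i + 1, len(taxa))
    ]
    return float(np.mean(dists))


def scale_tree(tree: dendropy.Tree, factor: float) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor


def attach_individuals(
    t: dendropy.Tree,
    n_per_species: int | dict[str, int],
    intraspecific_depth: float,
    seed: int = 0,
) -> dendropy.Tree:
    """Replace each species tip by a star of individual tips.

    Individual tip depths below the species node are exponential with mean
    ``intraspecific_depth / 2``, so a conspecific pair has expected path
    length equal to ``intraspecific_depth``. Tips are named
    ``<species>_ind<m>``; species with one individual are renamed in place.
    """
    t = t.clone(depth=1)
    rng = np.random.default_rng(seed)
    tns = t.taxon_namespace
    for leaf in list(t.leaf_node_iter()):
        label = leaf.taxon.label
        n = n_per_species if isinstance(n_per_species, int) else n_per_species[label]
        if n < 1:
            raise ValueError(f"need >= 1 individual for {label!r}")
        if n == 1:
            leaf.taxon = tns.require_taxon(label=f"{label}_ind1")
            continue
        leaf.taxon = None
        for m in range(1, n + 1):
            child = dendropy.Node(
                taxon=tns.require_taxon(label=f"{label}_ind{m}")
            )
            leaf.add_child(child)
            child.edge.length = (
                rng.exponential(intraspecific_depth / 2.0)
                if intraspecific_depth > 0 else 0.0
            )
    t.purge_taxon_namespace()
    return t


# ---------------------------------------------------------------------------
# sequence evolution


@dataclass
class SimTruth:
    """Ground truth of one simulated region."""

    gene_tree_newick: str
    root_sequence: str
    #: tip label -> merged deleted intervals (half-open, root coordinates)
    tip_deletions: dict[str, list[tuple[int, int]]]
    #: protected spacer span in root coordinates, when motifs were embedded
    core_span: tuple[int, int] | None = None
    #: tip label -> true spacer sequence (substituted, never deleted)
    core_by_tip: dict[str, str] | None = None
    #: whether the profile's depths imply an unambiguous barcoding gap
    well_separated: bool = False


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def evolve_sequences(t: dendropy.Tree, profile: RegionSimProfile,
                     seed: int = 0) -> tuple[Alignment, SimTruth]:
    """Evolve sequences along ``t`` under K80; returns the true alignment.

    Deletion events occur per branch as a Poisson process scaled so one
    root-to-tip path expects ``profile.indel_rate`` events; event spans are
    recorded, so emitted rows carry '-' exactly where truth says. When
    anchor motifs are set, the layout is flank + motif5' + spacer + motif3'
    + flank; motif columns are invariant and the spacer is shielded from
    deletion (not from substitution), so extraction has an exact oracle.
    """
    rng = np.random.default_rng(seed)
    tips = list(t.leaf_node_iter())
    if len(tips) < 2:
        raise ValueError("need at least 2 tips")

    L = max(50, int(round(rng.normal(profile.length_mean, profile.length_sd))))
    protected = np.zeros(L, dtype=bool)
    core_span = None
    root_codes = rng.integers(0, 4, size=L).astype(np.int8)
    if profile.motif_5p and profile.motif_3p:
        lo, hi = profile.core_length_range
        core_len = int(rng.integers(lo, hi + 1))
        m5 = [_BASES.index(c) for c in profile.motif_5p]
        m3 = [_BASES.index(c) for c in profile.motif_3p]
        inner = len(m5) + core_len + len(m3)
        if inner + 20 > L:
            raise ValueError("profile length too short for motifs + spacer")
        flank5 = (L - inner) // 2
        root_codes[flank5:flank5 + len(m5)] = m5
        core_start = flank5 + len(m5)
        core_end = core_start + core_len
        root_codes[core_end:core_end + len(m3)] = m3
        protected[flank5:flank5 + len(m5)] = True
        protected[core_end:core_end + len(m3)] = True
        core_span = (core_start, core_end)

    depths = []
    for leaf in tips:
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    mean_depth = float(np.mean(depths))

    lo_len, hi_len = profile.indel_length_range
    no_delete = protected.copy()
    if core_span is not None:
        no_delete[core_span[0]:core_span[1]] = True

    # motif columns never substitute; inflate the rate on the remaining
    # columns so the whole-sequence expected divergence still matches the
    # branch lengths (and hence the profile's depth targets)
    rate_boost = L / max(1, L - int(protected.sum()))

    codes: dict[int, np.ndarray] = {id(t.seed_node): root_codes}
    deletions: dict[int, list[tuple[int, int]]] = {id(t.seed_node): []}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length or 0.0
        parent_codes = codes[id(node.parent_node)]
        child = parent_codes.copy()
        if bl > 0:
            P = _k80_pmatrix(bl * rate_boost, profile.kappa)
            for s in range(4):
                idx = np.flatnonzero((parent_codes == s) & ~protected)
                if idx.size:
                    child[idx] = rng.choice(4, size=idx.size, p=P[s])
        codes[id(node)] = child

        events = list(deletions[id(node.parent_node)])
        if profile.indel_rate > 0 and mean_depth > 0 and bl > 0:
            lam = profile.indel_rate * bl / mean_depth
            for _ in range(rng.poisson(lam)):
                length = int(rng.integers(lo_len, hi_len + 1))
                for _try in range(20):
                    start = int(rng.integers(0, max(1, L - length)))
                    if not no_delete[start:start + length].any():
                        events.append((start, start + length))
                        break
        deletions[id(node)] = events

    records: list[SequenceRecord] = []
    tip_dels: dict[str, list[tuple[int, int]]] = {}
    core_by_tip: dict[str, str] | None = {} if core_span else None
    for leaf in tips:
        label = leaf.taxon.label
        seq = np.array([_BASES[c] for c in codes[id(leaf)]])
        merged = _merge_intervals(deletions[id(leaf)])
        for s, e in merged:
            seq[s:e] = "-"
        tip_dels[label] = merged
        records.append(SequenceRecord(label, "".join(seq)))
        if core_span:
            core_by_tip[label] = "".join(seq[core_span[0]:core_span[1]])
    truth = SimTruth(
        gene_tree_newick=tree_to_newick(t),
        root_sequence="".join(_BASES[c] for c in root_codes),
        tip_deletions=tip_dels,
        core_span=core_span,
        core_by_tip=core_by_tip,
        well_separated=(
            profile.intraspecific_depth * 3 < profile.interspecific_depth
        ),
    )
    return Alignment(records), truth


# ---------------------------------------------------------------------------
# whole datasets


@dataclass
class SimDataset:
    """A complete simulated study: per-region alignments, taxa and truth."""

    regions: list[tuple[str, Alignment]]
    taxa: TaxonMap
    truths: dict[str, SimTruth]
    species_tree_newick: str

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, aln in self.regions:
            p = out_dir / f"{name}.fasta"
            write_fasta(aln, p)
            written.append(p)
        p = out_dir / "map.tsv"
        write_taxon_map(self.taxa, p)
        written.append(p)
        p = out_dir / "species_tree.nwk"
        p.write_text(self.species_tree_newick + "\n")
        written.append(p)
        p = out_dir / "truth.json"
        payload = {
            name: {
                "gene_tree": tr.gene_tree_newick,
                "root_sequence": tr.root_sequence,
                "tip_deletions": tr.tip_deletions,
                "core_span": tr.core_span,
                "well_separated": tr.well_separated,
            }
            for name, tr in self.truths.items()
        }
        p.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(p)
        return written


def make_dataset(
    n_species: int = 28,
    n_per_species: int = 4,
    profiles: list[RegionSimProfile] | None = None,
    singleton_species: int = 5,
    outgroups: int = 2,
    seed: int = 0,
    enforce_separation: bool = False,
) -> SimDataset:
    """Simulate a full multi-region study with the default study shape.

    The defaults mirror a taxonomically dense sampling design: 28 species
    of which 5 are sampled once, plus 2 distant outgroups, leaving 23
    species evaluable after the standard exclusion rule. The same species
    tree topology underlies every region; branch lengths are rescaled per
    region so mean between-species tip distance hits that region's
    interspecific depth. Identical (parameters, seed) yield byte-identical
    outputs.

    ``enforce_separation=True`` additionally floors every species' pendant
    branch at 30% of the region's target depth, so even the most recent
    speciation is separated by far more than the within-species variation —
    the construction for ideal, perfectly identifiable datasets. Leave it
    off when emulating realistic overlap between recent species.
    """
    if profiles is None:
        profiles = default_profiles()
    if singleton_species >= n_species:
        raise ValueError("singleton_species must be < n_species")
    ss = np.random.SeedSequence(seed)
    tree_seed, *region_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(1 + 2 * len(profiles))
    ]
    base = simulate_species_tree(n_species, birth_rate=1.0, seed=tree_seed)
    base_mean = _mean_pairwise_tip_distance(base)

    species = sorted(tax.label for tax in base.taxon_namespace)
    counts = {
        sp: (1 if i >= n_species - singleton_species else n_per_species)
        for i, sp in enumerate(species)
    }
    og_labels = [f"outgroup{chr(ord('A') + i)}" for i in range(outgroups)]

    regions: list[tuple[str, Alignment]] = []
    truths: dict[str, SimTruth] = {}
    for k, profile in enumerate(profiles):
        tr = base.clone(depth=1)
        target = max(
            profile.interspecific_depth - profile.intraspecific_depth,
            profile.interspecific_depth / 2.0,
        )
        scale_tree(tr, target / base_mean)
        if enforce_separation:
            floor = 0.3 * target
            for leaf in tr.leaf_node_iter():
                if (leaf.edge.length or 0.0) < floor:
                    leaf.edge.length = floor
        height = max(
            sum(e.length or 0.0 for e in leaf_edge_path(tr, leaf))
            for leaf in tr.leaf_node_iter()
        )
        if og_labels:
            old_root = tr.seed_node
            new_root = dendropy.Node()
            new_root.add_child(old_root)
            old_root.edge.length = height * 0.25
            # outgroups form their own distant clade so a single branch
            # separates them from the ingroup
            if len(og_labels) == 1:
                holder = new_root
                stem = height * 1.5
            else:
                holder = dendropy.Node()
                new_root.add_child(holder)
                holder.edge.length = height * 1.2
                stem = height * 0.3
            for lab in og_labels:
                og = dendropy.Node(taxon=tr.taxon_namespace.require_taxon(label=lab))
                holder.add_child(og)
                og.edge.length = stem
            tr.seed_node = new_root
        gene = attach_individuals(
            tr, {**counts, **{lab: 1 for lab in og_labels}},
            profile.intraspecific_depth, seed=region_seeds[2 * k],
        )
        aln, truth = evolve_sequences(gene, profile, seed=region_seeds[2 * k + 1])
        regions.append((profile.name, aln))
        truths[profile.name] = truth

    entries = []
    for rec in regions[0][1]:
        label = rec.id
        sp = label.rsplit("_ind", 1)[0]
        entries.append(
            TaxonEntry(
                sequence_id=label, species=sp, individual=label,
                is_outgroup=sp in set(og_labels),
            )
        )
    taxa = TaxonMap(entries)
    return SimDataset(
        regions=regions,
        taxa=taxa,
        truths=truths,
        species_tree_newick=tree_to_newick(base),
    )


def leaf_edge_path(tree: dendropy.Tree, leaf: dendropy.Node):
    """Edges from a leaf up to the root."""
    node = leaf
    while node.parent_node is not None:
        yield node.edge
        node = node.parent_node
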