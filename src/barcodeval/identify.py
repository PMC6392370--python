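"""Best-match identification and the species-resolution scoreboard.

The similarity criterion is leave-one-out nearest-neighbor identity on the
aligned matrix: each sequence is queried against all remaining sequences
and scored by uncorrected identity (matching unambiguous sites / compared
unambiguous sites, pairwise deletion). At the dataset sizes this analysis
targets, exhaustive comparison is exact, deterministic and cheaper than a
heuristic local-alignment search, and the identification criterion depends
only on the identity-ranked top hit.

A species is identified successfully by the best-match criterion when every
one of its individuals has a non-empty rank-1 tie set containing only
conspecific sequences; any heterospecific sequence tied at rank 1 fails the
species (the strict reading of "top hit of only a conspecific individual").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from barcodeval.distances import distance_matrix, gap_criterion, partition_distances
from barcodeval.seqio import Alignment, TaxonMap, TaxonEntry, concatenate_alignments
from barcodeval.seqstats import percent
from barcodeval.trees import (
    ml_search,
    mp_search,
    nj_tree,
    root_at_outgroup,
    species_monophyly,
)

METHOD_LABELS = {
    "blast": "BLAST",
    "k2p": "K2P-distance",
    "nj": "NJ tree",
    "ml": "ML tree",
    "mp": "MP tree",
}


@dataclass
class HitList:
    """Leave-one-out ranked hits for one query sequence."""

    query: str
    #: (subject id, identity fraction, 1 - identity), sorted by identity desc
    hits: list[tuple[str, float, float]] = field(default_factory=list)
    #: subject ids tied at the best identity
    top_ties: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.hits


def identity_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise uncorrected identity over unambiguous compared sites.

    Entry (i, j) is matches / compared where both rows carry A/C/G/T;
    NaN when two rows share no compared site. Diagonal is NaN (a sequence
    is never its own hit).
    """
    from barcodeval.distances import encode_alignment

    codes = encode_alignment(aln)
    n = len(aln)
    out = np.full((n, n), np.nan)
    valid = codes >= 0
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            m = int(mask.sum())
            if m == 0:
                continue
            matches = int((mask & (codes[i] == codes[j])).sum())
            out[i, j] = out[j, i] = matches / m
    return out


def best_match(query_id: str, aln: Alignment) -> HitList:
    """Leave-one-out best-match hit list for one query."""
    if query_id not in aln:
        raise KeyError(f"query {query_id!r} not in alignment")
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    ids = aln.ids
    qi = ids.index(query_id)
    scores = identity_matrix(aln)[qi]
    ranked = sorted(
        (
            (ids[j], float(scores[j]), 1.0 - float(scores[j]))
            for j in range(len(ids))
            if j != qi and not np.isnan(scores[j])
        ),
        key=lambda h: (-h[1], h[0]),
    )
    hl = HitList(query=query_id, hits=ranked)
    if ranked:
        top = ranked[0][1]
        hl.top_ties = [sid for sid, sc, _ in ranked if sc == top]
    return hl


def evaluable_species(taxa: TaxonMap) -> list[str]:
    """Non-outgroup species with >= 2 sampled individuals, sorted."""
    members = taxa.species_members(include_outgroups=False)
    out = sorted(sp for sp, ids in members.items() if len(ids) >= 2)
    if not out:
        raise ValueError("no evaluable species (every species is a singleton)")
    return out


def blast_criterion(aln: Alignment, taxa: TaxonMap) -> pd.DataFrame:
    """Per-species best-match outcome (queries and references are ingroup)."""
    keep = [sid for sid in aln.ids if sid in taxa and not taxa.is_outgroup(sid)]
    sub = aln.subset(keep)
    ids = sub.ids
    scores = identity_matrix(sub)
    species = {sid: taxa.species_of(sid) for sid in ids}
    members: dict[str, list[str]] = {}
    for sid in ids:
        members.setdefault(species[sid], []).append(sid)

    rows = []
    for sp in sorted(members):
        sp_ids = members[sp]
        evaluable = len(sp_ids) >= 2
        passes = evaluable
        if evaluable:
            for sid in sp_ids:
                qi = ids.index(sid)
                row = scores[qi]
                finite = ~np.isnan(row)
                if not finite.any():
                    passes = False
                    break
                top = np.nanmax(row)
                ties = [ids[j] for j in np.flatnonzero(finite & (row == top))]
                if any(species[t] != sp for t in ties):
                    passes = False
                    break
        rows.append(
            {
                "species": sp,
                "n_individuals": len(sp_ids),
                "evaluable": evaluable,
                "passes": bool(passes),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class IdentificationOutcome:
    """Per-species outcome of one method on one barcode."""

    method: str  # key in METHOD_LABELS
    barcode: str
    per_species: pd.DataFrame  # columns: species, evaluable, passes

    @property
    def evaluable_set(self) -> frozenset[str]:
        df = self.per_species
        return frozenset(df.loc[df["evaluable"], "species"])

    @property
    def n_pass(self) -> int:
        df = self.per_species
        return int((df["evaluable"] & df["passes"]).sum())

    @property
    def resolution_pct(self) -> float:
        return percent(self.n_pass, len(self.evaluable_set))


def resolution_table(outcomes: list[IdentificationOutcome]) -> pd.DataFrame:
    """Method x barcode matrix of species-resolution percentages.

    All outcomes must share one evaluable-species set, so every cell uses
    the same denominator.
    """
    if not outcomes:
        raise ValueError("no outcomes supplied")
    sets = {o.evaluable_set for o in outcomes}
    if len(sets) != 1:
        raise ValueError(
            "outcomes disagree on the evaluable species set; cells would "
            "not be comparable"
        )
    methods = list(dict.fromkeys(o.method for o in outcomes))
    barcodes = list(dict.fromkeys(o.barcode for o in outcomes))
    table = pd.DataFrame(index=[METHOD_LABELS[m] for m in methods],
                         columns=barcodes, dtype=float)
    for o in outcomes:
        table.loc[METHOD_LABELS[o.method], o.barcode] = o.resolution_pct
    return table


@dataclass
class RunMatrixResult:
    table: pd.DataFrame
    outcomes: list[IdentificationOutcome]
    trees: dict[tuple[str, str], object]  # (method, barcode) -> dendropy.Tree


def _taxa_by_individual(taxa: TaxonMap) -> TaxonMap:
    """Taxon map re-keyed by individual id (for concatenated alignments)."""
    seen: dict[str, TaxonEntry] = {}
    for e in taxa.entries:
        prev = seen.get(e.individual)
        if prev is not None and (prev.species, prev.is_outgroup) != (
            e.species, e.is_outgroup
        ):
            raise ValueError(
                f"individual {e.individual!r} mapped to conflicting species"
            )
        seen[e.individual] = TaxonEntry(
            sequence_id=e.individual,
            species=e.species,
            individual=e.individual,
            is_outgroup=e.is_outgroup,
        )
    return TaxonMap(list(seen.values()))


def _cell_seed(seed: int, index: int) -> int:
    return (seed * 100003 + 7919 * index + 1) % (2**31)


def _tree_criterion(method: str, aln: Alignment, taxa: TaxonMap,
                    seed: int) -> tuple[pd.DataFrame, object]:
    if method == "nj":
        tree = nj_tree(distance_matrix(aln))
    elif method == "mp":
        tree, _ = mp_search(aln, restarts=1, seed=seed)
    elif method == "ml":
        tree, _, _ = ml_search(aln, seed=seed)
    else:  # pragma: no cover
        raise ValueError(method)
    if any(taxa.is_outgroup(sid) for sid in aln.ids if sid in taxa):
        tree = root_at_outgroup(tree, taxa)
    result = species_monophyly(tree, taxa)
    return result[["species", "evaluable", "passes"]], tree


def run_matrix(
    regions: list[tuple[str, Alignment]],
    taxa: TaxonMap,
    methods: list[str] = ("blast", "k2p", "nj", "ml", "mp"),
    combinations: list[list[str]] = (),
    seed: int = 0,
) -> RunMatrixResult:
    """Run every identification method on every barcode and combination.

    Combinations are concatenated on individuals (complete-case policy);
    stochastic searches receive a seed derived from (``seed``, cell index)
    so each cell is independently reproducible.
    """
    for m in methods:
        if m not in METHOD_LABELS:
            raise ValueError(f"unknown method {m!r}")
    region_map = dict(regions)
    if len(region_map) != len(regions):
        raise ValueError("duplicate region names")

    barcodes: list[tuple[str, Alignment, TaxonMap]] = []
    for name, aln in regions:
        barcodes.append((name, aln, taxa.restricted_to(aln.ids)))
    sample_key = {e.sequence_id: e.individual for e in taxa.entries}
    ind_taxa = _taxa_by_individual(taxa)
    for combo in combinations:
        missing = [r for r in combo if r not in region_map]
        if missing:
            raise ValueError(f"combination references unknown region(s) {missing}")
        name = " + ".join(combo)
        concat = concatenate_alignments(
            [(r, region_map[r]) for r in combo], sample_key
        )
        barcodes.append((name, concat, ind_taxa.restricted_to(concat.ids)))

    outcomes: list[IdentificationOutcome] = []
    trees: dict[tuple[str, str], object] = {}
    cell = 0
    for bc_name, aln, bc_taxa in barcodes:
        for method in methods:
            cell += 1
            try:
                if method == "blast":
                    df = blast_criterion(aln, bc_taxa)
                elif method == "k2p":
                    gap = partition_distances(distance_matrix(aln), bc_taxa)
                    df = gap_criterion(gap)
                else:
                    df, tree = _tree_criterion(
                        method, aln, bc_taxa, _cell_seed(seed, cell)
                    )
                    trees[(method, bc_name)] = tree
            except Exception as exc:
                raise RuntimeError(
                    f"cell (method={method!r}, barcode={bc_name!r}) failed: {exc}"
                ) from exc
            outcomes.append(
                IdentificationOutcome(
                    method=method,
                    barcode=bc_name,
                    per_species=df[["species", "evaluable", "passes"]],
                )
            )
    return RunMatrixResult(
        table=resolution_table(outcomes), outcomes=outcomes, trees=trees
    )
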