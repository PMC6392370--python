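"""Intra- vs interspecific K2P distances and the barcoding gap.

For each simulated region, partitions all pairwise K2P distances into
within-species and between-species classes, prints the class means and
ranges, and evaluates the per-species distance-gap criterion: a species is
identifiable when its smallest between-species distance strictly exceeds
its largest within-species distance.
"""

from barcodeval.distances import distance_matrix, gap_criterion, partition_distances
from barcodeval.synth import make_dataset

ds = make_dataset(seed=17)
for name, aln in ds.regions:
    g = partition_distances(distance_matrix(aln), ds.taxa)
    df = gap_criterion(g)
    n_pass = int(df["passes"].sum())
    n_eval = int(df["evaluable"].sum())
    lo_i, hi_i = g.intra_range
    lo_x, hi_x = g.inter_range
    print(
        f"{name:5s} intra {g.intra_mean:.4f} ({lo_i:.4f}-{hi_i:.4f})  "
        f"inter {g.inter_mean:.4f} ({lo_x:.4f}-{hi_x:.4f})  "
        f"gap criterion: {n_pass}/{n_eval} species"
    )

print(
    "\nA mean inter >> mean intra signals a usable barcode; the per-species"
    "\ncount shows how often the gap holds strictly for individual species."
)
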