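"""The full method x barcode species-resolution scoreboard.

Runs all five identification methods (best-match, distance gap, NJ/ML/MP
monophyly) on two simulated regions and their concatenation, and prints
the resolution matrix: the percentage of evaluable species each cell
identifies successfully.
"""

from barcodeval.identify import run_matrix
from barcodeval.synth import make_dataset, well_separated_profiles

ds = make_dataset(
    n_species=8, n_per_species=3, profiles=well_separated_profiles(2),
    singleton_species=2, outgroups=2, seed=17, enforce_separation=True,
)
res = run_matrix(
    ds.regions, ds.taxa,
    combinations=[[name for name, _ in ds.regions]], seed=17,
)
print(res.table.to_string(float_format=lambda v: f"{v:.1f}"))
print(
    "\nRows are methods, columns single regions plus their concatenation;"
    "\neach cell is 100 * identified / evaluable species. On this ideally"
    "\nseparated dataset every method resolves every species."
)
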