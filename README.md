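# barcodeval

Evaluation of candidate DNA barcode regions for species identification in
taxonomically difficult plant groups.

When a genus is species-rich and recently diverged, short standardized DNA
regions ("barcodes", e.g. the nuclear ITS/ITS2 spacers or the plastid
*matK* gene) may or may not carry enough signal to tell its species apart —
which matters for biodiversity surveys and for authenticating medicinal
plant material whose morphology is gone. `barcodeval` implements the
complete comparative analysis used to answer that question: it scores each
candidate region and each multi-region concatenation with three families
of identification criteria and reports a method × barcode resolution
scoreboard, plus all the supporting summaries (sequence characteristics,
distance distributions, trees). A calibrated simulator with known truth
makes every stage testable without touching sequence databases.

## The statistics

**K2P distance.** Pairwise distances use the Kimura 2-parameter model: with
transition proportion *P* (A↔G, C↔T) and transversion proportion *Q* over
compared sites (pairwise deletion of gaps/ambiguity),

    d = -(1/2) · ln((1 - 2P - Q) · √(1 - 2Q))

**Identification criteria**, all evaluated per species over the evaluable
set (non-outgroup species with ≥ 2 individuals):

* *distance gap* — the species' minimum interspecific K2P distance strictly
  exceeds its maximum intraspecific distance;
* *tree-based* (NJ, MP, ML trees; conspecific monophyly) — all individuals
  of the species form exactly one clade on the outgroup-rooted tree;
* *best match* (BLAST-style) — every individual's leave-one-out top
  identity hit set contains only conspecific sequences.

Resolution = 100 · (species passing) / (species evaluable), rounded
half-away-from-zero to one decimal.

**Trees.** NJ is the exact Saitou–Nei agglomeration (deterministic
tie-breaking, exact on additive matrices). MP and ML trees are found by
seeded nearest-neighbor-interchange hill-climbing from the NJ start; MP
scores with Fitch parsimony, ML with Felsenstein pruning under the
equal-frequency K80 model with an optimized transition/transversion ratio
κ.

## Worked example

```python
from barcodeval.identify import run_matrix
from barcodeval.synth import make_dataset, well_separated_profiles

ds = make_dataset(
    n_species=8, n_per_species=3, profiles=well_separated_profiles(2),
    singleton_species=2, outgroups=2, seed=17, enforce_separation=True,
)
res = run_matrix(ds.regions, ds.taxa,
                 combinations=[[n for n, _ in ds.regions]], seed=17)
print(res.table.to_string(float_format=lambda v: f"{v:.1f}"))
```

prints

```
              regA  regB  regA + regB
BLAST        100.0 100.0        100.0
K2P-distance 100.0 100.0        100.0
NJ tree      100.0 100.0        100.0
ML tree      100.0 100.0        100.0
MP tree      100.0 100.0        100.0
```

Rows are identification methods, columns the two simulated regions and
their concatenation; each cell is the percentage of evaluable species that
method identifies. On an ideally separated dataset every cell is 100.0;
with the realistic default profiles (`make_dataset(seed=17)`) the same
machinery produces partial resolution and a barcoding-gap summary such as

```
ITS   intra 0.0111 (0.0000-0.0528)  inter 0.0715 (0.0018-0.1338)
matK  intra 0.0015 (0.0000-0.0071)  inter 0.0524 (0.0000-0.0850)
ITS2  intra 0.0132 (0.0000-0.0719)  inter 0.0831 (0.0043-0.1961)
```

i.e. mean (range) of within- vs between-species K2P distances per region.
The `examples/` directory holds one short script per capability; the
`barcodeval` command exposes the same pipeline from a shell
(`barcodeval simulate | stats | gap | tree | run`).

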