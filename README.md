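# delforge

A desk-scale toolkit for the in-silico side of DNA-encoded library (DEL)
campaigns built on multifunctional skeletons: building-block selection,
combinatorial library enumeration from reaction SMARTS, DNA-barcode
encoding and decoding, negative-binomial input-count QC, enrichment
scoring of affinity selections, and fingerprint-based chemical-space
maps.

## Who it is for

DELs encode each member of a combinatorial compound collection with a
DNA barcode that records its synthetic history. A three-cycle campaign of
the kind this toolkit models starts from halogenated skeletons bearing a
protected secondary amine and a DNA-attachment handle (cycle 1), caps the
amine with a carboxylic acid, aldehyde, or sulfonyl chloride (cycle 2),
and diversifies the aryl halide by Suzuki coupling with a boronic
acid/ester — or an encoded null reaction (cycle 3). After an affinity
selection, sequencing the barcodes and comparing selection to input
frequencies ranks putative binders. `delforge` implements every
computational step of that pipeline so that library designers and
screeners can enumerate, QC, and score such campaigns, and test the whole
chain on simulated data with known ground truth.

## The statistics at the core

**Input counts.** Per-barcode input sequencing counts of each sub-library
(aryl-iodide- vs aryl-bromide-derived) are modelled as negative binomial
with mean m and size r (variance = m + m²/r). The ratio of the fitted
means estimates the sub-library pooling imbalance, which
`correct_pooling` converts into adjusted mixing weights.

**Enrichment.** For a barcode with selection count k_sel (sample total
N_sel) and input count k_in (total N_in), the point enrichment is the
frequency ratio (k_sel/N_sel)/(k_in/N_in). Ranking uses the lower bound
(lb) of its exact two-sided 95% confidence interval: conditional on
k_sel + k_in, k_sel is binomial with success probability
p = ρN_sel/(ρN_sel + N_in), so a Clopper–Pearson bound on p
back-transforms to a bound on the rate ratio ρ. Signal is aggregated over
cycle 1 by pooling counts per (cy2, cy3) disynthon, and per-building-block
scores sum the lb values of all disynthons containing that block.

**Chemical space.** Structures are compared as Morgan radius-2
fingerprints under Tanimoto distance and projected to 2-D by a native
Sammon mapping (stress E = Σ(δ−d)²/δ / Σδ, minimized by the pseudo-Newton
Sammon iteration with step halving and seeded multi-start), or by a thin
UMAP adapter for large collections.

## Worked example

Simulate a small campaign with five planted 50× binders, decode the
reads, and score the screen:

```python
from delforge.barcode_codec import count_reads, counts_to_table
from delforge.count_model import estimate_pooling_ratio
from delforge.enrichment import score_barcodes
from delforge.synthetic_data import (
    design_barcodes, make_truth, simulate_input_run, simulate_selection_run,
)

truth = make_truth(n_skel=2, n_caps=3, n_boronates=4, seed=1)
reads_in, _ = simulate_input_run(truth, 40_000, seed=2)
reads_sel, _ = simulate_selection_run(truth, 40_000, seed=3)

c_in, stats = count_reads(reads_in, truth.layout, truth.tags, max_mismatch=1)
c_sel, _ = count_reads(reads_sel, truth.layout, truth.tags, max_mismatch=1)
table = counts_to_table({"input": c_in, "selection": c_sel},
                        design_barcodes(truth.design))

ratio, _ = estimate_pooling_ratio(table, truth.sublibrary_of().to_numpy())
print(f"pooling ratio (I/Br): {ratio:.3f}")
scored = score_barcodes(table, "selection").sort_values("lb", ascending=False)
print(scored[["k_sel", "k_in", "ratio", "lb"]].head(5).round(2))
```

Output:

```
pooling ratio (I/Br): 1.261
                                         k_sel  k_in  ratio    lb
cy1   cy2   cy3
SK000 BB001 with_conditions_no_boronate   8117  1828   4.44  4.22
SK001 BB001 BO002                         3676   818   4.49  4.16
SK000 BB000 BO003                        10170  2336   4.35  4.16
      BB001 BO002                         6150  1422   4.32  4.08
      BB002 BO002                         9186  2155   4.26  4.07
```

The decode stage recovered 39,927 of 40,000 reads (73 rejected for tag
mismatches at the 0.5% simulated error rate). The pooling-ratio estimate
of 1.261 reflects the simulated 1.31-fold aryl-iodide excess at this
small design size (72 barcodes; at 50,000 barcodes per side the estimate
converges to ±0.05). The five top-ranked barcodes by lb are exactly the
five planted binders; note that the top hit's enrichment (4.44) is far
below its planted 50× multiplier because binders compete for a fixed read
budget — the ranking, not the absolute ratio, carries the signal.

A command-line interface mirrors the library
(`delforge simulate | select-bb | enumerate | decode | input-qc | enrich | map`);
run `delforge --help`.

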