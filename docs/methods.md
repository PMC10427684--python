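# Methods

This note documents the models, procedures, numerical choices and known
limitations behind `delforge`, module by module.

## Molecule and reaction primitives (`chem_core`)

All structure handling goes through RDKit. Canonical SMILES is the
identity key throughout: deduplication, reaction-product comparison and
duplicate-group assignment all compare canonical strings produced by the
same RDKit build. Canonicalization engines differ across toolkits and
versions, so comparisons against externally enumerated libraries should
be done at molecule level (parse both sides, compare canonical forms from
one engine) rather than by raw string equality.

Desalting keeps the fragment with the most heavy atoms; ties break by
lexicographic order of the fragments' canonical SMILES so the result is
deterministic. Reaction transforms are stored as reaction SMARTS in
`data/reactions.tsv` and cleaned at load (typesetting whitespace, unicode
arrows and minus signs are normalized). Products that fail valence
sanitization are dropped with a logged warning instead of aborting — in a
combinatorial run a rare bad pairing should cost one record, not the run.

### Skeleton normalization

Skeletons are modelled post-deprotection, as the pharmacophore a screener
would attribute to a hit. The DNA attachment site is marked with a single
tritium atom and the linker truncated by one of four rules, dispatched on
the recorded attachment chemistry:

1. **Alkyl-linker amide** — the di-acid linker between the skeleton
   nitrogen and DNA is truncated to a tritium-marked methyl amide. The
   implementation walks the sp3 chain from the free carboxylic acid to
   the linker's amide carbonyl and keeps only the methylene adjacent to
   it.
2. **Hydroxyl carbamate** — the carbamate-linked primary alcohol becomes
   a tritium-marked methyl ether.
3. **Acid amide** — the skeleton's own carboxylic acid becomes a
   tritium-marked N-methyl amide.
4. **Ester hydrolysis** — acyclic carboxylic esters known to hydrolyze
   cleanly during synthesis are hydrolyzed to the acid before the
   attachment rule runs (lactones are left alone).

These are implemented as explicit graph edits (RWMol surgery), not
reaction SMARTS, because rule 1 requires a variable-length chain walk
that a single SMARTS cannot express. Stereocenters are never touched by
the edits, so stereochemistry is preserved exactly; no stereo enumeration
is performed anywhere (designs are assumed stereopure).

## Building-block selection (`bb_selection`)

The funnel is: desalt/deduplicate → target functional-group SMARTS →
hierarchical exclusion filters → dummy enumeration → descriptor cutoffs →
MaxMin diversity picking, with a second, property-tightened round seeded
to avoid the first round's picks. Choices worth noting:

- The exclusion-filter list (alkyl halide, carboxylic acid, thiol,
  thioether, hydrazine, 1,2-amino alcohol, aldehyde, secondary amine) is
  a documented default and fully config-driven; real campaigns tune it
  per reactivity class. Removal is order-independent by construction
  (an entry matching *any* pattern is dropped).
- Descriptor cutoffs are strict inequalities applied simultaneously
  (SLogP < 6.0 and exactMW < 600 Da in round 1; < 5.0 and < 450 Da in
  round 2, on the dummy-enumerated products). HBD counts donor hydrogens
  (Lipinski N-H/O-H count), HBA uses RDKit's acceptor definition.
- Diversity picking is MaxMin on Tanimoto distance over Morgan radius-2
  2048-bit fingerprints with an explicit integer seed (RDKit's
  `MaxMinPicker`); when an avoid set is supplied it seeds the picker so
  new picks maximize distance to it.
- The LCMS inclusion rule is >70 %AUC desired product and <10 %AUC
  unknown species, both strict. The two-phase "BB num" ranking sorts
  records with ≤10 %AUC unknowns by decreasing product, then records
  above 10, ties breaking by ascending unknowns then input order.
- Consensus preference tiers (4 highest) reconstruct a plausible
  cross-campaign rule: 4 = included in both ArI and ArBr validation
  campaigns, 3 = included in one and >70 %AUC product in the other,
  2 = included in exactly one, 1 = neither. An "adjusted %AUC" hook
  exists and defaults to identity.

## Library enumeration (`library_enumeration`)

Capping reactions dispatch on building-block class (acid → acylation,
aldehyde → reductive amination, sulfonyl chloride → sulfonylation). The
capping templates match any nitrogen, so products are filtered to those
where the mapped reacting atom is the curator-designated encoded amine —
a stand-in for ranking nitrogen nucleophilicity computationally, which
the toolkit does not attempt. Suzuki transforms are selected by the
skeleton's halide; the two encoded null conditions copy the intermediate
structure unchanged under their own cycle-3 codes.

Enumeration failures keep their barcode with a null structure, so
count-table joins never lose keys (physical libraries also encode failed
wells). Duplicate groups are assigned by canonical product SMILES;
duplicates arise from null couplings sharing an intermediate and from a
boronic acid and its pinacol ester giving the same coupled product.

`count_design` exposes two barcode-counting conventions because the
encoding of the two null conditions at the tag level is a library-design
choice: `distinct_null` gives each null its own cycle-3 tag
(s·c·(b+2) barcodes), `merged_null` collapses them (s·c·(b+1)). For the
61 × 295 × 206 production design these give a 3,706,970-compound
theoretical matrix (nulls excluded by convention) and 3,724,965 barcodes
under `merged_null`.

No side-product enumeration is attempted beyond the skeleton ester rule
(e.g. nitrile hydrolysis or protecting-group loss on building blocks);
the enumerated structure is the design intent.

## Barcode codec (`barcode_codec`)

Reads are modelled as fixed-offset regions: constant prefix, cy1 tag,
spacer, cy2 tag, spacer, cy3 tag, closing region. The bundled default
layout is synthetic (real amplicon coordinates are instrument- and
design-specific) and fully user-overridable. Decoding takes each tag
region to its nearest library tag by Hamming distance, accepting only a
unique nearest tag within `max_mismatch`; failures are classified
`no_match`, `ambiguous`, or `truncated` and are data, not errors —
decoded + failed always equals total reads.

Default `max_mismatch` is 0 (exact): error-tolerant matching rescues
reads but makes zero-count diagnostics less conservative, so it is
opt-in (1 is appropriate for tag sets with pairwise Hamming ≥ 3, which
correct floor((h−1)/2) = 1 substitution per region). Tag design is
greedy-random under a seed: candidates with GC content in 25–75% are
accepted if they keep pairwise distance ≥ the floor, with a bounded
number of attempts before a capacity error. Reads shorter than the
layout are `truncated`, never partially decoded. Quality scores are
parsed and ignored.

## Input-count model (`count_model`)

The negative binomial is parameterized as (mean m, size r) with variance
m + m²/r — stated everywhere to avoid the two-convention ambiguity. The
MLE profiles the mean out (the sample mean is the MLE for any fixed r)
and optimizes the likelihood over log r with a bounded scalar method,
initialized at the method-of-moments estimate. Samples whose variance
does not exceed their mean carry no overdispersion signal: they are
flagged `poisson_limit` with r pinned at 10⁶ rather than chasing an
unbounded optimum. Fits include zero-count barcodes by default (zeros
are real outcomes of finite depth); truncation is available.

The pooling ratio is the ratio of fitted means, I over Br — a property
of the fitted distributions rather than of medians or raw sums — and the
correction divides the I-side mixing weight by the measured excess
before renormalizing. Unobserved-barcode analysis joins counts to the
full design, attributes zeros to cycle tags and (cy2, cy3) pairs per
sub-library, and flags features whose zero rate exceeds 10× the global
zero rate (configurable) or that are complete dropouts — the signature
of a failed tag ligation in one pool.

## Enrichment (`enrichment`)

The lb construction is the conditional-binomial exact interval for a
ratio of Poisson rates: given T = k_sel + k_in, k_sel ~ Binomial(T, p)
with p = ρN_sel/(ρN_sel + N_in); the Clopper–Pearson lower limit on p at
two-sided level 0.95 back-transforms to ρ. This is conservative
(one-sided coverage ≈ 98% at nominal 97.5%), monotone in both counts,
and handles zeros without pseudocounts: k_sel = 0 gives lb = 0 exactly.
Jeffreys and normal-approximation alternatives sit behind one flag.
Totals N are per-sample decoded-read sums, not design sizes. Replicates
are summarized by the minimum lb across replicates (conservative),
with pooled-counts mode available. Beads-only comparison flags barcodes
whose target lb exceeds the control lb by a configurable factor
(default 3×); matrix binders enrich in both samples and are not flagged.

## Chemical space (`chemspace`)

Boronate normalization removes the boron and its oxygen substituents
(the pinacol carbons disconnect and are discarded) and places a methyl
on the attachment atom, so an acid and its pinacol ester collapse to one
structure before mapping.

Sammon mapping minimizes E = (Σδ)⁻¹ Σ (δ−d)²/δ over 2-D configurations
using the classic pseudo-Newton update (gradient scaled by the absolute
diagonal Hessian, damped by a 0.35 factor), with step halving whenever a
proposed update would raise the stress — the stress trace is therefore
non-increasing over accepted iterations. The stress surface is
multimodal, so the optimizer runs from classical metric scaling plus 29
seeded random configurations (30 starts total, `n_init`) and returns the
best; on 10-point benchmark instances this matches a 50-restart L-BFGS
reference within 5%. Zero input distances are floored at 1e-12 in
denominators. Cost per start is O(n² · iterations), so for collections
beyond a few thousand structures use the UMAP adapter, which delegates
to umap-learn with a recorded seed and is deliberately not a
reimplementation.

## Synthetic data (`synthetic_data`)

The generators emulate the *structure* of a real campaign, not any
particular dataset:

- Toy designs use four chemically valid skeleton scaffolds (aryl-halide
  cyclic amino acids and a spiro-azetidine, covering all three
  attachment chemistries), decorated for variety; halides alternate I/Br
  so sub-libraries are balanced. Capping classes follow a roughly
  48:36:16 acid:aldehyde:sulfonyl-chloride balance, mirroring a
  production-scale 142:107:46 split. Boronate pools deliberately include
  acid/pinacol pairs of the same aryl group so duplicate accounting is
  exercised.
- Input abundances are NB draws per barcode (defaults: mean 30 on the Br
  side, size 2, I side scaled by a 1.31-fold pooling excess); reads are
  multinomial over abundances, encoded through the codec, with
  substitution errors at 0.5% per base by default. Errors are
  length-preserving (no indels) because the decoder assumes a fixed
  layout; an indel-bearing read presents as tag mismatches.
- Selections multiply planted binder abundances (multipliers ≥ 1) and
  renormalize, so enrichment competes for a fixed read budget as in a
  real screen; beads-only samples use a separate matrix-binder set.

Everything is bit-reproducible under a fixed seed. What passing tests on
these simulations do **not** show: real reads have quality-dependent and
position-dependent error structure, PCR duplicates and chimeras, and
synthesis yields that vary per reaction pair — none of which are
modelled. Recovery results here are statements about the pipeline's
correctness, not about expected performance on any particular instrument
output.

## Problem sizes and runtime

Default verification scales are sized for a laptop-class run: NB
parameter-recovery grid and pooling-ratio recovery at 50,000 barcodes
per side (count level), interval coverage and fuzzed bound checks at
10,000 draws, codec round trip at 10,000 tuples, read-level end-to-end
runs at 40,000–150,000 reads over designs of 72–8,800 barcodes, and
Sammon benchmarks at 10 points against a 50-restart reference. The full
test suite runs in under a minute; `scripts/acceptance.py` in a few
seconds. Full-scale (millions of barcodes) enumeration is supported by
the same code path but is a batch job, not a test.

## Known limitations

- Nitrogen "nucleophilicity" is curator-designated, not computed; a pKa
  ranking hook would slot into `enumerate_capping` but is not provided.
- Exclusion-filter SMARTS and preference-tier definitions are documented
  reconstructions, intended to be overridden per campaign.
- The decoder does not handle indels or use base qualities.
- Cross-engine canonical-SMILES equality is not guaranteed; compare
  molecules, not strings, against externally produced libraries.
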