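"""Ground-truth generators for end-to-end testing without downloads.

These build chemically valid toy libraries in the same shape as a real
split-and-pool DEL campaign — halogenated cyclic amino-acid skeletons
with a designated secondary amine, classed capping building blocks and
boronates, per-cycle DNA tags — and simulate input and selection
sequencing runs with known truth: negative-binomially distributed
per-barcode abundances (the aryl-iodide pool in deliberate excess),
multinomial read sampling, substitution errors, and multiplicative
enrichment of a planted binder set.

Default simulation parameters mirror the structure of a real input QC
experiment: NB mean ~30 reads/barcode, size dispersion 2, an I/Br pooling
excess of 1.31, and a 0.5% per-base substitution error rate. Scales are
sized for desk runs (designs up to ~8,000 barcodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .barcode_codec import ReadLayout, TagLibrary, design_tags, encode_read
from .chem_core import SkeletonRecord, normalize_skeleton
from .library_enumeration import BuildingBlockRecord, LibraryDesign

_ALPHABET = "ACGT"

# skeleton scaffolds: {hal} is the aryl halide, {sub} a decorating substituent
_SKELETON_TEMPLATES = [
    # 4-aryl proline analog, DNA-attached through its carboxylic acid
    ("O=C(O)C1CC(c2ccc({hal})cc2{sub})CN1", "acid_amide"),
    # spiro-azetidine skeleton acylated onto DNA through a glutarate linker
    ("O=C(O)CCCC(=O)N1CC(c2ccc({hal})cc2{sub})C2(CNC2)C1", "alkyl_linker_amide"),
    # hydroxymethyl pyrrolidine, carbamate-linked to DNA
    ("OCC1CC(c2ccc({hal})cc2{sub})CN1", "hydroxyl_carbamate"),
    # 4-aryl pipecolic acid analog
    ("O=C(O)C1CCC(c2ccc({hal})cc2{sub})CN1", "acid_amide"),
]

_ARYL_SUBS = ["", "F", "C", "OC", "Cl", "CC"]

_ACID_CORES = ["OC(=O)c1ccc({s})cc1", "OC(=O)Cc1ccc({s})cc1", "OC(=O)CCc1ccc({s})cc1"]
_ALDEHYDE_CORES = ["O=Cc1ccc({s})cc1", "O=CCc1ccc({s})cc1"]
_SULFONYL_CORES = ["ClS(=O)(=O)c1ccc({s})cc1", "ClS(=O)(=O)Cc1ccc({s})cc1"]
_BORONATE_CORES = ["OB(O)c1ccc({s})cc1", "CC1(C)OB(c2ccc({s})cc2)OC1(C)C"]
_BB_SUBS = ["", "C", "F", "OC", "Cl", "CC", "C(C)C", "S(N)(=O)=O", "C#N", "C(F)(F)F"]

#: capping class mix, roughly the acid/aldehyde/sulfonyl-chloride balance
#: of a production library (142:107:46)
_CLASS_WEIGHTS = {"acid": 0.48, "aldehyde": 0.36, "sulfonyl_chloride": 0.16}


def _aryl_series(cores: list[str]) -> list[str]:
    out = []
    for sub in _BB_SUBS:
        for core in cores:
            if sub == "":
                out.append(core.replace("({s})", ""))
            else:
                out.append(core.format(s=sub))
    # preserve order, drop accidental duplicates
    seen: dict[str, None] = {}
    for s in out:
        seen.setdefault(s)
    return list(seen)


def generate_skeletons(n: int, seed: int = 0) -> list[SkeletonRecord]:
    """n chemically valid, normalized skeletons; halides split evenly Br/I."""
    records: list[SkeletonRecord] = []
    variants = [
        (tmpl, attach, sub)
        for sub in _ARYL_SUBS
        for (tmpl, attach) in _SKELETON_TEMPLATES
    ]
    if n > len(variants):
        raise ValueError(f"at most {len(variants)} distinct toy skeletons available")
    for i in range(n):
        tmpl, attach, sub = variants[i]
        halide = "I" if i % 2 == 0 else "Br"
        smiles = tmpl.format(hal=halide, sub=sub)
        rec = SkeletonRecord(
            id=f"SK{i:03d}", loaded_smiles=smiles, halide=halide, attachment=attach
        )
        normalize_skeleton(rec)
        records.append(rec)
    return records


def generate_capping_bbs(n: int, seed: int = 0) -> list[BuildingBlockRecord]:
    """n classed capping building blocks in the production class balance."""
    pools = {
        "acid": _aryl_series(_ACID_CORES),
        "aldehyde": _aryl_series(_ALDEHYDE_CORES),
        "sulfonyl_chloride": _aryl_series(_SULFONYL_CORES),
    }
    n_by_class = {
        cls: max(1, round(w * n)) for cls, w in _CLASS_WEIGHTS.items()
    }
    while sum(n_by_class.values()) > n:
        n_by_class[max(n_by_class, key=n_by_class.get)] -= 1
    while sum(n_by_class.values()) < n:
        n_by_class["acid"] += 1
    records: list[BuildingBlockRecord] = []
    for cls, k in n_by_class.items():
        pool = pools[cls]
        if k > len(pool):
            raise ValueError(f"at most {len(pool)} toy {cls} building blocks available")
        for j in range(k):
            records.append(
                BuildingBlockRecord(
                    id=f"BB{len(records):03d}", smiles=pool[j], bb_class=cls
                )
            )
    return records


def generate_boronates(n: int, seed: int = 0) -> list[BuildingBlockRecord]:
    pool = _aryl_series(_BORONATE_CORES)
    if n > len(pool):
        raise ValueError(f"at most {len(pool)} toy boronates available")
    return [
        BuildingBlockRecord(id=f"BO{i:03d}", smiles=pool[i], bb_class="boronate")
        for i in range(n)
    ]


def generate_toy_design(
    n_skel: int, n_caps: int, n_boronates: int, seed: int = 0
) -> LibraryDesign:
    """A deterministic, chemically valid three-cycle toy design."""
    return LibraryDesign(
        skeletons=generate_skeletons(n_skel, seed),
        capping_bbs=generate_capping_bbs(n_caps, seed),
        boronates=generate_boronates(n_boronates, seed),
    )


def design_barcodes(design: LibraryDesign) -> list[tuple[str, str, str]]:
    cy3 = [b.id for b in design.boronates] + list(design.null_conditions)
    return [
        (s.id, c.id, t)
        for s in design.skeletons
        for c in design.capping_bbs
        for t in cy3
    ]


def tags_for_design(
    design: LibraryDesign, length: int = 7, min_hamming: int = 3, seed: int = 0
) -> TagLibrary:
    """A tag library whose tag ids are the design's cycle identifiers."""
    ids = {
        "cy1": [s.id for s in design.skeletons],
        "cy2": [c.id for c in design.capping_bbs],
        "cy3": [b.id for b in design.boronates] + list(design.null_conditions),
    }
    cycles = {}
    for k, (cycle, idlist) in enumerate(sorted(ids.items())):
        seqs = design_tags(len(idlist), length, min_hamming, seed=seed + k)
        cycles[cycle] = dict(zip(idlist, seqs.values()))
    return TagLibrary(cycles=cycles, min_hamming=min_hamming)


@dataclass
class SimulationTruth:
    """Everything needed to simulate a campaign and check recovery."""

    design: LibraryDesign
    tags: TagLibrary
    layout: ReadLayout
    pooling_ratio: float = 1.31  # I/Br mean excess
    nb_mean_br: float = 30.0
    nb_dispersion: float = 2.0
    binder_multipliers: dict[tuple[str, str, str], float] = field(default_factory=dict)
    matrix_binder_multipliers: dict[tuple[str, str, str], float] = field(
        default_factory=dict
    )
    error_rate: float = 0.005
    seed: int = 0
    _abundances: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        barcodes = set(design_barcodes(self.design))
        for mult_set in (self.binder_multipliers, self.matrix_binder_multipliers):
            for bc, m in mult_set.items():
                if m < 1:
                    raise ValueError("planted binder multipliers must be >= 1")
                if bc not in barcodes:
                    raise ValueError(f"binder barcode {bc} not in design")

    def sublibrary_of(self) -> pd.Series:
        by_skel = {s.id: s.halide for s in self.design.skeletons}
        barcodes = design_barcodes(self.design)
        index = pd.MultiIndex.from_tuples(barcodes, names=["cy1", "cy2", "cy3"])
        return pd.Series([by_skel[b[0]] for b in barcodes], index=index)

    def abundances(self) -> pd.Series:
        """Per-barcode expected relative abundance (NB draw, I-pool scaled)."""
        if self._abundances is not None:
            return self._abundances
        rng = np.random.default_rng(self.seed)
        sub = self.sublibrary_of()
        r = self.nb_dispersion
        lam = np.empty(len(sub))
        for name, mean in (("Br", self.nb_mean_br),
                           ("I", self.nb_mean_br * self.pooling_ratio)):
            mask = (sub == name).to_numpy()
            p = r / (r + mean)
            lam[mask] = rng.negative_binomial(r, p, size=int(mask.sum()))
        self._abundances = pd.Series(lam, index=sub.index)
        return self._abundances


def make_truth(
    n_skel: int = 4,
    n_caps: int = 6,
    n_boronates: int = 6,
    pooling_ratio: float = 1.31,
    n_binders: int = 5,
    binder_multiplier: float = 50.0,
    seed: int = 0,
    **kwargs,
) -> SimulationTruth:
    """Convenience constructor with a planted binder set chosen by seed."""
    design = generate_toy_design(n_skel, n_caps, n_boronates, seed=seed)
    tags = tags_for_design(design, seed=seed)
    layout = ReadLayout.default_for(tags)
    rng = np.random.default_rng(seed + 1)
    barcodes = design_barcodes(design)
    binder_idx = rng.choice(len(barcodes), size=min(n_binders, len(barcodes)),
                            replace=False)
    binders = {barcodes[i]: binder_multiplier for i in binder_idx}
    return SimulationTruth(
        design=design, tags=tags, layout=layout,
        pooling_ratio=pooling_ratio, binder_multipliers=binders,
        seed=seed, **kwargs,
    )


def _sample_counts(lam: pd.Series, n_reads: int, rng: np.random.Generator) -> pd.Series:
    total = lam.sum()
    if n_reads == 0 or total == 0:
        return pd.Series(0, index=lam.index, dtype=int)
    counts = rng.multinomial(n_reads, (lam / total).to_numpy())
    return pd.Series(counts, index=lam.index)


def _mutate(read: str, n_errors: int, rng: np.random.Generator) -> str:
    chars = list(read)
    for pos in rng.choice(len(chars), size=n_errors, replace=False):
        alternatives = [b for b in _ALPHABET if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def reads_from_counts(
    counts: pd.Series,
    layout: ReadLayout,
    tags: TagLibrary,
    error_rate: float,
    rng: np.random.Generator,
) -> list[str]:
    """Encode counts into reads, injecting per-base substitution errors."""
    reads: list[str] = []
    length = layout.total_length
    p_clean = (1.0 - error_rate) ** length
    for barcode, k in counts.items():
        if k == 0:
            continue
        clean = encode_read(barcode, layout, tags)
        n_err = rng.binomial(k, 1.0 - p_clean) if error_rate > 0 else 0
        reads.extend([clean] * (k - n_err))
        for _ in range(n_err):
            n = 0
            while n == 0:  # conditional on at least one substitution
                n = rng.binomial(length, error_rate)
            reads.append(_mutate(clean, n, rng))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def simulate_input_run(
    truth: SimulationTruth, n_reads: int, seed: int = 0
) -> tuple[list[str], pd.DataFrame]:
    """Simulated input sequencing: reads plus the true count table."""
    rng = np.random.default_rng(seed)
    counts = _sample_counts(truth.abundances(), n_reads, rng)
    reads = reads_from_counts(counts, truth.layout, truth.tags, truth.error_rate, rng)
    return reads, counts.to_frame("input")


def simulate_selection_run(
    truth: SimulationTruth, n_reads: int, seed: int = 0, sample: str = "selection"
) -> tuple[list[str], pd.DataFrame]:
    """Simulated affinity selection: binder abundances multiplied, renormalized.

    ``sample="beads_only"`` uses the matrix-binder multiplier set instead,
    modelling compounds that stick to the bead matrix.
    """
    rng = np.random.default_rng(seed)
    lam = truth.abundances().copy()
    multipliers = (
        truth.binder_multipliers if sample == "selection"
        else truth.matrix_binder_multipliers
    )
    for barcode, mult in multipliers.items():
        lam.loc[barcode] *= mult
    counts = _sample_counts(lam, n_reads, rng)
    reads = reads_from_counts(counts, truth.layout, truth.tags, truth.error_rate, rng)
    return reads, counts.to_frame(sample)


def write_fastq(reads: list[str], path: str | Path, quality_char: str = "I") -> None:
    """Write reads as plain-text FASTQ with constant placeholder qualities."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i}\n{read}\n+\n{quality_char * len(read)}\n")


def simulate_nb_counts(
    n_per_side: int,
    mean_br: float = 30.0,
    pooling_ratio: float = 1.31,
    dispersion: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Count-level two-sub-library simulation for pooling-ratio studies.

    Skips the read layer entirely: draws NB counts for n barcodes per
    sub-library with the I mean scaled by ``pooling_ratio``.
    """
    rng = np.random.default_rng(seed)
    r = dispersion
    out = {}
    for name, mean in (("Br", mean_br), ("I", mean_br * pooling_ratio)):
        p = r / (r + mean)
        out[name] = rng.negative_binomial(r, p, size=n_per_side)
    counts = np.concatenate([out["Br"], out["I"]])
    labels = np.array(["Br"] * n_per_side + ["I"] * n_per_side)
    table = pd.DataFrame({"input": counts})
    return table, labels
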