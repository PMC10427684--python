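"""Semi-automated building-block selection funnel and validation ranking.

The funnel mirrors a practical DEL building-block curation workflow: a
vendor catalog is desalted and deduplicated, filtered to a target
functional group by SMARTS, stripped of entries carrying undesirable
functionality, "dummy" enumerated into representative library members,
property-filtered by hard physicochemical cutoffs, and finally reduced to
a diverse subset by MaxMin picking on Morgan radius-2 fingerprints — with
an optional second, property-tightened round biased away from the first
round's picks.

Post-synthesis LCMS validation outcomes (percent area-under-the-curve of
desired product vs. unknown species) are classified against the inclusion
rule (>70 %AUC product and <10 %AUC unknown) and ranked for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.SimDivFilters.rdSimDivPickers import MaxMinPicker

from .chem_core import (
    MoleculeRef,
    ReactionDef,
    SmartsParseError,
    apply_reaction,
    mol_from_smiles,
)

logger = logging.getLogger(__name__)

#: default hierarchical exclusion filters (config-driven; the funnel removes
#: any entry matching ANY of these)
DEFAULT_EXCLUSION_FGS: dict[str, str] = {
    "alkyl_halide": "[CX4][F,Cl,Br,I]",
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "thiol": "[SX2H]",
    "thioether": "[#6][SX2][#6]",
    "hydrazine": "[NX3][NX3]",
    "amino_alcohol_1_2": "[NX3][CX4][CX4][OX2H]",
    "aldehyde": "[CX3H1]=O",
    "secondary_amine": "[NX3;H1]([CX4])[CX4]",
}


class ValidationError(ValueError):
    pass


@dataclass
class SelectionConfig:
    """Parameters of the two-round selection funnel."""

    target_fg: str = "[#7;h2]"
    exclusion_fgs: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_FGS)
    )
    dummy_template: ReactionDef | None = None
    round1_slogp_max: float = 6.0
    round1_mw_max: float = 600.0
    round2_slogp_max: float = 5.0
    round2_mw_max: float = 450.0
    round1_pick: int = 500
    round2_pick: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.round1_slogp_max, self.round1_mw_max,
               self.round2_slogp_max, self.round2_mw_max) <= 0:
            raise ValueError("cutoffs must be positive")
        if (self.round2_slogp_max > self.round1_slogp_max
                or self.round2_mw_max > self.round1_mw_max):
            raise ValueError("round-2 cutoffs must not exceed round-1 cutoffs")


@dataclass
class ValidationRecord:
    """LCMS validation outcome for one building block in one reaction class."""

    bb_id: str
    reaction_class: str
    pct_auc_product: float
    pct_auc_unknown: float
    included: bool = field(init=False)
    preference_tier: int = 1

    def __post_init__(self) -> None:
        self.included = classify_validation(self.pct_auc_product, self.pct_auc_unknown)


def filter_target_fg(
    entries: list[MoleculeRef], target_fg: str
) -> list[MoleculeRef]:
    """Retain entries matching the target functional-group SMARTS, in order."""
    patt = Chem.MolFromSmarts(target_fg)
    if patt is None:
        raise SmartsParseError(f"target SMARTS does not parse: {target_fg!r}")
    return [e for e in entries if mol_from_smiles(e.smiles).HasSubstructMatch(patt)]


def apply_exclusion_filters(
    entries: list[MoleculeRef], exclusion_fgs: dict[str, str] | list[str]
) -> list[MoleculeRef]:
    """Remove any entry matching any exclusion SMARTS (order-independent)."""
    if isinstance(exclusion_fgs, dict):
        exclusion_fgs = list(exclusion_fgs.values())
    patts = []
    for smarts in exclusion_fgs:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise SmartsParseError(f"exclusion SMARTS does not parse: {smarts!r}")
        patts.append(patt)
    kept = []
    for e in entries:
        mol = mol_from_smiles(e.smiles)
        if not any(mol.HasSubstructMatch(p) for p in patts):
            kept.append(e)
    return kept


def enumerate_dummy(
    entries: list[MoleculeRef], dummy_template: ReactionDef
) -> tuple[list[MoleculeRef], list[str]]:
    """One representative library member per entry.

    The dummy transform fixes the skeleton and the other building block in
    its product template, so each entry yields products by substituting its
    variable group; the first product after canonical sort is kept. Entries
    yielding no product are returned as failures and excluded downstream.
    """
    products: list[MoleculeRef] = []
    failures: list[str] = []
    for e in entries:
        prods = apply_reaction(dummy_template, e.smiles)
        if prods:
            products.append(MoleculeRef(smiles=prods[0], origin_id=e.origin_id))
        else:
            failures.append(e.origin_id)
    return products, failures


def compute_descriptors(mols: list[MoleculeRef]) -> pd.DataFrame:
    """Physicochemical descriptor table (one row per molecule).

    HBD counts donor hydrogens (N-H/O-H), so water contributes two.
    """
    rows = []
    for m in mols:
        mol = mol_from_smiles(m.smiles)
        rows.append(
            {
                "id": m.origin_id,
                "smiles": m.smiles,
                "exactMW": Descriptors.ExactMolWt(mol),
                "SLogP": Crippen.MolLogP(mol),
                "HBD": Lipinski.NHOHCount(mol),
                "HBA": rdMolDescriptors.CalcNumHBA(mol),
                "fsp3": rdMolDescriptors.CalcFractionCSP3(mol),
                "TPSA": rdMolDescriptors.CalcTPSA(mol),
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "smiles", "exactMW", "SLogP", "HBD", "HBA", "fsp3", "TPSA"]
    )


def apply_cutoffs(
    table: pd.DataFrame, slogp_max: float, mw_max: float
) -> pd.DataFrame:
    """Strict-inequality hard cutoffs applied simultaneously."""
    return table[(table["SLogP"] < slogp_max) & (table["exactMW"] < mw_max)]


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def morgan_fingerprints(smiles: list[str]):
    return [_FP_GEN.GetFingerprint(mol_from_smiles(s)) for s in smiles]


def diversity_pick(
    entries: list[MoleculeRef],
    n: int,
    seed: int = 0,
    avoid: list[MoleculeRef] | None = None,
) -> list[MoleculeRef]:
    """MaxMin diversity selection on Tanimoto distance of Morgan2 fingerprints.

    When ``avoid`` is given, those structures seed the picker so the n new
    picks maximize distance to the avoid set as well as to each other.
    Deterministic for a given seed.
    """
    if n > len(entries):
        logger.warning("requested %d picks from %d entries; returning all", n, len(entries))
        return list(entries)
    avoid = avoid or []
    fps = morgan_fingerprints([e.smiles for e in avoid + entries])
    picker = MaxMinPicker()
    first = list(range(len(avoid)))
    picks = picker.LazyBitVectorPick(
        fps, len(fps), len(avoid) + n, firstPicks=first, seed=seed
    )
    return [entries[i - len(avoid)] for i in picks if i >= len(avoid)]


def classify_validation(pct_product: float, pct_unknown: float) -> bool:
    """Inclusion rule: >70 %AUC desired product and <10 %AUC unknown species."""
    for v in (pct_product, pct_unknown):
        if not (0.0 <= v <= 100.0):
            raise ValidationError(f"%AUC out of range: {v}")
    return pct_product > 70.0 and pct_unknown < 10.0


def rank_building_blocks(records: list[ValidationRecord]) -> list[ValidationRecord]:
    """Two-phase "BB num" ranking.

    Phase 1: records with %AUC unknown <= 10, by decreasing %AUC product;
    phase 2: records with %AUC unknown > 10, by decreasing %AUC product.
    Ties in product break by ascending unknown, then input order.
    """
    indexed = list(enumerate(records))

    def key(item):
        i, r = item
        return (r.pct_auc_unknown > 10.0, -r.pct_auc_product, r.pct_auc_unknown, i)

    return [r for _, r in sorted(indexed, key=key)]


def preference_tier(
    included_i: bool, included_br: bool,
    pct_product_i: float = 0.0, pct_product_br: float = 0.0,
) -> int:
    """Consensus preference tier (4 highest) across ArI and ArBr campaigns.

    A reconstruction of the consensus-preference coloring: 4 = included in
    both campaigns; 3 = included in one with >70 %AUC product in the other;
    2 = included in exactly one; 1 = included in neither.
    """
    if included_i and included_br:
        return 4
    if included_i or included_br:
        other = pct_product_br if included_i else pct_product_i
        return 3 if other > 70.0 else 2
    return 1


def adjusted_pct_auc(pct_auc: float) -> float:
    """Adjustment hook for reported %AUC; identity by default."""
    return pct_auc


def run_funnel(
    entries: list[MoleculeRef], config: SelectionConfig
) -> tuple[list[MoleculeRef], pd.DataFrame]:
    """Run the full selection funnel; returns picks and a stage-count report."""
    stages: list[tuple[str, int]] = [("input", len(entries))]
    pool = filter_target_fg(entries, config.target_fg)
    stages.append(("target_fg", len(pool)))
    pool = apply_exclusion_filters(pool, config.exclusion_fgs)
    stages.append(("exclusion", len(pool)))
    by_id = {e.origin_id: e for e in pool}
    if config.dummy_template is not None:
        dummies, _failed = enumerate_dummy(pool, config.dummy_template)
    else:
        dummies = pool
    stages.append(("dummy_enumerated", len(dummies)))
    table = compute_descriptors(dummies)
    r1 = apply_cutoffs(table, config.round1_slogp_max, config.round1_mw_max)
    stages.append(("round1_cutoffs", len(r1)))
    r1_entries = [by_id[i] for i in r1["id"]]
    picks1 = diversity_pick(r1_entries, min(config.round1_pick, len(r1_entries)),
                            seed=config.seed)
    stages.append(("round1_pick", len(picks1)))
    r2 = apply_cutoffs(r1, config.round2_slogp_max, config.round2_mw_max)
    stages.append(("round2_cutoffs", len(r2)))
    r2_entries = [by_id[i] for i in r2["id"] if by_id[i] not in picks1]
    n2 = min(config.round2_pick, len(r2_entries))
    picks2 = diversity_pick(r2_entries, n2, seed=config.seed, avoid=picks1) if n2 else []
    stages.append(("round2_pick", len(picks2)))
    report = pd.DataFrame(stages, columns=["stage", "count"])
    return picks1 + picks2, report
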