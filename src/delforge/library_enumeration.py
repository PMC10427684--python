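"""Three-cycle combinatorial library enumeration.

Cycle 1 is the DNA-loaded skeleton, cycle 2 an amine-capping building
block (carboxylic acid, aldehyde, or sulfonyl chloride — dispatched to the
acylation, reductive-amination, or sulfonylation transform), and cycle 3 a
boronic acid/ester installed by Suzuki coupling on the skeleton's aryl
halide, or one of the encoded null conditions that leave the intermediate
unchanged. Every (cy1, cy2, cy3) barcode is kept — including enumeration
failures, which retain their barcode with a null structure so downstream
count-table joins never lose keys.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

from rdkit import Chem

from .chem_core import (
    ReactionDef,
    SkeletonRecord,
    canonicalize,
    load_reaction_defs,
    mol_from_smiles,
)

logger = logging.getLogger(__name__)

#: capping building-block class -> reaction role
CAPPING_DISPATCH = {
    "acid": "acylation",
    "aldehyde": "reductive_amination",
    "sulfonyl_chloride": "sulfonylation",
}

#: the two encoded null conditions of the Suzuki cycle
DEFAULT_NULL_CONDITIONS = ("with_conditions_no_boronate", "no_conditions")


@dataclass(frozen=True)
class BuildingBlockRecord:
    """A classed reactant appended in one encoded cycle."""

    id: str
    smiles: str
    bb_class: str  # acid | aldehyde | sulfonyl_chloride | boronate
    preference_tier: int = 1


@dataclass
class LibraryDesign:
    """The three-cycle combinatorial design."""

    skeletons: list[SkeletonRecord]
    capping_bbs: list[BuildingBlockRecord]
    boronates: list[BuildingBlockRecord]
    null_conditions: tuple[str, ...] = DEFAULT_NULL_CONDITIONS

    def __post_init__(self) -> None:
        if not self.skeletons or not self.capping_bbs:
            raise ValueError("design requires skeletons and capping building blocks")
        bad = [b.bb_class for b in self.capping_bbs if b.bb_class not in CAPPING_DISPATCH]
        if bad:
            raise ValueError(f"unknown capping classes: {sorted(set(bad))}")
        if any(b.bb_class != "boronate" for b in self.boronates):
            raise ValueError("cycle-3 building blocks must be boronates")

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.capping_bbs:
            counts[b.bb_class] = counts.get(b.bb_class, 0) + 1
        return counts


@dataclass
class IntermediateRecord:
    """An amine-capped skeleton awaiting the Suzuki cycle."""

    cy1_id: str
    cy2_id: str
    smiles: str | None  # None = enumeration failure, barcode retained
    sublibrary: str  # Br | I


@dataclass
class EnumeratedRecord:
    """One (barcode, product) pair of the enumerated library."""

    barcode: tuple[str, str, str]
    product_smiles: str | None
    sublibrary: str
    duplicate_group: int | None = None
    is_null: bool = False
    failed: bool = False


def _designated_n_products(
    rxn: ReactionDef, skeleton_smiles: str, amine_atom_index: int, bb_smiles: str
) -> list[str]:
    """Products of a capping reaction at the designated amine nitrogen only.

    The capping transforms match any nitrogen; products are filtered to
    those where the mapped reacting nitrogen is the curator-designated
    encoded amine (a stand-in for "most nucleophilic N-atom" ranking).
    """
    skel = mol_from_smiles(skeleton_smiles)
    bb = mol_from_smiles(bb_smiles)
    out: set[str] = set()
    for prod_set in rxn.rxn.RunReactants((skel, bb)):
        prod = prod_set[0]
        reacted_n = None
        for atom in prod.GetAtoms():
            if atom.HasProp("old_mapno") and atom.GetPropsAsDict()["old_mapno"] == 1:
                reacted_n = atom.GetPropsAsDict().get("react_atom_idx")
                break
        if reacted_n != amine_atom_index:
            continue
        try:
            Chem.SanitizeMol(prod)
        except Exception as exc:
            logger.warning("dropping unsanitizable capping product: %s", exc)
            continue
        out.add(Chem.MolToSmiles(prod))
    return sorted(out)


def enumerate_capping(
    design: LibraryDesign, reactions: dict[str, ReactionDef] | None = None
) -> list[IntermediateRecord]:
    """One intermediate per (skeleton, capping BB) pair.

    Pairs yielding zero valid products are flagged as failures (smiles
    None) and kept for barcode bookkeeping.
    """
    reactions = reactions or load_reaction_defs()
    records: list[IntermediateRecord] = []
    for skel in design.skeletons:
        if skel.normalized_smiles is None or skel.amine_atom_index is None:
            raise ValueError(f"skeleton {skel.id} is not normalized")
        for bb in design.capping_bbs:
            rxn = reactions[CAPPING_DISPATCH[bb.bb_class]]
            prods = _designated_n_products(
                rxn, skel.normalized_smiles, skel.amine_atom_index, bb.smiles
            )
            records.append(
                IntermediateRecord(
                    cy1_id=skel.id,
                    cy2_id=bb.id,
                    smiles=prods[0] if prods else None,
                    sublibrary=skel.halide,
                )
            )
            if not prods:
                logger.warning("capping failure: %s + %s", skel.id, bb.id)
    return records


def enumerate_suzuki(
    intermediates: list[IntermediateRecord],
    design: LibraryDesign,
    reactions: dict[str, ReactionDef] | None = None,
) -> list[EnumeratedRecord]:
    """One record per (intermediate x boronate) plus one per null condition.

    The halide-appropriate Suzuki transform is selected by sub-library;
    null records carry the intermediate structure unchanged under their
    own cycle-3 codes.
    """
    reactions = reactions or load_reaction_defs()
    records: list[EnumeratedRecord] = []
    for inter in intermediates:
        rxn = reactions["suzuki_I" if inter.sublibrary == "I" else "suzuki_Br"]
        for bor in design.boronates:
            if inter.smiles is None:
                prods: list[str] = []
            else:
                prods = _suzuki_products(rxn, inter.smiles, bor.smiles)
            records.append(
                EnumeratedRecord(
                    barcode=(inter.cy1_id, inter.cy2_id, bor.id),
                    product_smiles=prods[0] if prods else None,
                    sublibrary=inter.sublibrary,
                    failed=not prods,
                )
            )
        for null_label in design.null_conditions:
            records.append(
                EnumeratedRecord(
                    barcode=(inter.cy1_id, inter.cy2_id, null_label),
                    product_smiles=inter.smiles,
                    sublibrary=inter.sublibrary,
                    is_null=True,
                    failed=inter.smiles is None,
                )
            )
    return records


def _suzuki_products(rxn: ReactionDef, inter_smiles: str, bor_smiles: str) -> list[str]:
    inter = mol_from_smiles(inter_smiles)
    bor = mol_from_smiles(bor_smiles)
    out: set[str] = set()
    for prod_set in rxn.rxn.RunReactants((inter, bor)):
        prod = prod_set[0]
        try:
            Chem.SanitizeMol(prod)
        except Exception as exc:
            logger.warning("dropping unsanitizable Suzuki product: %s", exc)
            continue
        out.add(Chem.MolToSmiles(prod))
    return sorted(out)


def deduplicate(
    records: list[EnumeratedRecord],
) -> tuple[list[EnumeratedRecord], dict[str, int]]:
    """Assign duplicate groups by canonical product identity.

    Duplicates arise from null Suzuki couplings sharing an intermediate
    and from a boronic acid and its pinacol ester coupling to the same
    product. Failed records (no structure) share a single sentinel group.
    Returns the records plus a summary of barcode and unique-structure
    counts.
    """
    groups: dict[str, int] = {}
    n_failed = 0
    for rec in records:
        if rec.product_smiles is None:
            rec.duplicate_group = -1
            n_failed += 1
            continue
        key = canonicalize(rec.product_smiles)
        rec.duplicate_group = groups.setdefault(key, len(groups))
    summary = {
        "n_barcodes": len(records),
        "n_unique_structures": len(groups),
        "n_failed": n_failed,
    }
    return records, summary


def structure_hash(smiles: str) -> str:
    """Stable hash of a canonical SMILES, for sharded dedup bookkeeping."""
    return hashlib.sha1(canonicalize(smiles).encode()).hexdigest()[:16]


def count_design(
    n_skeletons: int,
    n_capping: int,
    n_boronates: int,
    n_nulls: int = 2,
    convention: str = "distinct_null",
) -> dict[str, int]:
    """Design-count arithmetic.

    ``theoretical_matrix`` is skeletons x capping x boronates — the
    counting convention that excludes null conditions. ``n_barcodes``
    depends on how the null conditions are encoded at the cycle-3 tag
    level: ``distinct_null`` gives each null condition its own tag;
    ``merged_null`` collapses them to one code. Both conventions are
    exposed because the encoding is a library-design choice.
    """
    if convention == "distinct_null":
        extra = n_nulls
    elif convention == "merged_null":
        extra = min(n_nulls, 1)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return {
        "theoretical_matrix": n_skeletons * n_capping * n_boronates,
        "n_barcodes": n_skeletons * n_capping * (n_boronates + extra),
    }


def count_design_for(design: LibraryDesign, convention: str = "distinct_null") -> dict[str, int]:
    return count_design(
        len(design.skeletons),
        len(design.capping_bbs),
        len(design.boronates),
        n_nulls=len(design.null_conditions),
        convention=convention,
    )


def build_validation_design(
    n_ar_i: int,
    n_ar_br: int,
    n_capping_reagents: int,
    n_boron_sources: int = 2,
    n_buffers: int = 2,
) -> dict[str, int]:
    """Row counts of the two-stage skeleton/BB validation matrices.

    Stage 1 crosses skeletons with capping reagents; stage 2 subjects each
    stage-1 product to each boron source in each buffer.
    """
    stage1 = (n_ar_i + n_ar_br) * n_capping_reagents
    return {"stage1_rows": stage1, "stage2_rows": stage1 * n_boron_sources * n_buffers}


def enumerate_library(
    design: LibraryDesign, reactions: dict[str, ReactionDef] | None = None
) -> tuple[list[EnumeratedRecord], dict[str, int]]:
    """Full enumeration: capping, Suzuki/nulls, duplicate accounting."""
    reactions = reactions or load_reaction_defs()
    intermediates = enumerate_capping(design, reactions)
    records = enumerate_suzuki(intermediates, design, reactions)
    return deduplicate(records)
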