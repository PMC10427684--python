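"""Molecule and reaction primitives for DEL design and enumeration.

This module wraps RDKit with the small set of operations the rest of the
toolkit is built on: canonicalization with desalting, substructure tests,
reaction-SMARTS application, and the normalization of DNA-loaded skeletons
to the "assumed pharmacophore" form used for library enumeration.

Skeleton normalization marks the DNA attachment site with a tritium atom
(``[3H]``) so that every enumerated product records where the barcode was
attached without carrying the full linker. Four rules are applied,
dispatched on the skeleton's attachment chemistry:

1. ``alkyl_linker_amide`` — skeletons acylated onto DNA through an alkyl
   di-acid linker are truncated to the corresponding methyl amide, the
   retained methylene carrying the tritium.
2. ``hydroxyl_carbamate`` — skeletons carbamylated onto DNA through a
   primary alcohol are represented as the tritium-marked methyl ether.
3. ``acid_amide`` — skeletons attached through their own carboxylic acid
   are represented as the tritium-marked N-methyl amide.
4. Ester groups known to hydrolyze cleanly during synthesis are hydrolyzed
   to the acid before the attachment rule is applied.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import rdChemReactions

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

#: reaction roles understood by the enumeration machinery
REACTION_ROLES = (
    "sulfonylation",
    "reductive_amination",
    "acylation",
    "suzuki_I",
    "suzuki_Br",
    "dummy_template",
)

#: expected number of reactant templates per role
_TEMPLATES_PER_ROLE = {role: 2 for role in REACTION_ROLES}
_TEMPLATES_PER_ROLE["dummy_template"] = 1  # fixed partners baked into the product


class ChemError(ValueError):
    """Raised for unparseable molecular input or invalid queries."""


class SmilesParseError(ChemError):
    pass


class SmartsParseError(ChemError):
    pass


class NormalizationError(ChemError):
    """Raised when a skeleton has no recognizable DNA-attachment group."""


def _clean_smarts(smarts: str) -> str:
    """Strip typesetting artifacts from a reaction SMARTS.

    Journal typesetting introduces spaces around ``=``, a unicode
    double-angle arrow, and unicode minus signs in ring closures; all are
    normalized so the stored definitions can be kept verbatim.
    """
    s = smarts.replace("≫", ">>").replace("−", "-")
    return re.sub(r"\s+", "", s)


@dataclass(frozen=True)
class MoleculeRef:
    """A canonical SMILES paired with the identifier of its source record."""

    smiles: str
    origin_id: str


@dataclass
class ReactionDef:
    """A named reaction-SMARTS transform with its dispatch role."""

    name: str
    smarts: str
    role: str
    _rxn: rdChemReactions.ChemicalReaction | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.role not in REACTION_ROLES:
            raise ValueError(f"unknown reaction role {self.role!r}")
        self.smarts = _clean_smarts(self.smarts)
        rxn = rdChemReactions.ReactionFromSmarts(self.smarts)
        if rxn is None:
            raise SmartsParseError(f"reaction SMARTS does not parse: {self.smarts!r}")
        expected = _TEMPLATES_PER_ROLE[self.role]
        if rxn.GetNumReactantTemplates() != expected:
            raise ValueError(
                f"role {self.role!r} expects {expected} reactant template(s), "
                f"got {rxn.GetNumReactantTemplates()}"
            )
        rxn.Initialize()
        self._rxn = rxn

    @property
    def rxn(self) -> rdChemReactions.ChemicalReaction:
        assert self._rxn is not None
        return self._rxn


@dataclass
class SkeletonRecord:
    """A multifunctional scaffold as loaded on DNA.

    ``normalized_smiles`` and ``amine_atom_index`` are filled in by
    :func:`normalize_skeleton`; ``amine_atom_index`` designates the encoded
    secondary-amine nitrogen (atom index in the normalized SMILES) at which
    capping reactions are allowed to react.
    """

    id: str
    loaded_smiles: str
    halide: str  # "Br" | "I"
    attachment: str  # "acid_amide" | "hydroxyl_carbamate" | "alkyl_linker_amide"
    protecting_group: str = "none"  # Fmoc | Boc | Ns | none (modelled post-deprotection)
    normalized_smiles: str | None = None
    amine_atom_index: int | None = None

    def validate(self) -> None:
        if self.halide not in ("Br", "I"):
            raise ValueError(f"halide must be Br or I, got {self.halide!r}")
        if self.normalized_smiles is None:
            return
        mol = mol_from_smiles(self.normalized_smiles)
        n_tritium = sum(
            1 for a in mol.GetAtoms() if a.GetAtomicNum() == 1 and a.GetIsotope() == 3
        )
        if n_tritium != 1:
            raise ValueError(
                f"normalized skeleton {self.id} carries {n_tritium} tritium atoms"
            )
        if not any(a.GetSymbol() == self.halide for a in mol.GetAtoms()):
            raise ValueError(f"skeleton {self.id}: halide {self.halide} absent")
        if self.amine_atom_index is not None:
            atom = mol.GetAtomWithIdx(self.amine_atom_index)
            if atom.GetAtomicNum() != 7:
                raise ValueError(
                    f"skeleton {self.id}: amine_atom_index does not address a nitrogen"
                )


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"SMILES does not parse: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Canonical SMILES; idempotent and invariant to atom ordering."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def desalt_and_canonicalize(smiles: str) -> str:
    """Keep the largest fragment by heavy-atom count, canonicalized.

    Ties between equally sized fragments are broken by lexicographic order
    of the fragments' canonical SMILES, so the result is deterministic.
    """
    mol = mol_from_smiles(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    best = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    return Chem.MolToSmiles(best)


def match_substructure(smiles: str, query: str) -> bool:
    """True iff ``query`` (SMARTS) has at least one embedding in the molecule."""
    patt = Chem.MolFromSmarts(query)
    if patt is None:
        raise SmartsParseError(f"SMARTS does not parse: {query!r}")
    return mol_from_smiles(smiles).HasSubstructMatch(patt)


def _sanitize_product(mol: Chem.Mol) -> str | None:
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # valence failures are data, not errors
        logger.warning("dropping unsanitizable product: %s", exc)
        return None
    return Chem.MolToSmiles(mol)


def apply_reaction(
    rxn: ReactionDef, reactant_a: str, reactant_b: str | None = None
) -> list[str]:
    """All distinct, sanitized products of the transform, canonically sorted.

    Products failing valence sanitization are dropped with a logged warning
    rather than aborting a combinatorial run. An empty list means no
    template matched.
    """
    reactants = [mol_from_smiles(reactant_a)]
    if rxn.rxn.GetNumReactantTemplates() == 2:
        if reactant_b is None:
            raise ValueError(f"reaction {rxn.name!r} requires two reactants")
        reactants.append(mol_from_smiles(reactant_b))
    products: set[str] = set()
    for prod_set in rxn.rxn.RunReactants(tuple(reactants)):
        smi = _sanitize_product(prod_set[0])
        if smi is not None:
            products.add(smi)
    return sorted(products)


# --- skeleton normalization -------------------------------------------------

_ACID = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")
_PRIMARY_OL = Chem.MolFromSmarts("[OX2H1][CH2]")
# acyclic carboxylic ester (excludes the acid itself and lactones)
_ESTER_RXN = rdChemReactions.ReactionFromSmarts(
    "[C:1](=[O:2])[O;!R:3][CX4]>>[C:1](=[O:2])[O:3][H]"
)


def _add_tritium(rw: Chem.RWMol, carbon_idx: int) -> None:
    h = Chem.Atom(1)
    h.SetIsotope(3)
    h_idx = rw.AddAtom(h)
    rw.AddBond(carbon_idx, h_idx, Chem.BondType.SINGLE)


def _finish(rw: Chem.RWMol) -> str:
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def hydrolyze_esters(smiles: str) -> str:
    """Hydrolyze acyclic carboxylic esters to the free acids."""
    mol = mol_from_smiles(smiles)
    while True:
        prods = _ESTER_RXN.RunReactants((mol,))
        if not prods:
            return Chem.MolToSmiles(mol)
        out = prods[0][0]
        Chem.SanitizeMol(out)
        mol = Chem.MolFromSmiles(Chem.MolToSmiles(out))


def _normalize_alkyl_linker(mol: Chem.Mol) -> str:
    match = mol.GetSubstructMatch(_ACID)
    if not match:
        raise NormalizationError("no carboxylic acid found for alkyl-linker rule")
    acid_c, acid_o, acid_oh = match
    # walk the sp3 chain from the acid carbon to the linker's amide carbonyl
    chain: list[int] = []
    prev = acid_c
    cur = next(
        (nb.GetIdx() for nb in mol.GetAtomWithIdx(acid_c).GetNeighbors()
         if nb.GetAtomicNum() == 6),
        None,
    )
    if cur is None:
        raise NormalizationError("acid carbon has no carbon neighbor")
    while True:
        atom = mol.GetAtomWithIdx(cur)
        is_amide_c = any(nb.GetAtomicNum() == 7 for nb in atom.GetNeighbors()) and any(
            b.GetBondTypeAsDouble() == 2.0 and b.GetOtherAtom(atom).GetAtomicNum() == 8
            for b in atom.GetBonds()
        )
        if is_amide_c:
            break
        chain.append(cur)
        nxt = [
            nb.GetIdx()
            for nb in atom.GetNeighbors()
            if nb.GetIdx() != prev and nb.GetAtomicNum() == 6
        ]
        if not nxt:
            raise NormalizationError("alkyl linker does not terminate in an amide")
        prev, cur = cur, nxt[0]
    if not chain:
        raise NormalizationError("no methylene linker between acid and amide")
    keep = chain[-1]  # methylene adjacent to the skeleton amide: becomes [3H]CH2
    rw = Chem.RWMol(mol)
    _add_tritium(rw, keep)
    for idx in sorted([acid_c, acid_o, acid_oh] + chain[:-1], reverse=True):
        rw.RemoveAtom(idx)
    return _finish(rw)


def _normalize_hydroxyl(mol: Chem.Mol) -> str:
    match = mol.GetSubstructMatch(_PRIMARY_OL)
    if not match:
        raise NormalizationError("no primary hydroxyl found for carbamate rule")
    o_idx = match[0]
    rw = Chem.RWMol(mol)
    c_idx = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(o_idx, c_idx, Chem.BondType.SINGLE)
    _add_tritium(rw, c_idx)
    return _finish(rw)


def _normalize_acid_amide(mol: Chem.Mol) -> str:
    match = mol.GetSubstructMatch(_ACID)
    if not match:
        raise NormalizationError("no carboxylic acid found for amide rule")
    _, _, acid_oh = match
    rw = Chem.RWMol(mol)
    rw.GetAtomWithIdx(acid_oh).SetAtomicNum(7)
    c_idx = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(acid_oh, c_idx, Chem.BondType.SINGLE)
    _add_tritium(rw, c_idx)
    return _finish(rw)


_ATTACHMENT_RULES = {
    "alkyl_linker_amide": _normalize_alkyl_linker,
    "hydroxyl_carbamate": _normalize_hydroxyl,
    "acid_amide": _normalize_acid_amide,
}

#: encoded secondary amine: N-H, sp3-bound, not an amide/sulfonamide nitrogen
SECONDARY_AMINE_SMARTS = "[NX3;H1;!$(N[C,S]=O)]"
_SECONDARY_AMINE = Chem.MolFromSmarts(SECONDARY_AMINE_SMARTS)


def find_secondary_amine(smiles: str) -> int:
    """Atom index of the unique encoded secondary amine, or raise."""
    mol = mol_from_smiles(smiles)
    matches = mol.GetSubstructMatches(_SECONDARY_AMINE)
    if len(matches) != 1:
        raise ChemError(
            f"expected exactly one secondary amine in {smiles!r}, found {len(matches)}"
        )
    return matches[0][0]


def normalize_skeleton(rec: SkeletonRecord, locate_amine: bool = True) -> SkeletonRecord:
    """Fill ``normalized_smiles`` (and optionally ``amine_atom_index``).

    Esters known to hydrolyze during synthesis are hydrolyzed first; the
    attachment-specific truncation rule then marks the DNA attachment site
    with a single tritium atom.
    """
    rule = _ATTACHMENT_RULES.get(rec.attachment)
    if rule is None:
        raise NormalizationError(f"unrecognized attachment mode {rec.attachment!r}")
    smiles = hydrolyze_esters(rec.loaded_smiles)
    rec.normalized_smiles = rule(mol_from_smiles(smiles))
    if locate_amine:
        rec.amine_atom_index = find_secondary_amine(rec.normalized_smiles)
    rec.validate()
    return rec


# --- bundled reaction definitions -------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"


def load_reaction_defs(path: str | Path | None = None) -> dict[str, ReactionDef]:
    """Load reaction definitions from a TSV of (name, role, smarts).

    Defaults to the bundled file holding the printed N-capping and Suzuki
    transforms; typesetting whitespace is stripped at load.
    """
    path = Path(path) if path is not None else _DATA_DIR / "reactions.tsv"
    defs: dict[str, ReactionDef] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            defs[row["name"]] = ReactionDef(
                name=row["name"], role=row["role"], smarts=row["smarts"]
            )
    return defs


def molecules_equal(smiles_a: str, smiles_b: str) -> bool:
    """Molecule-level equality via canonical SMILES of both sides."""
    return canonicalize(smiles_a) == canonicalize(smiles_b)


def load_skeletons_csv(path: str | Path) -> list[SkeletonRecord]:
    """Read skeletons from CSV (id, loaded_smiles, halide, attachment, protecting_group)."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                SkeletonRecord(
                    id=row["id"],
                    loaded_smiles=row["loaded_smiles"],
                    halide=row["halide"],
                    attachment=row["attachment"],
                    protecting_group=row.get("protecting_group", "none"),
                )
            )
    return records
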