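"""Ugi four-component reaction (ammonia/acrylic-acid variant) enumeration.

The U-4CR condenses an amine, an aldehyde, an isocyanide and a carboxylic
acid into a bis-amide with loss of one water. With ammonia as the amine and
acrylic acid as the acid, the product is an N-acryloyl amino-acid amide

    CH2=CH-C(=O)-NH-CH(R_ald)-C(=O)-NH-R_iso

carrying the acrylamide warhead and two secondary amide N-H groups. This
module enumerates such products from aldehyde and isocyanide building
blocks, computes elemental compositions and monoisotopic masses from the
package's pinned isotope table, and computes the five physicochemical
descriptors used for outcome modelling (SLogP, TopoPSA, SMR, MW, nHBDon).

The alpha-carbon stereocenter created by the reaction is emitted without
stereo annotation (the synthesis is racemic).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .constants import (
    ISOTOPE_MASS,
    MASS_ACRYLIC_ACID,
    MASS_AMMONIA,
    MASS_TOL_DA,
    MASS_WATER,
)

__all__ = [
    "BuildingBlock",
    "DescriptorVector",
    "ElementComposition",
    "StructuralValidationError",
    "UgiProduct",
    "UnknownElementError",
    "assemble_product",
    "compute_descriptors",
    "enumerate_library",
    "monoisotopic_mass",
    "normalize_01",
    "read_building_blocks_csv",
    "read_building_blocks_sdf",
    "write_products_csv",
    "write_products_sdf",
]

DESCRIPTOR_NAMES = ("slogp", "topopsa", "smr", "mw", "nhbdon")

# Aldehyde carbonyl: sp2 C bearing one H (two for formaldehyde) double-bonded to O.
_ALDEHYDE = Chem.MolFromSmarts("[CX3;H1,H2]=[OX1]")
# Isocyanide as RDKit sanitizes it: charge-separated terminal [C-]#[N+].
_ISOCYANIDE = Chem.MolFromSmarts("[C-]#[N+]")
_WARHEAD = Chem.MolFromSmarts("C=C-C(=O)-[NX3]")
_SECONDARY_AMIDE_NH = Chem.MolFromSmarts("[NX3H1]C(=O)")


class StructuralValidationError(ValueError):
    """A building block fails its role's substructure requirement."""


class UnknownElementError(KeyError):
    """An element symbol is absent from the pinned isotope table."""


class ElementComposition(Counter):
    """Element symbol -> non-negative atom count.

    A thin Counter specialisation housing formula arithmetic; supports
    ``+``/``-`` via Counter semantics (negative counts are dropped by
    Counter subtraction, so subtraction is only meaningful when the result
    is a true sub-formula).
    """

    @classmethod
    def from_mol(cls, mol: Chem.Mol) -> "ElementComposition":
        molh = Chem.AddHs(mol)
        return cls(atom.GetSymbol() for atom in molh.GetAtoms())

    @classmethod
    def from_smiles(cls, smiles: str) -> "ElementComposition":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smiles!r}")
        return cls.from_mol(mol)

    def hill_formula(self) -> str:
        """Molecular formula in Hill order (C, H, then alphabetical)."""
        parts = []
        for sym in ["C", "H"] + sorted(k for k in self if k not in ("C", "H")):
            n = self.get(sym, 0)
            if n > 0:
                parts.append(sym + (str(n) if n > 1 else ""))
        return "".join(parts)


def monoisotopic_mass(comp: ElementComposition | dict[str, int]) -> float:
    """Sum of count x most-abundant-isotope exact mass over the composition.

    Raises :class:`UnknownElementError` naming any symbol missing from the
    pinned table. Empty composition -> 0.0.
    """
    total = 0.0
    for sym, n in comp.items():
        if sym not in ISOTOPE_MASS:
            raise UnknownElementError(f"unknown element symbol: {sym!r}")
        total += n * ISOTOPE_MASS[sym]
    return total


@dataclass(frozen=True)
class BuildingBlock:
    """One aldehyde or isocyanide starting material.

    ``stock_molarity`` records the trifluoroethanol stock concentration
    (2.5 or 5.0 mol/L, metadata only).
    """

    id: str
    role: str  # "aldehyde" | "isocyanide"
    smiles: str
    stock_molarity: float = 2.5

    def __post_init__(self) -> None:
        if self.role not in ("aldehyde", "isocyanide"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.stock_molarity not in (2.5, 5.0):
            raise ValueError(
                f"stock_molarity must be 2.5 or 5.0, got {self.stock_molarity}"
            )

    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise StructuralValidationError(
                f"building block {self.id}: unparsable SMILES {self.smiles!r}"
            )
        if len(Chem.GetMolFrags(mol)) != 1:
            raise StructuralValidationError(
                f"building block {self.id}: SMILES is not one connected molecule"
            )
        return mol

    def validate(self) -> Chem.Mol:
        """Check the strict one-reactive-group invariant; return the mol.

        Exactly one aldehyde group for role=aldehyde, exactly one isocyanide
        group for role=isocyanide; bifunctional blocks are rejected.
        """
        mol = self.mol()
        pattern = _ALDEHYDE if self.role == "aldehyde" else _ISOCYANIDE
        n = len(mol.GetSubstructMatches(pattern))
        if n != 1:
            group = "aldehyde (HC=O)" if self.role == "aldehyde" else "isocyanide (N#C)"
            raise StructuralValidationError(
                f"building block {self.id} ({self.smiles}): expected exactly one "
                f"{group} group for role {self.role!r}, found {n}"
            )
        return mol


@dataclass(frozen=True)
class DescriptorVector:
    """The five descriptors most tied to precipitation success."""

    slogp: float      # Crippen octanol/water partition estimate, unitless
    topopsa: float    # Ertl topological polar surface area, A^2
    smr: float        # Crippen molar refractivity, unitless
    mw: float         # average molecular weight, Da
    nhbdon: int       # N-H / O-H hydrogen-bond donor count

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DESCRIPTOR_NAMES}


@dataclass(frozen=True)
class UgiProduct:
    """An enumerated acrylamide with composition, mass and provenance."""

    id: str
    aldehyde_id: str
    isocyanide_id: str
    smiles: str
    composition: ElementComposition = field(compare=False)
    monoisotopic_mass: float
    is_duplicate: bool = False


def _single_match(mol: Chem.Mol, pattern: Chem.Mol, what: str) -> tuple[int, ...]:
    matches = mol.GetSubstructMatches(pattern)
    if len(matches) != 1:
        raise StructuralValidationError(
            f"expected exactly one {what} group, found {len(matches)} "
            f"in {Chem.MolToSmiles(mol)}"
        )
    return matches[0]


def assemble_product(
    aldehyde: BuildingBlock, isocyanide: BuildingBlock, product_id: str | None = None
) -> UgiProduct:
    """Condense one aldehyde and one isocyanide into the Ugi acrylamide.

    The aldehyde carbonyl carbon becomes the alpha carbon: its oxygen is
    removed, an acryloyl-NH is grafted on, and the isocyanide carbon becomes
    the second amide carbonyl (C#N -> C(=O)-N) bonded to the alpha carbon.
    Composition therefore equals aldehyde + isocyanide + NH3 + acrylic acid
    - H2O.
    """
    if aldehyde.role != "aldehyde":
        raise StructuralValidationError(
            f"{aldehyde.id}: role {aldehyde.role!r} passed in the aldehyde slot"
        )
    if isocyanide.role != "isocyanide":
        raise StructuralValidationError(
            f"{isocyanide.id}: role {isocyanide.role!r} passed in the isocyanide slot"
        )
    ald = aldehyde.validate()
    iso = isocyanide.validate()

    ca, oa = _single_match(ald, _ALDEHYDE, "aldehyde (HC=O)")
    ci_raw, ni_raw = _single_match(iso, _ISOCYANIDE, "isocyanide (N#C)")

    combo = Chem.RWMol(Chem.CombineMols(ald, iso))
    ci = ci_raw + ald.GetNumAtoms()
    ni = ni_raw + ald.GetNumAtoms()
    combo.RemoveAtom(oa)
    if oa < ca:
        ca -= 1
    ci -= 1 if oa < ci else 0
    ni -= 1 if oa < ni else 0

    # isocyanide C#N+ -> amide C(=O)-N
    bond = combo.GetBondBetweenAtoms(ci, ni)
    bond.SetBondType(Chem.BondType.SINGLE)
    for idx in (ci, ni):
        atom = combo.GetAtomWithIdx(idx)
        atom.SetFormalCharge(0)
        atom.SetNoImplicit(False)
    o_amide = combo.AddAtom(Chem.Atom(8))
    combo.AddBond(ci, o_amide, Chem.BondType.DOUBLE)
    combo.AddBond(ca, ci, Chem.BondType.SINGLE)

    # acryloyl-NH on the alpha carbon: N-C(=O)-CH=CH2
    n_acr = combo.AddAtom(Chem.Atom(7))
    c_carbonyl = combo.AddAtom(Chem.Atom(6))
    o_acr = combo.AddAtom(Chem.Atom(8))
    c_alpha = combo.AddAtom(Chem.Atom(6))
    c_beta = combo.AddAtom(Chem.Atom(6))
    combo.AddBond(ca, n_acr, Chem.BondType.SINGLE)
    combo.AddBond(n_acr, c_carbonyl, Chem.BondType.SINGLE)
    combo.AddBond(c_carbonyl, o_acr, Chem.BondType.DOUBLE)
    combo.AddBond(c_carbonyl, c_alpha, Chem.BondType.SINGLE)
    combo.AddBond(c_alpha, c_beta, Chem.BondType.DOUBLE)

    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    Chem.RemoveStereochemistry(mol)  # racemic alpha carbon, no annotation

    comp = ElementComposition.from_mol(mol)
    mass = monoisotopic_mass(comp)

    # internal consistency: additivity of component masses
    expected = (
        monoisotopic_mass(ElementComposition.from_mol(ald))
        + monoisotopic_mass(ElementComposition.from_mol(iso))
        + MASS_AMMONIA
        + MASS_ACRYLIC_ACID
        - MASS_WATER
    )
    assert abs(mass - expected) < MASS_TOL_DA

    return UgiProduct(
        id=product_id or f"{aldehyde.id}_{isocyanide.id}",
        aldehyde_id=aldehyde.id,
        isocyanide_id=isocyanide.id,
        smiles=Chem.MolToSmiles(mol),
        composition=comp,
        monoisotopic_mass=mass,
    )


def enumerate_library(
    aldehydes: list[BuildingBlock], isocyanides: list[BuildingBlock]
) -> list[UgiProduct]:
    """One product per (aldehyde, isocyanide) pair, ordered by id pair.

    Distinct pairs yielding the same canonical structure are retained as
    separate reaction records (the campaign counts reactions, not unique
    structures); every record after the first carries ``is_duplicate``.
    """
    products: list[UgiProduct] = []
    seen: set[str] = set()
    for ald in sorted(aldehydes, key=lambda b: b.id):
        for iso in sorted(isocyanides, key=lambda b: b.id):
            prod = assemble_product(ald, iso)
            if prod.smiles in seen:
                prod = UgiProduct(
                    id=prod.id,
                    aldehyde_id=prod.aldehyde_id,
                    isocyanide_id=prod.isocyanide_id,
                    smiles=prod.smiles,
                    composition=prod.composition,
                    monoisotopic_mass=prod.monoisotopic_mass,
                    is_duplicate=True,
                )
            seen.add(prod.smiles)
            products.append(prod)
    return products


@lru_cache(maxsize=100_000)
def compute_descriptors(smiles: str) -> DescriptorVector:
    """SLogP/SMR (Crippen), TopoPSA (Ertl), average MW, and donor count."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return DescriptorVector(
        slogp=Crippen.MolLogP(mol),
        topopsa=Descriptors.TPSA(mol),
        smr=Crippen.MolMR(mol),
        mw=Descriptors.MolWt(mol),
        nhbdon=Lipinski.NumHDonors(mol),
    )


def product_has_warhead(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    return mol is not None and mol.HasSubstructMatch(_WARHEAD)


def count_secondary_amide_nh(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    return len(mol.GetSubstructMatches(_SECONDARY_AMIDE_NH))


def normalize_01(values: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each column to [0, 1]; constant columns map to zeros.

    Columns with non-finite entries raise, listing the offending row ids.
    """
    bad: dict[str, list] = {}
    for col in values.columns:
        nonfinite = values.index[~np.isfinite(values[col].to_numpy(dtype=float))]
        if len(nonfinite):
            bad[col] = list(nonfinite)
    if bad:
        raise ValueError(f"non-finite descriptor values: {bad}")
    out = values.astype(float).copy()
    for col in out.columns:
        lo, hi = out[col].min(), out[col].max()
        out[col] = 0.0 if hi == lo else (out[col] - lo) / (hi - lo)
    return out


# ---------------------------------------------------------------------------
# External interfaces: building-block CSV/SDF, product CSV/SDF

def read_building_blocks_csv(path) -> list[BuildingBlock]:
    df = pd.read_csv(path)
    required = {"id", "role", "smiles", "stock_molarity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"building-block CSV missing columns: {sorted(missing)}")
    return [
        BuildingBlock(
            id=str(r.id),
            role=str(r.role),
            smiles=str(r.smiles),
            stock_molarity=float(r.stock_molarity),
        )
        for r in df.itertuples(index=False)
    ]


def write_building_blocks_csv(blocks: list[BuildingBlock], path) -> None:
    pd.DataFrame(
        [
            {
                "id": b.id,
                "role": b.role,
                "smiles": b.smiles,
                "stock_molarity": b.stock_molarity,
            }
            for b in blocks
        ]
    ).to_csv(path, index=False)


def read_building_blocks_sdf(path) -> list[BuildingBlock]:
    """SDF with role and stock_molarity carried as tags."""
    blocks = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        blocks.append(
            BuildingBlock(
                id=mol.GetProp("id") if mol.HasProp("id") else mol.GetProp("_Name"),
                role=mol.GetProp("role"),
                smiles=Chem.MolToSmiles(mol),
                stock_molarity=float(mol.GetProp("stock_molarity")),
            )
        )
    return blocks


def products_to_frame(products: list[UgiProduct]) -> pd.DataFrame:
    rows = []
    for p in products:
        desc = compute_descriptors(p.smiles)
        rows.append(
            {
                "product_id": p.id,
                "aldehyde_id": p.aldehyde_id,
                "isocyanide_id": p.isocyanide_id,
                "smiles": p.smiles,
                "formula": p.composition.hill_formula(),
                "monoisotopic_mass": round(p.monoisotopic_mass, 6),
                "is_duplicate": p.is_duplicate,
                **{k: round(v, 6) for k, v in desc.as_dict().items()},
            }
        )
    return pd.DataFrame(rows)


def write_products_csv(products: list[UgiProduct], path) -> None:
    products_to_frame(products).to_csv(path, index=False)


def write_products_sdf(products: list[UgiProduct], path) -> None:
    with Chem.SDWriter(str(path)) as writer:
        for p in products:
            mol = Chem.MolFromSmiles(p.smiles)
            mol.SetProp("_Name", p.id)
            mol.SetProp("formula", p.composition.hill_formula())
            mol.SetProp("monoisotopic_mass", f"{p.monoisotopic_mass:.6f}")
            mol.SetProp("is_duplicate", str(p.is_duplicate))
            for k, v in compute_descriptors(p.smiles).as_dict().items():
                mol.SetProp(k, f"{v:.6f}" if isinstance(v, float) else str(v))
            writer.write(mol)


def frame_to_products(df: pd.DataFrame) -> list[UgiProduct]:
    """Rebuild products from the CSV form (composition from SMILES)."""
    out = []
    for r in df.itertuples(index=False):
        comp = ElementComposition.from_smiles(r.smiles)
        out.append(
            UgiProduct(
                id=str(r.product_id),
                aldehyde_id=str(r.aldehyde_id),
                isocyanide_id=str(r.isocyanide_id),
                smiles=str(r.smiles),
                composition=comp,
                monoisotopic_mass=float(r.monoisotopic_mass),
                is_duplicate=bool(r.is_duplicate),
            )
        )
    return out
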