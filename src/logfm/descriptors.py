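"""Structures and structure-derived descriptors.

Molecules are RDKit ``Mol`` objects parsed from SMILES or SDF (V2000)
records, valence-sanitized with aromaticity perceived and implicit hydrogens
assigned. The descriptor set is the physico-chemical block used by the
placental-transfer models: size (MW, van der Waals volume, density),
hydrogen bonding (nHA, nHD), flexibility (nRot, nRig, Flex), ring topology
(nRing, MaxRing), heteroatom content with hydrogens included (nHet),
saturation (Fsp3), polarity (TPSA) and a Crippen logP estimate.

Externally predicted ADMET fields (caco2, logVDss, Fu, PPB, MDCK, PAMPA,
logS, logD, Hmax, AATSC1c, ZMIC1) are never computed here — they are merged
from descriptor tables (see :mod:`logfm.tables`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski as _Lip, rdMolDescriptors

from .errors import MissingDescriptorError, ParseError

__all__ = [
    "DescriptorVector",
    "parse_structure",
    "parse_smiles_file",
    "parse_sdf",
    "count_het",
    "vdw_volume",
    "count_rotatable_bonds",
    "compute_structural_descriptors",
    "lipinski_flag",
    "NUMERIC_FIELDS",
    "STRUCTURAL_FIELDS",
    "EXTERNAL_FIELDS",
]

#: fields computable from structure alone
STRUCTURAL_FIELDS = (
    "MW", "Vol", "Dense", "nHA", "nHD", "nRot", "nRing", "MaxRing",
    "nHet", "nRig", "Flex", "Fsp3", "TPSA", "logP", "Lipinski",
)

#: fields that must be supplied externally (ADMET predictors, PaDEL block)
EXTERNAL_FIELDS = (
    "logS", "logD", "caco2", "MDCK", "PAMPA", "logVDss", "PPB", "Fu",
    "Hmax", "AATSC1c", "ZMIC1",
)

NUMERIC_FIELDS = STRUCTURAL_FIELDS + EXTERNAL_FIELDS


@dataclass
class DescriptorVector:
    """Named descriptor fields for one compound; ``None`` marks missing.

    Units: MW g/mol, Vol Å³, TPSA Å², Fu and PPB percent (0–100), caco2 and
    the other membrane permeabilities on the scale of the supplying table
    (ADMETLab convention, log cm/s), logVDss log L/kg. Lipinski is the
    binary Ro5 drug-likeness flag.
    """

    compound_id: str = ""
    MW: float | None = None
    Vol: float | None = None
    Dense: float | None = None
    nHA: float | None = None
    nHD: float | None = None
    nRot: float | None = None
    nRing: float | None = None
    MaxRing: float | None = None
    nHet: float | None = None
    nRig: float | None = None
    Flex: float | None = None
    Fsp3: float | None = None
    TPSA: float | None = None
    logP: float | None = None
    Lipinski: float | None = None
    logS: float | None = None
    logD: float | None = None
    caco2: float | None = None
    MDCK: float | None = None
    PAMPA: float | None = None
    logVDss: float | None = None
    PPB: float | None = None
    Fu: float | None = None
    Hmax: float | None = None
    AATSC1c: float | None = None
    ZMIC1: float | None = None
    GI_absorption: str | None = None
    extra: dict = field(default_factory=dict)

    def get(self, name: str):
        return getattr(self, name)

    def require(self, *names: str) -> list[float]:
        """Return the named fields, raising if any is missing."""
        out = []
        for name in names:
            value = getattr(self, name, None)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise MissingDescriptorError(name, self.compound_id or None)
            out.append(value)
        return out

    def to_dict(self) -> dict:
        d = {"compound_id": self.compound_id}
        for f in dc_fields(self):
            if f.name in ("compound_id", "extra"):
                continue
            d[f.name] = getattr(self, f.name)
        d.update(self.extra)
        return d


# ---------------------------------------------------------------------------
# parsing

def parse_structure(text: str) -> Chem.Mol:
    """Parse a single SMILES string or SDF (molblock) record.

    Records containing a newline are treated as molblocks, anything else as
    SMILES. Raises :class:`ParseError` naming the offending input.
    """
    if not text or not text.strip():
        raise ParseError(text, "empty structure record")
    if "\n" in text:
        mol = Chem.MolFromMolBlock(text, sanitize=True)
    else:
        mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        raise ParseError(text)
    return mol


def parse_smiles_file(path) -> list[tuple[str, Chem.Mol]]:
    """Read a SMILES file: one molecule per line, optional tab-separated id.

    Lines starting with ``#`` are skipped. Missing ids default to the
    1-based line position.
    """
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else str(i)
            out.append((cid, parse_structure(smiles)))
    return out


def parse_sdf(path) -> list[tuple[str, Chem.Mol]]:
    """Read an SDF (V2000) file; ids from the title line or record index."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier, 1):
        if mol is None:
            raise ParseError(f"record {i} of {path}", "unparseable SDF record")
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else str(i)
        out.append((cid, mol))
    return out


# ---------------------------------------------------------------------------
# individual descriptors

def count_het(mol: Chem.Mol) -> int:
    """Number of non-carbon atoms with hydrogens included.

    Defined as (total atom count including all hydrogens) minus (carbon
    count): water → 3, methane → 4.
    """
    molh = Chem.AddHs(mol)
    total = molh.GetNumAtoms()
    n_c = sum(1 for a in molh.GetAtoms() if a.GetAtomicNum() == 6)
    return total - n_c


_BOND_OVERLAP = 5.92       # Å³ removed per bond (any order)
_AROM_RING = 14.7          # Å³ removed per aromatic ring
_ALIPH_RING = 3.8          # Å³ removed per non-aromatic ring


def vdw_volume(mol: Chem.Mol) -> float:
    """Fast van der Waals volume (Å³) from Bondi sphere sums with bond and
    ring overlap corrections (the Zhao–Abraham–Zissimos estimate)."""
    pt = Chem.GetPeriodicTable()
    molh = Chem.AddHs(mol)
    vol = 0.0
    for atom in molh.GetAtoms():
        r = pt.GetRvdw(atom.GetAtomicNum())
        vol += 4.0 / 3.0 * math.pi * r ** 3
    n_bonds = molh.GetNumBonds()
    ri = mol.GetRingInfo()
    n_arom = n_aliph = 0
    for ring in ri.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            n_arom += 1
        else:
            n_aliph += 1
    return vol - _BOND_OVERLAP * n_bonds - _AROM_RING * n_arom - _ALIPH_RING * n_aliph


def _is_amide_cn(bond: Chem.Bond) -> bool:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for c, n in ((a, b), (b, a)):
        if c.GetAtomicNum() == 6 and n.GetAtomicNum() == 7:
            for nb_bond in c.GetBonds():
                other = nb_bond.GetOtherAtom(c)
                if other.GetAtomicNum() == 8 and nb_bond.GetBondType() == Chem.BondType.DOUBLE:
                    return True
    return False


def count_rotatable_bonds(mol: Chem.Mol) -> int:
    """Rotatable bonds under the pinned convention: single, non-ring bonds
    between two heavy atoms each of heavy-degree ≥ 2, amide C–N excluded."""
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() < 2 or b.GetDegree() < 2:
            continue
        if _is_amide_cn(bond):
            continue
        n += 1
    return n


def compute_structural_descriptors(mol: Chem.Mol, compound_id: str = "") -> DescriptorVector:
    """Fill every structure-derived field of a :class:`DescriptorVector`.

    Externally supplied ADMET fields are left unset. Flex is reported as 0
    when there are no rigid bonds (tiny molecules must not crash table
    processing). The Lipinski flag uses the Crippen logP estimate.
    """
    mw = Descriptors.MolWt(mol)
    vol = vdw_volume(mol)
    n_rot = count_rotatable_bonds(mol)
    n_heavy_bonds = mol.GetNumBonds()
    n_rig = n_heavy_bonds - n_rot
    # symmetrized SSSR: plain SSSR ring counts are atom-order dependent in
    # symmetric cages, which would break permutation invariance
    rings = [tuple(r) for r in Chem.GetSymmSSSR(mol)]
    logp = Crippen.MolLogP(mol)
    d = DescriptorVector(
        compound_id=compound_id,
        MW=mw,
        Vol=vol,
        Dense=mw / vol if vol > 0 else None,
        nHA=float(_Lip.NumHAcceptors(mol)),
        nHD=float(_Lip.NumHDonors(mol)),
        nRot=float(n_rot),
        nRing=float(len(rings)),
        MaxRing=float(max((len(r) for r in rings), default=0)),
        nHet=float(count_het(mol)),
        nRig=float(n_rig),
        Flex=n_rot / n_rig if n_rig > 0 else 0.0,
        Fsp3=rdMolDescriptors.CalcFractionCSP3(mol),
        TPSA=Descriptors.TPSA(mol),
        logP=logp,
    )
    d.Lipinski = float(lipinski_flag(d))
    return d


def lipinski_flag(d: DescriptorVector, ro5_max_violations: int = 0) -> int:
    """Binary rule-of-five drug-likeness flag.

    Criteria: MW ≤ 500, logP ≤ 5, nHD ≤ 5, nHA ≤ 10. The default policy is
    strict (no violation allowed); ``ro5_max_violations=1`` switches to the
    common ≤ 1-violation variant.
    """
    mw, logp, nhd, nha = d.require("MW", "logP", "nHD", "nHA")
    violations = sum([mw > 500, logp > 5, nhd > 5, nha > 10])
    return 1 if violations <= ro5_max_violations else 0
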