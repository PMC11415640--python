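"""Molecular structures, element compositions and ion m/z arithmetic.

All mass arithmetic in the package runs through :class:`ElementComposition`,
a fixed-order count vector over the supported element set {C, H, N, O, P, S}.
Ion m/z values follow the electron-inclusive convention: the m/z of a singly
charged ion is the sum of its atomic monoisotopic masses minus ``charge``
times the electron mass, so a protonated molecule sits at ``M + 1.007276``
and a deprotonated one at ``M - 1.007276``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import AllChem  # noqa: F401  (registers descriptors)

from .errors import (
    ConfigurationError,
    InfeasibleLossError,
    ParseError,
    UnsupportedElementError,
)

RDLogger.DisableLog("rdApp.*")

#: Supported elements, fixed order used by every composition vector.
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "P", "S")

_INDEX = {e: i for i, e in enumerate(ELEMENTS)}

#: Monoisotopic atomic masses (Da), IUPAC values rounded to 6 decimals.
#: Vendored so results are bit-stable across platforms.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
}

#: Electron rest mass in Da.
ELECTRON_MASS: float = 0.000549

#: Proton mass in Da (H minus one electron); the ±H adduct shift.
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

#: Atomic numbers, used for electron-parity (radical) bookkeeping.
_ATOMIC_NUMBER = {"C": 6, "H": 1, "N": 7, "O": 8, "P": 15, "S": 16}

_MASS_VECTOR = tuple(MONOISOTOPIC_MASS[e] for e in ELEMENTS)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementComposition:
    """Element -> count map over C,H,N,O,P,S plus a charge state.

    ``counts`` is a tuple aligned with :data:`ELEMENTS`.  Instances are
    immutable and hashable, so they can key dictionaries (fragment
    deduplication, knowledge tables).
    """

    counts: tuple[int, ...] = (0, 0, 0, 0, 0, 0)
    charge: int = 0
    radical: bool = False

    def __post_init__(self):
        if len(self.counts) != len(ELEMENTS):
            raise ValueError("counts must have one entry per supported element")
        if any(c < 0 for c in self.counts):
            raise InfeasibleLossError(f"negative element count in {self.counts}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dict(cls, counts: dict[str, int], charge: int = 0,
                  radical: bool = False) -> "ElementComposition":
        vec = [0] * len(ELEMENTS)
        for sym, n in counts.items():
            if sym not in _INDEX:
                raise UnsupportedElementError(sym)
            vec[_INDEX[sym]] = int(n)
        return cls(tuple(vec), charge, radical)

    @classmethod
    def from_formula(cls, formula: str, charge: int = 0) -> "ElementComposition":
        """Parse a molecular formula string such as ``"C9H15NO7"``."""
        vec = [0] * len(ELEMENTS)
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ParseError(f"cannot parse formula {formula!r}")
            pos = m.end()
            sym, digits = m.groups()
            if sym not in _INDEX:
                raise UnsupportedElementError(sym)
            vec[_INDEX[sym]] += int(digits) if digits else 1
        if pos != len(formula) or pos == 0:
            raise ParseError(f"cannot parse formula {formula!r}")
        return cls(tuple(vec), charge)

    # -- accessors ---------------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self.counts[_INDEX[element]]

    def as_dict(self) -> dict[str, int]:
        return {e: c for e, c in zip(ELEMENTS, self.counts) if c}

    @property
    def is_empty(self) -> bool:
        return not any(self.counts)

    @property
    def carbon_only(self) -> bool:
        """True when the composition contains no heteroatom (C/H only)."""
        return (self["C"] + self["H"]) > 0 and not (
            self["N"] or self["O"] or self["P"] or self["S"]
        )

    @property
    def electron_count(self) -> int:
        return sum(_ATOMIC_NUMBER[e] * c for e, c in zip(ELEMENTS, self.counts)) - self.charge

    @property
    def odd_electron(self) -> bool:
        return self.electron_count % 2 == 1

    def formula(self) -> str:
        """Hill-style formula string (C, H first, then alphabetical)."""
        order = ("C", "H", "N", "O", "P", "S")
        parts = []
        for e in order:
            c = self[e]
            if c == 1:
                parts.append(e)
            elif c > 1:
                parts.append(f"{e}{c}")
        return "".join(parts) or "[]"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        return ElementComposition(
            tuple(a + b for a, b in zip(self.counts, other.counts)),
            self.charge + other.charge,
        )

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        diff = tuple(a - b for a, b in zip(self.counts, other.counts))
        if any(d < 0 for d in diff):
            raise InfeasibleLossError(
                f"cannot subtract {other.formula()} from {self.formula()}"
            )
        return ElementComposition(diff, self.charge - other.charge)

    def add_hydrogen(self, n: int) -> "ElementComposition":
        """Return a copy with the hydrogen count shifted by ``n`` (may raise)."""
        vec = list(self.counts)
        vec[_INDEX["H"]] += n
        if vec[_INDEX["H"]] < 0:
            raise InfeasibleLossError("hydrogen count would become negative")
        return replace(self, counts=tuple(vec))

    def with_charge(self, charge: int) -> "ElementComposition":
        return replace(self, charge=charge)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        q = {1: "+", -1: "-", 0: ""}.get(self.charge, f"{self.charge:+d}")
        return self.formula() + q


def composition_subtract(a: ElementComposition, b: ElementComposition) -> ElementComposition:
    """Elementwise difference ``a - b``; raises :class:`InfeasibleLossError`."""
    return a - b


def monoisotopic_mass(composition: ElementComposition) -> float:
    """Monoisotopic mass (Da) of a composition.

    For charged compositions the electron mass is subtracted per positive
    charge (and added per negative charge), so the value is directly the
    m/z of a singly charged ion.
    """
    m = sum(c * w for c, w in zip(composition.counts, _MASS_VECTOR))
    return m - composition.charge * ELECTRON_MASS


# ---------------------------------------------------------------------------
# Adducts


@dataclass(frozen=True)
class AdductType:
    """A supported ESI adduct: ``m/z = multiplicity * M + mass_delta``."""

    name: str
    mode: str  # "positive" | "negative"
    multiplicity: int
    mass_delta: float
    charge: int
    #: net hydrogen-count change carried by the charged species (for the
    #: fragmenter's H bookkeeping); None when the adduct attaches a non-H
    #: species (Na, K, NH4, Cl, FA) that the fragmenter does not follow.
    hydrogen_delta: int | None = None


def _comp_mass(formula: str) -> float:
    return monoisotopic_mass(ElementComposition.from_formula(formula))


_H2O = _comp_mass("H2O")
_FA = _comp_mass("CH2O2")  # formic acid
_NH4 = _comp_mass("NH4")
_NA = 22.989770
_K = 38.963707
_CL = 34.968853

ADDUCTS: dict[str, AdductType] = {
    a.name: a
    for a in [
        AdductType("[M+H]+", "positive", 1, PROTON_MASS, +1, hydrogen_delta=+1),
        AdductType("[M-H2O+H]+", "positive", 1, PROTON_MASS - _H2O, +1),
        AdductType("[M+Na]+", "positive", 1, _NA - ELECTRON_MASS, +1),
        AdductType("[M+K]+", "positive", 1, _K - ELECTRON_MASS, +1),
        AdductType("[M+NH4]+", "positive", 1, _NH4 - ELECTRON_MASS, +1),
        AdductType("[M-H]-", "negative", 1, -PROTON_MASS, -1, hydrogen_delta=-1),
        AdductType("[M+FA-H]-", "negative", 1, _FA - PROTON_MASS, -1),
        AdductType("[2M-H]-", "negative", 2, -PROTON_MASS, -1, hydrogen_delta=-1),
        AdductType("[M+Cl]-", "negative", 1, _CL + ELECTRON_MASS, -1),
    ]
}


def get_adduct(name: str) -> AdductType:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown adduct {name!r}; supported: {sorted(ADDUCTS)}"
        ) from None


def adducts_for_mode(mode: str) -> list[AdductType]:
    return [a for a in ADDUCTS.values() if a.mode == mode]


def ion_mz(neutral_mass: float, adduct: AdductType | str) -> float:
    """Theoretical ion m/z of a neutral mass under an adduct hypothesis."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if neutral_mass <= 0:
        raise ConfigurationError("neutral mass must be positive")
    return adduct.multiplicity * neutral_mass + adduct.mass_delta


def neutral_mass_from_mz(mz: float, adduct: AdductType | str) -> float:
    """Invert :func:`ion_mz` to recover the neutral monoisotopic mass."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return (mz - adduct.mass_delta) / adduct.multiplicity


# ---------------------------------------------------------------------------
# Molecules


@dataclass(frozen=True)
class MoleculeMeta:
    source_id: str = ""
    annotation_level: int = 0  # 0..5; 0 = unknown provenance (worst meta score)
    chemical_class: str | None = None

    def __post_init__(self):
        if not (0 <= self.annotation_level <= 5):
            raise ValueError("annotation_level must be in 0..5")


@dataclass(frozen=True)
class Molecule:
    """A parsed neutral structure plus derived mass data."""

    smiles: str
    canonical_smiles: str
    composition: ElementComposition
    monoisotopic_mass: float
    meta: MoleculeMeta = field(default_factory=MoleculeMeta)

    @property
    def rdmol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_smiles)


def _composition_from_rdmol(mol: Chem.Mol) -> ElementComposition:
    counts = {e: 0 for e in ELEMENTS}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in counts:
            raise UnsupportedElementError(sym)
        counts[sym] += 1
        counts["H"] += atom.GetTotalNumHs()
    return ElementComposition.from_dict(counts)


def parse_molecule(smiles: str, meta: MoleculeMeta | dict | None = None) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Raises :class:`ParseError` for unparseable input and
    :class:`UnsupportedElementError` for elements outside C,H,N,O,P,S.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    comp = _composition_from_rdmol(mol)
    if isinstance(meta, dict):
        meta = MoleculeMeta(**meta)
    return Molecule(
        smiles=smiles,
        canonical_smiles=Chem.MolToSmiles(mol),
        composition=comp,
        monoisotopic_mass=monoisotopic_mass(comp),
        meta=meta or MoleculeMeta(),
    )


# ---------------------------------------------------------------------------
# Molecule tables (TSV: smiles, id, level, class)


def read_molecule_table(path) -> list[Molecule]:
    """Read molecules from a TSV file: ``smiles<TAB>id<TAB>level<TAB>class``.

    Missing trailing fields default to annotation level 0 / unknown class.
    Unparseable rows are skipped.
    """
    out: list[Molecule] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            source_id = parts[1] if len(parts) > 1 else ""
            level = int(parts[2]) if len(parts) > 2 and parts[2] else 0
            cls = parts[3] if len(parts) > 3 and parts[3] else None
            try:
                out.append(
                    parse_molecule(
                        smiles,
                        MoleculeMeta(source_id, level, cls),
                    )
                )
            except (ParseError, UnsupportedElementError):
                continue
    return out


def write_molecule_table(molecules, path) -> None:
    with open(path, "w") as fh:
        for m in molecules:
            fh.write(
                "\t".join(
                    [
                        m.canonical_smiles,
                        m.meta.source_id,
                        str(m.meta.annotation_level),
                        m.meta.chemical_class or "",
                    ]
                )
                + "\n"
            )
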