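"""Negative-mode MS/MS identification arithmetic for flavonoids.

Flavones and flavanones extracted from petal tissue are observed in
electrospray ionization (negative mode) as singly deprotonated ions
[M-H]-.  Glycosides shed their sugar/acyl residues as neutral losses
(e.g. a glucuronyl residue, 176 Da), and the flavonoid C-ring undergoes
a characteristic retro-Diels-Alder (RDA) cleavage across the O1-C2 and
C3-C4 bonds, yielding complementary A-ring and B-ring fragments.  All
m/z arithmetic here is on the nominal (integer, unit-resolution) scale,
the scale on which such spectra are reported; a monoisotopic variant is
provided for high-resolution inputs.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .errors import ChemistryError, FormatError, UsageError

#: Integer atomic masses for the nominal scale.
NOMINAL_MASS = {"C": 12, "H": 1, "O": 16, "N": 14, "S": 32, "P": 31}

#: Monoisotopic atomic masses (most abundant isotope).
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "N": 14.0030740048,
    "S": 31.97207100,
    "P": 30.97376163,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element-count vector with integer counts, e.g. apigenin C15H10O5."""

    counts: tuple[tuple[str, int], ...]
    label: str = ""

    @staticmethod
    def from_counts(counts: dict[str, int], label: str = "") -> "MolecularFormula":
        cleaned = {e: int(n) for e, n in counts.items() if n != 0}
        for element, n in cleaned.items():
            if element not in NOMINAL_MASS:
                raise ChemistryError(f"unknown element symbol {element!r}")
            if n < 0:
                raise ChemistryError(f"negative count for element {element}")
        if not cleaned:
            raise ChemistryError("formula must contain at least one atom")
        order = ["C", "H"] + sorted(e for e in cleaned if e not in ("C", "H"))
        return MolecularFormula(
            tuple((e, cleaned[e]) for e in order if e in cleaned), label
        )

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def count(self, element: str) -> int:
        return self.as_dict().get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for e, n in other.counts:
            merged[e] = merged.get(e, 0) + n
        return MolecularFormula.from_counts(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for e, n in other.counts:
            merged[e] = merged.get(e, 0) - n
        if any(v < 0 for v in merged.values()):
            raise ChemistryError(
                f"cannot subtract {other} from {self}: negative element count"
            )
        return MolecularFormula.from_counts(merged)

    def contains(self, other: "MolecularFormula") -> bool:
        mine = self.as_dict()
        return all(mine.get(e, 0) >= n for e, n in other.counts)

    def __str__(self) -> str:
        return "".join(
            f"{e}{n if n != 1 else ''}" for e, n in self.counts
        )


def parse_formula(text: str, label: str = "") -> MolecularFormula:
    """Parse a Hill-notation element-count string, e.g. ``"C15H10O5"``."""
    if not text or not text.strip():
        raise FormatError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormatError(f"malformed formula {text!r} at offset {pos}")
        if not match.group(0):
            break
        element, digits = match.group(1), match.group(2)
        if element not in NOMINAL_MASS:
            raise FormatError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormatError(f"malformed formula {text!r} at offset {pos}")
    return MolecularFormula.from_counts(counts, label or text)


def nominal_mass(formula: MolecularFormula) -> int:
    """Nominal neutral mass in Da (C=12, H=1, O=16)."""
    return sum(NOMINAL_MASS[e] * n for e, n in formula.counts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.counts)


def deprotonated_mz(formula: MolecularFormula, *, monoisotopic: bool = False) -> float:
    """m/z of the singly deprotonated [M-H]- ion on the nominal scale.

    On the nominal scale this is simply the neutral mass minus 1; the
    monoisotopic variant subtracts one proton mass.
    """
    if formula.count("H") < 1:
        raise ChemistryError(f"{formula} has no hydrogen to lose")
    if monoisotopic:
        return monoisotopic_mass(formula) - MONOISOTOPIC_MASS["H"]
    return nominal_mass(formula) - 1


@dataclass(frozen=True)
class Residue:
    """A glycosyl/acyl residue observed as a neutral loss."""

    name: str
    formula: MolecularFormula

    @property
    def mass(self) -> int:
        return nominal_mass(self.formula)


def default_residue_table() -> dict[str, Residue]:
    """Common flavonoid neutral-loss residues (nominal masses).

    Losses correspond to the dehydrated residue, i.e. sugar minus water:
    glucuronyl 176, hexosyl 162, deoxyhexosyl 146, pentosyl 132,
    malonyl 86.
    """
    entries = [
        ("glucuronyl", "C6H8O6"),
        ("hexosyl", "C6H10O5"),
        ("deoxyhexosyl", "C6H10O4"),
        ("pentosyl", "C5H8O4"),
        ("malonyl", "C3H2O3"),
    ]
    return {name: Residue(name, parse_formula(f, name)) for name, f in entries}


def neutral_loss(
    parent_mz: float,
    fragment_mz: float,
    table: dict[str, Residue] | None = None,
    tolerance: float = 0.0,
) -> list[Residue]:
    """Residues whose mass matches ``parent_mz - fragment_mz`` within tolerance.

    The match depends only on the mass difference, so it is invariant to
    adding a constant to both m/z values.  An empty list means no single
    residue explains the loss.
    """
    if parent_mz <= fragment_mz:
        raise UsageError(
            f"parent m/z ({parent_mz}) must exceed fragment m/z ({fragment_mz})"
        )
    table = table if table is not None else default_residue_table()
    diff = parent_mz - fragment_mz
    return [r for r in table.values() if abs(r.mass - diff) <= tolerance]


@dataclass(frozen=True)
class CleavageScheme:
    """Atom partition of an aglycone skeleton into two fragment formulas.

    The 1,3-RDA scheme for flavanones cleaves the C-ring between O1-C2
    and C3-C4: the A side keeps ring A plus O1 and the C4 carbonyl
    (C7H4O4 for an unsubstituted-beyond-5,7-dihydroxy A ring), the B
    side keeps ring B plus C2 and C3 (C8H8O for a 4'-hydroxy B ring).
    Extra hydroxylation of the aglycone relative to the reference
    skeleton is assigned to ``extra_side`` (B by default, where B-ring
    hydroxylation varies between naringenin and eriodictyol).
    """

    name: str
    a_side: MolecularFormula
    b_side: MolecularFormula
    extra_side: str = "B"

    @property
    def parent(self) -> MolecularFormula:
        return self.a_side + self.b_side


def flavanone_13_rda() -> CleavageScheme:
    """The 1,3 retro-Diels-Alder scheme for flavanones (naringenin skeleton)."""
    return CleavageScheme(
        name="1,3-RDA (flavanone)",
        a_side=parse_formula("C7H4O4", "A-ring fragment"),
        b_side=parse_formula("C8H8O", "B-ring fragment"),
    )


@dataclass(frozen=True)
class RdaFragments:
    a_neutral: MolecularFormula
    b_neutral: MolecularFormula
    a_ion_mz: int
    b_ion_mz: int


def rda_fragments(
    aglycone: MolecularFormula, scheme: CleavageScheme | None = None
) -> RdaFragments:
    """Complementary RDA fragment pair for an aglycone under a scheme.

    The two neutral-side formulas always sum, element-wise, to the
    parent aglycone; each ion m/z is the deprotonated nominal mass of
    its side (both charge-retention options are computed, matching the
    ions observed in negative mode).
    """
    scheme = scheme if scheme is not None else flavanone_13_rda()
    parent = scheme.parent
    if not aglycone.contains(parent):
        raise ChemistryError(
            f"aglycone {aglycone} is inconsistent with scheme skeleton {parent}"
        )
    extra = aglycone.as_dict()
    for e, n in parent.counts:
        extra[e] = extra.get(e, 0) - n
    extra = {e: n for e, n in extra.items() if n}
    a_side, b_side = scheme.a_side, scheme.b_side
    if extra:
        delta = MolecularFormula.from_counts(extra)
        if scheme.extra_side == "A":
            a_side = a_side + delta
        else:
            b_side = b_side + delta
    return RdaFragments(
        a_neutral=a_side,
        b_neutral=b_side,
        a_ion_mz=int(deprotonated_mz(a_side)),
        b_ion_mz=int(deprotonated_mz(b_side)),
    )


@dataclass(frozen=True)
class LibrarySpecies:
    """A candidate compound: an aglycone plus attached residues."""

    name: str
    aglycone: MolecularFormula
    residues: tuple[str, ...] = ()

    def full_formula(self, table: dict[str, Residue]) -> MolecularFormula:
        f = self.aglycone
        for rname in self.residues:
            f = f + table[rname].formula
        return f


@dataclass(frozen=True)
class FragmentAssignment:
    observed_mz: float
    species: str | None
    formula: MolecularFormula | None
    ion_type: str | None  # "[M-H]-", "M", "RDA-A-", "RDA-B-"
    rule: str | None  # "molecular ion" | "neutral loss" | "RDA"
    mass_error: float | None
    detail: str = ""

    @property
    def assigned(self) -> bool:
        return self.rule is not None


_RULE_PRECEDENCE = {"molecular ion": 0, "neutral loss": 1, "RDA": 2}


def _residue_combos(table: dict[str, Residue], max_residues: int = 2):
    names = sorted(table)
    for k in range(1, max_residues + 1):
        for combo in itertools.combinations_with_replacement(names, k):
            yield combo, sum(table[n].mass for n in combo)


def annotate_spectrum(
    peaks: list[float],
    library: list[LibrarySpecies],
    table: dict[str, Residue] | None = None,
    schemes: list[CleavageScheme] | None = None,
    tolerance: float = 0.0,
) -> list[FragmentAssignment]:
    """Assign each peak to a molecular ion, a neutral-loss product, or an
    RDA fragment of a library species.

    Rules are tried in precedence order: (i) molecular species (the
    deprotonated ion of the full glycoside, or its neutral nominal mass
    as printed on unit-resolution spectra); (ii) the species minus
    combinations of up to two residues from the table; (iii) RDA
    fragments of the aglycone.  Unmatched peaks are reported with
    ``rule=None``.  Output is sorted by m/z, then rule precedence.
    """
    if not peaks:
        raise UsageError("peak list is empty")
    if not library:
        raise UsageError("compound library is empty")
    table = table if table is not None else default_residue_table()
    schemes = schemes if schemes is not None else [flavanone_13_rda()]

    # Candidate (mass, assignment-template) list, in precedence order.
    candidates: list[tuple[float, int, FragmentAssignment]] = []
    for sp in library:
        full = sp.full_formula(table)
        ion = deprotonated_mz(full)
        candidates.append(
            (ion, 0, FragmentAssignment(0, sp.name, full, "[M-H]-", "molecular ion", None))
        )
        candidates.append(
            (nominal_mass(full), 0,
             FragmentAssignment(0, sp.name, full, "M", "molecular ion", None))
        )
        for combo, loss in _residue_combos(table):
            candidates.append(
                (ion - loss, 1,
                 FragmentAssignment(0, sp.name, None, "[M-H]-", "neutral loss", None,
                                    detail="-" + "-".join(combo)))
            )
        for scheme in schemes:
            if not sp.aglycone.contains(scheme.parent):
                continue
            frags = rda_fragments(sp.aglycone, scheme)
            candidates.append(
                (frags.a_ion_mz, 2,
                 FragmentAssignment(0, sp.name, frags.a_neutral, "RDA-A-", "RDA",
                                    None, detail=scheme.name))
            )
            candidates.append(
                (frags.b_ion_mz, 2,
                 FragmentAssignment(0, sp.name, frags.b_neutral, "RDA-B-", "RDA",
                                    None, detail=scheme.name))
            )

    out: list[FragmentAssignment] = []
    for mz in sorted(peaks):
        best = None
        for cand_mz, prec, template in candidates:
            err = mz - cand_mz
            if abs(err) <= tolerance:
                key = (prec, abs(err))
                if best is None or key < best[0]:
                    best = (key, template, err)
        if best is None:
            out.append(FragmentAssignment(mz, None, None, None, None, None))
        else:
            _, template, err = best
            out.append(
                FragmentAssignment(
                    mz, template.species, template.formula, template.ion_type,
                    template.rule, err, template.detail,
                )
            )
    return out
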