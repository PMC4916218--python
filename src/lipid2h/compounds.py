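"""Fatty-acid nomenclature and hydrogen accounting.

Parses labels like ``n-C16:1 Δ9`` or ``a-C17:0`` into structured identities
and derives the hydrogen inventories needed for the methyl-ester mass-balance
correction: a saturated mono-carboxylic acid CnH(2n)O₂ carries 2n hydrogen
atoms, of which only the carboxyl O–H is exchangeable (and is replaced by a
methyl group, +3 H, on derivatization to the FAME).  Each double bond removes
two hydrogens.  Branch points move hydrogens around but never change counts.

Branched chains start from amino-acid-derived acyl-CoA primers rather than
acetyl-CoA: 2-methylbutyryl-CoA (from isoleucine, 9 H) for odd anteiso
chains, isovaleryl-CoA (from leucine, 9 H) for odd iso chains and
isobutyryl-CoA (from valine, 7 H) for even iso chains.  The primer H counts
are carried so the pool of primer-derived hydrogen can be isolated by mass
balance downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .types import DomainError


class Branching(str, Enum):
    NORMAL = "normal"
    ISO = "iso"
    ANTEISO = "anteiso"


_PREFIX = {
    "n": Branching.NORMAL,
    "i": Branching.ISO,
    "iso": Branching.ISO,
    "a": Branching.ANTEISO,
    "ai": Branching.ANTEISO,
    "anteiso": Branching.ANTEISO,
}
_PREFIX_CANON = {Branching.NORMAL: "n", Branching.ISO: "i", Branching.ANTEISO: "a"}

_LABEL_RE = re.compile(
    r"""^\s*
    (?:(?P<prefix>n|i|iso|a|ai|anteiso)-)?
    C(?P<carbon>\d+)
    :(?P<dbonds>\d+)
    (?:\s*(?:Δ|D|d)(?P<dbpos>\d+))?
    \s*$""",
    re.VERBOSE,
)


class LabelParseError(ValueError):
    """Raised when a lipid label does not match the grammar."""


@dataclass(frozen=True)
class FattyAcid:
    """A parsed fatty-acid identity.

    ``db_position`` is the Δ-position of the (single) double bond when known;
    chromatographically resolved but positionally unassigned monounsaturates
    keep ``db_position=None``.
    """

    n_carbon: int
    branching: Branching = Branching.NORMAL
    n_double_bonds: int = 0
    db_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_carbon < 4:
            raise DomainError(f"chain of {self.n_carbon} carbons is below the C4 minimum")
        if self.n_double_bonds < 0:
            raise DomainError("double-bond count cannot be negative")
        max_db = (self.n_carbon - 2) // 2
        if self.n_double_bonds > max_db:
            raise DomainError(
                f"C{self.n_carbon} chain cannot host {self.n_double_bonds} double bonds "
                f"(max {max_db})"
            )

    @property
    def label(self) -> str:
        """Canonical text label, e.g. ``a-C17:1 Δ9``."""
        base = f"{_PREFIX_CANON[self.branching]}-C{self.n_carbon}:{self.n_double_bonds}"
        if self.db_position is not None:
            base += f" Δ{self.db_position}"
        return base

    @property
    def is_branched(self) -> bool:
        return self.branching is not Branching.NORMAL


def parse_lipid_label(label: str) -> FattyAcid:
    """Parse a fatty-acid label into a :class:`FattyAcid`.

    Grammar: optional branching prefix (``n-``, ``i-``/``iso-``,
    ``a-``/``ai-``/``anteiso-``; default normal), ``C<carbons>:<double bonds>``,
    optional Δ-position (``Δ9``, ``D9`` or ``d9``).  Reparsing the canonical
    label of the result is idempotent.
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise LabelParseError(f"cannot parse lipid label {label!r}")
    branching = _PREFIX[m.group("prefix")] if m.group("prefix") else Branching.NORMAL
    dbpos = int(m.group("dbpos")) if m.group("dbpos") else None
    try:
        return FattyAcid(
            n_carbon=int(m.group("carbon")),
            branching=branching,
            n_double_bonds=int(m.group("dbonds")),
            db_position=dbpos,
        )
    except DomainError as exc:
        raise LabelParseError(f"invalid lipid label {label!r}: {exc}") from exc


@dataclass(frozen=True)
class HydrogenInventory:
    """Hydrogen bookkeeping for one acid and its methyl ester(s).

    Invariants: ``h_fame == h_nonexch_acid + h_methyl_added`` and
    ``h_nonexch_acid == h_total_acid - n_carboxyl`` (one exchangeable O–H per
    acid group).
    """

    h_total_acid: int
    h_nonexch_acid: int
    h_methyl_added: int
    h_fame: int
    h_primer: int = 0

    def __post_init__(self) -> None:
        if self.h_fame != self.h_nonexch_acid + self.h_methyl_added:
            raise DomainError("h_fame must equal h_nonexch_acid + h_methyl_added")
        if self.h_primer > self.h_nonexch_acid:
            raise DomainError("primer hydrogen cannot exceed non-exchangeable hydrogen")


def _primer_hydrogen(fa: FattyAcid) -> int:
    # Acetyl-CoA primer (CH3CO-) for straight chains; amino-acid-derived
    # acyl-CoA primers for branched chains.
    if fa.branching is Branching.ANTEISO:
        return 9  # 2-methylbutyryl-CoA, from isoleucine
    if fa.branching is Branching.ISO:
        return 9 if fa.n_carbon % 2 == 1 else 7  # isovaleryl / isobutyryl
    return 3


def hydrogen_inventory(fa: FattyAcid) -> HydrogenInventory:
    """Hydrogen inventory of a mono-carboxylic fatty acid CnH(2n−2d)O₂.

    Branching does not change any count; each double bond removes 2 H.
    """
    h_total = 2 * fa.n_carbon - 2 * fa.n_double_bonds
    h_nonexch = h_total - 1
    return HydrogenInventory(
        h_total_acid=h_total,
        h_nonexch_acid=h_nonexch,
        h_methyl_added=3,
        h_fame=h_nonexch + 3,
        # very short or unsaturated chains cannot retain the primer's full
        # hydrogen complement; cap at what the molecule actually carries
        h_primer=min(_primer_hydrogen(fa), h_nonexch),
    )


def polyacid_inventory(n_carbon: int, n_H_total: int, n_carboxyl: int) -> HydrogenInventory:
    """Hydrogen inventory for an arbitrary (poly-)carboxylic acid.

    Used for derivatization standards that are not fatty acids, e.g. phthalic
    acid C₈H₆O₄ (two acid groups → 6 methyl H added on full esterification).
    """
    if n_carboxyl < 1:
        raise DomainError("a carboxylic acid needs at least one acid group")
    if n_H_total < n_carboxyl:
        raise DomainError(
            f"{n_H_total} total H cannot cover {n_carboxyl} exchangeable acid protons"
        )
    h_nonexch = n_H_total - n_carboxyl
    h_methyl = 3 * n_carboxyl
    return HydrogenInventory(
        h_total_acid=n_H_total,
        h_nonexch_acid=h_nonexch,
        h_methyl_added=h_methyl,
        h_fame=h_nonexch + h_methyl,
        h_primer=0,
    )


#: Fatty acids observed in the D. alaskensis G20 profiles (C14–C18, straight,
#: iso and anteiso, saturated and monounsaturated; Δ9 for the C16/C17 group,
#: Δ11 for the C18 group, unassigned for the two C17:1 peaks).
STUDY_FATTY_ACIDS: tuple[str, ...] = (
    "n-C14:0",
    "i-C15:0",
    "a-C15:0",
    "n-C15:0",
    "i-C16:1 Δ9",
    "i-C16:0",
    "n-C16:1 Δ9",
    "n-C16:0",
    "i-C17:1 Δ9",
    "a-C17:1 Δ9",
    "n-C17:1",
    "i-C17:0",
    "a-C17:0",
    "n-C17:0",
    "n-C18:1 Δ11",
    "i-C18:1 Δ11",
    "i-C18:0",
    "n-C18:0",
)

#: The co-injected quantitation / isotope reference compound.
COINJECTED_REFERENCE = "n-C24:0"


def compound_library() -> "pandas.DataFrame":  # noqa: F821 - forward to pandas
    """Tabulate hydrogen inventories for every study compound and standard.

    Returns a DataFrame mirroring the packaged ``compounds.csv``: one row per
    compound with chain description and derived H counts (free acid and FAME).
    """
    import pandas as pd

    rows = []
    for label in STUDY_FATTY_ACIDS + (COINJECTED_REFERENCE,):
        fa = parse_lipid_label(label)
        inv = hydrogen_inventory(fa)
        rows.append(
            {
                "compound": fa.label,
                "kind": "fatty_acid",
                "n_carbon": fa.n_carbon,
                "branching": fa.branching.value,
                "n_double_bonds": fa.n_double_bonds,
                "db_position": fa.db_position if fa.db_position is not None else "",
                "h_total_acid": inv.h_total_acid,
                "h_nonexch_acid": inv.h_nonexch_acid,
                "h_methyl_added": inv.h_methyl_added,
                "h_fame": inv.h_fame,
                "h_primer": inv.h_primer,
            }
        )
    # Derivatization isotope standards: myristic acid is n-C14:0; phthalic
    # acid (benzene-1,2-dicarboxylic, C8H6O4) is the diacid control.
    phthalic = polyacid_inventory(n_carbon=8, n_H_total=6, n_carboxyl=2)
    myristic = hydrogen_inventory(parse_lipid_label("n-C14:0"))
    for name, kind, inv in (
        ("myristic-acid", "isotope_standard", myristic),
        ("phthalic-acid", "isotope_standard", phthalic),
    ):
        rows.append(
            {
                "compound": name,
                "kind": kind,
                "n_carbon": 14 if name.startswith("myristic") else 8,
                "branching": "",
                "n_double_bonds": 0,
                "db_position": "",
                "h_total_acid": inv.h_total_acid,
                "h_nonexch_acid": inv.h_nonexch_acid,
                "h_methyl_added": inv.h_methyl_added,
                "h_fame": inv.h_fame,
                "h_primer": inv.h_primer,
            }
        )
    return pd.DataFrame(rows)


def load_compound_library() -> "pandas.DataFrame":  # noqa: F821
    """Load the packaged ``compounds.csv`` library."""
    import importlib.resources as resources

    import pandas as pd

    with resources.files("lipid2h").joinpath("data/compounds.csv").open() as fh:
        return pd.read_csv(fh, keep_default_na=False)
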