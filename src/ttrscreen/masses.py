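"""Average-mass arithmetic for intact proteins and point mutations.

Linear MALDI-TOF of whole proteins does not resolve isotope envelopes, so
all masses here are *average* masses (isotope-abundance-weighted).  The
module carries a versioned table of the 20 standard amino-acid residue
masses, the mature human transthyretin (TTR) chain, a parser for point
mutations in either ``Val30Met`` or ``V30M`` notation, and the theoretical
mass-shift catalogue used by the variant screen.

Mutation positions use mature-chain numbering: residue 1 is the first
residue of the secreted 127-residue protein (signal peptide removed), the
convention behind clinical labels such as Val30Met.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .errors import CatalogError, MutationParseError, ReferenceMismatchError

__all__ = [
    "AMINO_ACID_AVERAGE_MASSES",
    "WATER_AVERAGE_MASS",
    "RESOLVABILITY_THRESHOLD_DA",
    "MASS_TABLE_VERSION",
    "AminoAcidMassTable",
    "STANDARD_MASS_TABLE",
    "ProteinSequence",
    "TTR_MATURE",
    "WT_TTR_MONOMER_MASS",
    "TTR_VARIANT_LABELS",
    "PointMutation",
    "VariantCatalogEntry",
    "parse_mutation",
    "apply_mutation",
    "average_mass",
    "residue_delta",
    "is_resolvable",
    "build_catalog",
    "round_half_up",
]

#: Version tag for the residue-mass constants below.  Values are average
#: residue masses (Da) from the current IUPAC standard atomic weights,
#: stated to 4 decimals; a residue mass is the amino-acid mass minus one
#: water (the mass contributed inside a peptide chain).
MASS_TABLE_VERSION = "iupac-2021"

AMINO_ACID_AVERAGE_MASSES: Mapping[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

#: Average mass of one H2O (Da); added once per chain for the termini.
WATER_AVERAGE_MASS = 18.0153

#: Minimum |mass shift| (Da) the direct-MALDI screen can identify.
RESOLVABILITY_THRESHOLD_DA = 12.0

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention of printed shift tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AminoAcidMassTable:
    """The 20 standard average residue masses plus the terminal water mass."""

    residue_mass: Mapping[str, float] = field(
        default_factory=lambda: dict(AMINO_ACID_AVERAGE_MASSES)
    )
    water_mass: float = WATER_AVERAGE_MASS

    def __post_init__(self) -> None:
        keys = set(self.residue_mass)
        if keys != set(_ONE_TO_THREE):
            missing = set(_ONE_TO_THREE) - keys
            extra = keys - set(_ONE_TO_THREE)
            raise ValueError(
                f"mass table must hold exactly the 20 standard residues; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        if any(m <= 0 for m in self.residue_mass.values()):
            raise ValueError("all residue masses must be strictly positive")
        if min(self.residue_mass, key=self.residue_mass.get) != "G":
            raise ValueError("Gly must be the lightest residue")
        if max(self.residue_mass, key=self.residue_mass.get) != "W":
            raise ValueError("Trp must be the heaviest residue")
        if not 18.010 <= self.water_mass <= 18.020:
            raise ValueError(f"implausible water mass {self.water_mass}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.residue_mass[residue]
        except KeyError:
            raise KeyError(f"unknown residue code {residue!r}") from None


STANDARD_MASS_TABLE = AminoAcidMassTable()


@dataclass(frozen=True)
class ProteinSequence:
    """A one-letter protein sequence with an explicit numbering offset.

    ``numbering_offset`` is the position number of the first residue, so the
    mature TTR chain uses offset 1 and label positions map directly onto
    string indices as ``position - numbering_offset``.
    """

    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        bad = sorted(set(self.residues) - set(_ONE_TO_THREE))
        if bad:
            raise ValueError(f"sequence contains non-standard residues: {bad}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        idx = position - self.numbering_offset
        if not 0 <= idx < len(self.residues):
            raise IndexError(
                f"position {position} outside sequence "
                f"[{self.numbering_offset}, {self.numbering_offset + len(self.residues) - 1}]"
            )
        return self.residues[idx]


#: Mature human transthyretin chain, 127 residues, mature numbering 1-127
#: (the secreted protein; the 20-residue signal peptide is removed).
TTR_MATURE = ProteinSequence(
    "GPTGTGESKCPLMVKVLDAVRGSPAINVAVHVFRKAADDTWEPFASGKTSESGELHGLTT"
    "EEEFVEGIYKVEIDTKSYWKALGISPFHEHAEVVFTANDSGPRRYTIAALLSPYSYSTTA"
    "VVTNPKE",
    numbering_offset=1,
)

#: The 15 TTR variants of the reference screening cohort.
TTR_VARIANT_LABELS = (
    "Val28Ser", "Val28Met", "Val30Met", "Gly47Arg", "Thr49Ser", "Thr49Ile",
    "Gly53Glu", "Thr60Ala", "Glu61Lys", "Lys80Arg", "Gly83Arg", "Glu89Gln",
    "Ala97Gly", "Tyr114Ser", "Tyr114Cys",
)


@dataclass(frozen=True)
class PointMutation:
    """A single amino-acid substitution in mature-chain numbering."""

    wt_residue: str
    position: int
    mut_residue: str

    def __post_init__(self) -> None:
        for code in (self.wt_residue, self.mut_residue):
            if code not in _ONE_TO_THREE:
                raise MutationParseError(f"unknown residue code {code!r}")
        if self.wt_residue == self.mut_residue:
            raise MutationParseError(
                f"silent substitution {self.wt_residue}{self.position}{self.mut_residue}: "
                "wild-type and mutant residue must differ"
            )
        if self.position < 1:
            raise MutationParseError(f"position must be >= 1, got {self.position}")

    @property
    def label(self) -> str:
        """Canonical three-letter label, e.g. ``Val30Met``."""
        return (
            _ONE_TO_THREE[self.wt_residue]
            + str(self.position)
            + _ONE_TO_THREE[self.mut_residue]
        )

    def __str__(self) -> str:
        return self.label


_MUT_RE = re.compile(r"^([A-Za-z]{3}|[A-Z])(\d+)([A-Za-z]{3}|[A-Z])$")


def parse_mutation(text: str) -> PointMutation:
    """Parse ``Val30Met`` or ``V30M`` style substitution notation.

    Three-letter codes are case-insensitive in their tail letters
    (``VAL30MET`` parses); single letters must be upper case.
    """
    m = _MUT_RE.match(text.strip())
    if m is None:
        raise MutationParseError(f"cannot parse mutation {text!r}")
    wt_raw, pos, mut_raw = m.groups()

    def to_one(code: str) -> str:
        if len(code) == 1:
            if code not in _ONE_TO_THREE:
                raise MutationParseError(f"unknown residue code {code!r} in {text!r}")
            return code
        try:
            return _THREE_TO_ONE[code.capitalize()]
        except KeyError:
            raise MutationParseError(
                f"unknown residue code {code!r} in {text!r}"
            ) from None

    return PointMutation(to_one(wt_raw), int(pos), to_one(mut_raw))


def apply_mutation(seq: ProteinSequence, mut: PointMutation) -> ProteinSequence:
    """Return a copy of ``seq`` carrying the substitution.

    Raises :class:`ReferenceMismatchError` if the sequence does not hold the
    stated wild-type residue at the mutation position.
    """
    found = seq.residue_at(mut.position)
    if found != mut.wt_residue:
        raise ReferenceMismatchError(
            f"{mut.label}: expected {mut.wt_residue} at position {mut.position}, "
            f"reference has {found}"
        )
    idx = mut.position - seq.numbering_offset
    residues = seq.residues[:idx] + mut.mut_residue + seq.residues[idx + 1 :]
    return replace(seq, residues=residues)


def average_mass(
    seq: ProteinSequence, table: AminoAcidMassTable = STANDARD_MASS_TABLE
) -> float:
    """Average molecular mass (Da) of the neutral chain: sum of residue masses plus one water."""
    return sum(table[r] for r in seq.residues) + table.water_mass


#: Average mass of the reduced wild-type TTR monomer (the analyte species:
#: DTT reduction leaves the apo-monomer with a free Cys10 thiol).
WT_TTR_MONOMER_MASS = average_mass(TTR_MATURE)


def residue_delta(
    mut: PointMutation, table: AminoAcidMassTable = STANDARD_MASS_TABLE
) -> float:
    """Signed theoretical mass shift (Da) of the substitution: mutant minus wild-type residue mass."""
    return table[mut.mut_residue] - table[mut.wt_residue]


def is_resolvable(delta: float, threshold: float = RESOLVABILITY_THRESHOLD_DA) -> bool:
    """Whether a mass shift is large enough to show a separate variant peak.

    Inclusive at the threshold: a 12.0-Da shift counts as resolvable, matching
    the empirical minimum identifiable difference of the direct-MALDI screen.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return abs(delta) >= threshold


@dataclass(frozen=True)
class VariantCatalogEntry:
    """A catalogued substitution with its theoretical shift and resolvability flag."""

    mutation: PointMutation
    delta_mass: float
    resolvable: bool

    @property
    def label(self) -> str:
        return self.mutation.label


def build_catalog(
    mutations: Iterable[str | PointMutation],
    table: AminoAcidMassTable = STANDARD_MASS_TABLE,
    threshold: float = RESOLVABILITY_THRESHOLD_DA,
    reference: ProteinSequence = TTR_MATURE,
) -> list[VariantCatalogEntry]:
    """Build the theoretical-shift catalogue for a list of mutation labels.

    Entries are validated against the reference sequence, de-duplicated on
    the canonical label, and sorted by position (then label).
    """
    seen: dict[str, VariantCatalogEntry] = {}
    for item in mutations:
        try:
            mut = item if isinstance(item, PointMutation) else parse_mutation(item)
            apply_mutation(reference, mut)  # validates the WT residue
        except (MutationParseError, ReferenceMismatchError, IndexError) as exc:
            raise CatalogError(f"invalid catalogue entry {item!r}: {exc}") from exc
        if mut.label in seen:
            continue
        delta = residue_delta(mut, table)
        seen[mut.label] = VariantCatalogEntry(
            mutation=mut, delta_mass=delta, resolvable=is_resolvable(delta, threshold)
        )
    return sorted(seen.values(), key=lambda e: (e.mutation.position, e.label))


def default_catalog(**kwargs) -> list[VariantCatalogEntry]:
    """The 15-variant TTR screening catalogue with default settings."""
    return build_catalog(TTR_VARIANT_LABELS, **kwargs)
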