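"""Display-library schemes: flanking signatures, codon constraints, translation.

A phage-display library presents a random k-mer peptide whose coding insert sits
between fixed vector sequence. In the sequencing read, the insert is bounded by
short nucleotide signatures (for the NEB Ph.D. libraries: ``TCT`` on the 5' side
and ``GGAGGTGGA`` on the 3' side). The libraries are synthesised with degenerate
NNK codons — any base at positions 1–2, G or T at position 3 — which encode all
20 amino acids while excluding the TAA and TGA stop codons. The amber stop TAG
*is* an NNK codon; because these libraries are propagated in an amber-suppressor
(supE) host, TAG is read through as glutamine, so by default it translates to Q
here rather than terminating the peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable


class SelPepError(Exception):
    """Base class for errors raised by this package."""


class InvalidSchemeError(SelPepError, ValueError):
    """A library scheme violates its own constraints."""


_DNA = frozenset("ACGT")

#: IUPAC degenerate nucleotide codes, used for per-position codon constraints.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Constraint label meaning "any codon is a valid library member".
UNCONSTRAINED = "unconstrained"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # {"TAA", "TAG", "TGA"}
AMBER = "TAG"


def _validate_dna(s: str, what: str) -> None:
    if not s or not set(s) <= _DNA:
        raise InvalidSchemeError(f"{what} must be a non-empty A/C/G/T string, got {s!r}")


def _validate_constraint(pattern: str) -> None:
    if pattern == UNCONSTRAINED:
        return
    if len(pattern) != 3 or not all(c in IUPAC for c in pattern.upper()):
        raise InvalidSchemeError(
            f"codon constraint must be a 3-letter IUPAC pattern or {UNCONSTRAINED!r}, "
            f"got {pattern!r}"
        )


@dataclass(frozen=True)
class LibraryScheme:
    """Geometry and codon rules for one display library.

    Parameters
    ----------
    name:
        Human-readable label (preset names: ``NEB-PhD7``, ``NEB-PhD12``).
    flank5, flank3:
        Fixed nucleotide signatures immediately before / after the insert.
    peptide_length:
        Number of displayed residues k; the insert is ``3 * k`` nucleotides.
    codon_constraint:
        Per-position IUPAC pattern each codon must match (``"NNK"`` for NEB
        libraries) or :data:`UNCONSTRAINED`.
    amber_as_gln:
        Translate the amber codon TAG as glutamine (supE host read-through).
    codon_filter:
        Whether reads whose insert violates ``codon_constraint`` are rejected
        during processing. On for the NEB presets, off for custom schemes.
    """

    name: str
    flank5: str
    flank3: str
    peptide_length: int
    codon_constraint: str = UNCONSTRAINED
    amber_as_gln: bool = True
    codon_filter: bool = False

    def __post_init__(self) -> None:
        _validate_dna(self.flank5, "flank5")
        _validate_dna(self.flank3, "flank3")
        if not isinstance(self.peptide_length, int) or self.peptide_length < 1:
            raise InvalidSchemeError(
                f"peptide_length must be a positive integer, got {self.peptide_length!r}"
            )
        _validate_constraint(self.codon_constraint)
        if self.codon_constraint != UNCONSTRAINED:
            object.__setattr__(self, "codon_constraint", self.codon_constraint.upper())

    @property
    def insert_length(self) -> int:
        """Insert length in nucleotides (3 per displayed residue)."""
        return 3 * self.peptide_length


PRESETS: dict[str, LibraryScheme] = {
    "NEB-PhD7": LibraryScheme(
        name="NEB-PhD7", flank5="TCT", flank3="GGAGGTGGA", peptide_length=7,
        codon_constraint="NNK", amber_as_gln=True, codon_filter=True,
    ),
    "NEB-PhD12": LibraryScheme(
        name="NEB-PhD12", flank5="TCT", flank3="GGAGGTGGA", peptide_length=12,
        codon_constraint="NNK", amber_as_gln=True, codon_filter=True,
    ),
}


def make_scheme(
    name: str,
    flank5: str | None = None,
    flank3: str | None = None,
    peptide_length: int | None = None,
    codon_constraint: str | None = None,
    amber_as_gln: bool | None = None,
    codon_filter: bool | None = None,
) -> LibraryScheme:
    """Build a validated :class:`LibraryScheme`.

    Preset names resolve without further arguments; any argument given on top of
    a preset overrides that preset field. For custom schemes, ``flank5``,
    ``flank3`` and ``peptide_length`` are required; codon filtering defaults to
    off (the constraint mechanism only applies when the library is known to be
    degenerate-codon synthesised).
    """
    if name in PRESETS:
        base = PRESETS[name]
        return LibraryScheme(
            name=base.name,
            flank5=flank5 if flank5 is not None else base.flank5,
            flank3=flank3 if flank3 is not None else base.flank3,
            peptide_length=peptide_length if peptide_length is not None else base.peptide_length,
            codon_constraint=codon_constraint if codon_constraint is not None else base.codon_constraint,
            amber_as_gln=amber_as_gln if amber_as_gln is not None else base.amber_as_gln,
            codon_filter=codon_filter if codon_filter is not None else base.codon_filter,
        )
    if flank5 is None or flank3 is None or peptide_length is None:
        raise InvalidSchemeError(
            f"unknown preset {name!r}: custom schemes need flank5, flank3 and peptide_length"
        )
    return LibraryScheme(
        name=name,
        flank5=flank5,
        flank3=flank3,
        peptide_length=peptide_length,
        codon_constraint=codon_constraint if codon_constraint is not None else UNCONSTRAINED,
        amber_as_gln=True if amber_as_gln is None else amber_as_gln,
        codon_filter=False if codon_filter is None else codon_filter,
    )


def codon_is_allowed(codon: str, constraint: str) -> bool:
    """True iff ``codon`` matches the per-position degenerate ``constraint``.

    NNK: positions 1–2 any base, position 3 in {G, T}. An unconstrained scheme
    accepts every codon.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must be 3 nt, got {codon!r}")
    if constraint == UNCONSTRAINED:
        return True
    return all(base in IUPAC[pat] for base, pat in zip(codon, constraint))


@lru_cache(maxsize=None)
def allowed_codons(constraint: str) -> frozenset[str]:
    """The set of codons satisfying ``constraint`` (all 64 if unconstrained)."""
    _validate_constraint(constraint)
    return frozenset(
        "".join(c) for c in product("ACGT", repeat=3) if codon_is_allowed("".join(c), constraint)
    )


@lru_cache(maxsize=None)
def _codon_to_aa(amber_as_gln: bool) -> dict[str, str | None]:
    # None marks a terminating stop; under amber read-through TAG becomes Q.
    table: dict[str, str | None] = dict(_FORWARD)
    for stop in STOP_CODONS:
        table[stop] = None
    if amber_as_gln:
        table[AMBER] = "Q"
    return table


def translate_insert(insert: str, scheme: LibraryScheme) -> str | None:
    """Translate an insert codon by codon; ``None`` signals a stop-rejection.

    Stops are an expected outcome for reads that slipped through without codon
    filtering, so they are reported as a value rather than an exception. With
    ``scheme.amber_as_gln``, TAG yields Q and only TAA/TGA terminate.
    """
    if len(insert) != scheme.insert_length:
        raise ValueError(
            f"insert length {len(insert)} != scheme insert_length {scheme.insert_length}"
        )
    if not set(insert) <= _DNA:
        raise ValueError(f"insert contains non-ACGT characters: {insert!r}")
    table = _codon_to_aa(scheme.amber_as_gln)
    residues = []
    for i in range(0, len(insert), 3):
        aa = table[insert[i : i + 3]]
        if aa is None:
            return None
        residues.append(aa)
    return "".join(residues)
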