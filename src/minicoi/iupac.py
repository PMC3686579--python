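"""IUPAC nucleotide algebra, degenerate oligos and mitochondrial translation.

Every other module builds on the primitives here: the mapping from IUPAC
ambiguity codes to base sets, complement/reverse-complement on degenerate
strings, fold-degeneracy arithmetic, expansion of a degenerate oligo into its
concrete members, and codon translation under an NCBI genetic code (default:
invertebrate mitochondrial, table 5, the code of the metazoan COI marker).

Inosine ('I') is treated as a universal base: it pairs with any template base,
contributes a factor of 1 to the reported fold degeneracy (it is a single
physical nucleotide) but expands to all four bases in :func:`expand`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Data import CodonTable

#: IUPAC code -> set of concrete bases the code denotes. 'U' is normalised to
#: 'T' on input and never appears as a key here.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),  # inosine: universal base
}

#: Complement on IUPAC codes. Self-complementary: W, S, N; inosine maps to
#: itself (it is base-indifferent on both strands).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N", "I": "I",
}

#: Base set -> canonical (non-inosine) IUPAC symbol; used by consensus calling.
SET_TO_IUPAC: dict[frozenset[str], str] = {
    v: k for k, v in IUPAC_SETS.items() if k != "I"
}

DEFAULT_EXPANSION_CAP = 65_536


class InvalidSequenceError(ValueError):
    """A sequence contains a character outside the IUPAC alphabet."""


def normalize(seq: str) -> str:
    """Upper-case, map U->T and validate against the IUPAC alphabet.

    Raises :class:`InvalidSequenceError` naming the first offending position
    (1-based).
    """
    out = seq.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in IUPAC_SETS:
            raise InvalidSequenceError(
                f"invalid IUPAC character {ch!r} at position {i + 1} in {seq!r}"
            )
    return out


def base_set(symbol: str) -> frozenset[str]:
    """Concrete bases denoted by one IUPAC symbol."""
    try:
        return IUPAC_SETS[symbol.upper().replace("U", "T")]
    except KeyError:
        raise InvalidSequenceError(f"invalid IUPAC character {symbol!r}") from None


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-coded oligonucleotide, stored 5'->3'.

    ``orientation`` is 'forward' (anneals to the minus strand, extends along
    the plus strand) or 'reverse' (anneals to the plus strand; its reverse
    complement appears in plus-strand template coordinates).
    ``three_prime_block`` marks a non-extendable 3' end (Spacer-C3 style), the
    chemistry used for predator-blocking primers.
    """

    name: str
    sequence: str
    orientation: str = "forward"
    three_prime_block: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize(self.sequence))
        if len(self.sequence) < 1:
            raise InvalidSequenceError("primer sequence must be non-empty")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence)

    @property
    def n_degenerate_positions(self) -> int:
        return count_degenerate_positions(self.sequence)


def _seq(primer: "DegeneratePrimer | str") -> str:
    return primer.sequence if isinstance(primer, DegeneratePrimer) else normalize(primer)


def degeneracy(primer: "DegeneratePrimer | str") -> int:
    """Fold degeneracy: product over positions of |base set|.

    Inosine contributes a factor of 1 — it is one physical base, which is the
    convention behind reported "fold degeneracy" figures for primers that mix
    ambiguity codes with inosine.
    """
    seq = _seq(primer)
    if not seq:
        raise InvalidSequenceError("empty sequence has no degeneracy")
    prod = 1
    for ch in seq:
        if ch != "I":
            prod *= len(IUPAC_SETS[ch])
    return prod


def count_degenerate_positions(primer: "DegeneratePrimer | str") -> int:
    """Number of positions whose IUPAC code denotes more than one base.

    Inosine is excluded: it is a distinct physical base, not a degenerate
    synthesis position.
    """
    return sum(1 for ch in _seq(primer) if ch != "I" and len(IUPAC_SETS[ch]) > 1)


def expansion_size(primer: "DegeneratePrimer | str") -> int:
    """Size of expand(): like degeneracy but inosine counts as 4."""
    prod = 1
    for ch in _seq(primer):
        prod *= len(IUPAC_SETS[ch])
    return prod


def expand(primer: "DegeneratePrimer | str", cap: int = DEFAULT_EXPANSION_CAP) -> set[str]:
    """All concrete ACGT sequences consistent with the IUPAC string.

    Inosine expands to all four bases. Refuses (ValueError) when the expansion
    would exceed ``cap`` sequences, to prevent combinatorial blow-up.
    """
    seq = _seq(primer)
    n = expansion_size(seq)
    if n > cap:
        raise ValueError(
            f"expansion of {seq!r} has {n} members, exceeding the cap of {cap}"
        )
    pools = [sorted(IUPAC_SETS[ch]) for ch in seq]
    return {"".join(p) for p in itertools.product(*pools)}


def complement(seq: str) -> str:
    """Per-symbol IUPAC complement (no reversal)."""
    return "".join(IUPAC_COMPLEMENT[ch] for ch in normalize(seq))


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string; an involution that preserves
    degeneracy and the degenerate-position count."""
    return complement(seq)[::-1]


# ---------------------------------------------------------------------------
# Translation


@dataclass(frozen=True)
class GeneticCode:
    """A codon->amino-acid map (NCBI table) plus a reading-frame offset."""

    table_id: int = 5  # invertebrate mitochondrial
    frame: int = 0
    forward: dict[str, str] = field(init=False, repr=False, compare=False)
    stops: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")
        table = CodonTable.unambiguous_dna_by_id[self.table_id]
        object.__setattr__(self, "forward", dict(table.forward_table))
        object.__setattr__(self, "stops", frozenset(table.stop_codons))


#: Default code for metazoan mitochondrial COI.
INVERTEBRATE_MITO = GeneticCode(5)


def translate(seq: str, code: GeneticCode = INVERTEBRATE_MITO,
              frame: int | None = None) -> tuple[str, list[int]]:
    """Translate complete codons of ``seq`` in the given frame.

    Returns ``(amino_acids, stop_codon_indices)``. Stops appear as '*' in the
    string and their codon indices (0-based, within the translated frame) in
    the list. Codons containing an ambiguous base translate to 'X' rather than
    being dropped. The trailing partial codon, if any, is ignored.
    """
    seq = normalize(seq)
    offset = code.frame if frame is None else frame
    if offset not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    aa = []
    stops = []
    body = seq[offset:]
    for i in range(0, len(body) - len(body) % 3, 3):
        codon = body[i:i + 3]
        if any(len(IUPAC_SETS[ch]) > 1 for ch in codon):
            aa.append("X")
        elif codon in code.stops:
            aa.append("*")
            stops.append(i // 3)
        else:
            aa.append(code.forward[codon])
    return "".join(aa), stops


def has_inframe_stop(seq: str, code: GeneticCode = INVERTEBRATE_MITO, frame: int = 0) -> bool:
    return bool(translate(seq, code, frame)[1])
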