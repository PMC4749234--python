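"""Oligonucleotide primitives.

Sequences are uppercase strings over the alphabet ``A C G T Z`` where ``Z``
denotes the thiazole-orange double-labelled thymidine used in Eprobes: it
base-pairs like ``T`` but carries incremental thermodynamic terms.
"""

from __future__ import annotations

from dataclasses import dataclass

ALPHABET = frozenset("ACGTZ")
DNA_ALPHABET = frozenset("ACGT")

# Z pairs as T, hence complements to A.
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "Z": "A"}


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T, Z}."""


def clean_seq(seq: str, allow_z: bool = True) -> str:
    """Upper-case and validate a sequence string."""
    s = str(seq).strip().upper()
    allowed = ALPHABET if allow_z else DNA_ALPHABET
    bad = set(s) - allowed
    if bad:
        raise AlphabetError(f"illegal characters {sorted(bad)} in sequence {s!r}")
    return s


def complement(base: str) -> str:
    return _COMP[base]


def revcomp(seq: str) -> str:
    """Reverse complement; Z maps to A (it pairs as T)."""
    return "".join(_COMP[b] for b in reversed(seq))


def pairing_strand(seq: str) -> str:
    """Per-position complement, i.e. the perfectly paired strand written
    3'->5' so that ``pairing_strand(seq)[i]`` faces ``seq[i]``."""
    return "".join(_COMP[b] for b in seq)


def as_dna(seq: str) -> str:
    """Replace the labelled nucleotide Z by the underlying thymidine."""
    return seq.replace("Z", "T")


def gc_fraction(seq: str) -> float:
    s = as_dna(seq)
    if not s:
        return 0.0
    return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class Oligo:
    """An oligonucleotide placed on a template.

    Parameters
    ----------
    seq : str
        5'->3' sequence over {A, C, G, T, Z}. Z substitutes a thymidine.
    strand : str
        "+" if the oligo sequence matches the plus (template) strand,
        "-" if it matches the reverse complement.
    start : int
        0-based template offset of the oligo's leftmost (plus-strand
        coordinate) base; the half-open end is ``start + len(seq)``.
    role : str
        "primer" or "probe".
    """

    seq: str
    strand: str = "+"
    start: int = 0
    role: str = "probe"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_seq(self.seq))
        if len(self.seq) < 1:
            raise ValueError("empty oligo")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.role not in ("primer", "probe"):
            raise ValueError(f"role must be 'primer' or 'probe', got {self.role!r}")
        # Z must sit where the unlabelled sequence has a T (guaranteed by
        # construction: Z is only ever introduced by substituting a T).

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        """Half-open template end coordinate."""
        return self.start + len(self.seq)

    @property
    def dna_seq(self) -> str:
        return as_dna(self.seq)

    @property
    def label_positions(self) -> tuple[int, ...]:
        """0-based positions of labelled nucleotides within the oligo."""
        return tuple(i for i, b in enumerate(self.seq) if b == "Z")
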