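"""Hybrid duplex representation and sequence-level analysis.

An RNA/DNA hybrid duplex is an RNA strand (5'->3', alphabet ACGU) paired
with its Watson-Crick complementary DNA strand (5'->3', alphabet ACGT).
This module validates duplexes, decomposes them into nearest-neighbor (NN)
stacks, and computes the two composition factors -- excess G-C content
f(G-C) and RNA purine excess f(rPu) -- that drive the salt-response group
classification (A/B/C) used by the group-specific salt corrections.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "STACKS",
    "HybridDuplex",
    "SequenceFactors",
    "SaltGroup",
    "InitClass",
    "SequenceError",
    "complement_dna",
    "decompose",
    "count_stacks",
    "sequence_factors",
    "classify_group",
    "init_class",
    "parse_duplex",
    "read_fasta",
    "read_lines",
    "random_duplexes",
]

_RNA_TO_DNA = {"A": "T", "U": "A", "G": "C", "C": "G"}
_DNA_TO_RNA = {v: k for k, v in _RNA_TO_DNA.items()}

_PURINES = frozenset("AG")
_GC = frozenset("GC")


class SequenceError(ValueError):
    """Raised for invalid sequence input (bad alphabet, mispairing, ...)."""


def _clean(seq: str, alphabet: str, kind: str) -> str:
    seq = seq.strip().upper()
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise SequenceError(
                f"invalid {kind} character {ch!r} at position {i} in {seq!r}"
            )
    return seq


def complement_dna(rna: str) -> str:
    """Return the complementary DNA strand, written 5'->3'.

    The complement of RNA position i pairs with it antiparallel, so the
    returned string is the per-base complement read in reverse.

    >>> complement_dna("GCCGUGAG")
    'CTCACGGC'
    """
    rna = _clean(rna, "ACGU", "RNA")
    if not rna:
        raise SequenceError("empty RNA sequence")
    return "".join(_RNA_TO_DNA[b] for b in reversed(rna))


def reverse_transcribe(dna: str) -> str:
    """RNA strand (5'->3') complementary to a DNA strand (5'->3')."""
    dna = _clean(dna, "ACGT", "DNA")
    if not dna:
        raise SequenceError("empty DNA sequence")
    return "".join(_DNA_TO_RNA[b] for b in reversed(dna))


def _stack_label(rna_dinucleotide: str) -> str:
    dna = "".join(_RNA_TO_DNA[b] for b in reversed(rna_dinucleotide))
    return f"r{rna_dinucleotide}/d{dna}"


#: The 16 NN stack labels in canonical order (RNA dinucleotide 5'->3',
#: DNA dinucleotide 5'->3'; alphabetical in the RNA dinucleotide).
STACKS: tuple[str, ...] = tuple(
    _stack_label(a + b) for a in "ACGU" for b in "ACGU"
)


@dataclass(frozen=True)
class HybridDuplex:
    """An RNA strand paired with its complementary DNA strand.

    Both strands are stored 5'->3'.  The canonical rendering is
    ``r<RNA>/d<DNA>``, e.g. ``rGCCGUGAG/dCTCACGGC``.
    """

    rna: str
    dna: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        rna = _clean(self.rna, "ACGU", "RNA")
        dna = _clean(self.dna, "ACGT", "DNA") if self.dna else complement_dna(rna)
        object.__setattr__(self, "rna", rna)
        object.__setattr__(self, "dna", dna)
        if len(rna) < 2:
            raise SequenceError("a duplex needs at least 2 base pairs")
        if len(rna) != len(dna):
            raise SequenceError(
                f"strand lengths differ: RNA {len(rna)} vs DNA {len(dna)}"
            )
        expected = complement_dna(rna)
        if dna != expected:
            for i, (a, b) in enumerate(zip(dna, expected)):
                if a != b:
                    raise SequenceError(
                        "DNA strand is not the Watson-Crick complement of the "
                        f"RNA strand: position {i} is {a!r}, expected {b!r}"
                    )

    @classmethod
    def from_rna(
        cls, rna: str, label: str | None = None, *, transliterate_t: bool = False
    ) -> "HybridDuplex":
        """Build a duplex from the RNA strand alone.

        ``transliterate_t=True`` accepts 'T' in the input (common in FASTA
        files holding nominally-RNA sequences) and converts it to 'U' with a
        warning; by default 'T' is rejected.
        """
        rna = rna.strip().upper()
        if transliterate_t and "T" in rna:
            warnings.warn(
                f"transliterating T->U in RNA input {rna!r}", stacklevel=2
            )
            rna = rna.replace("T", "U")
        return cls(rna=rna, label=label)

    def __len__(self) -> int:
        return len(self.rna)

    def __str__(self) -> str:
        return f"r{self.rna}/d{self.dna}"


def parse_duplex(text: str, label: str | None = None) -> HybridDuplex:
    """Parse the canonical ``r<RNA>/d<DNA>`` rendering (DNA part optional)."""
    text = text.strip()
    if "/" in text:
        rna_part, dna_part = text.split("/", 1)
        if not (rna_part[:1] in "rR" and dna_part[:1] in "dD"):
            raise SequenceError(
                f"expected 'r<RNA>/d<DNA>' format, got {text!r}"
            )
        return HybridDuplex(rna=rna_part[1:], dna=dna_part[1:], label=label)
    if text[:1] in "rR" and set(text[1:].upper()) <= set("ACGU"):
        text = text[1:]
    return HybridDuplex(rna=text, label=label)


def decompose(duplex: HybridDuplex) -> list[str]:
    """Ordered NN stacks of the duplex, one per adjacent base-pair step.

    The i-th stack is formed by RNA positions i, i+1 (5'->3'); a duplex of
    N base pairs yields N-1 stacks.

    >>> decompose(HybridDuplex.from_rna("GCCGUGAG"))[:3]
    ['rGC/dGC', 'rCC/dGG', 'rCG/dCG']
    """
    rna = duplex.rna
    return [_stack_label(rna[i : i + 2]) for i in range(len(rna) - 1)]


def count_stacks(duplex: HybridDuplex) -> Counter:
    """Multiset of NN stacks; counts sum to len(duplex) - 1."""
    return Counter(decompose(duplex))


@dataclass(frozen=True)
class SequenceFactors:
    """Composition factors of a duplex.

    f_gc = (N_GC - N_AU/T)/N_total: excess of rG-dC / rC-dG pairs.
    f_pu = (N_pu - N_py)/N_total: purine excess on the RNA strand.
    Both lie in [-1, 1].
    """

    f_gc: float
    f_pu: float
    n_gc: int
    n_aut: int
    n_pu: int
    n_py: int
    n_total: int


class SaltGroup(enum.Enum):
    """Salt-response class of a hybrid: A (both factors > 0), B (both < 0),
    C (mixed signs or any factor zero)."""

    A = "A"
    B = "B"
    C = "C"


class InitClass(enum.Enum):
    """Helix-initiation class: GC if at least one terminal base pair is
    rG-dC or rC-dG, AU if both terminals are rA-dT or rU-dA."""

    GC = "GC"
    AU = "AU"


def sequence_factors(duplex: HybridDuplex) -> SequenceFactors:
    """Compute f(G-C) and f(rPu) and the underlying counts."""
    rna = duplex.rna
    n = len(rna)
    n_gc = sum(b in _GC for b in rna)
    n_pu = sum(b in _PURINES for b in rna)
    return SequenceFactors(
        f_gc=(n_gc - (n - n_gc)) / n,
        f_pu=(n_pu - (n - n_pu)) / n,
        n_gc=n_gc,
        n_aut=n - n_gc,
        n_pu=n_pu,
        n_py=n - n_pu,
        n_total=n,
    )


def classify_group(factors: SequenceFactors) -> SaltGroup:
    """Assign the salt-response group from the sequence factors.

    Strict sign tests: a zero factor always falls in Group C, consistent
    with balanced sequences like rAUGGCUCCAA being Group C.
    """
    if factors.f_gc > 0 and factors.f_pu > 0:
        return SaltGroup.A
    if factors.f_gc < 0 and factors.f_pu < 0:
        return SaltGroup.B
    return SaltGroup.C


def init_class(duplex: HybridDuplex) -> InitClass:
    """Initiation class from the terminal base pairs."""
    if duplex.rna[0] in _GC or duplex.rna[-1] in _GC:
        return InitClass.GC
    return InitClass.AU


def read_fasta(path: str | Path, *, transliterate_t: bool = True) -> list[HybridDuplex]:
    """Read RNA records from a FASTA file as hybrid duplexes."""
    from Bio import SeqIO

    return [
        HybridDuplex.from_rna(str(rec.seq), label=rec.id, transliterate_t=transliterate_t)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_lines(path: str | Path) -> list[HybridDuplex]:
    """Read one sequence (plain RNA or r.../d... rendering) per line."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(parse_duplex(line, label=f"line{i + 1}"))
    return out


def random_duplexes(
    n: int,
    rng,
    length_range: tuple[int, int] = (6, 14),
    labels: bool = True,
) -> list[HybridDuplex]:
    """Generate random valid duplexes (uniform bases), e.g. for fit tests."""
    lo, hi = length_range
    out = []
    for k in range(n):
        length = int(rng.integers(lo, hi + 1))
        rna = "".join(rng.choice(list("ACGU"), size=length))
        out.append(HybridDuplex.from_rna(rna, label=f"syn{k}" if labels else None))
    return out
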