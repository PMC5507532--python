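"""Nucleotide sequence primitives.

Sequences are plain Python strings over ``ACGT``.  Case is meaningful and
preserved by every operation: by the panel's oligo convention, lower-case
bases are universal tag sequence and upper-case bases are gene-specific (or
inserted partial-primer) sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "AlphabetError",
    "StemReport",
    "validate_sequence",
    "reverse_complement",
    "melting_temp",
    "find_terminal_stem",
    "read_fasta",
    "write_fasta",
    "TAG_T1",
    "TAG_T2",
]

# Universal tag sequences (TSCA-compatible); lower case marks them as tags.
TAG_T1 = "caacgatcgtcgaaattcgc"
TAG_T2 = "tacacgacgctcttccgatct"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = frozenset("ACGTacgt")


class AlphabetError(ValueError):
    """A sequence contains characters outside ACGT (either case)."""


def validate_sequence(seq: str) -> str:
    """Return *seq* unchanged if it is a valid ACGT string, else raise.

    Ambiguity codes (N, R, Y, ...) are rejected: panel oligos and synthetic
    references never contain them, and every downstream rule assumes a
    four-letter alphabet.
    """
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise AlphabetError(f"non-ACGT characters in sequence: {bad!r}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement, preserving per-position case."""
    validate_sequence(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def melting_temp(
    seq: str,
    method: str = "nearest_neighbor",
    *,
    Na: float = 50.0,
    Mg: float = 1.5,
    dnac: float = 250.0,
) -> float:
    """Melting temperature in degrees Celsius.

    method="wallace" is the 2(A+T)+4(G+C) rule; method="nearest_neighbor"
    uses the SantaLucia unified parameter set with ``Na`` mM monovalent and
    ``Mg`` mM divalent salt (Owczarzy correction) at ``dnac`` nM oligo.
    These defaults place typical 18-30 nt primers designed for a 60 C
    annealing step inside the 60 +/- 3 C window.
    """
    validate_sequence(seq)
    s = seq.upper()
    if method == "wallace":
        if not s:
            return 0.0
        return float(_mt.Tm_Wallace(s))
    if method == "nearest_neighbor":
        if len(s) < 2:
            raise ValueError("nearest_neighbor Tm needs length >= 2")
        return float(_mt.Tm_NN(s, Na=Na, Mg=Mg, dnac1=dnac, dnac2=0))
    raise ValueError(f"unknown Tm method {method!r}")


@dataclass(frozen=True)
class StemReport:
    """Terminal duplex of a single strand folding back on itself.

    ``stem_length`` is the largest L such that the 5' prefix of length L is
    the reverse complement of the 3' suffix of length L (perfect pairing,
    no G.U wobble, no bulges — constructed stems in a SLIMamp panel are
    exact by design).  ``loop_length`` is whatever remains between the two
    stem arms; L = 0 means no terminal stem.
    """

    stem_length: int
    loop_length: int
    stem_sequence: str

    def __post_init__(self) -> None:
        if self.stem_length < 0:
            raise ValueError("stem_length must be >= 0")


def find_terminal_stem(seq: str) -> StemReport:
    """Detect the longest perfect terminal hairpin stem of a single strand."""
    validate_sequence(seq)
    if not seq:
        raise ValueError("empty sequence has no stem structure")
    upper = seq.upper()
    max_l = len(seq) // 2
    best = 0
    for l in range(1, max_l + 1):
        if upper[:l] == reverse_complement(upper[-l:]):
            best = l
    return StemReport(
        stem_length=best,
        loop_length=len(seq) - 2 * best,
        stem_sequence=seq[:best],
    )


def left_align(pos: int, ref: str, alt: str, contig_seq: str
               ) -> tuple[int, str, str]:
    """Normalise a variant to its left-most, parsimonious VCF form.

    *pos* is 1-based; indels are shifted left through repeats and
    re-anchored on the previous reference base, matching standard VCF
    normalisation so calls and truth records compare exactly.
    """
    pos0 = pos - 1
    ref, alt = ref.upper(), alt.upper()
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
        if (not ref or not alt) and pos0 > 0:
            prev = contig_seq[pos0 - 1].upper()
            ref, alt = prev + ref, prev + alt
            pos0 -= 1
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return pos0 + 1, ref, alt


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = validate_sequence(str(rec.seq))
    return records


def write_fasta(path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    items: Iterator[tuple[str, str]]
    items = records.items() if isinstance(records, dict) else iter(records)
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(recs, str(path), "fasta")
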