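"""Synthetic fixtures: references, variant haplotypes and paired-end reads.

Everything is generated from a seed, bit-reproducibly, so the analysis
pipeline can be exercised end to end with known truth and no external
data.  Reads emulate the library structure the panel produces: each
fragment is a tagged amplicon molecule (universal tag + any F2^/R1^ insert
+ gene-specific product), read as a 2 x 250 bp pair, with seeded
substitution errors whose Phred qualities match the error rate used.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel import Panel
from .seqcore import left_align, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class VariantSpec:
    """A variant to inject: SNV, insertion (1+ bp) or deletion (1-40 bp).

    ``pos`` is 1-based; ``ref`` must match the reference there.  For an
    insertion/deletion, ref and alt share a leading anchor base (VCF
    style).  Zygosity 'het' means allele fraction 0.5, 'hom' means 1.0,
    unless ``fraction`` overrides it.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    zygosity: str = "het"
    fraction: float | None = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be het|hom, got {self.zygosity}")
        if self.fraction is not None and not 0.0 < self.fraction <= 1.0:
            raise ValueError("allele fraction must be in (0, 1]")
        if len(self.ref) > 1 and len(self.alt) > 1 and len(self.ref) != len(self.alt):
            raise ValueError("block substitutions are not supported")
        if len(self.ref) - len(self.alt) > 40:
            raise ValueError("deletions longer than 40 bp are not supported")

    @property
    def allele_fraction(self) -> float:
        if self.fraction is not None:
            return self.fraction
        return 0.5 if self.zygosity == "het" else 1.0

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "snv"
        return "ins" if len(self.alt) > len(self.ref) else "del"


@dataclass(frozen=True)
class ReadProfile:
    """Sequencing emulation parameters (2 x 250 bp convention)."""

    read_length: int = 250
    error_rate: float = 0.001
    depth_mean: float = 1000.0
    depth_log_sigma: float = 0.5   # log-normal amplification bias; 0 = constant
    seed: int = 0

    @property
    def phred(self) -> int:
        if self.error_rate <= 0:
            return 40
        return int(round(-10.0 * np.log10(self.error_rate)))


def make_reference(length: int, gc: float = 0.5, seed: int = 0,
                   contig: str = "chrS") -> dict[str, str]:
    """Seeded random reference with expected GC fraction *gc*."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=length, p=probs).tobytes().decode()
    return {contig: seq}


@dataclass
class Haplotype:
    """One haplotype: edited sequence plus a ref->alt coordinate map."""

    name: str
    fraction: float
    seqs: dict[str, str]
    # per contig: sorted (ref_pos0, length_delta) of indels, for mapping
    shifts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def map_pos(self, contig: str, pos0: int) -> int:
        off = 0
        for p, d in self.shifts.get(contig, []):
            if p < pos0:
                off += d
            else:
                break
        return pos0 + off


def apply_variants(reference: dict[str, str], specs: list[VariantSpec],
                   name: str = "alt", fraction: float = 0.5) -> Haplotype:
    """Apply edits right-to-left (original coordinates stay valid) and
    return the edited haplotype with truth-friendly coordinate shifts."""
    ordered = sorted(specs, key=lambda v: (v.contig, v.pos))
    for a, b in zip(ordered, ordered[1:]):
        if a.contig == b.contig and a.pos + len(a.ref) > b.pos:
            raise ValueError(f"overlapping variant specs at {b.contig}:{b.pos}")
    seqs = {}
    shifts: dict[str, list[tuple[int, int]]] = {}
    for contig, seq in reference.items():
        here = [v for v in ordered if v.contig == contig]
        s = seq
        for v in reversed(here):
            pos0 = v.pos - 1
            if s[pos0:pos0 + len(v.ref)].upper() != v.ref.upper():
                raise ValueError(
                    f"ref allele mismatch at {contig}:{v.pos}: expected "
                    f"{v.ref}, found {s[pos0:pos0 + len(v.ref)]}"
                )
            s = s[:pos0] + v.alt.upper() + s[pos0 + len(v.ref):]
        seqs[contig] = s
        shifts[contig] = [(v.pos - 1 + len(v.ref), len(v.alt) - len(v.ref))
                          for v in here if len(v.alt) != len(v.ref)]
    return Haplotype(name=name, fraction=fraction, seqs=seqs, shifts=shifts)


def truth_records(reference: dict[str, str], specs: list[VariantSpec]
                  ) -> list[dict]:
    """Left-aligned truth table (VCF-style dicts) for injected variants."""
    out = []
    for v in sorted(specs, key=lambda s: (s.contig, s.pos)):
        pos, ref, alt = left_align(v.pos, v.ref, v.alt, reference[v.contig])
        out.append({"contig": v.contig, "pos": pos, "ref": ref, "alt": alt,
                    "zygosity": v.zygosity, "kind": v.kind,
                    "fraction": v.allele_fraction})
    return out


def write_truth_vcf(path, reference: dict[str, str],
                    specs: list[VariantSpec]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, seq in reference.items():
            fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        fh.write('##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in truth_records(reference, specs):
            fh.write(f"{rec['contig']}\t{rec['pos']}\t.\t{rec['ref']}\t"
                     f"{rec['alt']}\t.\tPASS\tZYG={rec['zygosity']}\n")


def diploid_haplotypes(reference: dict[str, str], specs: list[VariantSpec]
                       ) -> list[Haplotype]:
    """Standard diploid pair: hom variants on both haplotypes, het on one."""
    hom = [v for v in specs if v.zygosity == "hom"]
    return [
        apply_variants(reference, specs, name="hap1", fraction=0.5),
        apply_variants(reference, hom, name="hap2", fraction=0.5),
    ]


def _fragment(panel: Panel, amp, hap: Haplotype) -> str:
    """Tagged molecule for one amplicon from one haplotype.

    Primer regions come from the oligos (the polymerase copies the primer,
    so variants under a primer site are invisible in that amplicon); the
    interior comes from the haplotype via the coordinate map.
    """
    inner_start = amp.start + len(amp.fwd.gene_seq)
    inner_end = amp.end - len(amp.rev.gene_seq)
    hseq = hap.seqs[amp.contig]
    a = hap.map_pos(amp.contig, inner_start)
    b = hap.map_pos(amp.contig, inner_end)
    inner = hseq[a:b]
    return (amp.fwd.oligo.upper() + inner
            + reverse_complement(amp.rev.oligo.upper()))


def simulate_reads(
    panel: Panel,
    haplotypes: list[Haplotype],
    profile: ReadProfile,
    out1=None,
    out2=None,
) -> list[tuple[str, str, str, str, str]]:
    """Generate paired 2 x ``read_length`` reads for every amplicon.

    Per amplicon a depth is drawn once from the log-normal bias model
    (mean ``depth_mean``, sigma ``depth_log_sigma``; sigma 0 gives the
    constant depth exactly); each fragment's haplotype is drawn by
    fraction.  Read 1 is the fragment 5' end, read 2 the reverse
    complement 3' end.  Substitution errors are seeded and their constant
    quality string encodes the error rate.  Returns (name, r1, q1, r2, q2)
    tuples and optionally writes FASTQ (gzip if the path ends in .gz).
    """
    rng = np.random.default_rng(profile.seed)
    fracs = np.array([h.fraction for h in haplotypes])
    fracs = fracs / fracs.sum()
    qual_char = chr(min(profile.phred, 40) + 33)
    records = []
    for amp in panel.amplicons:
        frags = [_fragment(panel, amp, h) for h in haplotypes]
        if profile.depth_log_sigma > 0:
            sigma = profile.depth_log_sigma
            depth = int(round(profile.depth_mean
                              * np.exp(rng.normal(0, sigma) - sigma ** 2 / 2)))
        else:
            depth = int(round(profile.depth_mean))
        depth = max(depth, 1)
        hap_idx = rng.choice(len(haplotypes), size=depth, p=fracs)
        for i, hi in enumerate(hap_idx):
            frag = frags[hi]
            r1 = frag[: profile.read_length]
            r2 = reverse_complement(frag)[: profile.read_length]
            r1 = _with_errors(r1, profile.error_rate, rng)
            r2 = _with_errors(r2, profile.error_rate, rng)
            name = f"sim:{amp.id}:{haplotypes[hi].name}:{i}"
            records.append((name, r1, qual_char * len(r1),
                            r2, qual_char * len(r2)))
    if out1 is not None and out2 is not None:
        _write_fastq(out1, [(n, s, q) for n, s, q, _, _ in records])
        _write_fastq(out2, [(n, s, q) for n, _, _, s, q in records])
    return records


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[rng.integers(3)]
    return "".join(s)


def _write_fastq(path, records) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Minimal FASTQ reader: (name, sequence, quality) tuples."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                break
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            out.append((header[1:], seq, qual))
    return out
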