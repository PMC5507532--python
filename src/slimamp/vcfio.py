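"""Minimal VCF 4.2 output/input for panel variant calls."""

from __future__ import annotations

from pathlib import Path

from .ampcall import VariantCall

_HEADER = """\
##fileformat=VCFv4.2
##source=slimamp
##INFO=<ID=QWF,Number=1,Type=Float,Description="Quality-weighted allele frequency">
##INFO=<ID=NOISE_MU,Number=1,Type=Float,Description="Segment noise mean qwf">
##INFO=<ID=NOISE_SD,Number=1,Type=Float,Description="Segment noise qwf standard deviation">
##INFO=<ID=AMPLICON,Number=1,Type=String,Description="Supporting amplicon">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Merged-read depth">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Supporting merged reads">
##FILTER=<ID=low_support,Description="Fewer than the minimum supporting reads">
##FILTER=<ID=low_frequency,Description="Allele frequency below the minimum">
"""


def write_vcf(calls: list[VariantCall], path,
              contigs: dict[str, int] | None = None) -> None:
    """Write calls as uncompressed VCF 4.2 (1-based, left-aligned)."""
    lines = [_HEADER]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for c in sorted(calls, key=lambda c: (c.contig, c.pos, c.ref, c.alt)):
        info = (f"QWF={c.qwf:.6f};NOISE_MU={c.noise_mu:.6g};"
                f"NOISE_SD={c.noise_sd:.6g};AMPLICON={c.amplicon_id};"
                f"DP={c.depth};AD={c.support}")
        lines.append(f"{c.contig}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t"
                     f"{c.filter}\t{info}\n")
    Path(path).write_text("".join(lines))


def read_vcf(path) -> list[VariantCall]:
    """Read a VCF written by :func:`write_vcf` back into calls."""
    calls = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        contig, pos, _, ref, alt, _, filt, info = line.split("\t")[:8]
        fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
        calls.append(VariantCall(
            contig=contig, pos=int(pos), ref=ref, alt=alt,
            qwf=float(fields.get("QWF", 0.0)),
            support=int(fields.get("AD", 0)),
            depth=int(fields.get("DP", 0)),
            filter=filt,
            amplicon_id=fields.get("AMPLICON", ""),
            noise_mu=float(fields.get("NOISE_MU", 0.0)),
            noise_sd=float(fields.get("NOISE_SD", 0.0)),
        ))
    return calls
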