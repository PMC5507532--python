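"""Tiled-amplicon panel design with stem-loop inhibition (SLIMamp) oligos.

A panel tiles each region of interest (ROI) with overlapping amplicons so
that every targeted base — including every primer binding site inside the
ROI — is covered by the *insert* of at least one amplicon.  At each overlap
junction the two inner primers carry the same universal tag, and a short
5'-prefix of one inner primer's gene-specific sequence is inserted into the
other (F2^ into R1, or equivalently R1^ into F2), so that the unwanted
short overlap product folds into a terminal stem-loop that blocks its own
re-priming.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import seqcore
from .seqcore import TAG_T1, TAG_T2, reverse_complement


class DesignError(ValueError):
    """Panel design constraints cannot be satisfied."""


@dataclass(frozen=True)
class DesignConfig:
    """Tunable panel-design parameters.

    Insert sizes and overlaps default to the deployed-panel regime
    (263-380 bp amplicons, 49-193 bp overlaps, ~331 bp preferred insert);
    primers are selected for a 60 +/- 3 C melting window.
    """

    size_bounds: tuple[int, int] = (263, 380)
    overlap_bounds: tuple[int, int] = (49, 193)
    preferred_size: int = 331
    preferred_overlap: int = 100
    primer_length_bounds: tuple[int, int] = (18, 30)
    primer_margin: int = 60          # outer-primer room beyond each ROI edge
                                     # (>= max primer length + inward slop so
                                     # terminal primers bind outside the ROI)
    primer_slop: int = 25            # max inward shift of a primer 5' end
    primer_outward_slop: int = 20    # max outward shift (grows the insert)
    tm_target: float = 60.0
    tm_window: float = 3.0
    tm_method: str = "nearest_neighbor"
    maf_threshold: float = 0.0009    # SNP-avoidance MAF ceiling (0.09%)
    snp_window: int = 10             # 3'-terminal bases screened for SNPs
    max_homopolymer: int = 4
    insert_len: int = 12             # F2^/R1^ length at junctions
    insert_side: str = "left_rev"    # or "right_fwd" (the R1^ orientation)
    tag1: str = TAG_T1
    tag2: str = TAG_T2


@dataclass
class TaggedPrimer:
    """One panel oligo: 5' universal tag + optional F2^/R1^ insert + gene part.

    Case encodes role: ``tag_seq`` is lower case, ``insert_seq`` and
    ``gene_seq`` upper case.  ``genomic_start``/``genomic_end`` give the
    0-based half-open binding interval of the gene-specific part on the
    reference; for a reverse primer the oligo is the reverse complement of
    that interval, so its 3' end sits at ``genomic_start``.
    """

    tag_id: str                       # "t1" | "t2" | "" before assignment
    tag_seq: str
    insert_seq: str
    gene_seq: str
    orientation: str                  # "forward" | "reverse"
    contig: str
    genomic_start: int
    genomic_end: int

    @property
    def oligo(self) -> str:
        return self.tag_seq + self.insert_seq + self.gene_seq

    @property
    def genomic_3prime_pos(self) -> int:
        if self.orientation == "forward":
            return self.genomic_end - 1
        return self.genomic_start

    def three_prime_window(self, window: int) -> tuple[int, int]:
        """Genomic half-open interval of the last *window* 3'-end bases."""
        if self.orientation == "forward":
            lo = max(self.genomic_start, self.genomic_end - window)
            return lo, self.genomic_end
        hi = min(self.genomic_end, self.genomic_start + window)
        return self.genomic_start, hi


@dataclass
class Amplicon:
    id: str
    contig: str
    start: int                        # insert interval incl. primer sites
    end: int
    fwd: TaggedPrimer | None = None
    rev: TaggedPrimer | None = None

    @property
    def insert_length(self) -> int:
        return self.end - self.start


@dataclass
class Junction:
    left_id: str
    right_id: str
    overlap_start: int
    overlap_end: int
    shared_tag_id: str = ""
    insert_len: int = 0
    insert_side: str = "left_rev"

    @property
    def overlap_length(self) -> int:
        return self.overlap_end - self.overlap_start


@dataclass
class VariantMask:
    """Known-polymorphism mask: (contig, 0-based position) -> minor AF."""

    entries: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (_, _), maf in self.entries.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"minor allele frequency {maf} outside [0, 1]")

    @classmethod
    def from_tsv(cls, path) -> "VariantMask":
        entries: dict[tuple[str, int], float] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                contig, pos, maf = line.split()[:3]
                entries[(contig, int(pos))] = float(maf)
        return cls(entries)


@dataclass
class Panel:
    amplicons: list[Amplicon]
    junctions: list[Junction]
    roi: list[tuple[str, int, int]]
    config: DesignConfig = field(default_factory=DesignConfig)

    def amplicon(self, amplicon_id: str) -> Amplicon:
        for amp in self.amplicons:
            if amp.id == amplicon_id:
                return amp
        raise KeyError(amplicon_id)

    def chains(self) -> list[list[Amplicon]]:
        """Amplicons grouped into overlap chains, in genomic order."""
        right_of = {j.left_id: j.right_id for j in self.junctions}
        left_of = {j.right_id: j.left_id for j in self.junctions}
        chains = []
        seen: set[str] = set()
        for amp in self.amplicons:
            if amp.id in seen or amp.id in left_of:
                continue
            chain = [amp]
            seen.add(amp.id)
            cur = amp.id
            while cur in right_of:
                cur = right_of[cur]
                chain.append(self.amplicon(cur))
                seen.add(cur)
            chains.append(chain)
        return chains


# ---------------------------------------------------------------------------
# tiling

def _plan_chain(length: int, cfg: DesignConfig) -> list[tuple[int, int]]:
    """Offsets (start, end) of amplicons tiling a span of *length* bases.

    Picks the amplicon count closest to the preferred-size / preferred-
    overlap regime, then equalises: all amplicons share one insert size and
    overlaps differ by at most one base.  Deterministic; no randomness.
    """
    smin, smax = cfg.size_bounds
    omin, omax = cfg.overlap_bounds
    if length <= smax:
        return [(0, max(length, smin))]
    step = cfg.preferred_size - cfg.preferred_overlap
    n0 = max(2, round((length - cfg.preferred_overlap) / step))
    for n in sorted(range(2, 4 * n0 + 4), key=lambda n: (abs(n - n0), n)):
        # need size s with (n*s - length)/(n-1) in [omin, omax-?] and s in bounds
        lo = max(smin, -(-(length + (n - 1) * omin) // n))      # ceil
        hi = min(smax, (length + (n - 1) * omax) // n)
        if lo > hi:
            continue
        target = round((length + (n - 1) * cfg.preferred_overlap) / n)
        s = min(max(target, lo), hi)
        total_overlap = n * s - length
        base, extra = divmod(total_overlap, n - 1)
        if base < omin or base + (1 if extra else 0) > omax:
            continue
        offsets = []
        pos = 0
        for i in range(n):
            offsets.append((pos, pos + s))
            ov = base + (1 if i < extra else 0)
            pos += s - ov
        assert offsets[-1][1] == length
        return offsets
    raise DesignError(
        f"span of {length} bp cannot be tiled with sizes {cfg.size_bounds} "
        f"and overlaps {cfg.overlap_bounds}"
    )


def tile_roi(
    roi: list[tuple[str, int, int]],
    reference: dict[str, str],
    config: DesignConfig | None = None,
) -> Panel:
    """Lay out overlapping amplicons covering every ROI interval.

    Each interval is padded by ``primer_margin`` on both sides so the
    outermost primers bind outside the targeted bases, then tiled into a
    chain of equal-size amplicons with near-equal overlaps.  Raises
    :class:`DesignError` naming the interval if the bounds are infeasible
    or the reference is too short.
    """
    cfg = config or DesignConfig()
    amplicons: list[Amplicon] = []
    junctions: list[Junction] = []
    n = 0
    for contig, rstart, rend in roi:
        if contig not in reference:
            raise DesignError(f"ROI contig {contig!r} not in reference")
        clen = len(reference[contig])
        if not (0 <= rstart < rend <= clen):
            raise DesignError(f"ROI {contig}:{rstart}-{rend} outside reference")
        margin = cfg.primer_margin
        roi_len = rend - rstart
        smax = cfg.size_bounds[1]
        if roi_len + 2 * margin > smax and roi_len + 50 <= smax:
            # shrink the padding so a short interval still fits one amplicon
            margin = (smax - roi_len) // 2
        span_start = rstart - margin
        span_end = rend + margin
        length = span_end - span_start
        if length < cfg.size_bounds[0]:
            pad = cfg.size_bounds[0] - length
            span_start -= pad // 2
            span_end += pad - pad // 2
            length = span_end - span_start
        if span_start < 0 or span_end > clen:
            raise DesignError(
                f"ROI {contig}:{rstart}-{rend} too close to the contig edge "
                f"for primer placement"
            )
        try:
            offsets = _plan_chain(length, cfg)
        except DesignError as err:
            raise DesignError(f"ROI {contig}:{rstart}-{rend}: {err}") from err
        chain_ids = []
        for s, e in offsets:
            n += 1
            amp = Amplicon(id=f"amp{n:03d}", contig=contig,
                           start=span_start + s, end=span_start + e)
            amplicons.append(amp)
            chain_ids.append(amp.id)
        for left_id, right_id in zip(chain_ids, chain_ids[1:]):
            left = next(a for a in amplicons if a.id == left_id)
            right = next(a for a in amplicons if a.id == right_id)
            junctions.append(Junction(left_id, right_id, right.start, left.end))
    return Panel(amplicons=amplicons, junctions=junctions, roi=list(roi),
                 config=cfg)


# ---------------------------------------------------------------------------
# primer selection

def check_3prime_snps(
    primer: TaggedPrimer,
    mask: VariantMask,
    maf_threshold: float = 0.0009,
    window: int = 10,
) -> bool:
    """True iff no masked SNP above *maf_threshold* sits under the primer's
    last *window* 3'-end genomic positions (strand-aware)."""
    lo, hi = primer.three_prime_window(window)
    for pos in range(lo, hi):
        maf = mask.entries.get((primer.contig, pos))
        if maf is not None and maf > maf_threshold:
            return False
    return True


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def select_primers(
    amplicon: Amplicon,
    reference: dict[str, str],
    mask: VariantMask | None = None,
    config: DesignConfig | None = None,
) -> tuple[TaggedPrimer, TaggedPrimer]:
    """Pick gene-specific fwd/rev primers at an amplicon's ends.

    Candidates are every (shift, length) combination: the primer 5' end
    may move inward up to ``primer_slop`` or outward up to
    ``primer_outward_slop`` bases (outward shifts are capped so the insert
    cannot exceed its size bound), lengths span the configured bounds.  A
    candidate must sit in the melting window, avoid homopolymers longer
    than the cap and masked 3'-end SNPs.  Ranking is |Tm - target|, then
    GC clamp, then smallest displacement, then 5'-most start, then length
    — fully deterministic.
    """
    cfg = config or DesignConfig()
    mask = mask or VariantMask()
    ref = reference[amplicon.contig]
    lmin, lmax = cfg.primer_length_bounds
    size_slack = max(0, cfg.size_bounds[1] - amplicon.insert_length)
    outward = min(cfg.primer_outward_slop, size_slack // 2)

    def candidates(orientation: str):
        found = []
        for shift in range(-outward, cfg.primer_slop + 1):
            for length in range(lmin, lmax + 1):
                if orientation == "forward":
                    gstart = amplicon.start + shift
                    gend = gstart + length
                    seq = ref[gstart:gend].upper()
                else:
                    gend = amplicon.end - shift
                    gstart = gend - length
                    seq = reverse_complement(ref[gstart:gend].upper())
                if gend > len(ref) or gstart < 0:
                    continue
                try:
                    tm = seqcore.melting_temp(seq, cfg.tm_method)
                except ValueError:
                    continue
                if abs(tm - cfg.tm_target) > cfg.tm_window:
                    continue
                if _max_homopolymer(seq) > cfg.max_homopolymer:
                    continue
                primer = TaggedPrimer(
                    tag_id="", tag_seq="", insert_seq="", gene_seq=seq,
                    orientation=orientation, contig=amplicon.contig,
                    genomic_start=gstart, genomic_end=gend,
                )
                if not check_3prime_snps(primer, mask, cfg.maf_threshold,
                                         cfg.snp_window):
                    continue
                gc_clamp = 0 if seq[-1] in "GC" else 1
                found.append((round(abs(tm - cfg.tm_target), 6), gc_clamp,
                              abs(shift), gstart, length, primer))
        if not found:
            raise DesignError(
                f"no {orientation} primer satisfies Tm "
                f"{cfg.tm_target}±{cfg.tm_window} C / SNP / homopolymer "
                f"constraints for {amplicon.id} "
                f"({amplicon.contig}:{amplicon.start}-{amplicon.end})"
            )
        found.sort(key=lambda t: t[:5])
        return found[0][-1]

    return candidates("forward"), candidates("reverse")


def design_primers(
    panel: Panel,
    reference: dict[str, str],
    mask: VariantMask | None = None,
) -> Panel:
    """Select primers for every amplicon and shrink inserts to primer ends."""
    cfg = panel.config
    for amp in panel.amplicons:
        fwd, rev = select_primers(amp, reference, mask, cfg)
        amp.fwd, amp.rev = fwd, rev
        amp.start, amp.end = fwd.genomic_start, rev.genomic_end
    for j in panel.junctions:
        left = panel.amplicon(j.left_id)
        right = panel.amplicon(j.right_id)
        j.overlap_start, j.overlap_end = right.start, left.end
        if j.overlap_length < cfg.overlap_bounds[0]:
            raise DesignError(
                f"junction {j.left_id}/{j.right_id} overlap shrank to "
                f"{j.overlap_length} bp after primer selection"
            )
    return panel


# ---------------------------------------------------------------------------
# tags and SLIMamp oligos

def assign_tags(panel: Panel) -> Panel:
    """2-colour tags along each overlap chain.

    Within an amplicon fwd and rev tags differ; at each junction the two
    inner primers (rev of the left amplicon, fwd of the right) share a tag.
    Both constraints propagate by strict alternation, so chains of any
    length are colourable; isolated amplicons get fwd=t2, rev=t1.
    """
    cfg = panel.config
    tags = {"t1": cfg.tag1, "t2": cfg.tag2}
    other = {"t1": "t2", "t2": "t1"}
    for chain in panel.chains():
        fwd_tag = "t2"
        for amp in chain:
            if amp.fwd is None or amp.rev is None:
                raise DesignError(f"{amp.id} has no primers yet")
            amp.fwd.tag_id, amp.fwd.tag_seq = fwd_tag, tags[fwd_tag]
            rev_tag = other[fwd_tag]
            amp.rev.tag_id, amp.rev.tag_seq = rev_tag, tags[rev_tag]
            fwd_tag = rev_tag  # junction partner shares the left rev tag
    for j in panel.junctions:
        left, right = panel.amplicon(j.left_id), panel.amplicon(j.right_id)
        assert left.rev.tag_id == right.fwd.tag_id, "junction tags must match"
        j.shared_tag_id = left.rev.tag_id
    for amp in panel.amplicons:
        assert amp.fwd.tag_id != amp.rev.tag_id, "amplicon tags must differ"
    return panel


def build_slimamp_oligos(
    panel: Panel,
    insert_len: int | dict[str, int] | None = None,
    insert_side: str | None = None,
) -> Panel:
    """Insert F2^/R1^ sequence at each junction to arm the stem-loop.

    ``insert_len`` may be one length for every junction or a mapping keyed
    by ``"left_id/right_id"``.  With side ``left_rev`` the first
    *insert_len* bases of the right amplicon's forward gene-specific primer
    (F2^) go between tag and gene part of the left amplicon's reverse
    primer; ``right_fwd`` is the mirrored R1^ construction.
    """
    cfg = panel.config
    side_default = insert_side or cfg.insert_side
    for j in panel.junctions:
        left, right = panel.amplicon(j.left_id), panel.amplicon(j.right_id)
        if isinstance(insert_len, dict):
            k = insert_len.get(f"{j.left_id}/{j.right_id}", cfg.insert_len)
        else:
            k = insert_len if insert_len is not None else cfg.insert_len
        side = side_default
        if side == "left_rev":
            partner, carrier = right.fwd, left.rev
        elif side == "right_fwd":
            partner, carrier = left.rev, right.fwd
        else:
            raise DesignError(f"unknown insert side {side!r}")
        if k > len(partner.gene_seq):
            raise DesignError(
                f"insert length {k} exceeds partner primer length "
                f"{len(partner.gene_seq)} at junction {j.left_id}/{j.right_id}"
            )
        carrier.insert_seq = partner.gene_seq[:k].upper()
        j.insert_len, j.insert_side = k, side
    return panel


def design_panel(
    roi: list[tuple[str, int, int]],
    reference: dict[str, str],
    mask: VariantMask | None = None,
    config: DesignConfig | None = None,
) -> Panel:
    """Full design: tile, select primers, assign tags, build oligos."""
    panel = tile_roi(roi, reference, config)
    design_primers(panel, reference, mask)
    assign_tags(panel)
    build_slimamp_oligos(panel)
    return panel


# ---------------------------------------------------------------------------
# product sequences

def amplicon_sequence(amp: Amplicon, reference: dict[str, str]) -> str:
    """Expected tagged product strand (5'->3', case-coded) of an amplicon."""
    ref = reference[amp.contig]
    body = ref[amp.start:amp.end].upper()
    return (amp.fwd.tag_seq + amp.fwd.insert_seq + body
            + reverse_complement(amp.rev.tag_seq + amp.rev.insert_seq))


def overlap_amplicon_sequence(
    panel: Panel, junction: Junction, reference: dict[str, str]
) -> str:
    """Predicted single strand of the unwanted overlap product at a junction.

    Its 5' end starts with the shared tag (+ any F2^ carried by the inner
    forward primer) and its 3' end is the reverse complement of the other
    inner primer's tag + insert, so the strand closes into the designed
    terminal stem of length tag + insert.
    """
    left = panel.amplicon(junction.left_id)
    right = panel.amplicon(junction.right_id)
    ref = reference[left.contig]
    body = ref[junction.overlap_start:junction.overlap_end].upper()
    return (right.fwd.tag_seq + right.fwd.insert_seq + body
            + reverse_complement(left.rev.tag_seq + left.rev.insert_seq))


# ---------------------------------------------------------------------------
# export / import

def export_panel(panel: Panel, reference: dict[str, str], outdir) -> None:
    """Write the panel manifest: BEDs, oligo table, amplicon FASTA, config.

    All BED intervals are 0-based half-open.  ``read_panel`` round-trips
    the manifest losslessly.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "inserts.bed", "w") as fh:
        for amp in panel.amplicons:
            fh.write(f"{amp.contig}\t{amp.start}\t{amp.end}\t{amp.id}\n")
    with open(out / "primers.bed", "w") as fh:
        for amp in panel.amplicons:
            for role, p in (("fwd", amp.fwd), ("rev", amp.rev)):
                fh.write(f"{p.contig}\t{p.genomic_start}\t{p.genomic_end}\t"
                         f"{amp.id}_{role}\t0\t"
                         f"{'+' if p.orientation == 'forward' else '-'}\n")
    with open(out / "roi.bed", "w") as fh:
        for contig, s, e in panel.roi:
            fh.write(f"{contig}\t{s}\t{e}\n")
    with open(out / "oligos.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["amplicon", "role", "tag_id", "tag_seq", "insert_seq",
                    "gene_seq", "full_oligo", "contig", "start", "end", "tm"])
        for amp in panel.amplicons:
            for role, p in (("fwd", amp.fwd), ("rev", amp.rev)):
                tm = seqcore.melting_temp(p.gene_seq, panel.config.tm_method)
                w.writerow([amp.id, role, p.tag_id, p.tag_seq, p.insert_seq,
                            p.gene_seq, p.oligo, p.contig, p.genomic_start,
                            p.genomic_end, f"{tm:.2f}"])
    seqcore.write_fasta(
        out / "amplicons.fasta",
        [(amp.id, amplicon_sequence(amp, reference).upper())
         for amp in panel.amplicons],
    )
    junctions = [
        {"left": j.left_id, "right": j.right_id,
         "overlap_start": j.overlap_start, "overlap_end": j.overlap_end,
         "shared_tag_id": j.shared_tag_id, "insert_len": j.insert_len,
         "insert_side": j.insert_side}
        for j in panel.junctions
    ]
    cfg = panel.config
    meta = {"junctions": junctions,
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in vars(cfg).items()}}
    (out / "panel.json").write_text(json.dumps(meta, indent=1))


def read_panel(indir) -> Panel:
    """Reconstruct a :class:`Panel` from an exported manifest directory."""
    ind = Path(indir)
    meta = json.loads((ind / "panel.json").read_text())
    raw = meta["config"]
    cfg = DesignConfig(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in raw.items()})
    amplicons: dict[str, Amplicon] = {}
    with open(ind / "inserts.bed") as fh:
        for line in fh:
            contig, s, e, aid = line.split()
            amplicons[aid] = Amplicon(id=aid, contig=contig,
                                      start=int(s), end=int(e))
    with open(ind / "oligos.tsv") as fh:
        rdr = csv.DictReader(fh, delimiter="\t")
        for row in rdr:
            p = TaggedPrimer(
                tag_id=row["tag_id"], tag_seq=row["tag_seq"],
                insert_seq=row["insert_seq"], gene_seq=row["gene_seq"],
                orientation="forward" if row["role"] == "fwd" else "reverse",
                contig=row["contig"], genomic_start=int(row["start"]),
                genomic_end=int(row["end"]),
            )
            amp = amplicons[row["amplicon"]]
            if row["role"] == "fwd":
                amp.fwd = p
            else:
                amp.rev = p
    roi = []
    with open(ind / "roi.bed") as fh:
        for line in fh:
            contig, s, e = line.split()[:3]
            roi.append((contig, int(s), int(e)))
    junctions = [
        Junction(j["left"], j["right"], j["overlap_start"], j["overlap_end"],
                 j["shared_tag_id"], j["insert_len"], j["insert_side"])
        for j in meta["junctions"]
    ]
    return Panel(amplicons=list(amplicons.values()), junctions=junctions,
                 roi=roi, config=cfg)


def read_panel_fasta(indir) -> dict[str, str]:
    """Amplicon-id -> expected tagged product sequence from a manifest."""
    return seqcore.read_fasta(Path(indir) / "amplicons.fasta")
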