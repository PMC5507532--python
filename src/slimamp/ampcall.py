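"""Panel-aware amplicon variant calling.

The pipeline mirrors standard amplicon NGS analysis, re-grounded on the
panel manifest instead of whole-genome mapping: read pairs are assigned to
their amplicon by primer prefix, locally realigned against the expected
tagged amplicon sequence (banded Smith-Waterman, catching indels that
simple anchoring misses), merged into a phred-weighted consensus, primer
regions soft-clipped, and per-segment pileups accumulated.  Variants are
called where an allele's quality-weighted frequency exceeds the segment's
background noise mean by six standard deviations, then filtered to
>= 20 supporting reads and >= 20% allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignScores, Alignment, encode, smith_waterman
from .panel import Panel
from .seqcore import left_align, reverse_complement

DEL = 4  # pileup code for a deleted base
_BASE = "ACGT-"

# phred -> probability the base is correct
_WEIGHT = 1.0 - np.power(10.0, -np.arange(0, 94) / 10.0)


@dataclass(frozen=True)
class CallConfig:
    """Pipeline thresholds; defaults follow the assay's published rules."""

    max_mismatch: int = 2          # primer-prefix mismatches for assignment
    band_halfwidth: int = 48       # realignment band (handles indels <= 48)
    scores: AlignScores = field(default_factory=AlignScores)
    fast_path_max_mismatch: int = 6  # ungapped shortcut before realignment
    merge_cap: int = 60
    merge_floor: int = 2
    candidate_exclusion: float = 0.05  # qwf ceiling for the noise set
    sd_multiplier: float = 6.0
    min_support: int = 20
    min_frequency: float = 0.20
    qwf_floor: float = 0.005       # noise gate when a segment's sd is zero


@dataclass
class AmpliconRef:
    """Precomputed per-amplicon lookups for assignment and realignment."""

    id: str
    contig: str
    seq: str                       # expected tagged product, upper case
    codes: np.ndarray
    p1: str                        # full fwd oligo (tag+insert+gene), upper
    p2: str                        # full rev oligo, upper
    clip_start: int                # amplicon coords: first non-primer base
    clip_end: int
    genomic_offset: int            # genomic = amplicon_pos + offset

    @property
    def clip_len(self) -> int:
        return self.clip_end - self.clip_start


def build_index(panel: Panel, amplicon_seqs: dict[str, str]
                ) -> list[AmpliconRef]:
    refs = []
    for amp in panel.amplicons:
        seq = amplicon_seqs[amp.id].upper()
        p1 = amp.fwd.oligo.upper()
        p2 = amp.rev.oligo.upper()
        prefix = len(amp.fwd.tag_seq) + len(amp.fwd.insert_seq)
        refs.append(AmpliconRef(
            id=amp.id, contig=amp.contig, seq=seq, codes=encode(seq),
            p1=p1, p2=p2,
            clip_start=len(p1),
            clip_end=len(seq) - len(p2),
            genomic_offset=amp.start - prefix,
        ))
    return refs


# ---------------------------------------------------------------------------
# read-pair assignment

def _hamming(a: str, b: str) -> int:
    return sum(c1 != c2 for c1, c2 in zip(a, b))


class AmpliconAssigner:
    """Assign read pairs to amplicons by their primer+tag prefixes.

    Exact-prefix dictionary first; pairs that miss (sequencing errors in
    the primer region) fall back to a Hamming scan.  Ambiguous pairs (two
    amplicons equally close within the mismatch budget) stay unassigned.
    """

    def __init__(self, refs: list[AmpliconRef], max_mismatch: int = 2):
        self.refs = refs
        self.max_mismatch = max_mismatch
        self.exact: dict[tuple[str, str], int] = {}
        self.length_combos = sorted({(len(r.p1), len(r.p2)) for r in refs})
        for idx, r in enumerate(refs):
            key = (r.p1, r.p2)
            if key in self.exact:
                raise ValueError(f"duplicate oligo pair for {r.id}")
            self.exact[key] = idx

    def assign(self, r1: str, r2: str) -> int | None:
        for l1, l2 in self.length_combos:
            idx = self.exact.get((r1[:l1], r2[:l2]))
            if idx is not None:
                return idx
        best_idx, best_d, tie = None, None, False
        for idx, ref in enumerate(self.refs):
            d1 = _hamming(r1[: len(ref.p1)], ref.p1)
            if d1 > self.max_mismatch:
                continue
            d2 = _hamming(r2[: len(ref.p2)], ref.p2)
            if d2 > self.max_mismatch:
                continue
            d = d1 + d2
            if best_d is None or d < best_d:
                best_idx, best_d, tie = idx, d, False
            elif d == best_d:
                tie = True
        if best_idx is None or tie:
            return None
        return best_idx


def assign_amplicon(r1: str, r2: str, refs: list[AmpliconRef],
                    max_mismatch: int = 2) -> str | None:
    """One-shot assignment; returns the amplicon id or None."""
    idx = AmpliconAssigner(refs, max_mismatch).assign(r1.upper(), r2.upper())
    return None if idx is None else refs[idx].id


# ---------------------------------------------------------------------------
# realignment and pair merging

@dataclass
class AlignedMate:
    """A mate projected onto amplicon coordinates.

    ``codes``/``quals`` cover [start, end); deleted reference positions
    carry code 4 with the min of the flanking base qualities; insertions
    are keyed by the reference position they precede.
    """

    start: int
    end: int
    codes: np.ndarray
    quals: np.ndarray
    insertions: dict[int, tuple[str, int]] = field(default_factory=dict)


class PairDropped(Exception):
    """Mates disagree structurally (incompatible indel paths)."""


def _project(read: str, quals: np.ndarray, aln: Alignment) -> AlignedMate:
    span = aln.ref_end - aln.ref_start
    codes = np.empty(span, dtype=np.int8)
    qarr = np.empty(span, dtype=np.int16)
    rcodes = encode(read)
    insertions: dict[int, tuple[str, int]] = {}
    r, p = aln.read_start, 0
    for op, length in aln.cigar:
        if op == "M":
            codes[p:p + length] = rcodes[r:r + length]
            qarr[p:p + length] = quals[r:r + length]
            r += length
            p += length
        elif op == "D":
            codes[p:p + length] = DEL
            left_q = quals[r - 1] if r > 0 else 30
            right_q = quals[r] if r < len(quals) else 30
            qarr[p:p + length] = min(int(left_q), int(right_q))
            p += length
        else:  # insertion relative to the amplicon reference
            q = int(quals[r:r + length].min())
            insertions[aln.ref_start + p] = (read[r:r + length], q)
            r += length
    return AlignedMate(start=aln.ref_start, end=aln.ref_end, codes=codes,
                       quals=qarr, insertions=insertions)


def align_mate(read: str, quals: np.ndarray, ref: AmpliconRef,
               anchored_start: bool, config: CallConfig) -> AlignedMate:
    """Place one mate on the amplicon: ungapped fast path, else banded SW."""
    n, L = len(read), len(ref.seq)
    rcodes = encode(read)
    if anchored_start:
        offset = 0
    else:
        offset = max(0, L - n)
    window = ref.codes[offset:offset + n]
    if len(window) == n:
        mism = int((window != rcodes).sum())
        if mism <= config.fast_path_max_mismatch:
            return AlignedMate(start=offset, end=offset + n,
                               codes=rcodes.copy(),
                               quals=quals.astype(np.int16))
    aln = smith_waterman(rcodes, ref.codes, config.scores,
                         band_center=offset,
                         band_halfwidth=config.band_halfwidth)
    if aln.read_end == aln.read_start:
        raise PairDropped("unalignable mate")
    return _project(read, quals, aln)


def merge_pair(m1: AlignedMate, m2: AlignedMate,
               config: CallConfig | None = None) -> AlignedMate:
    """Phred-weighted consensus of two mates on the same amplicon.

    Positions seen by one mate copy through.  Where both mates agree the
    consensus quality is min(Q1+Q2, cap); where they conflict the
    higher-quality base wins with quality max(|Q1-Q2|, floor).  Mates
    whose indel structure disagrees in the overlap raise
    :class:`PairDropped`.
    """
    cfg = config or CallConfig()
    start = min(m1.start, m2.start)
    end = max(m1.end, m2.end)
    codes = np.full(end - start, -1, dtype=np.int8)
    quals = np.zeros(end - start, dtype=np.int16)

    for m in (m1, m2):
        sl = slice(m.start - start, m.end - start)
        fresh = codes[sl] == -1
        agree = (~fresh) & (codes[sl] == m.codes)
        clash = (~fresh) & (codes[sl] != m.codes)
        if clash.any():
            c_old = codes[sl][clash]
            c_new = m.codes[clash]
            if ((c_old == DEL) != (c_new == DEL)).any():
                raise PairDropped("deletion present in only one mate")
        codes[sl][fresh] = m.codes[fresh]
        quals[sl][fresh] = m.quals[fresh]
        q_old = quals[sl][agree]
        quals[sl][agree] = np.minimum(q_old + m.quals[agree], cfg.merge_cap)
        if clash.any():
            q_old = quals[sl][clash]
            q_new = m.quals[clash]
            take_new = q_new > q_old
            merged_codes = codes[sl]
            tmp = merged_codes[clash]
            tmp[take_new] = m.codes[clash][take_new]
            merged_codes[clash] = tmp
            quals[sl][clash] = np.maximum(np.abs(q_new - q_old),
                                          cfg.merge_floor)

    insertions: dict[int, tuple[str, int]] = dict(m1.insertions)
    for pos, (seq, q) in m2.insertions.items():
        if pos in insertions:
            seq1, q1 = insertions[pos]
            if seq1 != seq:
                raise PairDropped("conflicting insertions")
            insertions[pos] = (seq, min(q1 + q, cfg.merge_cap))
        elif m1.start < pos < m1.end:
            raise PairDropped("insertion present in only one mate")
        else:
            insertions[pos] = (seq, q)
    for pos, _ in m1.insertions.items():
        if pos not in m2.insertions and m2.start < pos < m2.end:
            raise PairDropped("insertion present in only one mate")
    return AlignedMate(start=start, end=end, codes=codes, quals=quals,
                       insertions=insertions)


def clip_primers(merged: AlignedMate, ref: AmpliconRef) -> AlignedMate | None:
    """Soft-clip tag+insert+primer regions from both ends of the consensus.

    Returns None when nothing of the read survives outside the primer
    regions (such reads contribute no pileup evidence).
    """
    start = max(merged.start, ref.clip_start)
    end = min(merged.end, ref.clip_end)
    if end <= start:
        return None
    sl = slice(start - merged.start, end - merged.start)
    ins = {p: v for p, v in merged.insertions.items() if start < p < end}
    return AlignedMate(start=start, end=end, codes=merged.codes[sl],
                       quals=merged.quals[sl], insertions=ins)


# ---------------------------------------------------------------------------
# pileups, noise, calling

@dataclass
class SegmentPileup:
    """Per-position allele evidence for one amplicon's clipped segment."""

    ref: AmpliconRef
    weights: np.ndarray            # (L, 5) summed quality weights
    counts: np.ndarray             # (L, 5) read counts
    cover: np.ndarray              # (L,) merged reads covering the position
    # indel alleles: ("D", first_deleted_pos, length) / ("I", pos, seq)
    indels: dict[tuple, list] = field(default_factory=dict)

    @classmethod
    def empty(cls, ref: AmpliconRef) -> "SegmentPileup":
        L = ref.clip_len
        return cls(ref=ref, weights=np.zeros((L, 5)),
                   counts=np.zeros((L, 5), dtype=np.int64),
                   cover=np.zeros(L, dtype=np.int64))

    def add_read(self, clipped: AlignedMate) -> None:
        off = self.ref.clip_start
        lo, hi = clipped.start - off, clipped.end - off
        self.cover[lo:hi] += 1
        valid = clipped.codes >= 0
        pos = np.nonzero(valid)[0] + lo
        codes = clipped.codes[valid].astype(np.int64)
        w = _WEIGHT[np.clip(clipped.quals[valid], 0, 93)]
        np.add.at(self.weights, (pos, codes), w)
        np.add.at(self.counts, (pos, codes), 1)
        # aggregate deletion runs into single indel alleles
        if (clipped.codes == DEL).any():
            dd = np.flatnonzero(clipped.codes == DEL)
            run_start = dd[np.r_[True, np.diff(dd) > 1]]
            run_end = dd[np.r_[np.diff(dd) > 1, True]]
            for s, e in zip(run_start, run_end):
                key = ("D", int(s) + clipped.start, int(e - s) + 1)
                wq = float(_WEIGHT[np.clip(clipped.quals[s], 0, 93)])
                self.indels.setdefault(key, [0.0, 0])
                self.indels[key][0] += wq
                self.indels[key][1] += 1
        for p, (seq, q) in clipped.insertions.items():
            key = ("I", p, seq.upper())
            self.indels.setdefault(key, [0.0, 0])
            self.indels[key][0] += float(_WEIGHT[min(q, 93)])
            self.indels[key][1] += 1


@dataclass
class NoiseStats:
    """Background non-reference quality-weighted frequency of a segment."""

    segment_id: str
    mu: float
    sd: float
    n_obs: int
    flagged: bool = False          # zero-coverage segment


def estimate_noise(pileup: SegmentPileup,
                   candidate_exclusion: float = 0.05) -> NoiseStats:
    """Mean/SD of per-(position, allele) non-reference qwf values.

    Every alternate base (and the deletion column) at every covered
    position contributes one observation unless its qwf reaches the
    exclusion ceiling — those are candidate variants, not noise, and must
    not inflate the background.
    """
    ref = pileup.ref
    covered = pileup.cover > 0
    if not covered.any():
        return NoiseStats(ref.id, 0.0, 0.0, 0, flagged=True)
    W = pileup.weights[covered]
    tot = W.sum(axis=1)
    tot[tot == 0] = 1.0
    qwf = W / tot[:, None]
    ref_codes = ref.codes[ref.clip_start:ref.clip_end][covered]
    mask = np.ones_like(qwf, dtype=bool)
    mask[np.arange(len(ref_codes)), ref_codes] = False   # drop ref allele
    obs = qwf[mask]
    obs = obs[obs < candidate_exclusion]
    if obs.size == 0:
        return NoiseStats(ref.id, 0.0, 0.0, 0)
    return NoiseStats(ref.id, float(obs.mean()), float(obs.std()),
                      int(obs.size))


@dataclass
class VariantCall:
    contig: str
    pos: int                        # 1-based
    ref: str
    alt: str
    qwf: float
    support: int
    depth: int
    filter: str                     # PASS | low_support | low_frequency
    amplicon_id: str
    noise_mu: float
    noise_sd: float

    @property
    def frequency(self) -> float:
        return self.support / self.depth if self.depth else 0.0


def _status(support: int, depth: int, cfg: CallConfig) -> str:
    if support < cfg.min_support:
        return "low_support"
    if depth == 0 or support / depth < cfg.min_frequency:
        return "low_frequency"
    return "PASS"


def call_variants(pileup: SegmentPileup, noise: NoiseStats,
                  config: CallConfig | None = None,
                  sd_multiplier: float | None = None) -> list[VariantCall]:
    """Call alleles whose qwf clears the 6-SD noise gate, then filter.

    A degenerate segment (sd = 0) falls back to qwf > max(mu, floor).
    Indel alleles come from the realignment edit paths, aggregated per
    (position, allele) and reported left-aligned in VCF convention.
    """
    cfg = config or CallConfig()
    k = cfg.sd_multiplier if sd_multiplier is None else sd_multiplier
    ref = pileup.ref
    if noise.sd > 0:
        gate = noise.mu + k * noise.sd
    else:
        gate = max(noise.mu, cfg.qwf_floor)
    calls: list[VariantCall] = []
    W = pileup.weights
    tot = W.sum(axis=1)
    safe_tot = np.where(tot == 0, 1.0, tot)
    qwf = W / safe_tot[:, None]
    ref_codes = ref.codes[ref.clip_start:ref.clip_end]

    def genomic(p_amp: int) -> int:
        return p_amp + ref.genomic_offset

    cand_pos, cand_allele = np.nonzero(qwf > gate)
    for p, b in zip(cand_pos, cand_allele):
        if b == ref_codes[p] or b == DEL:
            continue  # deletions are called from aggregated runs
        p_amp = int(p) + ref.clip_start
        ref_base = ref.seq[p_amp]
        g0 = genomic(p_amp)          # 0-based genomic
        calls.append(VariantCall(
            contig=ref.contig, pos=g0 + 1, ref=ref_base, alt=_BASE[b],
            qwf=float(qwf[p, b]), support=int(pileup.counts[p, b]),
            depth=int(pileup.cover[p]),
            filter=_status(int(pileup.counts[p, b]), int(pileup.cover[p]),
                           cfg),
            amplicon_id=ref.id, noise_mu=noise.mu, noise_sd=noise.sd,
        ))
    for (kind, p_amp, payload), (w, count) in pileup.indels.items():
        anchor = p_amp if kind == "D" else p_amp - 1
        pi = anchor - ref.clip_start
        if pi < 0 or pi >= ref.clip_len:
            continue
        # deletion mass is part of the DEL column of tot; insertion reads
        # already contribute their anchor base, so both use weight/tot
        q = min(w / max(float(tot[pi]), 1e-12), 1.0)
        if q <= gate:
            continue
        depth = int(pileup.cover[pi])
        if kind == "D":
            length = payload
            vref = ref.seq[p_amp - 1: p_amp + length]
            valt = ref.seq[p_amp - 1]
            pos1 = genomic(p_amp - 1) + 1
        else:
            vref = ref.seq[anchor]
            valt = ref.seq[anchor] + payload
            pos1 = genomic(anchor) + 1
        # normalise within the amplicon sequence, then shift to genome
        pos_amp1 = pos1 - ref.genomic_offset
        norm_pos, vref, valt = left_align(pos_amp1, vref, valt, ref.seq)
        pos1 = norm_pos + ref.genomic_offset
        calls.append(VariantCall(
            contig=ref.contig, pos=pos1, ref=vref, alt=valt,
            qwf=float(q), support=int(count), depth=depth,
            filter=_status(int(count), depth, cfg),
            amplicon_id=ref.id, noise_mu=noise.mu, noise_sd=noise.sd,
        ))
    calls.sort(key=lambda c: (c.contig, c.pos, c.ref, c.alt))
    return calls


def dedupe_calls(calls: list[VariantCall]) -> list[VariantCall]:
    """Collapse the same variant seen from overlapping amplicons.

    Keeps the best-supported record (PASS preferred, then depth)."""
    best: dict[tuple, VariantCall] = {}
    for c in calls:
        key = (c.contig, c.pos, c.ref, c.alt)
        cur = best.get(key)
        if cur is None:
            best[key] = c
            continue
        rank = (c.filter == "PASS", c.depth)
        cur_rank = (cur.filter == "PASS", cur.depth)
        if rank > cur_rank:
            best[key] = c
    return sorted(best.values(), key=lambda c: (c.contig, c.pos, c.ref, c.alt))


# ---------------------------------------------------------------------------
# coverage statistics

COVERAGE_KS = (0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0)


@dataclass
class CoverageReport:
    mean: float
    median: float
    minimum: int
    maximum: int
    uniformity: float              # fraction of ROI bases >= 0.2x mean
    threshold_table: dict[float, float]
    mapping_rate: float
    on_target_rate: float
    per_amplicon: dict[str, float]  # non-overlap-region mean depth

    def to_dict(self) -> dict:
        return {
            "mean": self.mean, "median": self.median,
            "min": self.minimum, "max": self.maximum,
            "uniformity": self.uniformity,
            "threshold_table": {str(k): v
                                for k, v in self.threshold_table.items()},
            "mapping_rate": self.mapping_rate,
            "on_target_rate": self.on_target_rate,
            "per_amplicon": self.per_amplicon,
        }


def coverage_report(pileups: dict[str, SegmentPileup], panel: Panel,
                    total_pairs: int, assigned_pairs: int) -> CoverageReport:
    """ROI depth profile from merged (pair-collapsed) reads.

    Depth at a genomic base sums the covering merged reads of every
    amplicon whose clipped segment spans it; the relative-coverage table
    reports the fraction of ROI bases at or above each multiple of the
    mean.  Per-amplicon coverage is measured on each amplicon's
    non-overlapping region only.
    """
    depth_by_contig: dict[str, dict[int, int]] = {}
    for pid, pu in pileups.items():
        ref = pu.ref
        d = depth_by_contig.setdefault(ref.contig, {})
        base = ref.clip_start + ref.genomic_offset
        for i, c in enumerate(pu.cover):
            if c:
                d[base + i] = d.get(base + i, 0) + int(c)
    depths = []
    for contig, s, e in panel.roi:
        d = depth_by_contig.get(contig, {})
        depths.extend(d.get(p, 0) for p in range(s, e))
    arr = np.asarray(depths, dtype=np.int64)
    mean = float(arr.mean()) if arr.size else 0.0
    table = {}
    for k in COVERAGE_KS:
        table[k] = float((arr >= k * mean).mean()) if mean > 0 else 0.0

    overlap_pos: dict[str, set] = {}
    for j in panel.junctions:
        amp = panel.amplicon(j.left_id)
        overlap_pos.setdefault(amp.contig, set()).update(
            range(j.overlap_start, j.overlap_end))
    per_amp = {}
    for pid, pu in pileups.items():
        ref = pu.ref
        base = ref.clip_start + ref.genomic_offset
        ovl = overlap_pos.get(ref.contig, set())
        vals = [int(c) for i, c in enumerate(pu.cover)
                if (base + i) not in ovl]
        per_amp[pid] = float(np.mean(vals)) if vals else 0.0

    roi_bases = {(c, p) for c, s, e in panel.roi for p in range(s, e)}
    on_target_num = 0
    total_bases = 0
    for pid, pu in pileups.items():
        ref = pu.ref
        base = ref.clip_start + ref.genomic_offset
        for i, c in enumerate(pu.cover):
            total_bases += int(c)
            if (ref.contig, base + i) in roi_bases:
                on_target_num += int(c)
    return CoverageReport(
        mean=mean,
        median=float(np.median(arr)) if arr.size else 0.0,
        minimum=int(arr.min()) if arr.size else 0,
        maximum=int(arr.max()) if arr.size else 0,
        uniformity=table[0.2],
        threshold_table=table,
        mapping_rate=assigned_pairs / total_pairs if total_pairs else 0.0,
        on_target_rate=(on_target_num / total_bases) if total_bases else 0.0,
        per_amplicon=per_amp,
    )


# ---------------------------------------------------------------------------
# end-to-end driver

@dataclass
class PipelineResult:
    calls: list[VariantCall]
    all_candidates: list[VariantCall]
    noise: dict[str, NoiseStats]
    pileups: dict[str, SegmentPileup]
    coverage: CoverageReport
    tallies: dict[str, int]


def run_pipeline(
    pairs: list[tuple[str, str, str, str, str]],
    panel: Panel,
    amplicon_seqs: dict[str, str],
    config: CallConfig | None = None,
) -> PipelineResult:
    """Run assignment -> realignment -> merge -> clip -> pileup -> calls.

    ``pairs`` are (name, read1, qual1, read2, qual2) tuples (as produced
    by the read simulator or loaded from FASTQ).
    """
    cfg = config or CallConfig()
    refs = build_index(panel, amplicon_seqs)
    assigner = AmpliconAssigner(refs, cfg.max_mismatch)
    pileups = {r.id: SegmentPileup.empty(r) for r in refs}
    tallies = {"total_pairs": 0, "assigned": 0, "unassigned": 0,
               "merged": 0, "dropped_incompatible": 0, "clipped_away": 0}
    for _, r1, q1, r2, q2 in pairs:
        tallies["total_pairs"] += 1
        idx = assigner.assign(r1.upper(), r2.upper())
        if idx is None:
            tallies["unassigned"] += 1
            continue
        tallies["assigned"] += 1
        ref = refs[idx]
        q1a = np.frombuffer(q1.encode(), dtype=np.uint8).astype(np.int16) - 33
        q2a = np.frombuffer(q2.encode(), dtype=np.uint8).astype(np.int16) - 33
        try:
            m1 = align_mate(r1.upper(), q1a, ref, True, cfg)
            m2 = align_mate(reverse_complement(r2.upper()), q2a[::-1], ref,
                            False, cfg)
            merged = merge_pair(m1, m2, cfg)
        except PairDropped:
            tallies["dropped_incompatible"] += 1
            continue
        tallies["merged"] += 1
        clipped = clip_primers(merged, ref)
        if clipped is None:
            tallies["clipped_away"] += 1
            continue
        pileups[ref.id].add_read(clipped)

    noise = {rid: estimate_noise(pu, cfg.candidate_exclusion)
             for rid, pu in pileups.items()}
    candidates: list[VariantCall] = []
    for rid, pu in pileups.items():
        candidates.extend(call_variants(pu, noise[rid], cfg))
    candidates = dedupe_calls(candidates)
    coverage = coverage_report(pileups, panel, tallies["total_pairs"],
                               tallies["assigned"])
    return PipelineResult(
        calls=[c for c in candidates if c.filter == "PASS"],
        all_candidates=candidates,
        noise=noise,
        pileups=pileups,
        coverage=coverage,
        tallies=tallies,
    )
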