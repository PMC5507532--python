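"""Deterministic kinetics of multiplex PCR over overlapping amplicons.

Two adjacent overlapping amplicons amplified in one tube yield four
species: the two targets (Amplicon 1 and 2), the short unwanted overlap
product (Amplicon 3, made by the two inner primers) and the long spanning
product (Amplicon 4, made by the two outer primers).  Under a constant
annealing temperature with perfect efficiency the expected amplification
folds after n cycles are n*2^n, n*2^n, n^2*2^n and 2^n respectively: the
overlap product outgrows the targets linearly in cycle number and takes
over the reaction.

The stem-loop inhibition design defeats this by making the overlap
product's two ends complementary (same tag + an inserted primer prefix),
so that each single strand snaps into a terminal hairpin whose stem
sequesters part of the primer binding site.  The model here is
expected-copy (deterministic) bookkeeping: a branching recurrence during
the low-temperature gene-specific cycles, then end-primed exponential
growth during the high-temperature cycles, with per-end priming
efficiencies gated by a logistic function of the melting temperature of
the *accessible* (non-stem) portion of each primer's binding site, and a
length-dependent extension penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .seqcore import TAG_T1, TAG_T2, find_terminal_stem, melting_temp


@dataclass(frozen=True)
class SimParams:
    """Cycling and calibration parameters.

    ``delta_t`` shifts and ``slope`` scales the logistic priming-efficiency
    curve e = logistic((Tm_accessible - T_anneal + delta_t)/slope); both in
    degrees C.  ``length_decay`` is the per-bp exponential extension
    penalty.  Defaults are calibrated so the three qualitative gel
    outcomes hold: tag-only stems do not inhibit the overlap product,
    inserted-primer stems of >= 12 nt nearly abolish it, and the long
    spanning product stays faint.
    """

    total_cycles: int = 35
    stage1_cycles: int = 5
    stage1_anneal_t: float = 60.0
    stage2_anneal_t: float = 72.0
    delta_t: float = 22.0
    slope: float = 3.0
    length_decay: float = 0.002
    tm_method: str = "wallace"

    def __post_init__(self) -> None:
        if self.stage1_cycles > self.total_cycles:
            raise ValueError("stage1_cycles must be <= total_cycles")
        if self.slope <= 0 or self.length_decay < 0:
            raise ValueError("slope must be > 0 and length_decay >= 0")


@dataclass
class FoldTrajectory:
    """Expected copies of each species at one cycle."""

    cycle: int
    amplicon1: float
    amplicon2: float
    amplicon3: float
    amplicon4: float


def fold_closed_form(n: int) -> tuple[float, float, float, float]:
    """Idealised amplification folds (A1, A2, A4, A3) after n cycles.

    Assumes 100% efficiency and a constant annealing temperature; the
    overlap product A3 grows as n^2 * 2^n, n-fold beyond the targets.
    """
    if n < 0 or int(n) != n:
        raise ValueError("cycle number must be a non-negative integer")
    p = 2.0 ** n
    return (n * p, n * p, p, n * n * p)


def simulate_branching(
    n_cycles: int,
    efficiencies: dict[str, float] | None = None,
    initial_template: float = 1.0,
) -> list[FoldTrajectory]:
    """Per-cycle branching recurrence with constant annealing.

    Per cycle, the spanning product doubles from itself (seeded by the
    genomic template); each target gains copies from itself and from the
    spanning product; the overlap product gains from itself and from every
    longer species.  With all efficiencies 1 this reproduces 2^n exactly
    for the spanning product and the closed-form growth orders (not the
    constant factors) for the rest: A1 ~ n*2^(n-1), A3 ~ n(n+1)*2^(n-2),
    so A3/A1 = (n+1)/2 grows linearly in n.
    """
    eff = {"a1": 1.0, "a2": 1.0, "a3": 1.0, "a4": 1.0}
    if efficiencies:
        eff.update(efficiencies)
    for key, e in eff.items():
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"efficiency {key}={e} outside [0, 1]")
    a1 = a2 = a3 = 0.0
    a4 = float(initial_template)
    out = [FoldTrajectory(0, a1, a2, a3, a4)]
    for n in range(1, n_cycles + 1):
        na1 = a1 + eff["a1"] * (a1 + a4)
        na2 = a2 + eff["a2"] * (a2 + a4)
        na3 = a3 + eff["a3"] * (a3 + a1 + a2 + a4)
        na4 = a4 + eff["a4"] * a4
        a1, a2, a3, a4 = na1, na2, na3, na4
        out.append(FoldTrajectory(n, a1, a2, a3, a4))
    return out


def logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def priming_efficiency(
    oligo: str,
    accessible_len: int,
    anneal_t: float,
    params: SimParams | None = None,
) -> float:
    """Probability that a primer anneals and extends in one cycle.

    Only the 3'-most ``accessible_len`` bases of the binding site are open
    for hybridisation (the rest may be sequestered in a terminal stem);
    efficiency is a logistic function of the melting temperature of that
    accessible portion relative to the annealing temperature.
    """
    params = params or SimParams()
    if accessible_len > len(oligo):
        raise ValueError("accessible_len exceeds oligo length")
    if accessible_len <= 0:
        return 0.0
    tm = melting_temp(oligo[-accessible_len:], params.tm_method)
    return logistic((tm - anneal_t + params.delta_t) / params.slope)


# ---------------------------------------------------------------------------
# species-level simulation

@dataclass
class Species:
    """One PCR product: its two priming oligos and structural bookkeeping.

    ``stem_length`` is the terminal duplex of the product strand (0 when
    the two ends carry different tags); each end's accessible binding-site
    length is the full oligo minus the stem.
    """

    name: str
    length_bp: int
    fwd_oligo: str
    rev_oligo: str
    stem_length: int
    kind: str  # "target" | "overlap" | "spanning"


def species_efficiency(sp: Species, anneal_t: float, params: SimParams,
                       gene_only: bool, gene_lengths: tuple[int, int]) -> float:
    """Per-cycle efficiency: limiting-primer logistic gate x length decay.

    With ``gene_only`` (stage 1, genomic template) only the gene-specific
    3' parts can hybridise and no product stems exist yet; afterwards the
    accessible length is the full oligo minus the product's terminal stem.
    """
    es = []
    for oligo, glen in zip((sp.fwd_oligo, sp.rev_oligo), gene_lengths):
        if gene_only:
            acc = glen
        else:
            acc = max(0, len(oligo) - sp.stem_length)
        es.append(priming_efficiency(oligo, acc, anneal_t, params))
    return min(es) * math.exp(-params.length_decay * sp.length_bp)


def simulate_species(
    species: dict[str, Species],
    gene_lengths: dict[str, tuple[int, int]],
    params: SimParams | None = None,
    initial_template: float = 1.0,
) -> pd.DataFrame:
    """Run two-stage cycling over the four species of one junction.

    Stage 1 (low annealing temperature): gene-specific priming on genomic
    template, full branching — every longer species templates the overlap
    product.  Stage 2 (high annealing temperature): only fully formed
    tagged ends prime, gated by stem accessibility, so each species grows
    exponentially from its own pool.  Returns the per-cycle trajectory.
    """
    params = params or SimParams()
    pools = {"a1": 0.0, "a2": 0.0, "a3": 0.0, "a4": float(initial_template)}
    rows = [dict(cycle=0, **pools)]
    for cyc in range(1, params.total_cycles + 1):
        stage1 = cyc <= params.stage1_cycles
        anneal = params.stage1_anneal_t if stage1 else params.stage2_anneal_t
        eff = {k: species_efficiency(species[k], anneal, params, stage1,
                                     gene_lengths[k])
               for k in pools}
        if stage1:
            new = {
                "a1": pools["a1"] + eff["a1"] * (pools["a1"] + pools["a4"]),
                "a2": pools["a2"] + eff["a2"] * (pools["a2"] + pools["a4"]),
                "a3": pools["a3"] + eff["a3"] * (pools["a3"] + pools["a1"]
                                                 + pools["a2"] + pools["a4"]),
                "a4": pools["a4"] * (1.0 + eff["a4"]),
            }
        else:
            new = {k: pools[k] * (1.0 + eff[k]) for k in pools}
        pools = new
        rows.append(dict(cycle=cyc, **pools))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the two-amplicon proof-of-concept system

F1_GENE = "GTGAAAGACATATTTACAGACAGTTTC"
R1_GENE = "CTTGTGAGCTGGTCTGAATGT"
F2_GENE = "AGGGAAGCTTCATAAGTCAGTC"
R2_GENE = "TCCTCTAACACTCCCTTAACTTTGT"


@dataclass(frozen=True)
class TwoPlexDesign:
    """The 2-amplicon benchmark: 497 + 360 bp targets, 195 bp overlap.

    ``insert_len`` > 0 arms the stem-loop (F2^ inserted into R1);
    ``tag_extension`` > 0 instead lengthens the shared tag on both inner
    primers (tag-only stem), which builds an equally long stem but leaves
    the whole gene-specific binding site in the loop.
    """

    insert_len: int = 0
    tag_extension: int = 0
    a1_len: int = 497
    a2_len: int = 360
    overlap_len: int = 195
    tag1: str = TAG_T1
    tag2: str = TAG_T2
    extension_source: str = F2_GENE  # tStem extensions mirror F2^ sequence

    def species(self) -> tuple[dict[str, Species], dict[str, tuple[int, int]]]:
        ext = self.extension_source[: self.tag_extension].upper()
        ins = F2_GENE[: self.insert_len].upper()
        t1, t2 = self.tag1, self.tag2
        f1 = t2 + F1_GENE
        r1 = ext + t1 + ins + R1_GENE
        f2 = ext + t1 + F2_GENE
        r2 = t2 + R2_GENE
        tagged = 2 * len(t1)  # both product ends carry ~tag-length additions
        sp = {
            "a1": Species("Amplicon1", self.a1_len + tagged, f1, r1, 0,
                          "target"),
            "a2": Species("Amplicon2", self.a2_len + tagged, f2, r2, 0,
                          "target"),
            # overlap product: both ends share t1; stem = ext + tag + insert
            "a3": Species("Amplicon3", self.overlap_len + tagged, f2, r1,
                          len(ext) + len(t1) + len(ins), "overlap"),
            # spanning product: both outer primers carry t2 -> tag-only stem
            "a4": Species("Amplicon4",
                          self.a1_len + self.a2_len - self.overlap_len
                          + tagged, f1, r2, len(t2), "spanning"),
        }
        glens = {
            "a1": (len(F1_GENE), len(R1_GENE)),
            "a2": (len(F2_GENE), len(R2_GENE)),
            "a3": (len(F2_GENE), len(R1_GENE)),
            "a4": (len(F1_GENE), len(R2_GENE)),
        }
        return sp, glens


def simulate_two_plex(
    design: TwoPlexDesign, params: SimParams | None = None
) -> pd.DataFrame:
    """Virtual gel for the 2-plex benchmark: final copies and fractions."""
    params = params or SimParams()
    species, glens = design.species()
    traj = simulate_species(species, glens, params)
    final = traj.iloc[-1]
    total = sum(final[k] for k in ("a1", "a2", "a3", "a4"))
    rows = []
    for key in ("a1", "a2", "a3", "a4"):
        sp = species[key]
        rows.append({
            "species": sp.name, "length_bp": sp.length_bp,
            "copies": final[key], "fraction": final[key] / total,
        })
    return pd.DataFrame(rows)


def _run_single_species(sp: Species, gene_lengths: tuple[int, int],
                        params: SimParams,
                        initial_template: float = 1.0) -> float:
    """Two-stage expected-copy growth of one species in isolation.

    Stage 1 seeds the species from the genomic template with gene-specific
    priming; stage 2 is end-primed exponential growth gated by the
    species' terminal stem.  Cross-templating between junctions is not
    modelled at panel level.
    """
    pool = 0.0
    for cyc in range(1, params.total_cycles + 1):
        stage1 = cyc <= params.stage1_cycles
        anneal = params.stage1_anneal_t if stage1 else params.stage2_anneal_t
        e = species_efficiency(sp, anneal, params, stage1, gene_lengths)
        if stage1:
            pool = pool + e * (pool + initial_template)
        else:
            pool = pool * (1.0 + e)
    return pool


def simulate_slimamp(panel, reference: dict[str, str],
                     params: SimParams | None = None) -> pd.DataFrame:
    """Virtual gel for a designed panel: targets plus per-junction overlap
    and spanning products.

    Product strands are built from the panel oligos and their terminal
    stems measured directly with the stem finder; each species is cycled
    through the two-stage model independently.
    """
    from . import panel as panel_mod
    from .seqcore import reverse_complement

    params = params or SimParams()
    records = []

    def add(name, kind, strand, fwd, rev, glens):
        stem = find_terminal_stem(strand).stem_length
        sp = Species(name, len(strand), fwd, rev, stem, kind)
        copies = _run_single_species(sp, glens, params)
        records.append((name, kind, len(strand), copies))

    for amp in panel.amplicons:
        add(amp.id, "target", panel_mod.amplicon_sequence(amp, reference),
            amp.fwd.oligo, amp.rev.oligo,
            (len(amp.fwd.gene_seq), len(amp.rev.gene_seq)))
    for j in panel.junctions:
        left = panel.amplicon(j.left_id)
        right = panel.amplicon(j.right_id)
        add(f"{j.left_id}/{j.right_id}:overlap", "overlap",
            panel_mod.overlap_amplicon_sequence(panel, j, reference),
            right.fwd.oligo, left.rev.oligo,
            (len(right.fwd.gene_seq), len(left.rev.gene_seq)))
        span_strand = (
            left.fwd.tag_seq + left.fwd.insert_seq
            + reference[left.contig][left.start:right.end].upper()
            + reverse_complement(right.rev.tag_seq + right.rev.insert_seq)
        )
        add(f"{j.left_id}/{j.right_id}:spanning", "spanning", span_strand,
            left.fwd.oligo, right.rev.oligo,
            (len(left.fwd.gene_seq), len(right.rev.gene_seq)))
    df = pd.DataFrame(records, columns=["species", "kind", "length_bp",
                                        "copies"])
    df["fraction"] = df["copies"] / df["copies"].sum()
    return df
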