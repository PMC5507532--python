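import numpy as np
import pytest

from slimamp import ampcall, panel as pm, readsim
from slimamp.ampcall import (
    CallConfig,
    AlignedMate,
    AmpliconAssigner,
    NoiseStats,
    PairDropped,
    SegmentPileup,
    build_index,
    call_variants,
    clip_primers,
    coverage_report,
    dedupe_calls,
    estimate_noise,
    merge_pair,
    run_pipeline,
)
from slimamp.readsim import ReadProfile, VariantSpec, diploid_haplotypes
from slimamp.seqcore import reverse_complement


def _mate(start, bases, quals, insertions=None):
    from slimamp.align import encode
    return AlignedMate(start=start, end=start + len(bases),
                       codes=encode(bases) if isinstance(bases, str)
                       else bases,
                       quals=np.asarray(quals, dtype=np.int16),
                       insertions=insertions or {})


class TestAssignment:
    def test_error_free_pair_assigned_to_true_amplicon(self, two_amp_panel,
                                                       two_amp_ref,
                                                       two_amp_seqs):
        refs = build_index(two_amp_panel, two_amp_seqs)
        haps = diploid_haplotypes(two_amp_ref, [])
        for amp in two_amp_panel.amplicons:
            frag = readsim._fragment(two_amp_panel, amp, haps[0])
            got = ampcall.assign_amplicon(frag[:250],
                                          reverse_complement(frag)[:250],
                                          refs)
            assert got == amp.id

    def test_three_primer_mismatches_unassigned(self, two_amp_panel,
                                                two_amp_seqs, two_amp_ref):
        refs = build_index(two_amp_panel, two_amp_seqs)
        haps = diploid_haplotypes(two_amp_ref, [])
        frag = readsim._fragment(two_amp_panel, two_amp_panel.amplicons[0],
                                 haps[0])
        r1 = list(frag[:250])
        for p in (3, 9, 15):  # inside the tag/primer prefix
            r1[p] = "A" if r1[p] != "A" else "C"
        got = ampcall.assign_amplicon("".join(r1),
                                      reverse_complement(frag)[:250],
                                      refs, max_mismatch=2)
        assert got is None

    def test_bulk_assignment_rate_at_low_error(self, small_panel, small_ref,
                                               small_panel_seqs):
        refs = build_index(small_panel, small_panel_seqs)
        assigner = AmpliconAssigner(refs, max_mismatch=2)
        haps = diploid_haplotypes(small_ref, [])
        prof = ReadProfile(depth_mean=40, depth_log_sigma=0.0,
                           error_rate=0.001, seed=9)
        recs = readsim.simulate_reads(small_panel, haps, prof)
        correct = 0
        for name, r1, _, r2, _ in recs:
            idx = assigner.assign(r1, r2)
            if idx is not None and refs[idx].id == name.split(":")[1]:
                correct += 1
        assert correct / len(recs) >= 0.99


class TestMergePair:
    def test_agreeing_overlap_sums_quality_capped(self):
        m1 = _mate(0, "ACGT", [30, 30, 30, 30])
        m2 = _mate(2, "GTAA", [30, 35, 20, 20])
        merged = merge_pair(m1, m2)
        assert merged.start == 0 and merged.end == 6
        assert merged.quals[2] == 60   # 30 + 30 capped
        assert merged.quals[3] == 60   # 30 + 35 -> cap 60
        assert merged.quals[4] == 20   # mate2 only

    def test_conflict_keeps_higher_quality_base(self):
        m1 = _mate(0, "A", [35])
        m2 = _mate(0, "C", [10])
        merged = merge_pair(m1, m2)
        assert merged.codes[0] == 0    # A
        assert merged.quals[0] == 25   # |35 - 10|

    def test_conflict_quality_floor(self):
        merged = merge_pair(_mate(0, "A", [20]), _mate(0, "C", [19]))
        assert merged.quals[0] == 2

    def test_non_overlapping_mates_concatenate(self):
        m1 = _mate(0, "ACGT", [30] * 4)
        m2 = _mate(8, "ACGT", [25] * 4)
        merged = merge_pair(m1, m2)
        assert merged.start == 0 and merged.end == 12
        assert (merged.codes[4:8] == -1).all()
        assert merged.quals[0] == 30 and merged.quals[8] == 25

    def test_discordant_deletion_drops_pair(self):
        m1 = _mate(0, "ACGT", [30] * 4)
        codes = np.array([0, 4, 2, 3], dtype=np.int8)  # A - G T
        m2 = AlignedMate(0, 4, codes, np.array([30] * 4, dtype=np.int16))
        with pytest.raises(PairDropped):
            merge_pair(m1, m2)

    def test_conflicting_insertions_drop_pair(self):
        m1 = _mate(0, "ACGT", [30] * 4, {2: ("TT", 30)})
        m2 = _mate(0, "ACGT", [30] * 4, {2: ("TA", 30)})
        with pytest.raises(PairDropped):
            merge_pair(m1, m2)

    def test_matching_insertions_combine(self):
        m1 = _mate(0, "ACGT", [30] * 4, {2: ("TT", 30)})
        m2 = _mate(0, "ACGT", [30] * 4, {2: ("TT", 25)})
        merged = merge_pair(m1, m2)
        assert merged.insertions[2] == ("TT", 55)


class TestClip:
    def test_clip_window_arithmetic(self, two_amp_panel, two_amp_seqs):
        refs = build_index(two_amp_panel, two_amp_seqs)
        ref = refs[0]
        amp = two_amp_panel.amplicons[0]
        whole = _mate(0, ref.seq, [30] * len(ref.seq))
        clipped = clip_primers(whole, ref)
        assert clipped.start == len(amp.fwd.oligo)
        assert clipped.end == len(ref.seq) - len(amp.rev.oligo)

    def test_read_entirely_in_primer_region_dropped(self, two_amp_panel,
                                                    two_amp_seqs):
        refs = build_index(two_amp_panel, two_amp_seqs)
        ref = refs[0]
        inside = _mate(2, ref.seq[2:20], [30] * 18)
        assert clip_primers(inside, ref) is None


def _uniform_pileup(ref, depth, het_at=None):
    """Synthetic clean pileup, optionally with one 50% het SNV."""
    pu = SegmentPileup.empty(ref)
    L = ref.clip_len
    codes = ref.codes[ref.clip_start:ref.clip_end]
    w = 1.0 - 10 ** -3.0  # Q30
    for i in range(L):
        pu.cover[i] = depth
        pu.weights[i, codes[i]] = depth * w
        pu.counts[i, codes[i]] = depth
    if het_at is not None:
        i, alt = het_at
        pu.weights[i, codes[i]] = depth * w / 2
        pu.counts[i, codes[i]] = depth // 2
        pu.weights[i, alt] = depth * w / 2
        pu.counts[i, alt] = depth - depth // 2
    return pu


class TestNoise:
    def test_error_free_pileup_has_zero_noise(self, two_amp_panel,
                                              two_amp_seqs):
        refs = build_index(two_amp_panel, two_amp_seqs)
        pu = _uniform_pileup(refs[0], 100)
        ns = estimate_noise(pu)
        assert ns.mu == 0.0 and ns.sd == 0.0 and not ns.flagged

    def test_zero_coverage_segment_flagged(self, two_amp_panel,
                                           two_amp_seqs):
        refs = build_index(two_amp_panel, two_amp_seqs)
        ns = estimate_noise(SegmentPileup.empty(refs[0]))
        assert ns.flagged

    def test_true_het_excluded_from_noise_set(self, two_amp_panel,
                                              two_amp_seqs):
        refs = build_index(two_amp_panel, two_amp_seqs)
        codes = refs[0].codes[refs[0].clip_start:refs[0].clip_end]
        alt = (codes[10] + 1) % 4
        pu = _uniform_pileup(refs[0], 100, het_at=(10, alt))
        ns = estimate_noise(pu)
        assert ns.mu == 0.0 and ns.sd == 0.0

    def test_uniform_error_noise_mean_matches_expectation(self):
        """1% uniform substitution error -> per-alt-allele qwf ~ 0.01/3."""
        ref = readsim.make_reference(1500, 0.5, 31)
        panel = pm.design_panel([("chrS", 600, 850)], ref)
        assert len(panel.amplicons) == 1
        seqs = {a.id: pm.amplicon_sequence(a, ref).upper()
                for a in panel.amplicons}
        haps = diploid_haplotypes(ref, [])
        prof = ReadProfile(depth_mean=1000, depth_log_sigma=0.0,
                           error_rate=0.01, seed=13)
        recs = readsim.simulate_reads(panel, haps, prof)
        res = run_pipeline(recs, panel, seqs)
        ns = res.noise[panel.amplicons[0].id]
        # merged overlap corrects some errors; allow a wide but bounded window
        assert 0.01 / 3 * 0.5 < ns.mu < 0.01 / 3 * 1.2
        assert ns.sd > 0


class TestCalling:
    def test_clean_het_passes(self, two_amp_panel, two_amp_seqs):
        refs = build_index(two_amp_panel, two_amp_seqs)
        ref = refs[0]
        codes = ref.codes[ref.clip_start:ref.clip_end]
        alt = (codes[15] + 1) % 4
        pu = _uniform_pileup(ref, 1000, het_at=(15, alt))
        calls = call_variants(pu, estimate_noise(pu))
        assert len(calls) == 1
        c = calls[0]
        assert c.filter == "PASS"
        assert c.pos == ref.clip_start + 15 + ref.genomic_offset + 1
        assert c.qwf == pytest.approx(0.5, abs=0.01)

    def test_nineteen_percent_frequency_filtered(self, two_amp_panel,
                                                 two_amp_seqs):
        refs = build_index(two_amp_panel, two_amp_seqs)
        ref = refs[0]
        codes = ref.codes[ref.clip_start:ref.clip_end]
        alt = (codes[5] + 1) % 4
        pu = _uniform_pileup(ref, 1000)
        w = 1.0 - 1e-3
        pu.weights[5, codes[5]] = 810 * w
        pu.counts[5, codes[5]] = 810
        pu.weights[5, alt] = 190 * w
        pu.counts[5, alt] = 190
        calls = call_variants(pu, estimate_noise(pu))
        assert [c.filter for c in calls] == ["low_frequency"]

    def test_nineteen_reads_filtered_low_support(self, two_amp_panel,
                                                 two_amp_seqs):
        refs = build_index(two_amp_panel, two_amp_seqs)
        ref = refs[0]
        codes = ref.codes[ref.clip_start:ref.clip_end]
        alt = (codes[5] + 1) % 4
        pu = _uniform_pileup(ref, 38)
        w = 1.0 - 1e-3
        pu.weights[5, codes[5]] = 19 * w
        pu.counts[5, codes[5]] = 19
        pu.weights[5, alt] = 19 * w
        pu.counts[5, alt] = 19
        calls = call_variants(pu, estimate_noise(pu))
        assert [c.filter for c in calls] == ["low_support"]

    def test_sd_multiplier_monotonicity(self, small_panel, small_ref,
                                        small_panel_seqs):
        specs = [VariantSpec("chrS", 2000,
                             small_ref["chrS"][1999].upper(),
                             "A" if small_ref["chrS"][1999].upper() != "A"
                             else "T", "het")]
        haps = diploid_haplotypes(small_ref, specs)
        prof = ReadProfile(depth_mean=60, depth_log_sigma=0.0,
                           error_rate=0.005, seed=3)
        recs = readsim.simulate_reads(small_panel, haps, prof)
        res = run_pipeline(recs, small_panel, small_panel_seqs)
        counts = []
        for k in (2.0, 4.0, 6.0, 8.0, 12.0):
            n = 0
            for rid, pu in res.pileups.items():
                n += len(call_variants(pu, res.noise[rid],
                                       sd_multiplier=k))
            counts.append(n)
        assert counts == sorted(counts, reverse=True)

    def test_dedupe_prefers_pass_then_depth(self):
        a = ampcall.VariantCall("c", 10, "A", "T", 0.5, 30, 60,
                                "low_support", "amp1", 0, 0)
        b = ampcall.VariantCall("c", 10, "A", "T", 0.5, 500, 1000,
                                "PASS", "amp2", 0, 0)
        assert dedupe_calls([a, b]) == [b]


class TestCoverage:
    def test_constant_depth_full_uniformity(self):
        # a single amplicon has no overlap doubling: ROI depth is constant
        ref = readsim.make_reference(1500, 0.5, 31)
        panel = pm.design_panel([("chrS", 600, 850)], ref)
        assert len(panel.amplicons) == 1
        seqs = {a.id: pm.amplicon_sequence(a, ref).upper()
                for a in panel.amplicons}
        refs = build_index(panel, seqs)
        pileups = {r.id: _uniform_pileup(r, 50) for r in refs}
        rep = coverage_report(pileups, panel, 100, 100)
        for k, frac in rep.threshold_table.items():
            assert frac == 1.0
        assert rep.uniformity == 1.0
        assert rep.mapping_rate == 1.0

    def test_dropout_detected_at_point_one_x(self, two_amp_panel,
                                             two_amp_seqs):
        refs = build_index(two_amp_panel, two_amp_seqs)
        pileups = {refs[0].id: _uniform_pileup(refs[0], 50),
                   refs[1].id: SegmentPileup.empty(refs[1])}
        rep = coverage_report(pileups, two_amp_panel, 100, 100)
        assert rep.threshold_table[0.1] < 1.0

    def test_threshold_rows_monotone_non_increasing(self, two_amp_panel,
                                                    two_amp_seqs):
        rng = np.random.default_rng(8)
        refs = build_index(two_amp_panel, two_amp_seqs)
        pileups = {}
        for r in refs:
            pu = _uniform_pileup(r, int(rng.integers(20, 200)))
            pileups[r.id] = pu
        rep = coverage_report(pileups, two_amp_panel, 120, 100)
        vals = [rep.threshold_table[k] for k in ampcall.COVERAGE_KS]
        assert vals == sorted(vals, reverse=True)
        assert rep.mapping_rate == pytest.approx(100 / 120)


class TestPrimerShadow:
    def test_variant_under_primer_called_via_neighbour_only(
            self, two_amp_panel, two_amp_ref, two_amp_seqs):
        """A variant in one amplicon's primer site is invisible there but
        recovered from the overlapping neighbour's interior."""
        left, right = two_amp_panel.amplicons
        # pick a position inside the left amplicon's REV primer site
        pos0 = (left.rev.genomic_start + left.rev.genomic_end) // 2
        assert right.start + len(right.fwd.gene_seq) <= pos0  # in neighbour interior
        seq = two_amp_ref["chrS"]
        ref_b = seq[pos0].upper()
        alt_b = "A" if ref_b != "A" else "G"
        spec = VariantSpec("chrS", pos0 + 1, ref_b, alt_b, "het")
        haps = diploid_haplotypes(two_amp_ref, [spec])
        prof = ReadProfile(depth_mean=300, depth_log_sigma=0.0,
                           error_rate=0.0, seed=4)
        recs = readsim.simulate_reads(two_amp_panel, haps, prof)
        res = run_pipeline(recs, two_amp_panel, two_amp_seqs)
        assert len(res.calls) == 1
        c = res.calls[0]
        assert c.pos == pos0 + 1 and c.alt == alt_b
        assert c.amplicon_id == right.id
        assert c.qwf == pytest.approx(0.5, abs=0.06)
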