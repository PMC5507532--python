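"""Concordance, exact binomial confidence intervals and throughput math.

Sensitivity and specificity use Clopper-Pearson (exact binomial) 95%
intervals; the true-negative count follows the targeted-panel convention
TN = ROI size x number of samples - total true positives.  Throughput
projection converts a sequencing kit's raw paired-end read yield into the
mean and minimum amplicon coverage per pooled library, using the panel's
empirical requirement of 91,500 raw pairs per 500x mean amplicon coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from scipy import stats

from .seqcore import TAG_T1, TAG_T2

READS_FOR_500X = 91_500


def exact_binomial_ci(successes: int, trials: int,
                      confidence: float = 0.95) -> tuple[float, float]:
    """Two-sided Clopper-Pearson interval, returned in percent.

    For successes = trials the lower bound is (alpha/2)^(1/n) and the
    upper bound 100%; for zero successes the lower bound is 0.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    alpha = 1.0 - confidence
    if successes == 0:
        lower = 0.0
    else:
        lower = float(stats.beta.ppf(alpha / 2, successes,
                                     trials - successes + 1))
    if successes == trials:
        upper = 1.0
    else:
        upper = float(stats.beta.ppf(1 - alpha / 2, successes + 1,
                                     trials - successes))
    return 100.0 * lower, 100.0 * upper


@dataclass
class ConcordanceSummary:
    tp_het_snv: int
    tp_hom_snv: int
    tp_indel: int
    fp: int
    fn: int
    roi_size: int
    n_samples: int

    @property
    def tp(self) -> int:
        return self.tp_het_snv + self.tp_hom_snv + self.tp_indel

    @property
    def tn(self) -> int:
        return self.roi_size * self.n_samples - self.tp

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def sensitivity_ci(self, confidence: float = 0.95):
        if self.tp + self.fn == 0:
            return None
        return exact_binomial_ci(self.tp, self.tp + self.fn, confidence)

    def specificity_ci(self, confidence: float = 0.95):
        return exact_binomial_ci(self.tn, self.tn + self.fp, confidence)

    def summary(self) -> str:
        lines = [
            "Variant detection concordance",
            f"  TP {self.tp} (het SNV {self.tp_het_snv}, "
            f"hom SNV {self.tp_hom_snv}, indel {self.tp_indel})",
            f"  FP {self.fp}   FN {self.fn}   TN {self.tn} "
            f"(ROI {self.roi_size} bp x {self.n_samples} samples)",
        ]
        if self.sensitivity is not None:
            lo, hi = self.sensitivity_ci()
            lines.append(f"  sensitivity {100 * self.sensitivity:.2f}% "
                         f"(95% CI: {lo:.2f}%-{hi:.2f}%)")
        else:
            lines.append("  sensitivity n/a (no positives expected)")
        lo, hi = self.specificity_ci()
        lines.append(f"  specificity {100 * self.specificity:.2f}% "
                     f"(95% CI: {lo:.2f}%-{hi:.2f}%)")
        return "\n".join(lines)


def concordance(
    calls_by_sample: dict[str, list],
    truth_by_sample: dict[str, list[dict]],
    roi_size: int,
    n_samples: int | None = None,
) -> ConcordanceSummary:
    """Position+allele exact matching of calls against labelled truth.

    Truth records are dicts with contig/pos/ref/alt plus zygosity
    ('het'|'hom') and kind ('snv'|'ins'|'del') labels — both sides must be
    left-aligned identically.  Calls may be VariantCall objects or
    (contig, pos, ref, alt) tuples.
    """
    if roi_size <= 0:
        raise ValueError("roi_size must be positive")
    n_samples = n_samples if n_samples is not None else len(truth_by_sample)
    tp_het_snv = tp_hom_snv = tp_indel = fp = fn = 0
    for sample, truth in truth_by_sample.items():
        calls = calls_by_sample.get(sample, [])
        call_keys = set()
        for c in calls:
            if hasattr(c, "contig"):
                call_keys.add((c.contig, c.pos, c.ref.upper(), c.alt.upper()))
            else:
                contig, pos, ref, alt = c
                call_keys.add((contig, pos, ref.upper(), alt.upper()))
        truth_keys = set()
        for t in truth:
            key = (t["contig"], t["pos"], t["ref"].upper(), t["alt"].upper())
            truth_keys.add(key)
            if key in call_keys:
                if t["kind"] != "snv":
                    tp_indel += 1
                elif t["zygosity"] == "hom":
                    tp_hom_snv += 1
                else:
                    tp_het_snv += 1
            else:
                fn += 1
        fp += len(call_keys - truth_keys)
    return ConcordanceSummary(tp_het_snv, tp_hom_snv, tp_indel, fp, fn,
                              roi_size, n_samples)


@dataclass
class ThroughputProjection:
    kit_reads: int
    libraries: int
    reads_per_library: float
    mean_coverage: int
    min_coverage: int


def project_throughput(kit_reads: int, libraries: int,
                       reads_for_500x: int = READS_FOR_500X,
                       rounding: str = "floor100") -> ThroughputProjection:
    """Project mean/minimum amplicon coverage for a pooled run.

    mean = (kit_reads / libraries) / reads_for_500x * 500, floored to the
    nearest 100x by default; minimum coverage is 0.2x of the mean.
    """
    if libraries < 1:
        raise ValueError("libraries must be >= 1")
    per_lib = kit_reads / libraries
    mean_raw = per_lib / reads_for_500x * 500.0
    if rounding == "floor100":
        mean = int(math.floor(mean_raw / 100.0) * 100)
    elif rounding == "none":
        mean = int(round(mean_raw))
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    return ThroughputProjection(
        kit_reads=kit_reads, libraries=libraries, reads_per_library=per_lib,
        mean_coverage=mean, min_coverage=int(round(0.2 * mean)),
    )


def library_size(insert_mean: float, tag_total: float | None = None,
                 index_addition: float = 94.0) -> tuple[float, float]:
    """Fragment sizes through library prep: tagged and indexed.

    ``tag_total`` defaults to the combined length of the two configured
    universal tags; indexing adds the platform's index/adapter bases.
    """
    if tag_total is None:
        tag_total = len(TAG_T1) + len(TAG_T2)
    if insert_mean < 0 or tag_total < 0 or index_addition < 0:
        raise ValueError("sizes must be non-negative")
    tagged = insert_mean + tag_total
    return tagged, tagged + index_addition
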