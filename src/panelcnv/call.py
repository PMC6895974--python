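"""Amplification calling, tumor fraction, and absolute copy number (ABCN).

Tumor fraction p is estimated from the cfDNA fragment-size distribution:
tumor-derived fragments are shorter than those of normal cells, and the
proportion of fragments below 150 bp is taken as the ctDNA fraction of
total cfDNA.

A gene's observed log2 ratio in a sample with tumor fraction p relates to
its absolute copy number in the tumor compartment by

    log2Ratio = log2( (ABCN * p + 2 * (1 - p)) / 2 )            (forward)
    ABCN      = 2 * (2**log2Ratio + p - 1) / p                  (inverse)

— a diploid background contributes 2 copies at weight (1 - p).  The
quantity ABCN * p + 2 * (1 - p) is the *effective* copy number apparent in
the mixture; it is what a dilution series actually measures.

Amplification status is thresholded at 3 times the sample's SD of
segment-level log ratios (a per-sample noise estimate): segments — and
genes — with log2 ratio strictly above 3*SD are amplified.  Deletions are
never called: at the low tumor fractions typical of cfDNA, single-copy
losses are indistinguishable from noise and ploidy cannot be estimated
reliably.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EmptyDataError, ValidationError
from .normalize import LogRatioProfile
from .panel_io import FragmentSizeDistribution, ProbePanel
from .segment import SegmentSet

#: Fragments shorter than this are counted as tumor-derived.
DEFAULT_SIZE_THRESHOLD_BP = 150

#: Amplification threshold floor, guarding the degenerate flat-profile case
#: where the segment-level SD is 0.
MIN_AMP_THRESHOLD = 0.1

AMPLIFIED = "amplified"
NEUTRAL = "neutral"
NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class TumorFractionEstimate:
    """ctDNA fraction p = short fragments / total fragments."""

    sample_id: str
    p: float
    short_fragment_count: int
    total_fragment_count: int
    threshold_bp: int = DEFAULT_SIZE_THRESHOLD_BP

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"tumor fraction {self.p} outside [0, 1]")


@dataclass(frozen=True)
class GeneCNVCall:
    """Per-gene amplification status with absolute copy number when evaluable."""

    sample_id: str
    gene: str
    log2_ratio: float
    status: str
    threshold_used: float
    abcn: float | None = None

    def __post_init__(self) -> None:
        if self.status not in (AMPLIFIED, NEUTRAL, NOT_EVALUABLE):
            raise ValidationError(f"unknown status {self.status!r}")
        if self.abcn is not None and self.abcn < 0:
            raise ValidationError("abcn must be >= 0 when defined")


def estimate_tumor_fraction(
    dist: FragmentSizeDistribution, threshold_bp: int = DEFAULT_SIZE_THRESHOLD_BP
) -> TumorFractionEstimate:
    """Proportion of fragments strictly below ``threshold_bp``."""
    if threshold_bp <= 0:
        raise ValidationError("threshold_bp must be > 0")
    total = dist.total
    if total == 0:
        raise EmptyDataError(f"sample {dist.sample_id!r}: empty fragment distribution")
    short = dist.count_below(threshold_bp)
    return TumorFractionEstimate(
        sample_id=dist.sample_id,
        p=short / total,
        short_fragment_count=short,
        total_fragment_count=total,
        threshold_bp=threshold_bp,
    )


def log2_ratio_from_abcn(abcn: float, p: float) -> float:
    """Forward model: expected log2 ratio of a gene at ABCN in tumor fraction p."""
    if not 0 < p <= 1:
        raise ValidationError(f"tumor fraction p={p} must be in (0, 1]")
    if abcn < 0:
        raise ValidationError("abcn must be >= 0")
    mix = abcn * p + 2.0 * (1.0 - p)
    if mix <= 0:
        raise ValidationError("mixture copy number must be positive")
    return float(np.log2(mix / 2.0))


def abcn_from_log2_ratio(log2_ratio: float, p: float) -> float:
    """Inverse model: ABCN from observed log2 ratio at tumor fraction p.

    Exact inverse of :func:`log2_ratio_from_abcn` on its range; floored at
    0 (noise can push the raw inversion slightly negative).
    """
    if not 0 < p <= 1:
        raise ValidationError(f"tumor fraction p={p} must be in (0, 1]")
    return float(max(2.0 * (2.0**log2_ratio + p - 1.0) / p, 0.0))


def effective_copy_number(abcn: float, p: float) -> float:
    """Copy number apparent in a dilution: ABCN * p + 2 * (1 - p)."""
    if abcn < 0:
        raise ValidationError("abcn must be >= 0")
    if not 0 <= p <= 1:
        raise ValidationError(f"tumor fraction p={p} must be in [0, 1]")
    return float(abcn * p + 2.0 * (1.0 - p))


def amplification_threshold(segments: SegmentSet) -> float:
    """3 x SD of segment-level means, floored at MIN_AMP_THRESHOLD."""
    return max(3.0 * segments.sd_segments, MIN_AMP_THRESHOLD)


def call_amplifications(
    segments: SegmentSet,
    panel: ProbePanel,
    profile: LogRatioProfile,
    tf: TumorFractionEstimate | None = None,
    genes: Sequence[str] | None = None,
) -> list[GeneCNVCall]:
    """Gene-level amplification calls from a segmented sample.

    A gene's log2 ratio is the probe-count-weighted mean of the segment
    means overlapping its probes (weights: number of the gene's non-masked
    probes inside each segment).  Status is amplified iff the gene log2
    ratio is strictly above the threshold.  ABCN is computed from the
    inverse mixture model when a positive tumor fraction is available;
    otherwise status is still reported but ABCN is left undefined.
    """
    if genes is None:
        genes = sorted(panel.genes)
    threshold = amplification_threshold(segments)
    p = tf.p if tf is not None else 0.0
    calls: list[GeneCNVCall] = []
    for gene in genes:
        if gene not in panel.genes:
            raise ValidationError(f"gene {gene!r} not present in panel")
        idx = np.array(panel.genes[gene])
        evaluable = idx[~profile.mask[idx]]
        if len(evaluable) == 0:
            calls.append(
                GeneCNVCall(
                    sample_id=segments.sample_id,
                    gene=gene,
                    log2_ratio=float("nan"),
                    status=NOT_EVALUABLE,
                    threshold_used=threshold,
                )
            )
            continue
        weights = []
        means = []
        for seg in segments.segments:
            w = int(np.sum((evaluable >= seg.probe_start) & (evaluable < seg.probe_end)))
            if w > 0:
                weights.append(w)
                means.append(seg.mean_log2)
        log2_ratio = float(np.average(means, weights=weights))
        status = AMPLIFIED if log2_ratio > threshold else NEUTRAL
        abcn = abcn_from_log2_ratio(log2_ratio, p) if p > 0 else None
        calls.append(
            GeneCNVCall(
                sample_id=segments.sample_id,
                gene=gene,
                log2_ratio=log2_ratio,
                status=status,
                threshold_used=threshold,
                abcn=abcn,
            )
        )
    return calls


def enrichment_odds_ratio(
    a: int, b: int, c: int, d: int
) -> tuple[float, float, bool]:
    """Odds ratio (a/b) / (c/d) for a 2x2 table, with Fisher exact p-value.

    Returns (odds_ratio, p_value, haldane_corrected).  A zero cell
    triggers the Haldane correction (+0.5 to every cell) for the OR; the
    Fisher test uses the raw table.
    """
    cells = (a, b, c, d)
    if any(v < 0 for v in cells):
        raise ValidationError("all counts must be >= 0")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValidationError("zero marginal in 2x2 table")
    corrected = any(v == 0 for v in cells)
    fa, fb, fc, fd = ((v + 0.5 for v in cells) if corrected else cells)
    oratio = (fa / fb) / (fc / fd)
    _, pvalue = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(oratio), float(pvalue), corrected


def odds_ratio_from_proportions(p1: float, p2: float) -> float:
    """Odds ratio between two group proportions: (p1/(1-p1)) / (p2/(1-p2))."""
    for p in (p1, p2):
        if not 0 < p < 1:
            raise ValidationError(f"proportion {p} must be in (0, 1)")
    return (p1 / (1 - p1)) / (p2 / (1 - p2))


def write_calls(
    calls: Sequence[GeneCNVCall],
    path: str | Path,
    tf: TumorFractionEstimate | None = None,
    header_lines: Sequence[str] = (),
) -> None:
    """TSV export: sample, gene, log2_ratio, threshold, status, tumor_fraction, abcn."""
    p = f"{tf.p:.6g}" if tf is not None else "NA"
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("sample\tgene\tlog2_ratio\tthreshold\tstatus\ttumor_fraction\tabcn\n")
        for c in calls:
            lr = "NA" if np.isnan(c.log2_ratio) else f"{c.log2_ratio:.6g}"
            abcn = "NA" if c.abcn is None else f"{c.abcn:.6g}"
            fh.write(
                f"{c.sample_id}\t{c.gene}\t{lr}\t{c.threshold_used:.6g}\t"
                f"{c.status}\t{p}\t{abcn}\n"
            )
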