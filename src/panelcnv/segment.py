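"""Circular binary segmentation (CBS) of per-probe log2 ratios.

Per chromosome, CBS searches all arcs (i, j) of the (implicitly
circularized) probe sequence for the one maximizing a two-sample
t-like statistic between in-arc and out-of-arc probe means.  If a
permutation test (probe-label shuffling) deems the best arc significant
at level ``alpha``, the sequence is split at the arc boundaries and the
procedure recurses on each piece.  The search over arcs is exhaustive
(O(n^2), vectorized), so the only approximation is the permutation null.

The statistic for arc x[i:j] against its complement is

    T = (mean_in - mean_out) / (s * sqrt(1/k + 1/(n-k)))

with ``s`` the pooled residual SD after removing the two means.  Ties in
|T| are broken toward the smallest (i, j); the permutation RNG is seeded
and consumed depth-first, left to right, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EmptyDataError, ValidationError
from .normalize import LogRatioProfile
from .panel_io import ProbePanel


@dataclass(frozen=True)
class Segment:
    """A maximal run of probes with constant mean log2 ratio.

    ``probe_start``/``probe_end`` are half-open indices into the panel.
    ``n_probes`` counts the probes that contributed to the mean (masked
    probes spanned by the range are not counted).
    """

    chrom: str
    probe_start: int
    probe_end: int
    mean_log2: float
    n_probes: int

    def __post_init__(self) -> None:
        if self.probe_start >= self.probe_end:
            raise ValidationError("probe_start must be < probe_end")
        if self.n_probes < 1:
            raise ValidationError("a segment must contain at least one probe")


@dataclass
class SegmentSet:
    """Ordered CBS output for one sample, with the parameters that produced it."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)
    alpha: float = 0.01
    n_permutations: int = 1000
    seed: int = 0

    @property
    def sd_segments(self) -> float:
        return segment_sd(self)

    def __len__(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# Core statistic
# ---------------------------------------------------------------------------

def best_arc(x: np.ndarray) -> tuple[int, int, float]:
    """Exhaustively find the arc (i, j) maximizing |T|; ties to smallest (i, j).

    Returns (i, j, |T|).  Requires len(x) >= 2.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValidationError("need >= 2 probes to search for an arc")
    S = np.concatenate(([0.0], np.cumsum(x)))
    tot = S[-1]
    totsq = float(np.sum(x * x))
    idx = np.arange(n + 1)
    K = idx[None, :] - idx[:, None]  # K[i, j] = j - i
    A = S[None, :] - S[:, None]      # A[i, j] = sum x[i:j]
    valid = (K >= 1) & (K <= n - 1)
    Kf = np.where(valid, K, 1).astype(float)
    nK = np.where(valid, n - K, 1).astype(float)
    m1 = A / Kf
    m2 = (tot - A) / nK
    ss = totsq - Kf * m1**2 - nK * m2**2
    df = max(n - 2, 1)
    s2 = np.clip(ss, 0.0, None) / df
    var = s2 * (1.0 / Kf + 1.0 / nK)
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = diff / np.sqrt(var)
    # zero pooled variance: infinite statistic if the means differ, else 0
    stat = np.where(var <= 0, np.where(diff > 0, np.inf, 0.0), stat)
    stat = np.where(valid, stat, -np.inf)
    flat = int(np.argmax(stat))  # row-major: first max has smallest (i, j)
    i, j = divmod(flat, n + 1)
    # an edge arc (i, n) and its complement (0, i) define the same split and
    # carry mathematically equal statistics; canonicalize to the (0, i) form
    if j == n and i > 0:
        i, j = 0, i
    return i, j, float(stat[i, j])


def max_arc_stat(x: np.ndarray) -> float:
    return best_arc(x)[2]


def _permutation_pvalue(
    x: np.ndarray,
    observed: float,
    rng: np.random.Generator,
    n_permutations: int,
    alpha: float,
) -> float:
    """Permutation p-value for the best-arc statistic, with early stopping.

    Shuffles probe labels; p = (1 + #exceedances) / (1 + n_permutations).
    Stops early once the exceedance count guarantees p >= alpha.  Early
    stopping changes how many draws are consumed but not the decision, and
    consumption is deterministic given the generator state.
    """
    stop_count = int(np.ceil(alpha * (1 + n_permutations)))
    count = 0
    # relative tie tolerance: permutations that rearrange the same value
    # multiset reproduce the observed statistic up to float noise and must
    # count as exceedances
    if np.isfinite(observed):
        cutoff = observed - 1e-9 * max(1.0, abs(observed))
    else:
        cutoff = observed
    for b in range(n_permutations):
        perm = x[rng.permutation(len(x))]
        if max_arc_stat(perm) >= cutoff:
            count += 1
            if count >= stop_count:
                return (1 + count) / (2 + b)
    return (1 + count) / (1 + n_permutations)


def _segment_recursive(
    x: np.ndarray,
    rng: np.random.Generator,
    alpha: float,
    n_permutations: int,
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns half-open local index ranges."""
    n = len(x)
    if n < 2:
        return [(0, n)]
    i, j, stat = best_arc(x)
    if stat <= 0:
        return [(0, n)]
    p = _permutation_pvalue(x, stat, rng, n_permutations, alpha)
    if p >= alpha:
        return [(0, n)]
    out: list[tuple[int, int]] = []
    for a, b in ((0, i), (i, j), (j, n)):
        if b > a:
            out.extend(
                (a + s, a + e)
                for s, e in _segment_recursive(x[a:b], rng, alpha, n_permutations)
            )
    return out


def cbs_segment(
    profile: LogRatioProfile,
    panel: ProbePanel,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
) -> SegmentSet:
    """Segment a log2-ratio profile into constant-mean segments, per chromosome.

    Masked probes are dropped before segmentation; a segment's index range
    refers to the panel but its mean and ``n_probes`` cover only the
    non-masked probes inside it.  Deterministic given ``seed``.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    if len(profile) != len(panel):
        raise ValidationError("profile length does not match panel")
    if np.all(profile.mask):
        raise EmptyDataError("no non-masked probes to segment")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for chrom, sl in panel.chrom_slices().items():
        keep = ~profile.mask[sl]
        if not np.any(keep):
            continue
        global_idx = np.arange(sl.start, sl.stop)[keep]
        x = profile.log2_ratios[sl][keep]
        if len(x) == 1:
            ranges = [(0, 1)]
        else:
            ranges = _segment_recursive(x, rng, alpha, n_permutations)
        for s, e in ranges:
            segments.append(
                Segment(
                    chrom=chrom,
                    probe_start=int(global_idx[s]),
                    probe_end=int(global_idx[e - 1]) + 1,
                    mean_log2=float(np.mean(x[s:e])),
                    n_probes=e - s,
                )
            )
    return SegmentSet(
        sample_id=profile.sample_id,
        segments=segments,
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
    )


def segment_sd(segments: SegmentSet, ddof: int = 0) -> float:
    """Population SD of segment-level mean log2 ratios (0 for one segment)."""
    if not segments.segments:
        raise EmptyDataError("segment set is empty")
    means = np.array([s.mean_log2 for s in segments.segments])
    if len(means) <= ddof:
        return 0.0
    return float(np.std(means, ddof=ddof))


def write_seg(
    segments: SegmentSet,
    panel: ProbePanel,
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """SEG-like TSV export; genomic coordinates from first/last probe."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("sample\tchrom\tstart_bp\tend_bp\tn_probes\tmean_log2\n")
        for s in segments.segments:
            start_bp = panel.probes[s.probe_start].start
            end_bp = panel.probes[s.probe_end - 1].end
            fh.write(
                f"{segments.sample_id}\t{s.chrom}\t{start_bp}\t{end_bp}\t"
                f"{s.n_probes}\t{s.mean_log2:.6g}\n"
            )
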