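"""Panel definitions, per-probe depth extraction, and fragment-size histograms.

A targeted cfDNA assay is described by a :class:`ProbePanel`: an ordered set
of capture-probe intervals, each annotated with the three covariates the
bias model uses (GC fraction, probe overlap score, mappability).  Per-sample
data enter the pipeline either as alignments (SAM/BAM, via pysam) or as
pre-tabulated per-probe depth tables, and leave each stage as a
:class:`DepthProfile`.  Paired-end template lengths feed the fragment-size
tumor-fraction estimator through :class:`FragmentSizeDistribution`.

Coordinates are BED-style 0-based half-open throughout, so probe length is
always ``end - start``.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .errors import EmptyDataError, PanelFormatError, PanelMismatchError, ValidationError

#: Depth-profile processing stages, in pipeline order.
STAGES = ("raw", "median_normalized", "bias_corrected", "pon_normalized")

PANEL_COLUMNS = (
    "chrom",
    "start",
    "end",
    "probe_id",
    "gene",
    "gc_fraction",
    "overlap_score",
    "mappability",
)


@dataclass(frozen=True)
class ProbeInterval:
    """One capture probe with its bias covariates.

    ``start``/``end`` are 0-based half-open genomic coordinates.  ``gene`` may
    be empty for probes not assigned to a gene (e.g. intronic fusion probes).
    """

    chrom: str
    start: int
    end: int
    probe_id: str
    gene: str
    gc_fraction: float
    overlap_score: float
    mappability: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"probe {self.probe_id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValidationError(
                f"probe {self.probe_id!r}: gc_fraction {self.gc_fraction} outside [0, 1]"
            )
        if not 0.0 <= self.mappability <= 1.0:
            raise ValidationError(
                f"probe {self.probe_id!r}: mappability {self.mappability} outside [0, 1]"
            )
        if self.overlap_score < 0:
            raise ValidationError(
                f"probe {self.probe_id!r}: overlap_score {self.overlap_score} negative"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class ProbePanel:
    """An ordered, validated collection of probes.

    Probes are stored sorted by ``(chrom, start, end, probe_id)``; all
    per-probe vectors elsewhere in the package are aligned to this order.
    ``genes`` maps each non-empty gene symbol to the sorted tuple of probe
    indices covering it.
    """

    def __init__(self, probes: Iterable[ProbeInterval]):
        probes = sorted(probes, key=lambda p: (p.chrom, p.start, p.end, p.probe_id))
        if not probes:
            raise ValidationError("a panel must contain at least one probe")
        seen: dict[str, int] = {}
        for i, p in enumerate(probes):
            if p.probe_id in seen:
                raise PanelFormatError(f"duplicate probe_id {p.probe_id!r}")
            seen[p.probe_id] = i
        self.probes: tuple[ProbeInterval, ...] = tuple(probes)
        genes: dict[str, list[int]] = {}
        for i, p in enumerate(self.probes):
            if p.gene:
                genes.setdefault(p.gene, []).append(i)
        self.genes: dict[str, tuple[int, ...]] = {g: tuple(v) for g, v in genes.items()}
        self._index_by_id = seen

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def index_of(self, probe_id: str) -> int:
        return self._index_by_id[probe_id]

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p.probe_id for p in self.probes)

    @property
    def chroms(self) -> tuple[str, ...]:
        """Distinct chromosomes in panel order."""
        out: list[str] = []
        for p in self.probes:
            if not out or out[-1] != p.chrom:
                out.append(p.chrom)
        return tuple(out)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous probe-index slice per chromosome."""
        slices: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self.probes) + 1):
            if i == len(self.probes) or self.probes[i].chrom != self.probes[start].chrom:
                slices[self.probes[start].chrom] = slice(start, i)
                start = i
        return slices

    def covariates(self) -> dict[str, np.ndarray]:
        """Per-probe covariate vectors in panel order."""
        return {
            "gc_fraction": np.array([p.gc_fraction for p in self.probes]),
            "overlap_score": np.array([p.overlap_score for p in self.probes]),
            "mappability": np.array([p.mappability for p in self.probes]),
        }

    @property
    def checksum(self) -> str:
        """MD5 over all probe fields; binds PoN / bias models to this panel."""
        h = hashlib.md5()
        for p in self.probes:
            h.update(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.probe_id}\t{p.gene}\t"
                f"{p.gc_fraction:.6g}\t{p.overlap_score:.6g}\t{p.mappability:.6g}\n".encode()
            )
        return h.hexdigest()


@dataclass
class DepthProfile:
    """Per-probe depths of one sample at a given processing stage."""

    sample_id: str
    depths: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.stage != "pon_normalized" and np.any(self.depths < 0):
            raise ValidationError("depths must be non-negative before PoN normalization")

    def __len__(self) -> int:
        return len(self.depths)


@dataclass
class FragmentSizeDistribution:
    """Histogram of absolute cfDNA template lengths for one sample."""

    sample_id: str
    histogram: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for length, count in self.histogram.items():
            if length < 1:
                raise ValidationError(f"fragment length {length} < 1")
            if count < 0:
                raise ValidationError(f"negative count for length {length}")

    @property
    def total(self) -> int:
        return sum(self.histogram.values())

    def count_below(self, threshold_bp: int) -> int:
        return sum(c for length, c in self.histogram.items() if length < threshold_bp)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> ProbePanel:
    """Read a probe panel from an 8-column BED-like TSV.

    Columns: chrom, start, end, probe_id, gene, gc_fraction, overlap_score,
    mappability.  Lines starting with ``#`` are comments.  Input rows need
    not be sorted; the returned panel always is.
    """
    probes: list[ProbeInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise PanelFormatError(
                    f"{path}:{lineno}: expected 8 tab-separated columns, got {len(fields)}"
                )
            chrom, start_s, end_s, probe_id, gene, gc_s, ov_s, mp_s = fields
            try:
                start, end = int(start_s), int(end_s)
                gc, ov, mp = float(gc_s), float(ov_s), float(mp_s)
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                probes.append(
                    ProbeInterval(chrom, start, end, probe_id, gene, gc, ov, mp)
                )
            except ValidationError as exc:
                raise PanelFormatError(f"{path}:{lineno}: {exc}") from exc
    if not probes:
        raise PanelFormatError(f"{path}: no probes found")
    return ProbePanel(probes)


def write_panel(panel: ProbePanel, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# " + "\t".join(PANEL_COLUMNS) + "\n")
        for p in panel.probes:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.probe_id}\t{p.gene}\t"
                f"{p.gc_fraction:.6g}\t{p.overlap_score:.6g}\t{p.mappability:.6g}\n"
            )


def read_depth_table(path: str | Path, panel: ProbePanel, sample_id: str | None = None) -> DepthProfile:
    """Read a two-column (probe_id, depth) TSV into a raw DepthProfile.

    Row order is irrelevant; the probe_id set must match the panel exactly.
    """
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "probe_id":  # header row
                continue
            if len(fields) != 2:
                raise PanelFormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            if fields[0] in values:
                raise PanelFormatError(f"{path}:{lineno}: duplicate probe_id {fields[0]!r}")
            try:
                values[fields[0]] = float(fields[1])
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{lineno}: {exc}") from exc
    table_ids = set(values)
    panel_ids = set(panel.probe_ids)
    if table_ids != panel_ids:
        missing = sorted(panel_ids - table_ids)
        extra = sorted(table_ids - panel_ids)
        raise PanelMismatchError(
            f"{path}: probe_ids do not match panel; "
            f"missing={missing[:10]}{'...' if len(missing) > 10 else ''} "
            f"extra={extra[:10]}{'...' if len(extra) > 10 else ''}"
        )
    depths = np.array([values[pid] for pid in panel.probe_ids])
    if sample_id is None:
        sample_id = Path(path).stem
    return DepthProfile(sample_id=sample_id, depths=depths, stage="raw")


def write_depth_table(
    profile: DepthProfile, panel: ProbePanel, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    if len(profile) != len(panel):
        raise PanelMismatchError(
            f"profile has {len(profile)} depths but panel has {len(panel)} probes"
        )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("probe_id\tdepth\n")
        for pid, d in zip(panel.probe_ids, profile.depths):
            fh.write(f"{pid}\t{d:.10g}\n")


def write_fragment_histogram(
    dist: FragmentSizeDistribution, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("length\tcount\n")
        for length in sorted(dist.histogram):
            fh.write(f"{length}\t{dist.histogram[length]}\n")


def read_fragment_histogram(path: str | Path, sample_id: str | None = None) -> FragmentSizeDistribution:
    histogram: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("length\t"):
                continue
            fields = line.split("\t")
            try:
                histogram[int(fields[0])] = histogram.get(int(fields[0]), 0) + int(fields[1])
            except (IndexError, ValueError) as exc:
                raise PanelFormatError(f"{path}:{lineno}: {exc}") from exc
    if sample_id is None:
        sample_id = Path(path).stem
    return FragmentSizeDistribution(sample_id=sample_id, histogram=histogram)


# ---------------------------------------------------------------------------
# Alignment extraction
# ---------------------------------------------------------------------------

def _usable_read(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
    )


def count_probe_depths(
    alignments: str | Path,
    panel: ProbePanel,
    min_mapq: int = 20,
    sample_id: str | None = None,
) -> DepthProfile:
    """Mean per-base coverage per probe from a SAM/BAM file.

    Depth at a probe is total aligned bases falling inside the probe
    interval (from CIGAR-aligned blocks of primary, non-duplicate reads
    with MAPQ >= ``min_mapq``) divided by probe length.  Mean coverage
    rather than read count keeps probe length out of the normalization.
    """
    if min_mapq < 0:
        raise ValidationError("min_mapq must be >= 0")
    path = str(alignments)
    totals = np.zeros(len(panel))
    slices = panel.chrom_slices()
    starts = {
        chrom: np.array([p.start for p in panel.probes[sl]])
        for chrom, sl in slices.items()
    }
    ends = {
        chrom: np.array([p.end for p in panel.probes[sl]])
        for chrom, sl in slices.items()
    }
    with pysam.AlignmentFile(path, check_sq=False) as af:
        refs = set(af.references or ())
        missing = [c for c in panel.chroms if c not in refs]
        if missing:
            raise PanelMismatchError(
                f"contigs in panel absent from alignment header: {missing}"
            )
        for read in af:
            if not _usable_read(read) or read.mapping_quality < min_mapq:
                continue
            chrom = read.reference_name
            if chrom not in slices:
                continue
            sl = slices[chrom]
            ps, pe = starts[chrom], ends[chrom]
            for bstart, bend in read.get_blocks():
                # probes overlapping [bstart, bend): starts sorted per chrom
                lo = int(np.searchsorted(pe, bstart, side="right"))
                hi = int(np.searchsorted(ps, bend, side="left"))
                for k in range(lo, hi):
                    ov = min(bend, pe[k]) - max(bstart, ps[k])
                    if ov > 0:
                        totals[sl.start + k] += ov
    lengths = np.array([p.length for p in panel.probes])
    if sample_id is None:
        sample_id = Path(path).stem
    return DepthProfile(sample_id=sample_id, depths=totals / lengths, stage="raw")


def extract_fragment_sizes(
    alignments: str | Path, max_size: int = 1000, sample_id: str | None = None
) -> FragmentSizeDistribution:
    """Histogram of |TLEN| over properly paired first-in-pair reads.

    Counting only read 1 counts each template once.  Duplicates, secondary
    and supplementary alignments are excluded; lengths are restricted to
    ``1 <= |TLEN| <= max_size``.
    """
    if max_size <= 0:
        raise ValidationError("max_size must be > 0")
    counts: Counter[int] = Counter()
    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        for read in af:
            if not _usable_read(read):
                continue
            if not (read.is_paired and read.is_proper_pair and read.is_read1):
                continue
            tlen = abs(read.template_length)
            if 1 <= tlen <= max_size:
                counts[tlen] += 1
    if not counts:
        raise EmptyDataError(
            f"{alignments}: no properly paired fragments with |TLEN| in [1, {max_size}]"
        )
    if sample_id is None:
        sample_id = Path(str(alignments)).stem
    return FragmentSizeDistribution(sample_id=sample_id, histogram=dict(counts))
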