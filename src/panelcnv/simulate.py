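"""Synthetic data generation and the in-silico spike-in / LOD experiment.

The generator emulates the data a targeted cfDNA assay produces, at the
level the pipeline consumes (per-probe depths and fragment lengths, not
reads):

* a probe panel with per-probe GC, overlap-score and mappability
  covariates drawn from realistic ranges;
* healthy-donor depth profiles with a multiplicative covariate bias
  (quadratic in GC, linear in mappability/overlap) and lognormal
  sample noise;
* a high-copy "cell line" profile with specified per-gene absolute copy
  numbers (the reference validation uses ERBB2=60, EGFR=20, MET=13);
* fraction-ladder mixtures of the cell line into a normal background,
  with Poisson resampling standing in for read-level down-sampling —
  depth space is the sufficient statistic for this pipeline, and it keeps
  the experiment desk-scale;
* bimodal cfDNA fragment-length mixtures with a tumor-associated short
  mode (tumor ~ N(145, 10), normal ~ N(167, 10), truncated to [50, 400]).

The limit-of-detection (LOD) harness mixes the cell line into normal
background at a descending fraction ladder (5% ... 0.3%), runs the full
pipeline against independently generated panel-of-normals replicate sets,
and reports the smallest fraction detected in every replicate set.

All generators are deterministic given the configured seed; independent
streams are derived with composite seeds so sub-experiments do not share
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .call import (
    AMPLIFIED,
    amplification_threshold,
    call_amplifications,
    effective_copy_number,
    log2_ratio_from_abcn,
)
from .errors import PanelMismatchError, ValidationError
from .normalize import build_pon, fit_bias_model, median_normalize, normalize_sample, apply_bias_model
from .panel_io import DepthProfile, FragmentSizeDistribution, ProbeInterval, ProbePanel
from .segment import cbs_segment

#: Dilution ladder of the reference in-silico spike-in series.
DEFAULT_FRACTIONS = (0.05, 0.04, 0.03, 0.02, 0.01, 0.006, 0.003)

#: Cell-line absolute copy numbers used for technical validation
#: (HCC1954: ERBB2; NCI-H1573: EGFR, MET).
CELL_LINE_ABCN = {"ERBB2": 60.0, "EGFR": 20.0, "MET": 13.0}

# sub-stream tags for composite seeding
_TAG_PANEL = 11
_TAG_NORMALS = 23
_TAG_TUMOR = 37
_TAG_SPIKE = 41
_TAG_FRAGMENTS = 53
_TAG_CBS = 67


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiments.

    Depths are mean per-probe coverages.  ``target_depth`` defaults to
    500x, a desk-scale stand-in for very deep panel sequencing; LOD
    behaviour is governed by the noise level relative to the calling
    threshold, not by absolute depth.  ``noise_sigma`` is the scale of
    multiplicative lognormal per-probe sample noise.
    """

    seed: int = 0
    n_normals: int = 10
    n_genes: int = 150
    probes_per_gene: int = 10
    n_chromosomes: int = 22
    target_depth: float = 500.0
    noise_sigma: float = 0.05
    # covariate bias: quadratic in GC, linear in mappability / overlap
    gc_mean: float = 0.45
    gc_sd: float = 0.08
    gc_bias_amplitude: float = 1.5
    mappability_bias_slope: float = 0.5
    overlap_bias_slope: float = 0.0
    # fragment length mixture
    tumor_frag_mean: float = 145.0
    tumor_frag_sd: float = 10.0
    normal_frag_mean: float = 167.0
    normal_frag_sd: float = 10.0
    frag_min: int = 50
    frag_max: int = 400

    def __post_init__(self) -> None:
        if self.n_normals < 2:
            raise ValidationError("n_normals must be >= 2")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.target_depth <= 0:
            raise ValidationError("target_depth must be > 0")
        if self.n_genes < 1 or self.probes_per_gene < 1:
            raise ValidationError("panel must have >= 1 gene and >= 1 probe per gene")


@dataclass
class SpikeInSpec:
    """Spike-in dilution experiment: which genes are amplified, how diluted."""

    abcn_by_gene: dict[str, float] = field(
        default_factory=lambda: dict(CELL_LINE_ABCN)
    )
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    n_pon_sets: int = 3
    tumor_profile: DepthProfile | None = None

    def __post_init__(self) -> None:
        fr = tuple(self.fractions)
        if not all(0 < f < 1 for f in fr):
            raise ValidationError("fractions must lie in (0, 1)")
        if any(b >= a for a, b in zip(fr, fr[1:])) and len(fr) > 1:
            if not all(a > b for a, b in zip(fr, fr[1:])):
                raise ValidationError("fractions must be strictly decreasing")
        if self.n_pon_sets < 1:
            raise ValidationError("n_pon_sets must be >= 1")
        self.fractions = fr


@dataclass
class LODResult:
    """Per-gene detection matrix over (fraction, replicate set) and the LOD."""

    gene: str
    true_abcn: float
    fractions: tuple[float, ...]
    detections: np.ndarray  # shape (n_fractions, n_pon_sets), bool
    lod_fraction: float | None
    lod_effective_copies: float | None
    thresholds: np.ndarray | None = None  # realized 3*SD thresholds, same shape
    #: per-replicate-set log2 offset of the (unspiked) background sample at
    #: this gene — a fixed effect of each dilution series
    background_log2: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _rng(seed: int, tag: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag, *extra])


def generate_panel(
    config: SimulationConfig, gene_names: Sequence[str] | None = None
) -> ProbePanel:
    """Deterministic synthetic panel: contiguous gene blocks over chromosomes.

    Probes are 120 bp, spaced 200 bp apart; genes are laid out sequentially
    across ``n_chromosomes`` chromosomes.  GC is drawn from a clipped
    normal around ``gc_mean``; mappability near 1, overlap score near 0.2.
    """
    if gene_names is not None and len(gene_names) > config.n_genes:
        raise ValidationError("more gene names than genes")
    rng = _rng(config.seed, _TAG_PANEL)
    width = max(len(str(config.n_genes)), 3)
    names = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    if gene_names is not None:
        for i, nm in enumerate(gene_names):
            names[i] = nm
    genes_per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    probes: list[ProbeInterval] = []
    for g, gene in enumerate(names):
        chrom = f"chr{g // genes_per_chrom + 1}"
        within = g % genes_per_chrom
        for k in range(config.probes_per_gene):
            start = 10_000 + (within * config.probes_per_gene + k) * 200
            gc = float(np.clip(rng.normal(config.gc_mean, config.gc_sd), 0.05, 0.95))
            mapp = float(np.clip(rng.normal(0.9, 0.05), 0.5, 1.0))
            ov = float(np.clip(rng.normal(0.2, 0.1), 0.0, 1.0))
            probes.append(
                ProbeInterval(
                    chrom=chrom,
                    start=start,
                    end=start + 120,
                    probe_id=f"{gene}_p{k + 1:02d}",
                    gene=gene,
                    gc_fraction=gc,
                    overlap_score=ov,
                    mappability=mapp,
                )
            )
    return ProbePanel(probes)


def injected_bias(config: SimulationConfig, panel: ProbePanel) -> np.ndarray:
    """Ground-truth multiplicative bias per probe (the generator's ledger)."""
    cov = panel.covariates()
    bias = (
        (1.0 - config.gc_bias_amplitude * (cov["gc_fraction"] - config.gc_mean) ** 2)
        * (1.0 + config.mappability_bias_slope * (cov["mappability"] - 0.9))
        * (1.0 + config.overlap_bias_slope * (cov["overlap_score"] - 0.2))
    )
    return np.clip(bias, 0.05, None)


def generate_normals(
    config: SimulationConfig,
    panel: ProbePanel,
    n: int | None = None,
    set_id: int = 0,
) -> list[DepthProfile]:
    """Healthy-donor depth profiles: target_depth x bias x lognormal noise.

    ``set_id`` selects an independent random stream, so replicate
    panel-of-normals sets share the panel but not the noise.
    """
    n = config.n_normals if n is None else n
    bias = injected_bias(config, panel)
    out = []
    for i in range(n):
        rng = _rng(config.seed, _TAG_NORMALS, set_id, i)
        noise = rng.lognormal(mean=0.0, sigma=config.noise_sigma, size=len(panel)) \
            if config.noise_sigma > 0 else np.ones(len(panel))
        out.append(
            DepthProfile(
                sample_id=f"normal_s{set_id}_{i:02d}",
                depths=config.target_depth * bias * noise,
                stage="raw",
            )
        )
    return out


def generate_tumor_profile(
    config: SimulationConfig,
    panel: ProbePanel,
    abcn_by_gene: dict[str, float],
    sample_id: str = "cellline",
) -> DepthProfile:
    """A simulated cell line: depth proportional to copy number / 2, with bias."""
    for gene in abcn_by_gene:
        if gene not in panel.genes:
            raise ValidationError(f"gene {gene!r} not present in panel")
    rng = _rng(config.seed, _TAG_TUMOR)
    cn = np.full(len(panel), 2.0)
    for gene, abcn in abcn_by_gene.items():
        cn[list(panel.genes[gene])] = abcn
    bias = injected_bias(config, panel)
    noise = rng.lognormal(0.0, config.noise_sigma, size=len(panel)) \
        if config.noise_sigma > 0 else np.ones(len(panel))
    return DepthProfile(
        sample_id=sample_id,
        depths=config.target_depth * bias * (cn / 2.0) * noise,
        stage="raw",
    )


def spike_in(
    tumor: DepthProfile,
    background: DepthProfile,
    fraction: float,
    seed: int,
    target_depth: float | None = None,
) -> DepthProfile:
    """Mix a tumor profile into a normal background at a given fraction.

    Both profiles are scaled to relative depth by their median (the median
    tracks the diploid baseline, so amplified probes do not deflate the
    mixture), mixed linearly, rescaled to ``target_depth`` and resampled
    with Poisson noise — the depth-space analogue of down-sampling and
    merging read sets.
    """
    if len(tumor) != len(background):
        raise PanelMismatchError("tumor and background profiles differ in length")
    if not 0 <= fraction <= 1:
        raise ValidationError("fraction must be in [0, 1]")
    if target_depth is None:
        target_depth = float(np.median(background.depths))
    tum_rel = tumor.depths / np.median(tumor.depths)
    bg_rel = background.depths / np.median(background.depths)
    expected = target_depth * ((1.0 - fraction) * bg_rel + fraction * tum_rel)
    rng = _rng(seed, _TAG_SPIKE)
    depths = rng.poisson(expected).astype(float)
    return DepthProfile(
        sample_id=f"{background.sample_id}_spike{fraction:g}",
        depths=depths,
        stage="raw",
    )


def generate_fragments(
    config: SimulationConfig,
    tumor_fraction: float,
    n: int,
    seed: int | None = None,
) -> tuple[FragmentSizeDistribution, dict[str, int]]:
    """Draw n fragment lengths from the tumor/normal bimodal mixture.

    Returns the histogram and a ground-truth ledger with the realized
    number of tumor- and normal-mode draws.
    """
    if n <= 0:
        raise ValidationError("n must be > 0")
    if not 0 <= tumor_fraction <= 1:
        raise ValidationError("tumor_fraction must be in [0, 1]")
    rng = _rng(config.seed if seed is None else seed, _TAG_FRAGMENTS)
    n_tumor = int(rng.binomial(n, tumor_fraction))
    lengths = []
    for count, mean, sd in (
        (n_tumor, config.tumor_frag_mean, config.tumor_frag_sd),
        (n - n_tumor, config.normal_frag_mean, config.normal_frag_sd),
    ):
        if count == 0:
            continue
        a = (config.frag_min - mean) / sd
        b = (config.frag_max - mean) / sd
        draws = sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=count, random_state=rng)
        lengths.append(np.rint(draws).astype(int))
    values, counts = np.unique(np.concatenate(lengths), return_counts=True)
    hist = {int(v): int(c) for v, c in zip(values, counts)}
    dist = FragmentSizeDistribution(
        sample_id=f"frag_tf{tumor_fraction:g}", histogram=hist
    )
    return dist, {"n_tumor": n_tumor, "n_normal": n - n_tumor}


def expected_short_fraction(
    config: SimulationConfig, tumor_fraction: float, threshold_bp: int = 150
) -> float:
    """Closed-form mixture mass below the size threshold.

    Lengths are rounded to integers, so "below threshold" corresponds to
    continuous mass below threshold - 0.5.
    """
    masses = []
    for mean, sd in (
        (config.tumor_frag_mean, config.tumor_frag_sd),
        (config.normal_frag_mean, config.normal_frag_sd),
    ):
        a = (config.frag_min - mean) / sd
        b = (config.frag_max - mean) / sd
        masses.append(
            float(sps.truncnorm.cdf(threshold_bp - 0.5, a, b, loc=mean, scale=sd))
        )
    return tumor_fraction * masses[0] + (1.0 - tumor_fraction) * masses[1]


# ---------------------------------------------------------------------------
# LOD experiment
# ---------------------------------------------------------------------------

def run_spiked_sample(
    mixed: DepthProfile,
    model,
    pon,
    panel: ProbePanel,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, bool], float]:
    """Run normalize -> segment -> call on one mixed sample.

    Returns per-gene detection flags and the realized amplification
    threshold (3 x segment-level SD, floored)."""
    ratios = normalize_sample(mixed, model, pon, panel)
    segset = cbs_segment(
        ratios, panel, alpha=alpha, n_permutations=n_permutations, seed=seed
    )
    calls = call_amplifications(segset, panel, ratios)
    return (
        {c.gene: c.status == AMPLIFIED for c in calls},
        amplification_threshold(segset),
    )


def analytic_lod_fraction(
    abcn: float, threshold: float, fractions: Sequence[float]
) -> float | None:
    """Smallest ladder fraction whose expected log2 ratio exceeds the threshold."""
    detectable = [
        f for f in fractions if log2_ratio_from_abcn(abcn, f) > threshold
    ]
    return min(detectable) if detectable else None


def run_lod_experiment(
    spec: SpikeInSpec,
    config: SimulationConfig,
    panel: ProbePanel | None = None,
    alpha: float = 0.01,
    n_permutations: int = 1000,
) -> list[LODResult]:
    """Full in-silico dilution series against replicate panel-of-normals sets.

    For each replicate set an independent cohort of ``config.n_normals``
    healthy samples builds the bias model and PoN, and one further
    held-out normal serves as the dilution background.  The simulated cell
    line is mixed in at each ladder fraction, the full pipeline is run,
    and a spiked gene counts as detected when its call is amplified.  The
    LOD is the smallest fraction detected in *all* replicate sets.
    """
    if panel is None:
        panel = generate_panel(config, gene_names=sorted(spec.abcn_by_gene))
    tumor = spec.tumor_profile
    if tumor is None:
        tumor = generate_tumor_profile(config, panel, spec.abcn_by_gene)
    genes = sorted(spec.abcn_by_gene)
    n_fr = len(spec.fractions)
    detections = {g: np.zeros((n_fr, spec.n_pon_sets), dtype=bool) for g in genes}
    thresholds = np.zeros((n_fr, spec.n_pon_sets))
    background_log2 = {g: np.zeros(spec.n_pon_sets) for g in genes}
    for s in range(spec.n_pon_sets):
        cohort = generate_normals(config, panel, n=config.n_normals + 1, set_id=s + 1)
        normals, background = cohort[:-1], cohort[-1]
        mednorm = [median_normalize(p) for p in normals]
        model = fit_bias_model(mednorm, panel)
        corrected = [apply_bias_model(p, model, panel) for p in mednorm]
        pon = build_pon(corrected, panel)
        bg_ratios = normalize_sample(background, model, pon, panel)
        for g in genes:
            idx = np.array(panel.genes[g])
            keep = idx[~bg_ratios.mask[idx]]
            background_log2[g][s] = (
                float(np.mean(bg_ratios.log2_ratios[keep])) if len(keep) else np.nan
            )
        for fi, fraction in enumerate(spec.fractions):
            mixed = spike_in(
                tumor,
                background,
                fraction,
                seed=np.random.SeedSequence([config.seed, _TAG_SPIKE, s, fi])
                .generate_state(1)[0] % (2**31),
                target_depth=config.target_depth,
            )
            detected, threshold = run_spiked_sample(
                mixed, model, pon, panel,
                alpha=alpha, n_permutations=n_permutations,
                seed=int(
                    np.random.SeedSequence([config.seed, _TAG_CBS, s, fi])
                    .generate_state(1)[0] % (2**31)
                ),
            )
            thresholds[fi, s] = threshold
            for g in genes:
                detections[g][fi, s] = detected[g]
    results = []
    for g in genes:
        det = detections[g]
        all_sets = det.all(axis=1)
        lod = None
        for fi in np.flatnonzero(all_sets):
            f = spec.fractions[fi]
            if lod is None or f < lod:
                lod = f
        eff = effective_copy_number(spec.abcn_by_gene[g], lod) if lod is not None else None
        results.append(
            LODResult(
                gene=g,
                true_abcn=spec.abcn_by_gene[g],
                fractions=spec.fractions,
                detections=det,
                lod_fraction=lod,
                lod_effective_copies=eff,
                thresholds=thresholds,
                background_log2=background_log2[g],
            )
        )
    return results
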