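"""Depth normalization: median scaling, covariate bias correction, panel of normals.

The tumor-only error model is built in three stages.  Each sample is first
scaled by its median probe depth, removing library-size differences.  A
combined bias model — a local-quadratic (loess) curve in GC fraction
followed by a linear correction on probe overlap score and mappability —
is fitted on the per-probe medians of a set of healthy-donor cfDNA samples
and divided out of every sample.  Finally a panel of normals (PoN) stores
the per-probe median and robust scale of the bias-corrected normal depths;
dividing a tumor sample by the PoN medians yields the per-probe log2
ratios that are segmented downstream.

Robust statistics (median, MAD) are used throughout because the normal set
is small (ten donors in the reference design) and outlier-prone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EmptyDataError, PanelMismatchError, ValidationError
from .panel_io import DepthProfile, ProbePanel

#: Predicted relative depth is clipped below at this floor before division.
PREDICTION_FLOOR = 0.01

#: Probes whose PoN median falls below this (median-normalized units) are masked.
DEFAULT_MIN_DEPTH = 0.2

MAD_SCALE = 1.4826  # consistency factor: MAD -> SD under normality


@dataclass
class LogRatioProfile:
    """Per-probe log2(sample / PoN median) values with an exclusion mask."""

    sample_id: str
    log2_ratios: np.ndarray
    mask: np.ndarray  # True where the probe is excluded

    def __post_init__(self) -> None:
        self.log2_ratios = np.asarray(self.log2_ratios, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.log2_ratios.shape != self.mask.shape:
            raise ValidationError("log2_ratios and mask must have equal length")
        if not np.all(np.isfinite(self.log2_ratios[~self.mask])):
            raise ValidationError("non-masked log2 ratios must be finite")

    def __len__(self) -> int:
        return len(self.log2_ratios)


@dataclass
class BiasModel:
    """Fitted combined depth-bias model (GC loess + linear covariates).

    The model predicts, per probe, the expected relative depth of a
    median-normalized sample.  ``gc_x``/``gc_y`` tabulate the loess curve at
    the training GC values; prediction interpolates linearly between them.
    The linear part multiplies the GC prediction by
    ``intercept + c_overlap * (overlap - overlap_center) + c_mapp * (mappability - mapp_center)``.
    A final scalar rescale makes the median log2 residual on the training
    medians exactly zero.
    """

    panel_checksum: str
    gc_x: np.ndarray
    gc_y: np.ndarray
    intercept: float
    coef_overlap: float
    coef_mappability: float
    overlap_center: float
    mappability_center: float
    scale: float
    residual_sd_log2: float

    def predict(self, panel: ProbePanel) -> np.ndarray:
        """Expected relative depth per probe, clipped at PREDICTION_FLOOR."""
        if panel.checksum != self.panel_checksum:
            raise PanelMismatchError("bias model was fitted on a different panel")
        cov = panel.covariates()
        gc_pred = np.interp(cov["gc_fraction"], self.gc_x, self.gc_y)
        lin = (
            self.intercept
            + self.coef_overlap * (cov["overlap_score"] - self.overlap_center)
            + self.coef_mappability * (cov["mappability"] - self.mappability_center)
        )
        pred = gc_pred * np.clip(lin, 0.1, None) * self.scale
        return np.clip(pred, PREDICTION_FLOOR, None)


@dataclass
class PanelOfNormals:
    """Per-probe reference location/scale from healthy-donor cfDNA samples."""

    panel_checksum: str
    n_samples: int
    probe_median: np.ndarray
    probe_sd: np.ndarray
    excluded_probes: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.probe_median = np.asarray(self.probe_median, dtype=float)
        self.probe_sd = np.asarray(self.probe_sd, dtype=float)
        if self.n_samples < 2:
            raise ValidationError("a PoN requires at least 2 normal samples")
        if np.any(self.probe_sd < 0):
            raise ValidationError("probe_sd must be non-negative")
        kept = np.ones(len(self.probe_median), dtype=bool)
        if self.excluded_probes:
            kept[list(self.excluded_probes)] = False
        if np.any(self.probe_median[kept] <= 0):
            raise ValidationError("non-excluded probes must have positive PoN median")

    def mask(self) -> np.ndarray:
        m = np.zeros(len(self.probe_median), dtype=bool)
        if self.excluded_probes:
            m[list(self.excluded_probes)] = True
        return m


def median_normalize(profile: DepthProfile) -> DepthProfile:
    """Scale a raw profile by its median probe depth (resulting median 1)."""
    if profile.stage != "raw":
        raise ValidationError(f"expected a raw profile, got stage {profile.stage!r}")
    depths = profile.depths
    if not np.any(depths > 0):
        raise EmptyDataError(f"sample {profile.sample_id!r}: all probe depths are zero")
    med = float(np.median(depths))
    if med <= 0:  # pathological: more than half the probes empty
        med = float(np.median(depths[depths > 0]))
    return DepthProfile(
        sample_id=profile.sample_id, depths=depths / med, stage="median_normalized"
    )


def _loess_quadratic(x: np.ndarray, y: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Local quadratic regression of y on x, evaluated at the unique x values.

    Tricube weights over the nearest ``frac`` of points.  Local quadratic
    (rather than linear) fitting reproduces smooth curvature without
    boundary flattening; on data lying exactly on a quadratic it is exact.
    """
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    ux = np.unique(xs)
    k = max(5, int(np.ceil(frac * len(xs))))
    k = min(k, len(xs))
    fitted = np.empty(len(ux))
    for i, x0 in enumerate(ux):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = ys[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        xl, yl = xs[idx], ys[idx]
        deg = min(2, len(np.unique(xl)) - 1)
        try:
            coeffs = np.polyfit(xl - x0, yl, deg=deg, w=np.sqrt(w))
        except np.linalg.LinAlgError:
            coeffs = np.array([np.average(yl, weights=w)])
        fitted[i] = coeffs[-1]  # value at x0
    return ux, fitted


def fit_bias_model(
    normals: Sequence[DepthProfile], panel: ProbePanel, gc_frac: float = 0.4
) -> BiasModel:
    """Fit the combined GC / overlap / mappability bias model on normal samples.

    The per-probe median across median-normalized normals is the training
    target.  The GC curve is fitted first; the ratio of observed to
    GC-predicted depth is then regressed linearly on the centered overlap
    score and mappability.  The fit is deterministic (no randomness).
    """
    if len(normals) < 2:
        raise ValidationError("need >= 2 normal samples to fit a bias model")
    for p in normals:
        if p.stage != "median_normalized":
            raise ValidationError(
                f"normal {p.sample_id!r}: expected stage median_normalized, got {p.stage!r}"
            )
        if len(p) != len(panel):
            raise PanelMismatchError(f"normal {p.sample_id!r} length does not match panel")
    target = np.median(np.vstack([p.depths for p in normals]), axis=0)
    cov = panel.covariates()
    gc = cov["gc_fraction"]

    if len(np.unique(gc)) < 3:
        warnings.warn(
            "degenerate GC covariate (fewer than 3 distinct values); "
            "using identity GC curve",
            stacklevel=2,
        )
        gc_x = np.array([0.0, 1.0])
        gc_y = np.array([1.0, 1.0]) * max(float(np.median(target)), PREDICTION_FLOOR)
    else:
        gc_x, gc_y = _loess_quadratic(gc, target, frac=gc_frac)
        gc_y = np.clip(gc_y, PREDICTION_FLOOR, None)

    gc_pred = np.interp(gc, gc_x, gc_y)
    ratio = target / np.clip(gc_pred, PREDICTION_FLOOR, None)

    c_ov = float(np.mean(cov["overlap_score"]))
    c_mp = float(np.mean(cov["mappability"]))
    dov = cov["overlap_score"] - c_ov
    dmp = cov["mappability"] - c_mp
    design_cols = [np.ones(len(panel))]
    use_ov = float(np.ptp(dov)) > 1e-12
    use_mp = float(np.ptp(dmp)) > 1e-12
    if use_ov:
        design_cols.append(dov)
    if use_mp:
        design_cols.append(dmp)
    design = np.column_stack(design_cols)
    coef, *_ = np.linalg.lstsq(design, ratio, rcond=None)
    intercept = float(coef[0])
    b_ov = float(coef[1]) if use_ov else 0.0
    b_mp = float(coef[1 + use_ov]) if use_mp else 0.0

    model = BiasModel(
        panel_checksum=panel.checksum,
        gc_x=gc_x,
        gc_y=gc_y,
        intercept=intercept,
        coef_overlap=b_ov,
        coef_mappability=b_mp,
        overlap_center=c_ov,
        mappability_center=c_mp,
        scale=1.0,
        residual_sd_log2=0.0,
    )
    # rescale so the median log2 residual on the training medians is exactly 0
    pred = model.predict(panel)
    pos = target > 0
    resid = np.log2(target[pos] / pred[pos])
    model.scale = float(2.0 ** np.median(resid))
    pred = model.predict(panel)
    resid = np.log2(target[pos] / pred[pos])
    model.residual_sd_log2 = float(MAD_SCALE * np.median(np.abs(resid - np.median(resid))))
    return model


def apply_bias_model(
    profile: DepthProfile, model: BiasModel, panel: ProbePanel
) -> DepthProfile:
    """Divide a median-normalized profile by the model's expected relative depth."""
    if profile.stage != "median_normalized":
        raise ValidationError(
            f"expected stage median_normalized, got {profile.stage!r}"
        )
    pred = model.predict(panel)  # raises on checksum mismatch
    return DepthProfile(
        sample_id=profile.sample_id, depths=profile.depths / pred, stage="bias_corrected"
    )


def build_pon(
    normals: Sequence[DepthProfile],
    panel: ProbePanel,
    min_depth: float = DEFAULT_MIN_DEPTH,
) -> PanelOfNormals:
    """Build a panel of normals from bias-corrected normal profiles.

    Per probe: median across normals and a MAD-based robust SD
    (1.4826 x MAD).  Probes with median below ``min_depth`` are excluded —
    low-coverage probes dominate false positives downstream.
    """
    if len(normals) < 2:
        raise ValidationError("need >= 2 normal samples to build a PoN")
    for p in normals:
        if p.stage != "bias_corrected":
            raise ValidationError(
                f"normal {p.sample_id!r}: expected stage bias_corrected, got {p.stage!r}"
            )
        if len(p) != len(panel):
            raise PanelMismatchError(f"normal {p.sample_id!r} length does not match panel")
    mat = np.vstack([p.depths for p in normals])
    med = np.median(mat, axis=0)
    sd = MAD_SCALE * np.median(np.abs(mat - med), axis=0)
    excluded = frozenset(int(i) for i in np.flatnonzero(med < min_depth))
    return PanelOfNormals(
        panel_checksum=panel.checksum,
        n_samples=len(normals),
        probe_median=med,
        probe_sd=sd,
        excluded_probes=excluded,
    )


def pon_log_ratio(
    profile: DepthProfile, pon: PanelOfNormals, panel: ProbePanel
) -> LogRatioProfile:
    """Per-probe log2 ratio of a bias-corrected sample against the PoN median.

    Zero depths are replaced by half the smallest positive depth in the
    sample (pseudodepth), so a biological dropout yields a strongly
    negative — later ignored — ratio rather than -inf.
    """
    if profile.stage != "bias_corrected":
        raise ValidationError(f"expected stage bias_corrected, got {profile.stage!r}")
    if panel.checksum != pon.panel_checksum:
        raise PanelMismatchError("PoN was built on a different panel")
    if len(profile) != len(panel):
        raise PanelMismatchError("profile length does not match panel")
    mask = pon.mask()
    depths = profile.depths.copy()
    pos = depths > 0
    if not np.any(pos):
        raise EmptyDataError(f"sample {profile.sample_id!r}: all depths zero")
    pseudo = 0.5 * depths[pos].min()
    depths[~pos] = pseudo
    ratios = np.full(len(depths), np.nan)
    keep = ~mask
    ratios[keep] = np.log2(depths[keep] / pon.probe_median[keep])
    return LogRatioProfile(sample_id=profile.sample_id, log2_ratios=ratios, mask=mask)


def normalize_sample(
    profile: DepthProfile,
    model: BiasModel,
    pon: PanelOfNormals,
    panel: ProbePanel,
) -> LogRatioProfile:
    """Full chain: median normalize -> bias correct -> PoN log2 ratios."""
    return pon_log_ratio(
        apply_bias_model(median_normalize(profile), model, panel), pon, panel
    )


# ---------------------------------------------------------------------------
# Serialization (versioned TSV / JSON)
# ---------------------------------------------------------------------------

PON_FORMAT_TAG = "panelcnv_pon_v1"
BIAS_FORMAT_TAG = "panelcnv_bias_v1"


def write_bias_model(model: BiasModel, path: str | Path) -> None:
    import json

    payload = {
        "format": BIAS_FORMAT_TAG,
        "panel_checksum": model.panel_checksum,
        "gc_x": model.gc_x.tolist(),
        "gc_y": model.gc_y.tolist(),
        "intercept": model.intercept,
        "coef_overlap": model.coef_overlap,
        "coef_mappability": model.coef_mappability,
        "overlap_center": model.overlap_center,
        "mappability_center": model.mappability_center,
        "scale": model.scale,
        "residual_sd_log2": model.residual_sd_log2,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_bias_model(path: str | Path) -> BiasModel:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != BIAS_FORMAT_TAG:
        raise ValidationError(f"{path}: not a {BIAS_FORMAT_TAG} file")
    return BiasModel(
        panel_checksum=payload["panel_checksum"],
        gc_x=np.asarray(payload["gc_x"]),
        gc_y=np.asarray(payload["gc_y"]),
        intercept=payload["intercept"],
        coef_overlap=payload["coef_overlap"],
        coef_mappability=payload["coef_mappability"],
        overlap_center=payload["overlap_center"],
        mappability_center=payload["mappability_center"],
        scale=payload["scale"],
        residual_sd_log2=payload["residual_sd_log2"],
    )


def write_pon(
    pon: PanelOfNormals, panel: ProbePanel, path: str | Path
) -> None:
    if panel.checksum != pon.panel_checksum:
        raise PanelMismatchError("PoN does not belong to this panel")
    with open(path, "w") as fh:
        fh.write(
            f"# {PON_FORMAT_TAG} panel_checksum={pon.panel_checksum} "
            f"n_samples={pon.n_samples}\n"
        )
        fh.write("probe_id\tmedian\tsd\texcluded\n")
        mask = pon.mask()
        for i, pid in enumerate(panel.probe_ids):
            fh.write(
                f"{pid}\t{pon.probe_median[i]:.10g}\t{pon.probe_sd[i]:.10g}\t"
                f"{int(mask[i])}\n"
            )


def read_pon(path: str | Path, panel: ProbePanel) -> PanelOfNormals:
    meta: dict[str, str] = {}
    rows: dict[str, tuple[float, float, bool]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line.lstrip("# ").split()
                if parts and parts[0] == PON_FORMAT_TAG:
                    meta.update(
                        dict(p.split("=", 1) for p in parts[1:] if "=" in p)
                    )
                continue
            if not line or line.startswith("probe_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 columns")
            rows[fields[0]] = (float(fields[1]), float(fields[2]), bool(int(fields[3])))
    if meta.get("panel_checksum") != panel.checksum:
        raise PanelMismatchError(
            f"{path}: PoN checksum {meta.get('panel_checksum')!r} does not match panel"
        )
    if set(rows) != set(panel.probe_ids):
        raise PanelMismatchError(f"{path}: probe_ids do not match panel")
    med = np.array([rows[pid][0] for pid in panel.probe_ids])
    sd = np.array([rows[pid][1] for pid in panel.probe_ids])
    excluded = frozenset(
        i for i, pid in enumerate(panel.probe_ids) if rows[pid][2]
    )
    return PanelOfNormals(
        panel_checksum=panel.checksum,
        n_samples=int(meta.get("n_samples", 2)),
        probe_median=med,
        probe_sd=sd,
        excluded_probes=excluded,
    )
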