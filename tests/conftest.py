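"""Shared fixtures: hand-built panels, synthetic cohorts, SAM writers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from panelcnv import (
    DepthProfile,
    ProbeInterval,
    ProbePanel,
    SimulationConfig,
    generate_normals,
    generate_panel,
)
from panelcnv.normalize import (
    apply_bias_model,
    build_pon,
    fit_bias_model,
    median_normalize,
)


@pytest.fixture
def small_panel() -> ProbePanel:
    """Three EGFR probes plus two ERBB2 probes on two chromosomes."""
    return ProbePanel(
        [
            ProbeInterval("chr7", 55_019_000, 55_019_100, "EGFR_e1", "EGFR", 0.48, 0.1, 0.99),
            ProbeInterval("chr7", 55_020_000, 55_020_120, "EGFR_e2", "EGFR", 0.52, 0.0, 1.0),
            ProbeInterval("chr7", 55_021_000, 55_021_100, "EGFR_e3", "EGFR", 0.45, 0.2, 0.95),
            ProbeInterval("chr17", 39_700_000, 39_700_100, "ERBB2_e1", "ERBB2", 0.55, 0.0, 1.0),
            ProbeInterval("chr17", 39_701_000, 39_701_150, "ERBB2_e2", "ERBB2", 0.50, 0.1, 0.98),
        ]
    )


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """Desk-scale study conditions for unit tests (smaller than defaults)."""
    return SimulationConfig(
        seed=7, n_genes=40, probes_per_gene=4, n_chromosomes=20, n_normals=10
    )


@pytest.fixture(scope="session")
def sim_panel(sim_config) -> ProbePanel:
    return generate_panel(sim_config, gene_names=["ERBB2", "EGFR", "MET"])


@pytest.fixture(scope="session")
def fitted_reference(sim_config, sim_panel):
    """Bias model + PoN fitted on the configured normal cohort."""
    normals = generate_normals(sim_config, sim_panel)
    mednorm = [median_normalize(p) for p in normals]
    model = fit_bias_model(mednorm, sim_panel)
    corrected = [apply_bias_model(p, model, sim_panel) for p in mednorm]
    pon = build_pon(corrected, sim_panel)
    return model, pon


def write_sam(path: Path, references: list[tuple[str, int]], reads: list[dict]) -> Path:
    """Write a minimal SAM file.

    Each read dict: name, flag, ref, pos (0-based), mapq, cigar, tlen.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in references:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in reads:
            rlen = sum(
                int(n) for n, op in _cigar_ops(r["cigar"]) if op in "MIS=X"
            )
            fh.write(
                f"{r['name']}\t{r['flag']}\t{r['ref']}\t{r['pos'] + 1}\t"
                f"{r.get('mapq', 60)}\t{r['cigar']}\t"
                f"{r.get('rnext', '=') if r['flag'] & 1 else '*'}\t"
                f"{r.get('pnext', r['pos']) + 1 if r['flag'] & 1 else 0}\t"
                f"{r.get('tlen', 0)}\t{'A' * rlen}\t*\n"
            )
    return path


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


def proper_pair(name: str, ref: str, pos: int, tlen: int, read_len: int = 50) -> list[dict]:
    """A properly paired read pair with the given outer template length."""
    mate_pos = pos + tlen - read_len
    return [
        {
            "name": name, "flag": 0x1 | 0x2 | 0x20 | 0x40, "ref": ref, "pos": pos,
            "cigar": f"{read_len}M", "tlen": tlen, "pnext": mate_pos,
        },
        {
            "name": name, "flag": 0x1 | 0x2 | 0x10 | 0x80, "ref": ref, "pos": mate_pos,
            "cigar": f"{read_len}M", "tlen": -tlen, "pnext": pos,
        },
    ]


@pytest.fixture
def flat_normals(small_panel):
    """Two all-ones normals at stage median_normalized (identity conditions)."""
    ones = np.ones(len(small_panel))
    return [
        DepthProfile(sample_id=f"n{i}", depths=ones.copy(), stage="median_normalized")
        for i in range(2)
    ]
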