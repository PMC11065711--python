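"""End-to-end orchestration: ingest/simulate -> QC -> LD -> decay + panel ->
LD-based Ne, and pedigree -> coancestry/inbreeding Ne, each run leaving a
reproducibility manifest (config echo, input digests, seed, output list).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .decay import (DEFAULT_EDGES_BP, DEFAULT_R2_THRESHOLD, bin_ld,
                    bins_frame, decay_crossing, panel_size)
from .errors import DataError
from .io import read_ped_map, read_pedigree, write_ped_map, write_tsv
from .ld import ld_pairs_frame, pairwise_ld_scan
from .ne_ld import NeLdConfig, ne_trajectory
from .pedigree import coancestry_analysis
from .qc import QCThresholds, apply_qc
from .simulate import SimulationTruth, simulate_wright_fisher

logger = logging.getLogger(__name__)

AUTOSOMAL_GENOME_KB = 2_510_605  # cattle autosomal genome length used for panel sizing


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    tool_version: str
    config: dict
    input_digests: dict
    outputs: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


@dataclass
class GenomicConfig:
    """All thresholds and constants of the genomic arm, in one place."""

    ped_path: Optional[str] = None
    map_path: Optional[str] = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    max_dist_bp: int = 500_000
    edges_bp: tuple = DEFAULT_EDGES_BP
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    genome_len_kb: float = AUTOSOMAL_GENOME_KB
    ne_ld: NeLdConfig = field(default_factory=NeLdConfig)
    simulate: Optional[SimulationTruth] = None
    out_dir: str = "popne_out"

    def echo(self) -> dict:
        d = {
            "min_call_rate": self.qc.min_call_rate,
            "min_maf": self.qc.min_maf,
            "hwe_p_floor": self.qc.hwe_p_floor,
            "max_dist_bp": self.max_dist_bp,
            "edges_bp": list(self.edges_bp),
            "r2_threshold": self.r2_threshold,
            "genome_len_kb": self.genome_len_kb,
            "k_morgan_per_bp": self.ne_ld.k_morgan_per_bp,
            "alpha": self.ne_ld.alpha,
            "beta": self.ne_ld.beta,
            "ne_bins": self.ne_ld.n_bins,
            "ne_min_dist_bp": self.ne_ld.min_dist_bp,
            "ne_max_dist_bp": self.ne_ld.max_dist_bp,
        }
        if self.simulate is not None:
            d["simulation"] = json.loads(self.simulate.to_json())
        return d


def run_genomic(config: GenomicConfig) -> dict:
    """Run the genomic arm; returns a dict of output paths plus key results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digests = {}
    if config.simulate is not None:
        logger.info("stage simulate: Wright-Fisher panel (seed=%d)", config.simulate.seed)
        dataset = simulate_wright_fisher(config.simulate)
        write_ped_map(dataset, out / "sim.ped", out / "sim.map")
        (out / "sim_truth.json").write_text(config.simulate.to_json() + "\n")
    else:
        if not config.ped_path or not config.map_path:
            raise DataError("ingest stage: PED and MAP paths are required "
                            "when no simulation is requested")
        logger.info("stage ingest: %s / %s", config.ped_path, config.map_path)
        try:
            dataset = read_ped_map(config.ped_path, config.map_path)
        except OSError as exc:
            raise DataError(f"ingest stage: {exc}") from exc
        digests = {config.ped_path: _digest(config.ped_path),
                   config.map_path: _digest(config.map_path)}

    logger.info("stage qc: %d variants in", dataset.n_variants)
    filtered, report = apply_qc(dataset, config.qc)
    qc_df = pd.DataFrame([{
        "N_INPUT": report.n_input, "N_PASS": report.n_pass,
        "PASS_PROPORTION": report.pass_proportion,
        **{f"FAIL_{k.upper()}": v for k, v in report.n_fail_by_rule.items()},
    }])
    write_tsv(qc_df, out / "qc_report.tsv")
    write_ped_map(filtered, out / "filtered.ped", out / "filtered.map")

    logger.info("stage ld: scanning pairs within %d bp", config.max_dist_bp)
    pairs = list(pairwise_ld_scan(filtered, max_dist_bp=max(config.max_dist_bp,
                                                            config.ne_ld.max_dist_bp)))
    window_pairs = [p for p in pairs if p.dist_bp <= config.max_dist_bp]
    write_tsv(ld_pairs_frame(window_pairs, filtered), out / "ld_pairs.tsv")

    logger.info("stage decay: binning %d pairs", len(window_pairs))
    bins = bin_ld(window_pairs, config.edges_bp)
    write_tsv(bins_frame(bins), out / "decay_bins.tsv")
    crossing = decay_crossing(bins, config.r2_threshold)
    panel_rows = {"STATUS": crossing.status, "R2_THRESHOLD": config.r2_threshold,
                  "CROSSING_BP": crossing.crossing_bp,
                  "CROSSING_COARSE_BP": crossing.crossing_coarse_bp,
                  "GENOME_KB": config.genome_len_kb, "N_MARKERS": None}
    if crossing.crossing_bp is not None:
        panel_rows["N_MARKERS"] = panel_size(config.genome_len_kb,
                                             crossing.crossing_bp / 1000.0)
    write_tsv(pd.DataFrame([panel_rows]), out / "panel.tsv")

    logger.info("stage ne-ld: %d-bin trajectory", config.ne_ld.n_bins)
    traj = ne_trajectory(pairs, filtered.n_samples, config.ne_ld)
    write_tsv(traj.frame(), out / "ne_trajectory.tsv")

    outputs = ["qc_report.tsv", "filtered.ped", "filtered.map", "ld_pairs.tsv",
               "decay_bins.tsv", "panel.tsv", "ne_trajectory.tsv"]
    # outputs recorded relative to the run directory so manifest-identical
    # runs are byte-identical wherever they land
    manifest = RunManifest(tool_version=__version__, config=config.echo(),
                           input_digests=digests, outputs=outputs)
    manifest.write(out / "manifest.json")
    return {"out_dir": str(out), "qc_report": report, "n_pairs": len(window_pairs),
            "bins": bins, "crossing": crossing, "trajectory": traj,
            "manifest": str(out / "manifest.json")}


@dataclass
class PedigreeConfig:
    pedigree_path: str = ""
    reference_year: Optional[int] = None
    out_dir: str = "popne_out"


def run_pedigree(config: PedigreeConfig) -> dict:
    """Run the pedigree arm: NeC, NeF, S and exclusion counts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        ped = read_pedigree(config.pedigree_path)
    except OSError as exc:
        raise DataError(f"pedigree ingest stage: {exc}") from exc
    reference = None
    if config.reference_year is not None:
        if ped.birth_years is None:
            raise DataError("reference-year filtering requested but the "
                            "pedigree has no birth_year column")
        reference = [i for i, y in zip(ped.ids, ped.birth_years)
                     if y == config.reference_year]
    res = coancestry_analysis(ped, reference)
    df = pd.DataFrame([{
        "NE_CI": res.ne_ci.value, "NE_CI_SE": res.ne_ci.se,
        "NE_CI_REASON": res.ne_ci.reason,
        "NE_FI": res.ne_fi.value, "NE_FI_REASON": res.ne_fi.reason,
        "S": res.s_ratio,
        "N_PAIRS": res.ne_ci.n_used, "N_PAIRS_EXCLUDED": res.ne_ci.n_excluded,
        "N_INDIV": res.ne_fi.n_used, "N_INDIV_EXCLUDED": res.ne_fi.n_excluded,
    }])
    write_tsv(df, out / "pedigree_ne.tsv")
    manifest = RunManifest(
        tool_version=__version__,
        config={"pedigree": config.pedigree_path,
                "reference_year": config.reference_year},
        input_digests={config.pedigree_path: _digest(config.pedigree_path)},
        outputs=["pedigree_ne.tsv"])
    manifest.write(out / "pedigree_manifest.json")
    return {"out_dir": str(out), "result": res,
            "manifest": str(out / "pedigree_manifest.json")}
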