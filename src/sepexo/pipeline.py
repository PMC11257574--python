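"""Run orchestration: the full synthetic demo as one reproducible pipeline.

A :class:`RunConfig` collects every threshold and simulation size; ``run``
executes the selected stages in dependency order (simulate inputs -> screen
-> feasibility -> quant -> frap), writes TSV/JSON reports plus a resolved
config and log under the output directory, and returns a summary report.
Reruns with the same config and seed produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accessibility import SubunitOffset, compute_sasa, feasibility_percent, map_interface_residues
from .fluor_quant import (
    RectROI,
    align_profiles,
    axial_colocalization_profile,
    line_scan,
    project,
    rim_spread_index,
)
from .frap import analyze_trace
from .interface_screen import screen_all_pairs, screen_report
from .synthetic_data import (
    make_complex_model,
    make_division_stack,
    make_frap_trace,
    make_pair_model,
)

__all__ = ["RunConfig", "run", "SEPTINS", "EXOCYST"]

SEPTINS = ["Spn1", "Spn2", "Spn3", "Spn4"]
EXOCYST = ["Sec3", "Sec5", "Sec6", "Sec8", "Sec10", "Sec15", "Exo70", "Exo84"]

logger = logging.getLogger("sepexo")

_ALL_STAGES = ("screen", "feasibility", "quant", "frap")


@dataclass
class RunConfig:
    """All thresholds and simulation sizes of a pipeline run."""

    seed: int = 1
    out_dir: str = "runs/demo"
    stages: list[str] = field(default_factory=lambda: list(_ALL_STAGES))

    # screen thresholds
    cutoff_angstrom: float = 4.0
    min_plddt: float = 50.0
    min_contacts: int = 1
    filter_scope: str = "both"

    # feasibility
    rsa_threshold: float = 0.25
    buried_fraction: float = 0.3
    complex_chains: int = 4
    complex_residues_per_chain: int = 10

    # quant
    roi_ratio: float = 2.0
    n_cells: int = 20
    second_channel_offset_um: float = 0.4

    # frap
    smoothing_window: int = 3
    smooth_frap: bool = True

    # screen simulation sizes
    n_models_per_order: int = 5
    residues_per_chain: int = 16
    n_consensus_pairs: int = 6
    n_decoy_pairs: int = 5
    contacts_per_interface: int = 8

    def validate(self) -> None:
        if self.cutoff_angstrom <= 0:
            raise ValueError(f"cutoff_angstrom must be positive, got {self.cutoff_angstrom}")
        if not 0 <= self.min_plddt <= 100:
            raise ValueError("min_plddt must lie in [0, 100]")
        if self.min_contacts < 1:
            raise ValueError("min_contacts must be >= 1")
        if self.filter_scope not in ("both", "either"):
            raise ValueError("filter_scope must be 'both' or 'either'")
        if not 0 <= self.rsa_threshold:
            raise ValueError("rsa_threshold must be non-negative")
        if self.roi_ratio <= 1:
            raise ValueError("roi_ratio must exceed 1")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; known: {_ALL_STAGES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Fingerprint of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# stages

def _stage_screen(config: RunConfig, rng: np.random.Generator, reports: Path) -> dict:
    """Simulate the 4x8 subunit grid (both input orders) and screen it."""
    pairs = [(s, e) for s in SEPTINS for e in EXOCYST]
    order = rng.permutation(len(pairs))
    consensus_planted = {pairs[i] for i in order[: config.n_consensus_pairs]}
    decoys = {pairs[i] for i in order[config.n_consensus_pairs:
                                      config.n_consensus_pairs + config.n_decoy_pairs]}

    models_by_order = {}
    for s, e in pairs:
        for a, b in ((s, e), (e, s)):
            has_contacts = (s, e) in consensus_planted or (
                (s, e) in decoys and (a, b) == (s, e)  # decoys: septin-first order only
            )
            models = []
            for k in range(config.n_models_per_order):
                n_contacts = config.contacts_per_interface if (has_contacts and k == 0) else 0
                plddt = 92.0 - 3.0 * k - round(float(rng.uniform(0, 1)), 2)
                model, _ = make_pair_model(
                    n_res_a=config.residues_per_chain,
                    n_res_b=config.residues_per_chain,
                    n_planted_contacts=n_contacts,
                    plddt_a=plddt,
                    plddt_b=plddt,
                    seed=int(rng.integers(2**31)),
                    model_id=f"{a}_{b}_model{k}",
                )
                models.append(model)
            models_by_order[(a, b)] = models

    results = screen_all_pairs(
        models_by_order,
        cutoff_angstrom=config.cutoff_angstrom,
        min_plddt=config.min_plddt,
        min_contacts=config.min_contacts,
        filter_scope=config.filter_scope,
    )
    df = screen_report(results)
    _write_tsv(df, reports / "screen.tsv")
    contacts_obj = {
        "-".join(r.pair_label): {
            iset.order_tag: [dataclasses.asdict(c) for c in iset.filtered_contacts]
            for iset in (r.interface_ab, r.interface_ba)
            if iset is not None
        }
        for r in results
    }
    _write_json(contacts_obj, reports / "screen_contacts.json")

    found = {r.pair_label for r in results if r.consensus}
    planted = {tuple(sorted(p)) for p in consensus_planted}
    n_correct = len(found & planted)
    logger.info("screen: %d/%d planted consensus pairs recovered", n_correct, len(planted))
    return {
        "n_pairs": len(pairs),
        "n_consensus_planted": len(planted),
        "n_consensus_found": len(found),
        "n_consensus_correct": n_correct,
        "top_scores_are_consensus": all(
            r.consensus for r in results[: len(found)]
        ),
    }


def _stage_feasibility(config: RunConfig, rng: np.random.Generator, reports: Path) -> dict:
    complex_model, truth = make_complex_model(
        n_chains=config.complex_chains,
        residues_per_chain=config.complex_residues_per_chain,
        buried_fraction=config.buried_fraction,
        seed=int(rng.integers(2**31)),
    )
    offsets = {c.chain_id: SubunitOffset(chain_id=c.chain_id)
               for c in complex_model.chains if c.chain_id in truth.labels}
    mappings, unmappable = map_interface_residues(
        truth.interface_residues(), complex_model, offsets
    )
    sasa = compute_sasa(complex_model)
    report = feasibility_percent(
        mappings,
        sasa,
        rsa_threshold=config.rsa_threshold,
        n_unmappable=len(unmappable),
        complex_id=complex_model.model_id,
    )
    _write_tsv(report.to_frame(), reports / "feasibility.tsv")
    summary = {
        "percent_accessible": round(report.percent_accessible, 4),
        "expected_percent_accessible": round(truth.expected_percent_accessible(), 4),
        "n_mapped": len(mappings),
        "n_unmappable": report.n_unmappable,
        "rsa_threshold": report.rsa_threshold,
        "max_asa_table": report.max_asa_table,
    }
    _write_json(summary, reports / "feasibility.json")
    logger.info("feasibility: %.1f%% accessible (planted %.1f%%)",
                report.percent_accessible, truth.expected_percent_accessible())
    return summary


def _stage_quant(config: RunConfig, rng: np.random.Generator, reports: Path) -> dict:
    rim_rows = []
    for pattern in ("ring", "disk"):
        for i in range(config.n_cells):
            stack, truth = make_division_stack(
                pattern=pattern,
                psf_sigma_um=0.1,
                poisson_noise=True,
                seed=int(rng.integers(2**31)),
            )
            mid = stack.data.shape[1] // 2
            image = stack.data[0, mid]
            n = image.shape[1]
            c = int(truth.center_px)
            r_px = int(round(truth.cell_radius_um / stack.pixel_size_um))
            profile = line_scan(
                image,
                (c - r_px, c),
                (c + r_px, c),
                width_pixels=3,
                pixel_size_um=stack.pixel_size_um,
            )
            rim_rows.append(
                {"cell": i, "pattern": pattern, "rim_spread_index": round(rim_spread_index(profile), 4)}
            )
    rim_df = pd.DataFrame(rim_rows)
    _write_tsv(rim_df, reports / "quant_rim.tsv")

    # planted two-channel axial offset, recovered from aligned profiles
    stack, truth = make_division_stack(
        pattern="disk",
        second_channel_offset_um=config.second_channel_offset_um,
        seed=int(rng.integers(2**31)),
    )
    mid = stack.data.shape[1] // 2
    roi_h = int(round(1.5 / stack.pixel_size_um))
    n = stack.data.shape[-1]
    roi = RectROI(x0=0, y0=(n - roi_h) // 2, width=n, height=roi_h)
    profiles = [
        axial_colocalization_profile(
            project(stack, ch, mode="max"), roi, stack.pixel_size_um, label=ch
        )
        for ch in stack.channels
    ]
    aligned = align_profiles(profiles, "brightest_pixel")
    separation = abs(aligned[1].alignment["origin_um"] - aligned[0].alignment["origin_um"])
    prof_df = pd.DataFrame(
        {
            "position_um": aligned[0].positions,
            **{p.label: p.values for p in aligned},
        }
    )
    _write_tsv(prof_df, reports / "quant_profiles.tsv")

    # background-subtracted ROI intensity on the sum projection
    image = project(stack, "ch1", mode="sum")
    c = int(truth.center_px)
    half1 = int(round(truth.cell_radius_um / stack.pixel_size_um)) - 4
    roi1 = RectROI(c - half1, c - half1, 2 * half1, 2 * half1)
    grow = int(round(half1 * (np.sqrt(config.roi_ratio) - 1)))
    grow = min(grow, roi1.x0, roi1.y0,
               image.shape[1] - (roi1.x0 + roi1.width),
               image.shape[0] - (roi1.y0 + roi1.height))
    roi2 = RectROI(roi1.x0 - grow, roi1.y0 - grow, roi1.width + 2 * grow, roi1.height + 2 * grow)
    from .fluor_quant import roi_background_subtracted_intensity

    corrected = roi_background_subtracted_intensity(image, roi1, roi2)
    summary = {
        "rim_index_ring_max": float(rim_df[rim_df.pattern == "ring"].rim_spread_index.max()),
        "rim_index_disk_min": float(rim_df[rim_df.pattern == "disk"].rim_spread_index.min()),
        "channel_offset_planted_um": config.second_channel_offset_um,
        "channel_offset_measured_um": round(float(separation), 4),
        "roi_corrected_intensity": round(float(corrected), 4),
    }
    _write_json(summary, reports / "quant.json")
    logger.info("quant: ring rim index <= %.3f, disk >= %.3f",
                summary["rim_index_ring_max"], summary["rim_index_disk_min"])
    return summary


def _stage_frap(config: RunConfig, rng: np.random.Generator, reports: Path) -> dict:
    rows = []
    designs = [(0.33, 150, 0.1), (10.0, 70, 0.005)]
    for dt, n_post, m3 in designs:
        for noise_sd in (0.0, 2.0):
            trace, truth = make_frap_trace(
                m1=80.0,
                m2=-80.0,
                m3=m3,
                dt=dt,
                n_post=n_post,
                acquisition_bleach_rate=0.002,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
            )
            fit, _, _ = analyze_trace(
                trace, smooth=config.smooth_frap, window=config.smoothing_window
            )
            rows.append(
                {
                    "dt_s": dt,
                    "n_post": n_post,
                    "noise_sd": noise_sd,
                    "m3_planted": m3,
                    "m1_fit": round(fit.m1, 6),
                    "m2_fit": round(fit.m2, 6),
                    "m3_fit": round(fit.m3, 8),
                    "t_half_s": round(fit.t_half, 6),
                    "m3_rel_error": round(abs(fit.m3 - m3) / m3, 8),
                    "converged": fit.converged,
                }
            )
    df = pd.DataFrame(rows)
    _write_tsv(df, reports / "frap.tsv")
    noiseless = df[df.noise_sd == 0.0]
    summary = {
        "max_noiseless_m3_rel_error": float(noiseless.m3_rel_error.max()),
        "max_noisy_m3_rel_error": float(df[df.noise_sd > 0].m3_rel_error.max()),
        "all_converged": bool(df.converged.all()),
    }
    logger.info("frap: max noiseless m3 relative error %.2e",
                summary["max_noiseless_m3_rel_error"])
    return summary


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary run report."""
    config.validate()
    out = Path(config.out_dir)
    reports = out / "reports"
    reports.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        (out / "config.resolved").write_text(
            f"# sepexo {__version__}  config_hash={config.config_hash}\n" + config.to_yaml()
        )
        rng = np.random.default_rng(config.seed)
        report: dict = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash,
            "stages": {},
        }
        stage_fns = {
            "screen": _stage_screen,
            "feasibility": _stage_feasibility,
            "quant": _stage_quant,
            "frap": _stage_frap,
        }
        for stage in _ALL_STAGES:  # dependency order, regardless of config order
            if stage not in config.stages:
                continue
            logger.info("running stage %s", stage)
            report["stages"][stage] = stage_fns[stage](config, rng, reports)
        _write_json(report, reports / "run_report.json")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
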