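"""End-to-end analyses tying the measurement stages together.

Two entry points mirror the study's two experiments:

* :func:`run_clearing_analysis` — per-specimen transparency and retained
  size over a directory of annotated image pairs, cohort h_max, pooled
  group summaries and pairwise Mann-Whitney tests.
* :func:`run_psf_analysis` — bead detection, profile fits and per-condition
  FWHM summaries over a set of bead z-stacks.

Both are deterministic for fixed inputs and configuration; every run
writes a resolved-config snapshot and a manifest (h_max, version, config
hash) for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .errors import AnnotationError, ConfigError, NoBeadsError
from .group_stats import compare_treatments
from .image_io import load_annotated_pair, load_stack, write_results_table
from .morphometry import compute_retained_size, medulla_height
from .psf_fitting import analyze_bead_stack, summarize_fwhm
from .transparency import compute_transparency

logger = logging.getLogger("clearquant")

__all__ = ["PipelineConfig", "StackEntry", "run_clearing_analysis", "run_psf_analysis"]


@dataclass(frozen=True)
class StackEntry:
    """One bead z-stack with its condition label and voxel pitch."""

    path: str
    condition: str
    voxel_size_um: tuple[float, float, float]


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    input_dir: str = "."
    output_dir: str = "out"
    pooling_rules: dict[str, str] = field(default_factory=dict)
    pairs: list[tuple[str, str]] | None = None
    stacks: list[StackEntry] = field(default_factory=list)
    threshold_rel: float = 0.5
    min_separation_um: float = 2.0
    bead_diameter_um: float = 0.2
    half_width_lat_um: float = 0.6
    half_width_ax_um: float = 1.5
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("threshold_rel", "min_separation_um", "bead_diameter_um",
                     "half_width_lat_um", "half_width_ax_um"):
            if getattr(self, name) <= 0 and name != "bead_diameter_um":
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.threshold_rel < 1:
            raise ConfigError("threshold_rel must be in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        stacks = [
            StackEntry(
                path=s["path"],
                condition=s["condition"],
                voxel_size_um=tuple(s["voxel_size_um"]),
            )
            for s in raw.pop("stacks", [])
        ]
        pairs = raw.pop("pairs", None)
        if pairs is not None:
            pairs = [tuple(p) for p in pairs]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(stacks=stacks, pairs=pairs, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stacks"] = [dataclasses.asdict(s) for s in self.stacks]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(config: PipelineConfig, out: Path, extra: dict) -> None:
    manifest = {
        "clearquant_version": __version__,
        "config_hash": config.config_hash(),
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "resolved_config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True, default=str)
    )


def run_clearing_analysis(config: PipelineConfig) -> pd.DataFrame:
    """Run the transparency + shrinkage experiment over an annotated cohort.

    Validates every annotation document before computing anything (fail
    fast with the complete list of problems), derives h_max over the run,
    and writes ``results.csv``, ``group_summary.csv``, ``pairwise_tests.csv``,
    the scatter table and a manifest to the output directory.
    """
    in_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann_paths = sorted(
        p for p in in_dir.glob("*.json")
        if p.name not in ("manifest.json", "resolved_config.json")
    )
    if not ann_paths:
        raise AnnotationError(f"no annotation documents found in {in_dir}")

    pairs_loaded, failures = [], []
    for p in ann_paths:
        try:
            pairs_loaded.append(load_annotated_pair(p))
        except Exception as exc:  # collect everything, then abort
            failures.append(f"{p.name}: {exc}")
    if failures:
        raise AnnotationError(
            "validation failed for {} specimen(s):\n  {}".format(
                len(failures), "\n  ".join(failures)
            )
        )

    h_by_specimen = {pair.specimen_id: medulla_height(pair) for pair in pairs_loaded}
    h_max = max(h_by_specimen.values())
    logger.info("cohort of %d specimens, h_max = %.6g um", len(pairs_loaded), h_max)

    rows = []
    for pair in pairs_loaded:
        tr = compute_transparency(pair, h_max)
        rs = compute_retained_size(pair)
        rows.append(
            {
                "specimen_id": pair.specimen_id,
                "treatment": pair.treatment,
                "c_brain": tr.c_brain,
                "c_ctrl": tr.c_ctrl,
                "t": tr.t,
                "h_um": tr.h_um,
                "h_max_um": tr.h_max_um,
                "t_norm": tr.t_norm,
                "d_pre_um": rs.d_pre_um,
                "d_post_um": rs.d_post_um,
                "retained_size": rs.r,
            }
        )
    write_results_table(rows, out / "results.csv")

    summaries, tests = compare_treatments(rows, config.pooling_rules, config.pairs)
    summary_rows = []
    for s in summaries:
        for metric, stats in (("t_norm", s.t_norm), ("retained_size", s.retained_size)):
            summary_rows.append(
                {
                    "treatment": s.treatment,
                    "metric": metric,
                    "n": s.n,
                    "median": stats.median,
                    "q25": stats.q25,
                    "q75": stats.q75,
                    "whisker_low": stats.whisker_low,
                    "whisker_high": stats.whisker_high,
                }
            )
    pd.DataFrame(summary_rows).to_csv(out / "group_summary.csv", index=False,
                                      float_format="%.8g")
    pd.DataFrame(
        [
            {
                "group_a": t.group_a, "group_b": t.group_b, "metric": t.metric,
                "n_a": t.n_a, "n_b": t.n_b, "u": t.u_statistic,
                "p": t.p_value, "method": t.method,
            }
            for t in tests
        ]
    ).to_csv(out / "pairwise_tests.csv", index=False, float_format="%.8g")
    pd.DataFrame(
        [
            {"treatment": r["treatment"], "t_norm": r["t_norm"],
             "retained_size": r["retained_size"]}
            for r in rows
        ]
    ).to_csv(out / "scatter.csv", index=False, float_format="%.8g")
    logger.info("performed %d pairwise tests (no multiplicity correction applied)",
                len(tests))
    _write_manifest(config, out, {"h_max_um": h_max, "n_specimens": len(rows)})
    return pd.DataFrame(rows)


def run_psf_analysis(config: PipelineConfig) -> pd.DataFrame:
    """Run the bead-PSF experiment over the configured stacks.

    Writes a per-bead fit table and a per-condition FWHM summary; beads
    with clipped windows or non-converged fits are excluded with a logged
    count.  Fails naming the condition if none of its stacks yields a bead.
    """
    if not config.stacks:
        raise ConfigError("no bead stacks configured")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    bead_rows, summary_rows = [], []
    by_condition: dict[str, list] = {}
    for entry in config.stacks:
        path = Path(config.input_dir) / entry.path
        stack = load_stack(path, entry.voxel_size_um)
        try:
            fits, excluded = analyze_bead_stack(
                stack,
                bead_diameter_um=config.bead_diameter_um,
                threshold_rel=config.threshold_rel,
                min_separation_um=config.min_separation_um,
                half_width_lat_um=config.half_width_lat_um,
                half_width_ax_um=config.half_width_ax_um,
            )
        except NoBeadsError:
            fits, excluded = [], 0
        if excluded:
            logger.info("%s: excluded %d bead(s) (edge-clipped or not converged)",
                        entry.path, excluded)
        by_condition.setdefault(entry.condition, []).extend(fits)
        for i, triplet in enumerate(fits):
            for ax, fit in triplet.items():
                bead_rows.append(
                    {
                        "condition": entry.condition, "stack": entry.path,
                        "bead_id": i, "axis": ax, "a": fit.a, "b": fit.b,
                        "mu_um": fit.mu, "sigma_um": fit.sigma, "e_um": fit.e,
                        "fwhm_um": fit.fwhm_um, "residual_rms": fit.residual_rms,
                        "converged": fit.converged,
                    }
                )

    for condition, fits in sorted(by_condition.items()):
        if not fits:
            raise NoBeadsError(f"condition '{condition}': no usable beads in any stack")
        s = summarize_fwhm(fits)
        summary_rows.append(
            {
                "condition": condition, "n_beads": s.n_beads,
                "lateral_fwhm_um": s.lateral_fwhm_um,
                "sem_lateral_um": s.sem_lateral_um,
                "axial_fwhm_um": s.axial_fwhm_um,
                "sem_axial_um": s.sem_axial_um,
            }
        )
    pd.DataFrame(bead_rows).to_csv(out / "bead_fits.csv", index=False,
                                   float_format="%.8g")
    df = pd.DataFrame(summary_rows)
    df.to_csv(out / "fwhm_summary.csv", index=False, float_format="%.8g")
    _write_manifest(config, out, {"n_conditions": len(summary_rows)})
    return df
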