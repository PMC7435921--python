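"""End-to-end orchestration: load or simulate a cohort, extract spectral and
information-theoretic parameters per window, and summarize the population.

A run is fully determined by its :class:`RunConfig` (echoed into the output
manifest): rerunning with the same config and seed produces byte-identical
CSVs.  Cohort simulation expands the single seed into per-patient substreams
(seed + patient index) so subsets of the cohort are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError, ValidationError
from .info import (
    DEFAULT_BIN_WIDTH,
    info_measures_for_pair,
    sweep_binwidth_cardiac,
)
from .io import EGMPair, read_egm_ascii, segment_window
from .spectral import extract_spectral_params
from .stats import summarize_cohort
from .synthetic import VFSignalConfig, generate_cohort

logger = logging.getLogger(__name__)

SPECTRAL_COLUMNS = [
    "patient", "channel", "window", "f0", "DF", "fmean",
    "Pn_f0", "Pn_f1", "Pn_f2", "Pn_f3", "Pn_f4", "Pn_f5",
    "BW_f0", "BW_f1", "OI", "LK",
]


@dataclass(frozen=True)
class SimulateConfig:
    """Cohort simulation block: size plus the generator settings."""

    n_patients: int = 22
    f0_mean: float = 4.74
    f0_sd: float = 0.5
    base: VFSignalConfig = field(default_factory=VFSignalConfig)


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one input source, windows, bin widths, seed."""

    output_dir: str | Path = "vfegm_run"
    input_dir: str | Path | None = None
    simulate: SimulateConfig | None = None
    windows: tuple[str, ...] = ("W1", "W2")
    bin_width: float = DEFAULT_BIN_WIDTH
    binwidth_grid: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValidationError("exactly one of input_dir / simulate must be given")
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be positive")
        if not self.windows:
            raise ValidationError("at least one analysis window is required")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from a flat YAML file with an optional simulate block."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim = raw.pop("simulate", None)
        if sim is not None:
            base_kwargs = {
                k: v for k, v in sim.items()
                if k not in ("n_patients", "f0_mean", "f0_sd")
            }
            sim = SimulateConfig(
                n_patients=int(sim.get("n_patients", 22)),
                f0_mean=float(sim.get("f0_mean", 4.74)),
                f0_sd=float(sim.get("f0_sd", 0.5)),
                base=VFSignalConfig(**base_kwargs),
            )
        for key in ("windows", "binwidth_grid"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)


@dataclass(frozen=True)
class RunResult:
    """Paths of the artifacts a pipeline run produced."""

    output_dir: Path
    spectral_csv: Path
    info_csv: Path
    cohort_csv: Path
    cohort_txt: Path
    manifest_json: Path
    sweep_csv: Path | None = None


def _load_pairs(config: RunConfig) -> list[EGMPair]:
    if config.simulate is not None:
        sim = config.simulate
        pairs, _ = generate_cohort(
            n_patients=sim.n_patients,
            base=sim.base,
            seed=config.seed,
            f0_mean=sim.f0_mean,
            f0_sd=sim.f0_sd,
        )
        return pairs
    input_dir = Path(config.input_dir)
    files = sorted(p for p in input_dir.glob("*.txt"))
    if not files:
        raise PipelineError(f"[load] no .txt recordings found in {input_dir}")
    pairs = []
    for path in files:
        try:
            pairs.append(read_egm_ascii(path))
        except Exception as exc:
            raise PipelineError(f"[load] {path.name}: {exc}") from exc
    return pairs


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write the run artifacts.

    Stages: load/simulate → per-window spectral parameters → per-window
    entropy/MI at the configured bin width → optional fixed-N bin-width
    sweep → cohort summary (mean ± SD and paired LV-vs-RV tests) → manifest.
    Any stage failure aborts with a message naming the stage and patient.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = _load_pairs(config)

    spectral_rows = []
    info_rows = []
    sweep_frames = []
    for pair in pairs:
        for window in config.windows:
            try:
                for sp in extract_spectral_params(pair, window):
                    row = {
                        "patient": sp.patient_id,
                        "channel": sp.channel,
                        "window": sp.window,
                        "f0": sp.f0,
                        "DF": sp.dominant_f,
                        "fmean": sp.f_mean,
                        **{f"Pn_f{k}": sp.peak_powers[k] for k in range(6)},
                        "BW_f0": sp.bw_f0,
                        "BW_f1": sp.bw_f1,
                        "OI": sp.oi,
                        "LK": sp.lk,
                    }
                    spectral_rows.append(row)
            except Exception as exc:
                raise PipelineError(
                    f"[spectral] patient {pair.patient_id}, window {window}: {exc}"
                ) from exc
            try:
                seg = segment_window(pair, window)
                m = info_measures_for_pair(seg, config.bin_width)
                info_rows.append(
                    {
                        "patient": pair.patient_id,
                        "window": window,
                        "H_LV": m.h_lv,
                        "H_RV": m.h_rv,
                        "H_joint": m.h_joint,
                        "MI": m.mi,
                        "bin_width": m.bin_width,
                        "N": m.n_samples,
                    }
                )
            except Exception as exc:
                raise PipelineError(
                    f"[info] patient {pair.patient_id}, window {window}: {exc}"
                ) from exc
        if config.binwidth_grid:
            try:
                sweep = sweep_binwidth_cardiac(pair, config.binwidth_grid)
                frame = sweep.to_frame()
                frame.insert(0, "patient", pair.patient_id)
                sweep_frames.append(frame)
            except Exception as exc:
                raise PipelineError(f"[sweep] patient {pair.patient_id}: {exc}") from exc

    spectral = pd.DataFrame(spectral_rows)[SPECTRAL_COLUMNS]
    spectral_csv = out / "spectral.csv"
    spectral.to_csv(spectral_csv, index=False)

    info = pd.DataFrame(info_rows)
    info_csv = out / "info.csv"
    info.to_csv(info_csv, index=False)

    sweep_csv = None
    if sweep_frames:
        sweep_csv = out / "sweep.csv"
        pd.concat(sweep_frames, ignore_index=True).to_csv(sweep_csv, index=False)

    # cohort summary over spectral parameters and per-channel entropies
    try:
        ent_long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "patient": info["patient"],
                        "channel": ch,
                        "window": info["window"],
                        "H": info[f"H_{ch}"],
                    }
                )
                for ch in ("LV", "RV")
            ],
            ignore_index=True,
        )
        cohort = summarize_cohort(
            pd.merge(spectral, ent_long, on=["patient", "channel", "window"], how="left")
        )
    except Exception as exc:
        raise PipelineError(f"[cohort] {exc}") from exc
    cohort_csv = out / "cohort.csv"
    cohort.to_csv(cohort_csv)
    cohort_txt = out / "cohort.txt"
    cohort_txt.write_text(cohort.to_text())

    manifest = {
        "vfegm_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_patients": len(pairs),
        "config": _config_dict(config),
    }
    manifest_json = out / "manifest.json"
    manifest_json.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))

    return RunResult(
        output_dir=out,
        spectral_csv=spectral_csv,
        info_csv=info_csv,
        cohort_csv=cohort_csv,
        cohort_txt=cohort_txt,
        manifest_json=manifest_json,
        sweep_csv=sweep_csv,
    )


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["output_dir"] = str(d["output_dir"])
    if d.get("input_dir") is not None:
        d["input_dir"] = str(d["input_dir"])
    return d
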