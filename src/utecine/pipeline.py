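"""End-to-end pipeline orchestration, configuration and protocol math."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .phantom import DynamicPhantom, mouse_heart_phantom
from .quant import functional_report_from_cine
from .recon import GridParams, reconstruct_cine
from .selfgate import CARDIAC_BAND, RESP_BAND, gate_spokes
from .sequencer import SequenceParams, acquire, get_preset, navigator_sigma_for_snr

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "protocol_summary"]

log = logging.getLogger("utecine")


class ConfigError(ValueError):
    """Raised for unresolvable pipeline configuration before any compute."""


@dataclass
class PipelineConfig:
    phantom: str | dict = "mouse-default"
    sequence: str | dict = "ute-reference"
    n_slices: int | None = 5            # override of the sequence preset
    noise_sigma: float | None = None    # absolute; exclusive with navigator_snr
    navigator_snr: float | None = 10.0
    seed: int = 0
    resp_band: tuple[float, float] = RESP_BAND
    cardiac_band: tuple[float, float] = CARDIAC_BAND
    accept_fraction: float = 0.7
    n_frames: int = 16
    kernel_width: int = 4
    oversampling: float = 2.0
    c_flow: float = 0.0
    outdir: str = "utecine_out"

    # -- resolution ------------------------------------------------------
    def resolve_phantom(self) -> DynamicPhantom:
        if isinstance(self.phantom, str):
            if self.phantom != "mouse-default":
                raise ConfigError(f"unknown phantom preset {self.phantom!r}")
            n = self.n_slices or 5
            return mouse_heart_phantom(n_slices=n)
        return DynamicPhantom.from_dict(self.phantom)

    def resolve_sequence(self) -> SequenceParams:
        if isinstance(self.sequence, str):
            try:
                params = get_preset(self.sequence)
            except KeyError as e:
                raise ConfigError(str(e)) from e
        else:
            params = SequenceParams(**self.sequence)
        if self.n_slices is not None:
            params = replace(params, n_slices=self.n_slices)
        return params

    def resolve_noise(self, phantom: DynamicPhantom) -> float:
        if self.noise_sigma is not None:
            return float(self.noise_sigma)
        if self.navigator_snr is not None:
            return navigator_sigma_for_snr(phantom, self.navigator_snr)
        return 0.0

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")
        self.resolve_phantom()
        self.resolve_sequence()

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["resp_band"] = list(d["resp_band"])
        d["cardiac_band"] = list(d["cardiac_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("resp_band", "cardiac_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """acquire -> gate -> reconstruct -> quantify, persisting every stage.

    Returns a dict of output paths plus the in-memory objects.  Rerunning
    with the same configuration is bit-identical.
    """
    config.validate()
    phantom = config.resolve_phantom()
    params = config.resolve_sequence()
    sigma = config.resolve_noise(phantom)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("acquire: %d slices x %d spokes, sigma=%.4g",
             params.n_slices, params.spokes_per_slice, sigma)
    spokes = acquire(phantom, params, noise_sigma=sigma, seed=config.seed,
                     c_flow=config.c_flow)
    spokes.save(outdir / "spokes.h5")

    gating = gate_spokes(spokes, config.resp_band, config.cardiac_band,
                         config.accept_fraction)
    log.info("gate: cardiac %.2f Hz, resp %.2f Hz, rejected %d/%d spokes",
             gating.cardiac_rate, gating.resp_rate,
             gating.n_rejected_resp, gating.n_spokes)
    gating.to_csv(outdir / "gating.csv")

    gp = GridParams(matrix=params.matrix, kernel_width=config.kernel_width,
                    oversampling=config.oversampling)
    cine = reconstruct_cine(spokes, gating, n_frames=config.n_frames, grid_params=gp)
    log.info("recon: %d slices x %d frames, %d-%d spokes/frame",
             cine.n_slices, cine.n_frames,
             cine.spokes_per_frame.min(), cine.spokes_per_frame.max())
    cine.save_nifti(outdir / "cine.nii")

    report = functional_report_from_cine(cine, phantom,
                                         heart_rate_bpm=gating.cardiac_rate * 60.0)
    report.to_json(outdir / "report.json")

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "version": __version__,
        "noise_sigma": sigma,
        "n_spokes": int(spokes.n_spokes),
        "n_rejected_resp": int(gating.n_rejected_resp),
        "spokes_per_frame": cine.spokes_per_frame.tolist(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {
        "spokes_path": outdir / "spokes.h5",
        "gating_path": outdir / "gating.csv",
        "cine_path": outdir / "cine.nii",
        "report_path": outdir / "report.json",
        "manifest_path": outdir / "manifest.json",
        "spokes": spokes, "gating": gating, "cine": cine, "report": report,
        "phantom": phantom, "params": params, "noise_sigma": sigma,
    }


# ---------------------------------------------------------------------------

def _fmt_min_sec(seconds: float) -> str:
    s = int(round(seconds))
    return f"{s // 60} min {s % 60} sec"


def protocol_summary(params: SequenceParams) -> dict:
    """Derived protocol numbers with raw values and display strings.

    Scan time per slice is n_projections x n_movie_cycles x TR for the
    radial sequence and matrix_lines x n_repetitions x TR for the
    Cartesian one; in-plane pixel size is FOV/matrix; the navigator is
    sampled once per TR.
    """
    if params.sequence == "flash":
        scan_time_s = params.matrix * params.n_movie_cycles * params.tr * 1e-3
    else:
        scan_time_s = params.n_projections * params.n_movie_cycles * params.tr * 1e-3
    pixel_mm = params.fov / params.matrix
    return {
        "scan_time_s": scan_time_s,
        "scan_time_display": _fmt_min_sec(scan_time_s),
        "pixel_um": pixel_mm * 1000.0,
        "pixel_display": f"{round(pixel_mm * 1000.0)} μm",
        "spokes_per_slice": params.spokes_per_slice,
        "spokes_total": params.spokes_per_slice * params.n_slices,
        "navigator_rate_hz": params.navigator_rate,
    }
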