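"""End-to-end segmentation: CLAHE -> ES-BM3D -> detector -> diffusion -> ISODATA.

The whole chain is deterministic for a fixed input and configuration; the
run log records every stage's parameters and the converged threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage

from .preprocess import ClaheParams, extract_vessel_channel, clahe_enhance, estimate_fov
from .sbm3d import DenoiserParams
from .ensemble import EnsembleConfig, default_ensemble, ensemble_denoise
from .detectors import FrangiParams, LineDetectorParams, improved_frangi, multiscale_line_response
from .postprocess import DiffusionParams, anisotropic_diffusion, isodata_threshold, binarize

__all__ = ["PipelineConfig", "segment"]


@dataclass
class PipelineConfig:
    polarity: str = "dark"               # real fundus vessels are dark
    clahe: ClaheParams = field(default_factory=ClaheParams)
    ensemble: EnsembleConfig = field(default_factory=default_ensemble)
    detector: str = "frangi"             # 'frangi' or 'multiscale'
    frangi: FrangiParams = field(default_factory=FrangiParams)
    line: LineDetectorParams = field(default_factory=LineDetectorParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    denoise: bool = True
    single_stage: bool = False
    min_component: int = 0               # pixels; 0 disables removal
    fov_threshold_fraction: float = 0.5

    def validate(self) -> None:
        if self.detector not in ("frangi", "multiscale"):
            raise ValueError("detector must be 'frangi' or 'multiscale'")
        self.clahe.validate()
        self.ensemble.validate()
        self.frangi.validate()
        self.line.validate()
        self.diffusion.validate()

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        kw = {}
        for key, sub in (("clahe", ClaheParams), ("frangi", FrangiParams),
                         ("line", LineDetectorParams), ("diffusion", DiffusionParams)):
            if key in d:
                val = d.pop(key)
                if key == "clahe" and "tile_grid" in val:
                    val["tile_grid"] = tuple(val["tile_grid"])
                for tk in ("scales", "sigma_v", "length_ratios", "orientations"):
                    if tk in val:
                        val[tk] = tuple(val[tk])
                kw[key] = sub(**val)
        if "ensemble" in d:
            ens = d.pop("ensemble")
            members = [DenoiserParams(**m) for m in ens.pop("members", [])]
            kw["ensemble"] = EnsembleConfig(members=members, **ens)
        kw.update(d)
        return cls(**kw)


def _remove_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    return np.isin(labels, keep)


def segment(img: np.ndarray, fov: np.ndarray | None = None,
            cfg: PipelineConfig | None = None):
    """Segment vessels in a fundus image; returns (mask, vesselness, run_log).

    Stages: vessel-channel extraction (with polarity inversion), FOV-aware
    CLAHE, ensemble S-BM3D despeckling, vesselness detection, anisotropic
    diffusion of the response map, ISODATA thresholding within the FOV.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    img = np.asarray(img, dtype=float)
    log: dict = {"stages": []}

    def _run(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    if fov is None:
        fov = _run("estimate_fov", lambda: estimate_fov(img, cfg.fov_threshold_fraction))
    fov = fov.astype(bool)

    chan = _run("extract_vessel_channel",
                lambda: extract_vessel_channel(img, cfg.polarity))
    # neutralize the region outside the FOV so the border does not leak
    # ridge responses into the rim
    if fov.any() and not fov.all():
        chan = chan.copy()
        chan[~fov] = float(np.median(chan[fov]))
    log["stages"].append({"name": "extract_vessel_channel", "polarity": cfg.polarity})

    enh = _run("clahe_enhance", lambda: clahe_enhance(chan, fov, cfg.clahe))
    log["stages"].append({"name": "clahe_enhance", **asdict(cfg.clahe)})

    if cfg.denoise:
        if cfg.single_stage:
            from .sbm3d import sbm3d_denoise
            den = _run("sbm3d_single_stage",
                       lambda: np.mean([sbm3d_denoise(enh, m, single_stage=True)
                                        for m in cfg.ensemble.members], axis=0))
        else:
            den = _run("ensemble_denoise", lambda: ensemble_denoise(enh, cfg.ensemble))
        den = np.clip(den, 0.0, 1.0)
        log["stages"].append({"name": "ensemble_denoise",
                              "members": [m.to_dict() for m in cfg.ensemble.members],
                              "combine": cfg.ensemble.combine,
                              "single_stage": cfg.single_stage})
    else:
        den = enh
        log["stages"].append({"name": "denoise_bypassed"})

    if cfg.detector == "frangi":
        vmap = _run("improved_frangi", lambda: improved_frangi(den, cfg.frangi, fov))
        log["stages"].append({"name": "improved_frangi", **asdict(cfg.frangi)})
    else:
        vmap = _run("multiscale_line_response",
                    lambda: multiscale_line_response(den, cfg.line))
        log["stages"].append({"name": "multiscale_line_response",
                              **{k: list(v) if isinstance(v, tuple) else v
                                 for k, v in asdict(cfg.line).items()}})
    vmap = np.where(fov, vmap, 0.0)

    smooth = _run("anisotropic_diffusion",
                  lambda: anisotropic_diffusion(vmap, cfg.diffusion))
    log["stages"].append({"name": "anisotropic_diffusion", **asdict(cfg.diffusion)})

    t = _run("isodata_threshold", lambda: isodata_threshold(smooth, fov))
    mask = binarize(smooth, t, fov)
    if cfg.min_component > 0:
        mask = _remove_small(mask, cfg.min_component)
    log["stages"].append({"name": "isodata_threshold", "threshold": float(t)})
    log["threshold"] = float(t)
    return mask, vmap, log
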