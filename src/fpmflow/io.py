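"""File formats and run configuration.

Interchange formats: multi-page TIFF for image stacks (one page per LED,
scan order) with a JSON sidecar carrying wavevectors and geometry; 32-bit
float TIFF for reconstructed amplitude/phase; CSV for Zernike coefficient
tables; YAML or JSON for run configuration.  Pixel (0, 0) is the top-left;
frequency-domain arrays use the centered layout (documented in sidecars).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .exceptions import ConfigurationError, DimensionMismatchError, ValidationError
from .forward_model import AcquisitionStack, ComplexField
from .optics import LEDArray, OpticalSystem, Pupil, ZernikeBasis

__all__ = [
    "RunConfig",
    "write_stack",
    "read_stack",
    "write_reconstruction",
    "read_zernike_csv",
    "write_zernike_csv",
    "load_config",
    "save_config",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated nested run configuration with explicit defaults."""

    system: dict = field(
        default_factory=lambda: {
            "wavelength_um": 0.532,
            "na": 0.1,
            "camera_pixel_um": 3.45,
            "magnification": 4.0,
            "hires": 64,
            "upsampling": 4,
        }
    )
    leds: dict = field(
        default_factory=lambda: {"rows": 9, "cols": 9, "pitch_mm": 4.0, "height_mm": 100.0}
    )
    phantom: dict = field(
        default_factory=lambda: {
            "amplitude_pattern": "blobs",
            "phase_pattern": "blobs",
            "amplitude_range": [0.5, 1.0],
            "phase_scale": 0.5,
            "defocus_um": 50.0,
        }
    )
    training: dict = field(
        default_factory=lambda: {
            "epochs": 2000,
            "lr_sample": 100.0,
            "lr_pupil": 10.0,
            "delta": 1.0,
            "zernike_n_max": 4,
            "upsample_method": "fourier",
            "mode": "end_to_end",
        }
    )
    metrics: dict = field(default_factory=lambda: {"ssim_mode": "windowed", "win_size": 7})
    paths: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        known = set(cfg.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
        for section, value in data.items():
            default = getattr(cfg, section)
            if isinstance(default, dict):
                bad = set(value) - set(default) if default else set()
                if bad and default:
                    raise ConfigurationError(
                        f"unknown keys in config section {section!r}: {sorted(bad)}"
                    )
                default.update(value)
            else:
                setattr(cfg, section, value)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def system_from_config(cfg: RunConfig) -> OpticalSystem:
    s = cfg.system
    u = int(s["upsampling"])
    return OpticalSystem(
        wavelength=float(s["wavelength_um"]),
        na=float(s["na"]),
        pixel_size_obj=float(s["camera_pixel_um"]) / float(s["magnification"]) / u,
        hires_shape=(int(s["hires"]), int(s["hires"])),
        upsampling=u,
    )


def leds_from_config(cfg: RunConfig) -> LEDArray:
    l = cfg.leds
    return LEDArray(
        grid_shape=(int(l["rows"]), int(l["cols"])),
        pitch=float(l["pitch_mm"]),
        height=float(l["height_mm"]),
        wavelength=float(cfg.system["wavelength_um"]),
    )


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------


def _system_meta(system: OpticalSystem) -> dict:
    return {
        "wavelength_um": system.wavelength,
        "na": system.na,
        "pixel_size_obj_um": system.pixel_size_obj,
        "hires_shape": list(system.hires_shape),
        "upsampling": system.upsampling,
    }


def write_stack(stack: AcquisitionStack, path: str | Path) -> Path:
    """Multi-page float32 TIFF (one page per LED, scan order) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.images.astype(np.float32))
    sidecar = {
        "format": "fpmflow acquisition stack",
        "version": __version__,
        "layout": "pixel (0,0) top-left; pages in LED scan order; "
        "frequencies centered (zero frequency at n//2)",
        "wavevectors_cyc_per_um": np.asarray(stack.wavevectors).tolist(),
        "system": _system_meta(stack.system),
        "noise_seed": stack.noise_seed,
    }
    if stack.leds is not None:
        sidecar["leds"] = {
            "grid_shape": list(stack.leds.grid_shape),
            "pitch_mm": stack.leds.pitch,
            "height_mm": stack.leds.height,
            "scan_order": np.asarray(stack.leds.scan_order).tolist(),
        }
    sidecar_path = path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return path


def _to_unit_float(img: np.ndarray) -> np.ndarray:
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(float) / np.iinfo(img.dtype).max
    return img.astype(float)


def read_stack(path: str | Path) -> AcquisitionStack:
    """Read a stack written by :func:`write_stack`, or a directory of
    numbered TIFF/PNG images with a ``manifest.json``.

    Integer images are scaled by the dtype maximum into [0, 1].
    """
    path = Path(path)
    if path.is_dir():
        manifest_path = path / "manifest.json"
        if not manifest_path.exists():
            raise ValidationError(f"stack directory {path} has no manifest.json")
        manifest = json.loads(manifest_path.read_text())
        files = manifest.get("files")
        if files is None:
            files = sorted(
                p.name for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
            )
        images = []
        for name in files:
            fp = path / name
            if fp.suffix.lower() in (".tif", ".tiff"):
                images.append(_to_unit_float(tifffile.imread(fp)))
            else:
                from imageio.v3 import imread

                images.append(_to_unit_float(np.asarray(imread(fp))))
        images = np.stack(images)
        meta = manifest
    else:
        images = _to_unit_float(tifffile.imread(path))
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise ValidationError(f"stack {path} has no JSON sidecar {sidecar_path.name}")
        meta = json.loads(sidecar_path.read_text())
    wavevectors = np.asarray(meta["wavevectors_cyc_per_um"], dtype=float)
    if len(wavevectors) != len(images):
        raise DimensionMismatchError(
            f"{len(images)} images but {len(wavevectors)} wavevectors in manifest"
        )
    s = meta["system"]
    system = OpticalSystem(
        wavelength=s["wavelength_um"],
        na=s["na"],
        pixel_size_obj=s["pixel_size_obj_um"],
        hires_shape=tuple(s["hires_shape"]),
        upsampling=s["upsampling"],
    )
    return AcquisitionStack(
        images=images,
        wavevectors=wavevectors,
        system=system,
        noise_seed=meta.get("noise_seed"),
    )


# ---------------------------------------------------------------------------
# reconstructions and coefficient tables
# ---------------------------------------------------------------------------


def write_zernike_csv(path: str | Path, basis: ZernikeBasis, coeffs: np.ndarray) -> None:
    lines = ["j,n,m,coeff_rad"]
    for (j, n, m), c in zip(basis.terms, coeffs):
        lines.append(f"{j},{n},{m},{float(c)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_zernike_csv(path: str | Path) -> tuple[ZernikeBasis, np.ndarray]:
    rows = Path(path).read_text().strip().splitlines()
    if rows[0].strip() != "j,n,m,coeff_rad":
        raise ValidationError(f"unexpected Zernike CSV header {rows[0]!r}")
    terms, coeffs = [], []
    for line in rows[1:]:
        j, n, m, c = line.split(",")
        terms.append((int(j), int(n), int(m)))
        coeffs.append(float(c))
    return ZernikeBasis(terms=tuple(terms)), np.array(coeffs)


def write_reconstruction(
    obj: ComplexField,
    pupil: Pupil | None,
    outdir: str | Path,
    metadata: dict | None = None,
) -> Path:
    """Write amplitude/phase float32 TIFFs, Zernike CSV and run metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "amplitude.tif", obj.amplitude.astype(np.float32))
    # np.angle already yields values in (−π, π]
    tifffile.imwrite(outdir / "phase.tif", obj.phase.astype(np.float32))
    if pupil is not None:
        tifffile.imwrite(outdir / "pupil_amplitude.tif", pupil.amplitude.astype(np.float32))
        if pupil.basis is not None and pupil.zernike_coeffs is not None:
            write_zernike_csv(outdir / "zernike.csv", pupil.basis, pupil.zernike_coeffs)
    meta = {"version": __version__, "layout": "pixel (0,0) top-left; phase in rad, (−π, π]"}
    meta.update(metadata or {})
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=1, default=str))
    return outdir


def read_reconstruction(outdir: str | Path) -> ComplexField:
    outdir = Path(outdir)
    amp = tifffile.imread(outdir / "amplitude.tif").astype(float)
    phase = tifffile.imread(outdir / "phase.tif").astype(float)
    return ComplexField(amp * np.exp(1j * phase), "space")
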