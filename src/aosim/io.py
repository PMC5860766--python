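"""Readers/writers for the pipeline's standard formats.

Phases are stored in radians (HDF5 attribute ``units``); modal coefficient
columns are micrometres of wavefront; images go to 32-bit float TIFF; traces,
centroid fields and P matrices to CSV; configs to YAML; run manifests to JSON.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from . import __version__
from .errors import ConfigurationError
from .modal_basis import InfluenceFunctionSet, ModalBasis
from .pupil_optics import CameraImage, OpticalConfig, PhaseMap, PSFStack
from .shack_hartmann import CentroidField, SHGeometry

__all__ = [
    "load_run_config",
    "save_phase_map",
    "load_phase_map",
    "save_basis",
    "load_basis",
    "save_influence_functions",
    "save_images_tiff",
    "load_images_tiff",
    "save_psf_stack",
    "save_centroids_csv",
    "load_centroids_csv",
    "save_trace_csv",
    "write_manifest",
    "sha256_file",
]


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

_OPTICS_KEYS = {
    "wavelength_um",
    "focal_length_mm",
    "aperture_diameter_mm",
    "grid_n",
    "pupil_fill",
    "z_planes_um",
    "pixel_size_camera_um",
}
_SECTION_KEYS = {
    "optics": _OPTICS_KEYS,
    "shack_hartmann": {"n_sub", "lenslet_focal_mm", "min_coverage"},
    "dm": {"layout", "n_act", "coupling", "r_act"},
    "basis": {"sv_cutoff_rel", "normalize", "max_modes", "method"},
    "correction": {"probe_amplitude_um", "iterations", "clamp_factor", "n_spots", "window"},
    "validation": {"n", "amp_max_um", "pairs"},
    "axial": {"n_planes", "T_factor", "T_um"},
}
_TOP_KEYS = set(_SECTION_KEYS) | {"seed", "output"}


def load_run_config(path: str | Path) -> dict:
    """Load and schema-check a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    for section, allowed in _SECTION_KEYS.items():
        sub = raw.get(section) or {}
        bad = set(sub) - allowed
        if bad:
            raise ConfigurationError(f"unknown keys in [{section}]: {sorted(bad)}")
    raw["optics_config"] = OpticalConfig(**(raw.get("optics") or {}))
    return raw


# --------------------------------------------------------------------------- #
# HDF5: phases, bases, influence functions
# --------------------------------------------------------------------------- #


def save_phase_map(path: str | Path, phase: PhaseMap) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("phase", data=phase.values)
        ds.attrs["units"] = "radian"


def load_phase_map(path: str | Path) -> PhaseMap:
    with h5py.File(path, "r") as fh:
        return PhaseMap(fh["phase"][()])


def save_influence_functions(path: str | Path, influence: InfluenceFunctionSet) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("phases", data=influence.phases)
        ds.attrs["units"] = "radian/command"
        if influence.centers is not None:
            fh.create_dataset("centers", data=influence.centers)
        fh.attrs["layout"] = influence.layout


def save_basis(path: str | Path, basis: ModalBasis) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("coefficients", data=basis.coefficients)
        fh.create_dataset("singular_values", data=basis.singular_values)
        fh.create_dataset("displacement_flags", data=basis.displacement_flags)
        fh.create_dataset("retained_indices", data=basis.retained_indices)
        if basis.mode_phases is not None:
            ds = fh.create_dataset("mode_phases", data=basis.mode_phases)
            ds.attrs["units"] = "radian (unit gradient norm)"


def load_basis(path: str | Path) -> ModalBasis:
    with h5py.File(path, "r") as fh:
        return ModalBasis(
            coefficients=fh["coefficients"][()],
            singular_values=fh["singular_values"][()],
            displacement_flags=fh["displacement_flags"][()].astype(bool),
            mode_phases=fh["mode_phases"][()] if "mode_phases" in fh else None,
            retained_indices=fh["retained_indices"][()],
        )


# --------------------------------------------------------------------------- #
# TIFF images
# --------------------------------------------------------------------------- #


def save_images_tiff(path: str | Path, images: list[CameraImage] | np.ndarray) -> None:
    if isinstance(images, np.ndarray):
        stack = np.asarray(images, dtype=np.float32)
    else:
        stack = np.stack([im.intensity for im in images]).astype(np.float32)
    tifffile.imwrite(path, stack)


def load_images_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def save_psf_stack(path: str | Path, psf: PSFStack) -> None:
    """Complex field stack as HDF5 with axial/lateral sampling metadata."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("fields", data=psf.fields)
        fh.create_dataset("z_planes_um", data=np.asarray(psf.z_planes_um))
        fh.attrs["sampling_um"] = psf.sampling_um


# --------------------------------------------------------------------------- #
# CSV: centroids, traces
# --------------------------------------------------------------------------- #


def save_centroids_csv(path: str | Path, field: CentroidField) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sub_x", "sub_y", "dx", "dy", "weight"])
        for (x, y), dx, dy, w in zip(field.positions, field.dx, field.dy, field.weights):
            writer.writerow(
                [repr(float(v)) for v in (x, y, dx, dy, w)]
            )


def load_centroids_csv(
    path: str | Path, geometry: SHGeometry, mask_area: float
) -> CentroidField:
    rows = np.genfromtxt(path, delimiter=",", names=True)
    rows = np.atleast_1d(rows)
    return CentroidField(
        dx=rows["dx"],
        dy=rows["dy"],
        weights=rows["weight"],
        positions=np.column_stack([rows["sub_x"], rows["sub_y"]]),
        geometry=geometry,
        mask_area=mask_area,
    )


def save_trace_csv(path: str | Path, trace: list[dict]) -> None:
    cols = ["iter", "mode", "M0", "Mplus", "Mminus", "a_opt", "flag"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for row in trace:
            writer.writerow({c: row[c] for c in cols})


# --------------------------------------------------------------------------- #
# manifests
# --------------------------------------------------------------------------- #


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict | None,
    seed: int | None,
    outputs: list[str | Path],
) -> Path:
    """Record tool version, config hash, seed and output checksums."""
    out_dir = Path(out_dir)
    cfg = {k: v for k, v in (config or {}).items() if k != "optics_config"}
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "tool": "aosim",
        "version": __version__,
        "command": command,
        "created_unix": time.time(),
        "seed": seed,
        "config_sha256": cfg_hash,
        "config": cfg,
        "outputs": {str(Path(p).name): sha256_file(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
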