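"""NIfTI volume I/O and run provenance."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_nifti", "write_nifti", "write_provenance", "stage_seed"]


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI-1 volume; returns (data, affine)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    return np.asarray(img.get_fdata()), img.affine


def write_nifti(volume: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a NIfTI-1 volume; inverse of :func:`read_nifti`."""
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2³¹) from one global seed.

    A counter-free scheme: the stage name is hashed into the seed
    sequence, so every stage is independently reproducible from the
    global seed alone.
    """
    digest = hashlib.sha256(stage.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence([int(global_seed), key])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def write_provenance(out_dir, stage: str, seed: int, config: dict,
                     version: str | None = None) -> Path:
    """Write the sidecar JSON that makes a stage re-runnable: stage name,
    seed, config and its hash, package version, timestamp."""
    if version is None:
        from . import __version__ as version
    payload = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "version": version,
        "written": datetime.now(timezone.utc).isoformat(),
    }
    out = Path(out_dir) / f"{stage}_provenance.json"
    out.write_text(json.dumps(payload, indent=2, default=str))
    return out
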