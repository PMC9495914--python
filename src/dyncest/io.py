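"""Series and result I/O: NIfTI volume stacks with JSON schedule sidecars.

A dynamic series is stored as a single 4D NIfTI volume (x, y, 1, time; one
volume per schedule entry), a ``*_entries.json`` sidecar carrying the
per-image schedule metadata (offset, role, instance, retain flag and
timestamps — dynamic CEST metadata has no standardized NIfTI header slot),
an integer-label ``*_masks.nii.gz`` volume, and an optional ``*_truth.yaml``
ground-truth block for synthetic data.  Curves and maps are written as tidy
CSV.  All externally visible times are minutes (as plotted); the sidecar
stores the raw per-entry seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .schedule import ScheduleEntry, TimingParams
from .synth import DynamicSeries, GroundTruth

__all__ = ["write_series", "read_series"]

_MASK_LABELS = {"background": 0, "liver": 1}


def write_series(series: DynamicSeries, outdir: str | Path, prefix: str = "series") -> dict[str, Path]:
    """Write a DynamicSeries; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    data = np.asarray(series.images, np.float32).transpose(1, 2, 0)[:, :, None, :]
    img = nib.Nifti1Image(data, affine=np.eye(4))
    paths["images"] = outdir / f"{prefix}.nii.gz"
    nib.save(img, paths["images"])

    label = np.zeros(series.images.shape[1:], np.int16)
    for name, mask in series.masks.items():
        label[np.asarray(mask, bool)] = _MASK_LABELS.get(name, max(_MASK_LABELS.values()) + 1)
    paths["masks"] = outdir / f"{prefix}_masks.nii.gz"
    nib.save(nib.Nifti1Image(label[:, :, None], affine=np.eye(4)), paths["masks"])

    meta = {
        "name": series.name,
        "timing": {
            "tr_s": series.timing.tr_s,
            "n_spokes": series.timing.n_spokes,
            "sat_pulse_s": series.timing.sat_pulse_s,
            "injection_start_min": series.timing.injection_start_min,
            "injection_duration_min": series.timing.injection_duration_min,
        },
        "entries": [
            {
                "offset_ppm": e.offset_ppm, "role": e.role, "instance": e.instance,
                "retain": e.retain, "t_start_s": e.t_start_s, "t_mid_s": e.t_mid_s,
                "cycle": e.cycle,
            }
            for e in series.entries
        ],
    }
    paths["entries"] = outdir / f"{prefix}_entries.json"
    paths["entries"].write_text(json.dumps(meta, indent=1))

    if series.truth is not None:
        t = series.truth
        truth = {
            "times_min": t.times_min.tolist(),
            "offsets_ppm": t.offsets_ppm.tolist(),
            "mtr_injected": t.mtr_injected.tolist(),
            "z_true": t.z_true.tolist(),
            "uptake_mtr": t.uptake_mtr.tolist(),
            "fraction_added": t.fraction_added.tolist(),
            "fraction_per_mtr": float(t.fraction_per_mtr),
            "spike_amplitude_mtr": float(t.spike_amplitude_mtr),
        }
        paths["truth"] = outdir / f"{prefix}_truth.yaml"
        paths["truth"].write_text(yaml.safe_dump(truth))
    return paths


def read_series(outdir: str | Path, prefix: str = "series") -> DynamicSeries:
    """Read a DynamicSeries written by :func:`write_series`.

    Raises with the offending file names on a volume/sidecar count mismatch
    or missing pieces.
    """
    outdir = Path(outdir)
    img_path = outdir / f"{prefix}.nii.gz"
    meta_path = outdir / f"{prefix}_entries.json"
    mask_path = outdir / f"{prefix}_masks.nii.gz"
    for p in (img_path, meta_path, mask_path):
        if not p.exists():
            raise FileNotFoundError(f"missing series component: {p}")
    meta = json.loads(meta_path.read_text())
    data = np.asarray(nib.load(img_path).dataobj, np.float64)
    images = data[:, :, 0, :].transpose(2, 0, 1)
    if images.shape[0] != len(meta["entries"]):
        raise ValueError(
            f"{img_path.name} has {images.shape[0]} volumes but "
            f"{meta_path.name} lists {len(meta['entries'])} entries")
    entries = [ScheduleEntry(**e) for e in meta["entries"]]
    label = np.asarray(nib.load(mask_path).dataobj)[:, :, 0]
    if label.shape != images.shape[1:]:
        raise ValueError(f"{mask_path.name} grid does not match the image grid")
    masks = {name: label == code for name, code in _MASK_LABELS.items()}
    timing = TimingParams(**meta["timing"])

    truth = None
    truth_path = outdir / f"{prefix}_truth.yaml"
    if truth_path.exists():
        t = yaml.safe_load(truth_path.read_text())
        truth = GroundTruth(
            np.array(t["times_min"]), np.array(t["offsets_ppm"]),
            np.array(t["mtr_injected"]), np.array(t["z_true"]),
            np.array(t["uptake_mtr"]), np.array(t["fraction_added"]),
            t["fraction_per_mtr"], t["spike_amplitude_mtr"],
        )
    return DynamicSeries(images, entries, masks, timing, truth, meta.get("name", ""))
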