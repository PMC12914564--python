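"""Disk interchange: TIFF image stacks with a JSON sidecar, CSV tables.

One multi-page 16-bit TIFF per slice (channels as pages) plus a sidecar
``stack.json`` recording channel names, pixel size, and AP positions; CSV
tables are plain RFC-4180 with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import SliceImage

__all__ = ["write_stack", "read_stack", "write_truth_csv"]

SIDECAR_NAME = "stack.json"


def write_stack(slices: list[SliceImage], out_dir: str | Path) -> Path:
    """Write one multi-page TIFF per slice and the JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"pixel_size_um": slices[0].pixel_size_um, "slices": []}
    for s in slices:
        names = sorted(s.channels)
        fname = f"{s.slice_id}.tif"
        pages = np.stack([np.asarray(s.channels[n], dtype=np.uint16)
                          for n in names])
        tifffile.imwrite(out / fname, pages, compression="deflate")
        meta["slices"].append({
            "file": fname, "slice_id": s.slice_id, "animal_id": s.animal_id,
            "ap_position_mm": s.ap_position_mm, "channels": names,
        })
    (out / SIDECAR_NAME).write_text(json.dumps(meta, indent=1))
    return out


def read_stack(stack_dir: str | Path) -> list[SliceImage]:
    """Read a TIFF stack written by :func:`write_stack`."""
    stack_dir = Path(stack_dir)
    meta = json.loads((stack_dir / SIDECAR_NAME).read_text())
    slices = []
    for entry in meta["slices"]:
        pages = tifffile.imread(stack_dir / entry["file"])
        if pages.ndim == 2:
            pages = pages[None]
        channels = dict(zip(entry["channels"], pages))
        slices.append(SliceImage(channels=channels,
                                 pixel_size_um=meta["pixel_size_um"],
                                 ap_position_mm=entry["ap_position_mm"],
                                 animal_id=entry["animal_id"],
                                 slice_id=entry["slice_id"]))
    return slices


def write_truth_csv(truth, path: str | Path) -> Path:
    """Ground-truth summary table for a phantom stack."""
    rows = []
    for i, ap in enumerate(truth.spec.slice_positions_mm):
        n_ipsi, n_contra = truth.pnn_counts(i)
        rot, (tr, tc) = truth.planted_transforms[i]
        rows.append({
            "slice_index": i, "ap_position_mm": ap,
            "lesion_area_mm2": truth.per_slice_lesion_area_mm2[i],
            "n_microglia": len(truth.microglia_xy_px[i]),
            "n_pnn_ipsi": n_ipsi, "n_pnn_contra": n_contra,
            "planted_rotation_deg": rot,
            "planted_shift_row_px": tr, "planted_shift_col_px": tc,
        })
    df = pd.DataFrame(rows)
    df.insert(0, "lesion_volume_mm3", truth.lesion_volume_mm3)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
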