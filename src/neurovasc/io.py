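"""File I/O: hyperstack TIFFs with JSON sidecars, masks, count matrices.

Hyperstacks are written as multi-page TIFF in T-Z-C-Y-X order with voxel
spacing, channel labels and timestamps carried in the shaped-TIFF metadata,
so a round trip through disk reconstructs the in-memory object exactly.
Count matrices are read either as MatrixMarket triplets with genes/barcodes
sidecars (the Cell Ranger layout, genes x cells, transposed on load) or as
dense CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import tifffile

from ._errors import StructuralError
from .synthetic_imaging import GroundTruth, Hyperstack


def write_hyperstack(path, stack: Hyperstack) -> None:
    """Write a hyperstack as TZCYX multi-page TIFF with metadata."""
    data = np.moveaxis(stack.data, 1, 2)  # (T, C, Z, ...) -> (T, Z, C, ...)
    tifffile.imwrite(
        str(path),
        data.astype(np.float32),
        metadata={
            "axes": "TZCYX",
            "voxel_spacing_um": list(stack.voxel_spacing),
            "channels": list(stack.channels),
            "timestamps_min": [float(t) for t in stack.timestamps],
        },
    )


def read_hyperstack(path) -> Hyperstack:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim != 5:
        raise StructuralError(f"expected a 5D TZCYX stack, got shape {data.shape}")
    return Hyperstack(
        data=np.moveaxis(data, 2, 1).astype(float),
        voxel_spacing=tuple(meta.get("voxel_spacing_um", (1.0, 1.0, 5.0))),
        channels=tuple(meta.get("channels", ("vessel", "tracer"))),
        timestamps=np.asarray(meta.get("timestamps_min", np.arange(data.shape[0]))),
    )


def write_ground_truth(tiff_path, json_path, truth: GroundTruth) -> None:
    """Truth mask as TIFF plus a JSON sidecar for the rest of the record."""
    tifffile.imwrite(str(tiff_path), truth.vessel_mask.astype(np.uint8))
    payload = {
        "drift_schedule_dxdydz": truth.drift_schedule.tolist(),
        "leak_coefficients_per_min": {str(k): v for k, v in truth.leak_coefficients.items()},
        "particles": truth.particles,
    }
    Path(json_path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(tiff_path, json_path) -> GroundTruth:
    mask = tifffile.imread(str(tiff_path)).astype(bool)
    payload = json.loads(Path(json_path).read_text())
    return GroundTruth(
        vessel_mask=mask,
        drift_schedule=np.asarray(payload["drift_schedule_dxdydz"], dtype=float),
        leak_coefficients={
            float(k): v for k, v in payload["leak_coefficients_per_min"].items()
        },
        particles=payload["particles"],
    )


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(bool)


def read_counts(path, genes_path=None, barcodes_path=None) -> ad.AnnData:
    """Load a count matrix as AnnData (cells x genes).

    ``.mtx`` files follow the Cell Ranger triplet convention (genes x
    cells) and require the genes/barcodes sidecar text files; ``.csv``
    files are dense genes x cells tables with gene names in the first
    column and cell ids as the header.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        if genes_path is None or barcodes_path is None:
            raise StructuralError("MTX input needs genes and barcodes sidecar files")
        m = np.asarray(mmread(str(path)).todense())
        genes = [ln.split("\t")[0].strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
        cells = [ln.strip() for ln in Path(barcodes_path).read_text().splitlines() if ln.strip()]
        adata = ad.AnnData(
            X=m.T.astype(np.int32),
            obs=pd.DataFrame(index=cells),
            var=pd.DataFrame(index=genes),
        )
    else:
        df = pd.read_csv(path, index_col=0)
        adata = ad.AnnData(
            X=df.to_numpy().T.astype(np.int32),
            obs=pd.DataFrame(index=df.columns),
            var=pd.DataFrame(index=df.index),
        )
    adata.var["mito"] = [g.lower().startswith("mt-") for g in adata.var_names]
    return adata
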