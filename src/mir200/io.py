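"""Readers and writers for the pipeline's on-disk formats.

Expression matrices travel as TSV (features x samples, header row of sample
ids), clinical tables and tidy results as CSV, gene sets as GMT, DWI series
as multi-page TIFF (one page per b-value) with a YAML sidecar of b-values
and voxel size, masks and RGB sections as TIFF, and networks as SIF or
GraphML.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
import yaml

from .adc import DWISeries


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature", float_format="%.10g")


def read_matrix_tsv(path, scale: str | None = None) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col="feature")
    if scale:
        m.attrs["scale"] = scale
    return m


def write_dwi(series: DWISeries, tiff_path, sidecar_path) -> None:
    tifffile.imwrite(
        tiff_path, np.asarray(series.signals, np.float32), photometric="minisblack"
    )
    meta = {
        "b_values": [float(b) for b in series.b_values],
        "voxel_size_mm": float(series.voxel_size_mm),
    }
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh)


def read_dwi(tiff_path, sidecar_path, roi_path=None) -> DWISeries:
    signals = tifffile.imread(tiff_path).astype(float)
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    roi = tifffile.imread(roi_path).astype(bool) if roi_path else None
    return DWISeries(
        signals=signals,
        b_values=np.asarray(meta["b_values"], float),
        roi=roi,
        voxel_size_mm=float(meta.get("voxel_size_mm", 1.0)),
    )


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_rgb(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.clip(np.asarray(image), 0, 255).astype(np.uint8))


def write_candidate_map_tsv(candidates: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tgene\n")
        for mir in sorted(candidates):
            for g in sorted(candidates[mir]):
                fh.write(f"{mir}\t{g}\n")


def read_candidate_map_tsv(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for mir, sub in df.groupby("mirna"):
        out[str(mir)] = set(sub["gene"].astype(str))
    return out


def write_network_sif(net: nx.Graph, path) -> None:
    mirnas = [n for n, d in net.nodes(data=True) if d.get("bipartite") == "mirna"]
    with open(path, "w") as fh:
        for m in sorted(mirnas):
            for g in sorted(net.neighbors(m)):
                fh.write(f"{m}\ttargets\t{g}\n")


def write_network_graphml(net: nx.Graph, path) -> None:
    clean = nx.Graph()
    for n, d in net.nodes(data=True):
        clean.add_node(n, **{k: str(v) for k, v in d.items()})
    for u, v, d in net.edges(data=True):
        clean.add_edge(u, v, **{k: float(x) for k, x in d.items() if np.isfinite(x)})
    nx.write_graphml(clean, path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
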