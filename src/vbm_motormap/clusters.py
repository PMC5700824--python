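"""Cluster extraction, atlas labelling and post-hoc correlation tables.

Thresholded statistic maps are decomposed into connected components
(default 18-connectivity), each reported with its size, signed peak
statistic, peak voxel index and world-mm (MNI-convention) coordinate, and
the modal atlas label covering it.  Cluster-averaged GM intensities can
then be correlated post hoc with the motor (sub)scores; because clusters
were selected for showing an effect, those post-hoc correlations are
biased by selection and every exported table carries a note saying so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from vbm_motormap.clinical import SUBSCORE_LABELS, critical_r
from vbm_motormap.voxelstats import GMVolumeStack, StatMap

__all__ = [
    "AtlasVolume",
    "ClusterTable",
    "extract_clusters",
    "voxel_to_world",
    "label_cluster",
    "posthoc_cluster_correlations",
    "CIRCULARITY_NOTE",
]

CIRCULARITY_NOTE = (
    "Note: post-hoc correlations are computed on clusters selected for "
    "showing an effect; the reported r values are optimistically biased "
    "(circular) and are descriptive, not confirmatory."
)


@dataclass
class AtlasVolume:
    """Integer-labelled parcellation on the analysis grid.

    Label 0 is background; every nonzero label must appear in ``name_map``.
    """

    labels: np.ndarray
    name_map: dict[int, str]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        unnamed = sorted(present - set(self.name_map))
        if unnamed:
            raise ValueError(f"atlas labels without names: {unnamed}")

    def region_mask(self, *names: str) -> np.ndarray:
        ids = [i for i, n in self.name_map.items() if n in names]
        if not ids:
            raise KeyError(f"no atlas region named {names}")
        return np.isin(self.labels, ids)

    @classmethod
    def from_nifti(cls, label_path, name_map_path) -> "AtlasVolume":
        img = nib.load(str(label_path))
        names = pd.read_csv(name_map_path, sep="\t", header=None, names=["id", "name"])
        return cls(
            labels=np.asarray(img.dataobj).astype(np.int32),
            name_map=dict(zip(names["id"].astype(int), names["name"])),
            affine=img.affine,
        )

    def to_nifti(self, label_path, name_map_path=None) -> None:
        if self.affine is None:
            raise ValueError("atlas has no affine; cannot export NIfTI")
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine), str(label_path))
        if name_map_path is not None:
            pd.DataFrame(sorted(self.name_map.items())).to_csv(
                name_map_path, sep="\t", header=False, index=False
            )


@dataclass
class ClusterTable:
    """Suprathreshold clusters, sorted by descending size.

    ``table`` rows: cluster_id, size, peak_i/j/k, peak_x/y/z_mm, peak_stat,
    label, label_coverage.  ``label_volume`` assigns each suprathreshold
    voxel its cluster_id (0 elsewhere).
    """

    table: pd.DataFrame
    label_volume: np.ndarray
    affine: np.ndarray
    threshold: float
    tail: str

    def __len__(self) -> int:
        return len(self.table)

    def cluster_mask(self, cluster_id: int) -> np.ndarray:
        return self.label_volume == cluster_id

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")

    def to_json(self, path) -> None:
        Path(path).write_text(self.table.to_json(orient="records", indent=2))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def voxel_to_world(ijk: Sequence[float], affine: np.ndarray) -> np.ndarray:
    """Map a voxel index to world mm via the homogeneous affine."""
    ijk = np.asarray(ijk, dtype=float)
    return (affine @ np.append(ijk, 1.0))[:3]


def world_to_voxel(xyz: Sequence[float], affine: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_world` (continuous voxel coordinates)."""
    return (np.linalg.inv(affine) @ np.append(np.asarray(xyz, float), 1.0))[:3]


def label_cluster(
    cluster_mask: np.ndarray, atlas: AtlasVolume
) -> tuple[str, float]:
    """Modal nonzero atlas label among cluster voxels, with its coverage.

    Ties break to the lowest label id.  Clusters lying entirely in atlas
    background are reported as ("unlabeled", 0.0).
    """
    if cluster_mask.shape != atlas.labels.shape:
        raise ValueError("cluster mask and atlas are on different grids")
    vals = atlas.labels[cluster_mask]
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        return "unlabeled", 0.0
    ids, counts = np.unique(nonzero, return_counts=True)
    best = ids[np.argmax(counts)]  # np.unique sorts ids, argmax takes first max
    coverage = counts[ids == best][0] / vals.size
    return atlas.name_map[int(best)], float(coverage)


def extract_clusters(
    stat: StatMap,
    threshold: float,
    tail: str | None = None,
    connectivity: int = 18,
    affine: np.ndarray | None = None,
    atlas: AtlasVolume | None = None,
) -> ClusterTable:
    """Connected components of suprathreshold voxels.

    ``tail`` defaults to the map's own tail convention: for ``one_neg``
    voxels with t < threshold are suprathreshold, for ``one_pos`` t >
    threshold, for ``two`` |t| > threshold.  Peaks are the tail-extreme
    statistic and are always reported signed.  An empty table is a valid
    result.
    """
    tail = tail or stat.tail
    t = np.nan_to_num(stat.t, nan=0.0)
    if tail == "one_neg":
        supra = t < threshold
    elif tail == "one_pos":
        supra = t > threshold
    elif tail == "two":
        supra = np.abs(t) > abs(threshold)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    if affine is None:
        affine = np.eye(4)

    labelled, n_found = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    rows = []
    for cid in range(1, n_found + 1):
        mask = labelled == cid
        tv = stat.t[mask]
        if tail == "one_neg":
            local = np.argmin(tv)
        elif tail == "one_pos":
            local = np.argmax(tv)
        else:
            local = np.argmax(np.abs(tv))
        ijk = np.array(np.nonzero(mask)).T[local]
        mm = voxel_to_world(ijk, affine)
        row = {
            "cluster_id": cid,
            "size": int(mask.sum()),
            "peak_i": int(ijk[0]),
            "peak_j": int(ijk[1]),
            "peak_k": int(ijk[2]),
            "peak_x_mm": mm[0],
            "peak_y_mm": mm[1],
            "peak_z_mm": mm[2],
            "peak_stat": float(tv[local]),
        }
        if atlas is not None:
            row["label"], row["label_coverage"] = label_cluster(mask, atlas)
        rows.append(row)

    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("size", ascending=False, kind="stable").reset_index(drop=True)
        # renumber ids by descending size, and relabel the volume to match
        remap = np.zeros(n_found + 1, dtype=np.int32)
        remap[table["cluster_id"].to_numpy()] = np.arange(1, len(table) + 1)
        labelled = remap[labelled]
        table["cluster_id"] = np.arange(1, len(table) + 1)
    return ClusterTable(
        table=table, label_volume=labelled, affine=affine, threshold=threshold, tail=tail
    )


def posthoc_cluster_correlations(
    stack: GMVolumeStack,
    clusters: ClusterTable,
    subscores: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate cluster-averaged GM with each motor (sub)score.

    ``subscores`` must carry the axial/bradykinesia/rigidity/tremor/total
    columns aligned with the stack's subjects (matched on ``subject_id``
    when present, otherwise by order).  Correlations are two-tailed
    Pearson; entries with |r| above the critical value at ``alpha``
    (df = n - 2) are flagged significant.
    """
    if len(clusters) == 0:
        raise ValueError("cluster table is empty; nothing to correlate")
    if "subject_id" in subscores.columns:
        ids = list(subscores["subject_id"].astype(str))
        if ids != [str(s) for s in stack.subject_ids]:
            raise ValueError("subject order mismatch between stack and subscore table")
    elif len(subscores) != stack.n_subjects:
        raise ValueError("subscore table length does not match n_subjects")

    n = stack.n_subjects
    rcrit = critical_r(alpha, n - 2, tails="two")
    scores = subscores.loc[:, list(SUBSCORE_LABELS)].to_numpy(dtype=float)
    rows = []
    for cid in clusters.table["cluster_id"]:
        mean_gm = stack.data[:, clusters.cluster_mask(int(cid))].mean(axis=1)
        row: dict = {"cluster_id": int(cid)}
        if "label" in clusters.table.columns:
            row["label"] = clusters.table.set_index("cluster_id").loc[int(cid), "label"]
        for j, lab in enumerate(SUBSCORE_LABELS):
            col = scores[:, j]
            if col.std() == 0 or mean_gm.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(mean_gm, col)[0, 1])
            row[f"r_{lab}"] = r
            row[f"sig_{lab}"] = bool(np.isfinite(r) and abs(r) > rcrit)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["critical_r"] = rcrit
    out.attrs["df"] = n - 2
    out.attrs["note"] = CIRCULARITY_NOTE
    return out
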