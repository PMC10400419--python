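"""Vertex-level feature tables, parcellations, and per-region samples.

The raw substrate for cortical similarity analysis is a table of surface
vertices, each carrying a handful of morphometric features (cortical
thickness, surface area, gray-matter volume, mean curvature, sulcal depth
for standard T1w pipelines), a hemisphere label, and a parcellation region
label.  This module reads that table from FreeSurfer per-vertex scalar
("curv") files plus a ``.annot`` parcellation, or from a generic TSV, then
filters biologically unfeasible vertices, z-scores each feature across the
whole brain, and splits the result into per-region multivariate samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Region label given to vertices not covered by the parcellation
#: (e.g. the medial wall / "unknown" label of FreeSurfer annotations).
UNLABELED = "__unlabeled__"

#: Default mapping from the semantic roles used by the vertex filter to
#: feature column names.
DEFAULT_ROLE_MAP = {"thickness": "CT", "volume": "Vol", "area": "SA"}

REQUIRED_COLUMNS = ("vertex_id", "hemisphere", "region")
HEMISPHERES = ("left", "right")


@dataclass
class VertexFeatureTable:
    """Per-vertex morphometry with hemisphere and region labels.

    Parameters
    ----------
    df
        DataFrame with columns ``vertex_id``, ``hemisphere`` (``left`` /
        ``right``), ``region``, followed by one column per feature.
    feature_names
        Ordered feature column names; order is preserved through every
        downstream operation so that region samples are comparable.
    """

    df: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"missing required column {col!r}")
        missing = [f for f in self.feature_names if f not in self.df.columns]
        if missing:
            raise ValueError(f"feature columns absent from table: {missing}")
        bad_hemi = set(self.df["hemisphere"].unique()) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        for hemi in HEMISPHERES:
            ids = self.df.loc[self.df["hemisphere"] == hemi, "vertex_id"]
            if ids.duplicated().any():
                raise ValueError(f"duplicate vertex_id within hemisphere {hemi!r}")

    @property
    def n_vertices(self) -> int:
        return len(self.df)

    @property
    def d(self) -> int:
        return len(self.feature_names)

    def features(self) -> np.ndarray:
        """The n × d feature matrix in declared column order."""
        return self.df[self.feature_names].to_numpy(dtype=float)

    def copy(self) -> "VertexFeatureTable":
        return VertexFeatureTable(self.df.copy(), list(self.feature_names))

    def to_tsv(self, path) -> None:
        cols = list(REQUIRED_COLUMNS) + self.feature_names
        self.df[cols].to_csv(path, sep="\t", index=False)


@dataclass
class ParcellationScheme:
    """Catalogue of cortical regions (network nodes) with metadata.

    ``table`` is indexed by ``region_id`` and may carry ``name``,
    ``hemisphere``, ``cyto_class`` (cytoarchitectonic class, e.g. a Von
    Economo label), centroid coordinates ``x, y, z`` (mm), and
    ``parent_region`` mapping each region to one region of a coarser
    scheme.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.name != "region_id":
            if "region_id" in self.table.columns:
                self.table = self.table.set_index("region_id")
            else:
                raise ValueError("parcellation table needs a region_id index/column")
        if self.table.index.duplicated().any():
            raise ValueError("region_ids must be unique")

    @property
    def region_ids(self) -> list:
        return list(self.table.index)

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def hemispheres(self) -> pd.Series:
        return self.table["hemisphere"]

    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    def parent_map(self) -> pd.Series:
        """region_id -> parent_region; raises if the mapping is partial."""
        if "parent_region" not in self.table.columns:
            raise ValueError("parcellation carries no parent_region column")
        parents = self.table["parent_region"]
        if parents.isna().any():
            missing = list(self.table.index[parents.isna()])
            raise ValueError(f"regions without a parent: {missing}")
        return parents

    @classmethod
    def from_tsv(cls, path) -> "ParcellationScheme":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


@dataclass
class RegionSample:
    """One region's n_r × d matrix of (standardized) vertex features."""

    region_id: object
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("RegionSample.data must be 2-D (n_r × d)")

    @property
    def n(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# Readers


def read_vertex_features_tsv(path) -> VertexFeatureTable:
    """Read the generic TSV dialect: vertex_id, hemisphere, region, features…"""
    df = pd.read_csv(path, sep="\t")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(
                f"unsupported TSV dialect: column {col!r} missing from {path}; "
                "expected columns vertex_id, hemisphere, region, <features...>"
            )
    feats = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if not feats:
        raise ValueError(f"no feature columns found in {path}")
    df["region"] = df["region"].fillna(UNLABELED)
    return VertexFeatureTable(df, feats)


def read_vertex_features_freesurfer(
    curv_files: Mapping[str, Mapping[str, str]],
    annot_files: Mapping[str, str],
) -> tuple[VertexFeatureTable, ParcellationScheme]:
    """Read FreeSurfer per-vertex scalar files plus ``.annot`` parcellations.

    Parameters
    ----------
    curv_files
        ``{hemisphere: {feature_name: path}}`` of per-vertex scalar
        ("curv"-format) files, e.g. ``{"left": {"CT": "lh.thickness", ...}}``.
    annot_files
        ``{hemisphere: path}`` of ``.annot`` files labelling each vertex.

    Vertices whose annotation label is -1 or named ``unknown`` are kept in
    the table under the :data:`UNLABELED` sentinel and excluded downstream.
    """
    import nibabel.freesurfer.io as fsio

    frames = []
    regions: dict[str, dict] = {}
    feature_names: list[str] | None = None
    for hemi, files in curv_files.items():
        if feature_names is None:
            feature_names = list(files)
        arrays = {}
        counts = {}
        for feat, path in files.items():
            arr = np.asarray(fsio.read_morph_data(path), dtype=float)
            arrays[feat] = arr
            counts[str(path)] = arr.size
        labels, _ctab, names = fsio.read_annot(annot_files[hemi])
        counts[str(annot_files[hemi])] = labels.size
        if len(set(counts.values())) > 1:
            detail = ", ".join(f"{p}: {n}" for p, n in counts.items())
            raise ValueError(f"mismatched vertex counts between files ({detail})")
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in names]
        region_of = np.array(
            [
                UNLABELED
                if lab < 0 or names[lab] in ("unknown", "Unknown", "???")
                else f"{hemi[0]}h_{names[lab]}"
                for lab in labels
            ],
            dtype=object,
        )
        df = pd.DataFrame(arrays)
        df.insert(0, "region", region_of)
        df.insert(0, "hemisphere", hemi)
        df.insert(0, "vertex_id", np.arange(labels.size))
        frames.append(df)
        for rid in np.unique(region_of):
            if rid != UNLABELED:
                regions[rid] = {"region_id": rid, "hemisphere": hemi}
    table = VertexFeatureTable(pd.concat(frames, ignore_index=True), feature_names or [])
    parc = ParcellationScheme(pd.DataFrame(list(regions.values())))
    return table, parc


# ---------------------------------------------------------------------------
# Standardisation pipeline


def filter_vertices(
    table: VertexFeatureTable,
    role_map: Mapping[str, str] | None = None,
) -> VertexFeatureTable:
    """Discard vertices with non-positive thickness, volume, or surface area.

    Zero values of these size metrics mark biologically unfeasible surface
    locations; they are removed before any moment estimation.  ``role_map``
    maps the roles ``thickness`` / ``volume`` / ``area`` to the table's
    column names (default ``CT`` / ``Vol`` / ``SA``).
    """
    role_map = dict(role_map or DEFAULT_ROLE_MAP)
    cols = []
    for role, col in role_map.items():
        if col not in table.df.columns:
            raise ValueError(f"vertex filtering requires a {role} column named {col!r}")
        cols.append(col)
    keep = (table.df[cols] > 0).all(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_vertices: removed %d vertices with non-positive %s", removed, cols)
    return VertexFeatureTable(table.df.loc[keep].reset_index(drop=True), list(table.feature_names))


def standardize_features(table: VertexFeatureTable) -> VertexFeatureTable:
    """z-score each feature across all retained vertices of both hemispheres.

    Standardisation is within-subject and whole-brain (not per region, not
    per cohort), using the sample standard deviation (ddof=1).
    """
    df = table.df.copy()
    for feat in table.feature_names:
        col = df[feat].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"feature {feat!r} has zero variance; cannot standardize")
        df[feat] = (col - col.mean()) / sd
    return VertexFeatureTable(df, list(table.feature_names))


def split_regions(
    table: VertexFeatureTable, parc: ParcellationScheme
) -> list[RegionSample]:
    """Partition the vertex table into one RegionSample per parcel.

    Returns one sample per region in ``parc`` (possibly empty), in the
    parcellation's region order.  Vertices carrying the unlabeled sentinel
    are excluded and their count logged.
    """
    d = table.d
    n_unlabeled = int((table.df["region"] == UNLABELED).sum())
    if n_unlabeled:
        logger.info("split_regions: excluding %d unlabeled vertices", n_unlabeled)
    groups = {
        rid: sub[table.feature_names].to_numpy(dtype=float)
        for rid, sub in table.df[table.df["region"] != UNLABELED].groupby("region", sort=False)
    }
    known = set(parc.region_ids)
    stray = set(groups) - known
    if stray:
        raise ValueError(f"vertex regions absent from parcellation: {sorted(map(str, stray))}")
    samples = []
    for rid in parc.region_ids:
        data = groups.get(rid, np.empty((0, d)))
        if data.shape[0] == 0:
            logger.warning("split_regions: region %s has zero vertices", rid)
        samples.append(RegionSample(rid, data))
    return samples
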