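"""Readers and writers for the plain-text interchange formats.

All tables are tab-separated text; gene sets use the standard GMT layout
(``name<TAB>description<TAB>gene1<TAB>...``).  Matrices are dense TSV with
row/column order equal to the atlas region order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CohortTable, Connectome, ParcelAtlas

logger = logging.getLogger(__name__)

ATLAS_COLUMNS = ["region_id", "hemisphere", "x", "y", "z", "network", "cortical_type"]
CENTROID_TOL = 1e-6


def load_atlas(path) -> ParcelAtlas:
    """Read an atlas TSV; centroids are renormalised to unit length.

    Centroids whose norm deviates from 1 by more than 1e-6 are rejected
    (they do not describe a point on the projection sphere); zero vectors
    are rejected as degenerate.
    """
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    missing = set(ATLAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"atlas file missing column(s): {sorted(missing)}")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    norms = np.linalg.norm(coords, axis=1)
    if np.any(norms == 0):
        bad = df["region_id"][norms == 0].iloc[0]
        raise ValueError(f"degenerate centroid (zero vector) for region {bad}")
    if np.any(np.abs(norms - 1.0) > CENTROID_TOL):
        bad = df["region_id"][np.abs(norms - 1.0) > CENTROID_TOL].iloc[0]
        raise ValueError(f"non-unit centroid beyond tolerance for region {bad}")
    coords = coords / norms[:, None]
    return ParcelAtlas(
        region_ids=df["region_id"].to_numpy(dtype=object),
        hemisphere=df["hemisphere"].to_numpy(dtype=object),
        coords=coords,
        network=df["network"].to_numpy(dtype=object),
        cortical_type=df["cortical_type"].to_numpy(dtype=object),
    )


def write_atlas(atlas: ParcelAtlas, path) -> None:
    df = pd.DataFrame(
        {
            "region_id": atlas.region_ids,
            "hemisphere": atlas.hemisphere,
            "x": atlas.coords[:, 0],
            "y": atlas.coords[:, 1],
            "z": atlas.coords[:, 2],
            "network": atlas.network,
            "cortical_type": atlas.cortical_type,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_matrix(path, atlas: ParcelAtlas, kind: str) -> np.ndarray:
    """Read a dense connectivity matrix keyed to the atlas order.

    The matrix must be square with one row per atlas region.  Asymmetry
    within 1e-8 is repaired by averaging; larger asymmetry is an error.
    The diagonal is forced to zero.  ``kind='functional'`` additionally
    requires entries in [-1, 1] (1e-8 slack, then clipped).
    """
    if kind not in ("structural", "functional"):
        raise ValueError("kind must be 'structural' or 'functional'")
    m = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{kind} matrix must be square, got shape {m.shape}")
    if m.shape[0] != atlas.n_regions:
        raise ValueError(
            f"matrix size {m.shape[0]} does not match atlas ({atlas.n_regions} regions)"
        )
    if np.max(np.abs(m - m.T)) > 1e-8:
        raise ValueError(f"{kind} matrix is asymmetric beyond tolerance")
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    if kind == "functional":
        if np.any(np.abs(m) > 1 + 1e-8):
            raise ValueError("functional entries outside [-1, 1]")
        m = np.clip(m, -1.0, 1.0)
    else:
        if np.any(m < 0):
            raise ValueError("structural entries must be non-negative")
    return m


def write_matrix(m: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(m, dtype=float)).to_csv(path, sep="\t", index=False, header=False)


def load_cohort(path, atlas: ParcelAtlas) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "site": str})
    return CohortTable.from_frame(df, list(atlas.region_ids))


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False)


def parse_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered ``{set_name: gene_list}`` map.

    Duplicate genes within a set are removed (first occurrence kept) with a
    logged warning; duplicate set names and short lines are errors.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning(
                    "GMT set %r: %d duplicate gene(s) removed", name, len(genes) - len(unique)
                )
            sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def load_expression(path, atlas: ParcelAtlas) -> pd.DataFrame:
    """Read a regions x genes expression TSV (first column = region_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(atlas.region_ids):
        raise ValueError("expression rows must match atlas region order")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="region_id")


def connectome_from_files(sc_path, fc_path, atlas: ParcelAtlas) -> Connectome:
    return Connectome(
        sc=load_matrix(sc_path, atlas, "structural"),
        fc=load_matrix(fc_path, atlas, "functional"),
    )
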