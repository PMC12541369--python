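"""Reading and writing the pipeline's delimited-text and TIFF formats."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd
import tifffile

from .recombination import MarkerMap
from .smlm import LOCALIZATION_COLUMNS, LocalizationCloud
from .synthetic import Image2D

__all__ = [
    "write_localizations",
    "read_localizations",
    "write_image",
    "read_image",
    "write_genotypes",
    "read_genotypes",
    "write_marker_map",
    "read_marker_map",
    "write_table",
    "read_table",
]

_SEP = "\t"


def write_localizations(clouds: Iterable[LocalizationCloud], path) -> None:
    """One row per localization: focus_id, x_nm, y_nm, z_nm, locprec_nm,
    locprec_z_nm, channel (tab-delimited, with header)."""
    frames = []
    for cloud in clouds:
        df = cloud.data[LOCALIZATION_COLUMNS].copy()
        df.insert(0, "focus_id", cloud.focus_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=_SEP, index=False)


def read_localizations(path, roi_halfwidth: float = 200.0) -> List[LocalizationCloud]:
    df = pd.read_csv(path, sep=_SEP)
    clouds = []
    for focus_id, sub in df.groupby("focus_id", sort=False):
        clouds.append(
            LocalizationCloud(
                str(focus_id),
                sub[LOCALIZATION_COLUMNS].reset_index(drop=True),
                roi_halfwidth=roi_halfwidth,
            )
        )
    return clouds


def write_image(image: Image2D, path) -> None:
    tifffile.imwrite(
        path,
        image.data.astype(np.float32),
        resolution=(1e7 / image.pixel_size, 1e7 / image.pixel_size),
        metadata={"pixel_size_nm": image.pixel_size},
    )


def read_image(path, pixel_size: float) -> Image2D:
    return Image2D(tifffile.imread(path), pixel_size)


def write_genotypes(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep=_SEP, index=False)


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEP, dtype=str, keep_default_na=False)


def write_marker_map(markers: MarkerMap, path) -> None:
    pd.DataFrame(
        {
            "marker": markers.labels,
            "chrom": markers.chromosome,
            "pos_bp": markers.positions_bp,
        }
    ).to_csv(path, sep=_SEP, index=False)


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep=_SEP)
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("marker map must be on a single chromosome")
    return MarkerMap(tuple(df["marker"]), tuple(df["pos_bp"]), str(chroms[0]))


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_SEP, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEP)
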