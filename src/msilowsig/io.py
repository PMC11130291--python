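"""Reading and writing the package's on-disk artifacts.

Dense cubes travel as NPZ archives with an embedded m/z table; annotations
as 32-bit TIFF or CSV; peptide tables as MaxQuant-shaped TSV; peak
references as CSV.  imzML ingestion/export is available when pyimzml is
installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .patching import AnnotationImage
from .preproc import IntensityCube, PeakReference


def save_cube(cube: IntensityCube, path: str | Path) -> None:
    np.savez_compressed(
        path,
        sample_id=np.asarray(cube.sample_id),
        mz=cube.mz,
        intensities=cube.intensities,
        background_mask=cube.background_mask,
    )


def load_cube(path: str | Path) -> IntensityCube:
    with np.load(path, allow_pickle=False) as archive:
        return IntensityCube(
            sample_id=str(archive["sample_id"]),
            mz=archive["mz"],
            intensities=archive["intensities"],
            background_mask=archive["background_mask"],
        )


def save_annotation(ann: AnnotationImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, ann.values.astype(np.float32))
    else:
        np.savetxt(path, ann.values, delimiter=",")


def load_annotation(path: str | Path, sample_id: str = "") -> AnnotationImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        values = np.asarray(tifffile.imread(path), dtype=float)
    else:
        values = np.loadtxt(path, delimiter=",")
    return AnnotationImage(sample_id or path.stem, values)


def save_peak_reference(ref: PeakReference, path: str | Path) -> None:
    pd.DataFrame({"mz": ref.peaks, "bin_count": ref.bin_counts}).to_csv(
        path, index=False
    )


def load_peak_reference(path: str | Path) -> PeakReference:
    df = pd.read_csv(path)
    return PeakReference(df["mz"].to_numpy(), df["bin_count"].to_numpy())


def save_peptide_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_peptide_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"Sequence", "Proteins", "Gene names", "Mass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptide table is missing columns: {sorted(missing)}")
    return df


def load_imzml(path: str | Path, sample_id: str = "") -> IntensityCube:
    """Read a continuous-mode imzML file into a dense cube.

    Pixels absent from the file are treated as background.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords = np.asarray(parser.coordinates)
    xs, ys = coords[:, 0], coords[:, 1]
    w = int(xs.max())
    h = int(ys.max())
    mz0, _ = parser.getspectrum(0)
    cube = np.zeros((h, w, len(mz0)))
    background = np.ones((h, w), dtype=bool)
    for i, (x, y, *_rest) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        if len(mzs) != len(mz0):
            raise ValueError("processed-mode imzML requires a common axis")
        cube[y - 1, x - 1] = ints
        background[y - 1, x - 1] = False
    return IntensityCube(
        sample_id=sample_id or Path(path).stem,
        mz=mz0,
        intensities=np.clip(cube, 0, None),
        background_mask=background,
    )
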