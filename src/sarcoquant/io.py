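"""File formats.

TSV for LFC/DE tables (columns ``gene_id``, ``lfc``, ``qval``; header
required) and TPM matrices (genes x samples, first column ``gene_id``);
GMT for gene sets (set name, description, tab-separated member ids);
two-column CSV (``position_um``, ``intensity``) for intensity profiles and
(``sample_index``, ``intensity``) for lane profiles; grayscale TIFF for
images (float internally, 16-bit on write, per microscopy convention).

Parsing is fail-loud: malformed rows raise :class:`ParseError` naming the
file and line; rows are never silently dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .densitometry import LaneProfile
from .errors import ParseError
from .geneset import GeneSet, LfcTable
from .morphometry import IntensityProfile

_LFC_COLUMNS = ("gene_id", "lfc", "qval")


def read_lfc_table(path: str | Path, comparison_label: str | None = None) -> LfcTable:
    """Read a per-gene LFC/DE table from TSV, validating every row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read TSV: {exc}", str(path)) from exc
    missing = set(_LFC_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(
            f"missing required column(s) {sorted(missing)}", str(path), line=1
        )
    out = pd.DataFrame({"gene_id": df["gene_id"].astype(str)})
    for col in ("lfc", "qval"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna() | df[col].isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"non-numeric {col} value {df[col].iloc[bad[0]]!r}",
                str(path), line=int(bad[0]) + 2,
            )
        out[col] = vals.astype(float)
    label = comparison_label if comparison_label is not None else path.stem
    return LfcTable(out, comparison_label=label)


def write_lfc_table(table: LfcTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from a GMT file (name, description, member ids)."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT line needs >= 3 tab-separated fields "
                    "(name, description, ids...)", str(path), line=lineno,
                )
            name = fields[0].strip()
            if not name:
                raise ParseError("empty gene-set name", str(path), line=lineno)
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r}",
                                 str(path), line=lineno)
            ids = [g.strip() for g in fields[2:] if g.strip()]
            if not ids:
                raise ParseError(f"gene set {name!r} has no members",
                                 str(path), line=lineno)
            sets[name] = GeneSet(name, frozenset(ids))
    if not sets:
        raise ParseError("GMT file contains no gene sets", str(path))
    return sets


def write_gmt(sets: dict[str, GeneSet], path: str | Path,
              description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            ids = "\t".join(sorted(sets[name].gene_ids))
            fh.write(f"{name}\t{description}\t{ids}\n")


def read_tpm_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TPM matrix TSV (first column gene_id, one column per sample)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError("TPM matrix must have a gene_id column", str(path), line=1)
    if df.shape[1] < 2:
        raise ParseError("TPM matrix has no sample columns", str(path), line=1)
    df = df.set_index("gene_id")
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        row = int(np.where(vals.isna().any(axis=1))[0][0])
        raise ParseError("non-numeric TPM value", str(path), line=row + 2)
    return vals


def write_tpm_matrix(tpm: pd.DataFrame, path: str | Path) -> None:
    tpm.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.10g")


def read_profile_csv(path: str | Path) -> IntensityProfile:
    """Read an intensity profile from CSV with columns position_um, intensity."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("position_um", "intensity"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r}", str(path), line=1)
    pos = df["position_um"].to_numpy(dtype=float)
    if pos.size < 2:
        raise ParseError("profile needs >= 2 samples", str(path))
    steps = np.diff(pos)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12) or steps[0] <= 0:
        raise ParseError("position_um must increase with uniform spacing", str(path))
    return IntensityProfile(df["intensity"].to_numpy(dtype=float), float(steps[0]))


def write_profile_csv(profile: IntensityProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"position_um": profile.positions_um, "intensity": profile.intensities}
    ).to_csv(path, index=False, float_format="%.10g")


def read_lane_csv(path: str | Path, lane_id: str | None = None) -> LaneProfile:
    """Read a gel-lane profile from CSV with columns sample_index, intensity."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("sample_index", "intensity"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r}", str(path), line=1)
    return LaneProfile(df["intensity"].to_numpy(dtype=float),
                       lane_id if lane_id is not None else path.stem)


def write_lane_csv(lane: LaneProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_index": np.arange(len(lane)), "intensity": lane.intensities}
    ).to_csv(path, index=False, float_format="%.10g")


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG image as a float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # collapse trivial channel axes
        img = img.mean(axis=-1)
    return img


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a float image as 16-bit grayscale TIFF, rescaled to full range."""
    arr = np.asarray(img, dtype=float)
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    tifffile.imwrite(path, (scaled * 65535).astype(np.uint16))
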