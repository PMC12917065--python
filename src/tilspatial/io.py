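"""Reading, validation and writing of cell-coordinate and clinical tables.

Coordinate tables are one row per annotated cell, as exported by an
image-analysis platform: subject id, cell class (``cancer`` or ``cd8``),
x/y position in micrometres, and optionally the platform's precomputed
shortest distance from a CD8+ cell to a tumor gland (also in um).  All
downstream spatial work is done in millimetres; the fixed 1:1000 rescaling
lives in :func:`build_subject_pattern`.

Clinical tables are one row per subject: treatment arm (``NAT`` for
neoadjuvant-treated, ``naive`` for upfront surgery), sex, age in years,
tumor grade (G1-G3), TNM stage (I-IV), follow-up time in days and the
death-event indicator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MM_PER_UM = 1e-3

CELL_CLASSES = ("cancer", "cd8")

#: default column mapping for cell tables (canonical name -> file header)
DEFAULT_DIALECT = {
    "subject_id": "subject_id",
    "cell_class": "class",
    "x_um": "x_um",
    "y_um": "y_um",
    "dist_um": "dist_um",
}

REQUIRED_CELL_COLUMNS = ("subject_id", "cell_class", "x_um", "y_um")

CLINICAL_COLUMNS = (
    "subject_id",
    "treatment",
    "sex",
    "age",
    "grade",
    "stage",
    "time",
    "event",
)

TREATMENTS = ("naive", "NAT")
GRADES = ("G1", "G2", "G3")
STAGES = ("I", "II", "III", "IV")


class CellTableError(ValueError):
    """Malformed cell-coordinate table (missing column, bad rows in strict mode)."""


@dataclass
class Window:
    """Axis-aligned observation rectangle in mm."""

    x0: float
    x1: float
    y0: float
    y1: float

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (
            (xy[:, 0] >= self.x0)
            & (xy[:, 0] <= self.x1)
            & (xy[:, 1] >= self.y0)
            & (xy[:, 1] <= self.y1)
        )


@dataclass
class SubjectPattern:
    """One subject's two-class planar point pattern, coordinates in mm.

    ``cd8_dist_um`` carries the platform-exported distance-to-gland per CD8+
    cell when the input table had one; ``dist_source`` records whether TIL
    filtering used that column or fell back to nearest cancer-centroid
    distances.
    """

    subject_id: str
    cancer: np.ndarray  # (n, 2) mm
    cd8: np.ndarray  # (m, 2) mm
    window: Window
    cd8_dist_um: np.ndarray | None = None
    dist_source: str | None = None
    til_filtered: bool = False

    def __post_init__(self) -> None:
        self.cancer = np.asarray(self.cancer, dtype=float).reshape(-1, 2)
        self.cd8 = np.asarray(self.cd8, dtype=float).reshape(-1, 2)
        if self.window.area <= 0:
            raise ValueError(
                f"subject {self.subject_id}: window has non-positive area"
            )
        for name, pts in (("cancer", self.cancer), ("cd8", self.cd8)):
            if pts.size and not self.window.contains(pts).all():
                raise ValueError(
                    f"subject {self.subject_id}: {name} points outside window"
                )

    @property
    def n_cancer(self) -> int:
        return len(self.cancer)

    @property
    def n_cd8(self) -> int:
        return len(self.cd8)


@dataclass
class Exclusion:
    subject_id: str
    reason: str


def _resolve_dialect(dialect: dict | None) -> dict:
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    return d


def _read_delimited(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "\t" if suffix in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_cell_table(
    path: str | Path,
    dialect: dict | None = None,
    errors: str = "warn",
) -> pd.DataFrame:
    """Read a cell-coordinate table into canonical columns.

    Parameters
    ----------
    path
        CSV, TSV or xlsx file, one row per cell.
    dialect
        Optional mapping from canonical column names
        (``subject_id, cell_class, x_um, y_um, dist_um``) to the file's
        header names; unspecified entries use :data:`DEFAULT_DIALECT`.
    errors
        ``"warn"`` drops rows with non-numeric coordinates or unknown cell
        classes and logs each with its 1-based data line number;
        ``"raise"`` raises :class:`CellTableError` instead.

    Returns
    -------
    DataFrame with columns ``subject_id`` (str), ``cell_class``
    (``cancer``/``cd8``), ``x_um``, ``y_um`` (float) and, when present in
    the input, ``dist_um`` (float, NaN where missing).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    d = _resolve_dialect(dialect)
    raw = _read_delimited(path)
    # accept canonical names as a fallback for the dialect's header names
    for canon in d:
        if d[canon] not in raw.columns and canon in raw.columns:
            d[canon] = canon
    missing = [d[c] for c in REQUIRED_CELL_COLUMNS if d[c] not in raw.columns]
    if missing:
        raise CellTableError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    out = pd.DataFrame(
        {
            "subject_id": raw[d["subject_id"]].astype(str),
            "cell_class": raw[d["cell_class"]].astype(str).str.strip().str.lower(),
            "x_um": pd.to_numeric(raw[d["x_um"]], errors="coerce"),
            "y_um": pd.to_numeric(raw[d["y_um"]], errors="coerce"),
        }
    )
    has_dist = d["dist_um"] in raw.columns
    if has_dist:
        out["dist_um"] = pd.to_numeric(raw[d["dist_um"]], errors="coerce")

    if out.empty:
        logger.warning("%s: header-only file, no cell records", path)
        return out

    bad_coord = out["x_um"].isna() | out["y_um"].isna()
    bad_coord |= ~np.isfinite(out["x_um"].fillna(np.inf)) | ~np.isfinite(
        out["y_um"].fillna(np.inf)
    )
    bad_class = ~out["cell_class"].isin(CELL_CLASSES)
    if has_dist:
        bad_dist = out["dist_um"].notna() & (out["dist_um"] < 0)
    else:
        bad_dist = pd.Series(False, index=out.index)
    bad = bad_coord | bad_class | bad_dist
    if bad.any():
        lines = [i + 1 for i in out.index[bad]]  # 1-based data line numbers
        msg = f"{path}: {bad.sum()} malformed row(s) at data line(s) {lines[:20]}"
        if errors == "raise":
            raise CellTableError(msg)
        logger.warning("%s (rows dropped)", msg)
        out = out[~bad]
    return out.reset_index(drop=True)


def write_cell_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write canonical cell records to CSV with 6-decimal coordinates."""
    cols = [c for c in ("subject_id", "cell_class", "x_um", "y_um", "dist_um")
            if c in records.columns]
    records[cols].to_csv(path, index=False, float_format="%.6f")


def build_subject_pattern(records: pd.DataFrame, subject_id: str) -> SubjectPattern:
    """Assemble one subject's point pattern from canonical cell records.

    Coordinates are rescaled 1:1000 from um to mm.  The observation window
    is the bounding box of all of the subject's points (both classes),
    which is reproducible from the coordinates alone; for a single point a
    degenerate box is inflated by 1 um per side so the window keeps
    positive area.
    """
    sub = records[records["subject_id"].astype(str) == str(subject_id)]
    if sub.empty:
        raise ValueError(f"no cell records for subject {subject_id!r}")
    xy_mm = sub[["x_um", "y_um"]].to_numpy(dtype=float) * MM_PER_UM
    x0, y0 = xy_mm.min(axis=0)
    x1, y1 = xy_mm.max(axis=0)
    if x1 - x0 <= 0:
        x0, x1 = x0 - 5e-4, x1 + 5e-4
    if y1 - y0 <= 0:
        y0, y1 = y0 - 5e-4, y1 + 5e-4
    is_cancer = (sub["cell_class"] == "cancer").to_numpy()
    is_cd8 = (sub["cell_class"] == "cd8").to_numpy()
    dist = None
    if "dist_um" in sub.columns:
        cd8_dist = sub.loc[sub["cell_class"] == "cd8", "dist_um"]
        if cd8_dist.notna().all() and len(cd8_dist):
            dist = cd8_dist.to_numpy(dtype=float)
    return SubjectPattern(
        subject_id=str(subject_id),
        cancer=xy_mm[is_cancer],
        cd8=xy_mm[is_cd8],
        window=Window(x0, x1, y0, y1),
        cd8_dist_um=dist,
    )


def build_all_patterns(records: pd.DataFrame) -> list[SubjectPattern]:
    """One :class:`SubjectPattern` per subject, in order of first appearance."""
    ids = records["subject_id"].astype(str).drop_duplicates()
    return [build_subject_pattern(records, sid) for sid in ids]


def apply_subject_inclusion(
    patterns: list[SubjectPattern],
    min_cancer: int = 10,
    min_cd8: int = 10,
) -> tuple[list[SubjectPattern], list[Exclusion]]:
    """Drop subjects with inadequate cell numbers.

    A subject is kept iff it has at least ``min_cancer`` cancer cells *and*
    at least ``min_cd8`` CD8+ cells (counts as seen in the supplied
    patterns — i.e. after TIL filtering when applied upstream).  Returns
    the kept patterns and one :class:`Exclusion` per dropped subject; the
    two lists partition the input.
    """
    kept: list[SubjectPattern] = []
    excluded: list[Exclusion] = []
    for p in patterns:
        reasons = []
        if p.n_cancer < min_cancer:
            reasons.append(f"cancer<{min_cancer}")
        if p.n_cd8 < min_cd8:
            reasons.append(f"cd8<{min_cd8}")
        if reasons:
            excluded.append(Exclusion(p.subject_id, ";".join(reasons)))
            logger.info("excluding subject %s: %s", p.subject_id, reasons)
        else:
            kept.append(p)
    return kept, excluded


def write_pattern_csv(patterns: list[SubjectPattern], path: str | Path) -> None:
    """Normalized per-subject output: subject_id, class, x_mm, y_mm."""
    rows = []
    for p in patterns:
        for cls, pts in (("cancer", p.cancer), ("cd8", p.cd8)):
            for x, y in pts:
                rows.append((p.subject_id, cls, x, y))
    pd.DataFrame(rows, columns=["subject_id", "class", "x_mm", "y_mm"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_exclusions_csv(excluded: list[Exclusion], path: str | Path) -> None:
    pd.DataFrame(
        [(e.subject_id, e.reason) for e in excluded],
        columns=["subject_id", "reason"],
    ).to_csv(path, index=False)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the subject-level clinical table (CSV).

    Expected columns: ``subject_id, treatment, sex, age, grade, stage,
    time, event``.  ``treatment`` must be ``NAT`` or ``naive``; ``time``
    (follow-up, days) must be positive; ``event`` is 0/1 with 1 = death
    observed.
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: clinical table missing column(s) {missing}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["treatment"] = df["treatment"].astype(str)
    bad_treat = ~df["treatment"].isin(TREATMENTS)
    if bad_treat.any():
        raise ValueError(
            f"{path}: unknown treatment values {sorted(df.loc[bad_treat, 'treatment'].unique())}"
        )
    df["age"] = pd.to_numeric(df["age"])
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = pd.to_numeric(df["event"]).astype(int)
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: follow-up time must be positive")
    if (df["age"] <= 0).any():
        raise ValueError(f"{path}: age must be positive")
    if not df["event"].isin((0, 1)).all():
        raise ValueError(f"{path}: event must be 0/1")
    return df
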