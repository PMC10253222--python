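"""The 16-landmark catalog and coordinate-table I/O.

Sixteen craniofacial bony landmarks are used, with four bilateral
(left/right mirror) pairs.  Coordinate tables hold one (x, y, z) triple
per landmark per case, in pixel units, and are stored as long-format CSV
(one row per case × landmark) so they round-trip losslessly as decimal
text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ParameterError

#: (code, abbreviation, description) in canonical order; model i of the
#: refinement phases always refers to code L(i+1).
CATALOG: tuple[tuple[str, str, str], ...] = (
    ("L01", "A", "Point A"),
    ("L02", "AntNS", "Anterior nasal spine"),
    ("L03", "LGoni", "Left gonion"),
    ("L04", "LOrbi", "Left inferior lateral orbital rim"),
    ("L05", "LPori", "Left porion"),
    ("L06", "LsupO", "Left supra orbital incisura"),
    ("L07", "Mento", "Menton"),
    ("L08", "Nasio", "Nasion"),
    ("L09", "PocEx", "External occipital protuberance"),
    ("L10", "PosNS", "Posterior nasal spine"),
    ("L11", "RGoni", "Right gonion"),
    ("L12", "ROrbi", "Right inferior lateral orbital rim"),
    ("L13", "RPori", "Right porion"),
    ("L14", "RsupO", "Right supra orbital incisura"),
    ("L15", "Sella", "Center of sella turcica"),
    ("L16", "XstaG", "Top of crista galli"),
)

CODES: tuple[str, ...] = tuple(c for c, _, _ in CATALOG)
N_LANDMARKS = len(CATALOG)

#: left/right mirror pairs (gonion, orbital rim, porion, supraorbital incisura)
BILATERAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("L03", "L11"),
    ("L04", "L12"),
    ("L05", "L13"),
    ("L06", "L14"),
)

_CODE_INDEX = {code: i for i, code in enumerate(CODES)}


def code_index(code: str) -> int:
    """Catalog position of a landmark code (L01 -> 0)."""
    try:
        return _CODE_INDEX[code]
    except KeyError:
        raise InputError(f"unknown landmark code {code!r}") from None


@dataclass
class LandmarkTable:
    """Per-case landmark coordinates: 16 named points, (x, y, z) in px."""

    case_id: str
    points: np.ndarray = field()  # (16, 3) float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.shape != (N_LANDMARKS, 3):
            raise FormatError(
                f"case {self.case_id}: expected {N_LANDMARKS}x3 points, got {pts.shape}"
            )
        if not np.isfinite(pts).all():
            raise FormatError(f"case {self.case_id}: non-finite coordinate")
        self.points = pts

    def point(self, code: str) -> np.ndarray:
        return self.points[code_index(code)]


# ----------------------------------------------------------------------
# CSV I/O (long format: case_id, code, x, y, z)


def write_table(tables: list[LandmarkTable], path) -> None:
    rows = []
    for t in tables:
        for (code, _, _), (x, y, z) in zip(CATALOG, t.points):
            rows.append((t.case_id, code, x, y, z))
    df = pd.DataFrame(rows, columns=["case_id", "code", "x", "y", "z"])
    # shortest round-trip decimal text, so read/write is lossless
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_table(path) -> list[LandmarkTable]:
    """Read a landmark CSV; landmark order follows the catalog."""
    try:
        df = pd.read_csv(
            path, dtype={"case_id": str, "code": str}, float_precision="round_trip"
        )
    except ValueError as exc:
        raise FormatError(f"unreadable landmark CSV {path}: {exc}") from exc
    required = {"case_id", "code", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"landmark CSV must have columns {sorted(required)}")
    for col in ("x", "y", "z"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"non-numeric value in column {col!r}")
    tables = []
    for case_id, grp in df.groupby("case_id", sort=False):
        if len(grp) != N_LANDMARKS:
            raise FormatError(
                f"case {case_id} has {len(grp)} landmarks, expected {N_LANDMARKS}"
            )
        codes = set(grp["code"])
        if codes != set(CODES):
            raise FormatError(f"case {case_id}: landmark codes do not match the catalog")
        grp = grp.set_index("code").loc[list(CODES)]
        tables.append(LandmarkTable(case_id=str(case_id), points=grp[["x", "y", "z"]].to_numpy()))
    return tables


# ----------------------------------------------------------------------


def split_train_test(
    tables: list, n_train: int = 90, n_test: int = 30, seed: int = 0
) -> tuple[list, list]:
    """Random, reproducible, disjoint train/test designation."""
    if n_train < 0 or n_test < 0 or n_train + n_test > len(tables):
        raise ParameterError(
            f"cannot split {len(tables)} cases into {n_train} train + {n_test} test"
        )
    order = np.random.default_rng(seed).permutation(len(tables))
    train = [tables[i] for i in sorted(order[:n_train])]
    test = [tables[i] for i in sorted(order[n_train : n_train + n_test])]
    return train, test


def interobserver_gap(a: LandmarkTable, b: LandmarkTable) -> np.ndarray:
    """Per-landmark 3D Euclidean distance between two observers' plots."""
    if a.case_id != b.case_id:
        raise InputError(f"case mismatch: {a.case_id!r} vs {b.case_id!r}")
    return np.linalg.norm(a.points - b.points, axis=1)
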