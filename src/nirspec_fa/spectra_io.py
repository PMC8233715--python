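"""Reading, writing and joining NIR spectra with reference chemistry.

Spectra are absorbance scans recorded as log(1/R) on a shared uniform
wavelength grid (default 1000-2500 nm in 0.5 nm steps, 3001 points).  The
file carrier is plain CSV: the first two columns are ``sample_id`` and
``scan_index``, the remaining column headers are wavelengths in nm, one scan
per row.  Reference chemistry is a long-format CSV with columns
``sample_id, fraction, analyte, value_mg_per_100g``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AssemblyError, GridMismatchError, SpectralParseError

logger = logging.getLogger(__name__)

#: Closed vocabulary of analytes: the 20 detected fatty acids plus the four
#: computed group sums.  Names follow the short chain:double-bond notation
#: used in meat-lipid work (``9c11tCLA`` is the c9,t11 conjugated linoleic
#: acid isomer; ``ald`` marks plasmalogen-derived aldehydes).
FATTY_ACIDS: tuple[str, ...] = (
    "12:0", "14:0", "16:0", "16:0ald", "16:1", "18:0", "18:0ald",
    "18:1t9", "18:1c9", "18:1c11", "18:2n-6", "20:1", "18:3n-3",
    "9c11tCLA", "20:3n-6", "20:4n-6", "20:5n-3", "22:4n-6", "22:5n-3",
    "22:6n-3",
)
GROUPS: tuple[str, ...] = ("TotalFA", "SFA", "MUFA", "PUFA")
ANALYTES: tuple[str, ...] = FATTY_ACIDS + GROUPS
FRACTIONS: tuple[str, ...] = ("phospholipid", "total")


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres."""

    start_nm: float = 1000.0
    step_nm: float = 0.5
    n_points: int = 3001

    def __post_init__(self) -> None:
        if self.start_nm <= 0 or self.step_nm <= 0:
            raise ValueError("grid start and step must be positive")
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def end_nm(self) -> float:
        return self.start_nm + self.step_nm * (self.n_points - 1)

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def normalized(self) -> np.ndarray:
        """Wavelengths affinely mapped to [-1, 1] (for polynomial baselines)."""
        return np.linspace(-1.0, 1.0, self.n_points)


DEFAULT_GRID = WavelengthGrid()


@dataclass
class Spectrum:
    """One log(1/R) scan aligned to a wavelength grid."""

    sample_id: str
    absorbance: np.ndarray
    scan_index: int | None = None
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (self.grid.n_points,):
            raise ValueError(
                f"spectrum length {self.absorbance.size} does not match "
                f"grid with {self.grid.n_points} points"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError(f"non-finite absorbance in sample {self.sample_id!r}")


@dataclass
class Dataset:
    """Aligned spectra matrix and single-analyte concentration vector.

    Rows of ``X`` and entries of ``y`` are in identical sample order.
    """

    grid: WavelengthGrid
    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    fraction: str
    analyte: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (len(self.sample_ids), self.grid.n_points):
            raise ValueError("X shape inconsistent with sample_ids/grid")
        if self.y.shape != (len(self.sample_ids),):
            raise ValueError("y length inconsistent with sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id in dataset")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def write_spectra(path, spectra: Sequence[Spectrum]) -> None:
    """Write scans to the CSV dialect read back by :func:`read_spectra`."""
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].grid
    cols = [f"{w:.4f}".rstrip("0").rstrip(".") for w in grid.wavelengths()]
    rows = []
    for s in spectra:
        rows.append(
            [s.sample_id, "" if s.scan_index is None else s.scan_index]
            + list(np.asarray(s.absorbance, dtype=float))
        )
    df = pd.DataFrame(rows, columns=["sample_id", "scan_index"] + cols)
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra(path, grid: WavelengthGrid | None = None) -> list[Spectrum]:
    """Read scans from CSV, validating the wavelength header against *grid*.

    Raises
    ------
    GridMismatchError
        If the header wavelengths differ from the grid by more than 1e-9 nm,
        naming the first offending wavelength.
    SpectralParseError
        If any absorbance cell is non-numeric (reported with row and column).
    """
    grid = grid or DEFAULT_GRID
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "scan_index"]:
        raise SpectralParseError(
            "expected columns sample_id, scan_index, then wavelengths"
        )
    try:
        header = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise SpectralParseError(f"non-numeric wavelength header: {exc}") from exc
    expected = grid.wavelengths()
    if header.size != expected.size:
        raise GridMismatchError(
            f"file has {header.size} wavelength columns, grid expects {expected.size}"
        )
    bad = np.nonzero(np.abs(header - expected) > 1e-9)[0]
    if bad.size:
        i = int(bad[0])
        raise GridMismatchError(
            f"wavelength column {i} is {header[i]} nm, expected {expected[i]} nm"
        )

    spectra: list[Spectrum] = []
    for r, row in enumerate(df.itertuples(index=False)):
        vals = row[2:]
        try:
            absorbance = np.array([float(v) for v in vals])
        except (TypeError, ValueError):
            for c, v in enumerate(vals):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise SpectralParseError(
                        f"non-numeric absorbance at row {r}, wavelength "
                        f"{expected[c]} nm: {v!r}"
                    ) from None
            raise
        scan = row[1]
        scan_index = None if scan in ("", None) or pd.isna(scan) else int(float(scan))
        spectra.append(
            Spectrum(sample_id=str(row[0]), scan_index=scan_index,
                     absorbance=absorbance, grid=grid)
        )
    return spectra


def average_replicates(scans: Iterable[Spectrum]) -> list[Spectrum]:
    """Arithmetic mean of replicate scans per sample_id.

    Output order follows first appearance of each sample; ``scan_index`` is
    cleared.  Idempotent on already-averaged data.
    """
    by_id: dict[str, list[Spectrum]] = {}
    order: list[str] = []
    for s in scans:
        if s.sample_id not in by_id:
            by_id[s.sample_id] = []
            order.append(s.sample_id)
        by_id[s.sample_id].append(s)
    out = []
    for sid in order:
        group = by_id[sid]
        mean = np.mean([g.absorbance for g in group], axis=0)
        out.append(Spectrum(sample_id=sid, absorbance=mean,
                            scan_index=None, grid=group[0].grid))
    return out


def write_reference(path, table: pd.DataFrame) -> None:
    """Write a long-format chemistry table (sample_id, fraction, analyte, value)."""
    cols = ["sample_id", "fraction", "analyte", "value_mg_per_100g"]
    table.loc[:, cols].to_csv(path, index=False, float_format="%.17g")


def read_reference(path) -> pd.DataFrame:
    """Read a reference-chemistry CSV, validating names and non-negativity."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "fraction", "analyte", "value_mg_per_100g"}
    missing = required - set(df.columns)
    if missing:
        raise SpectralParseError(f"chemistry table missing columns: {sorted(missing)}")
    bad_frac = set(df["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise SpectralParseError(f"unknown fraction labels: {sorted(bad_frac)}")
    bad_an = set(df["analyte"]) - set(ANALYTES)
    if bad_an:
        raise SpectralParseError(f"unknown analyte names: {sorted(bad_an)}")
    if (df["value_mg_per_100g"] < 0).any():
        raise SpectralParseError("negative concentration in chemistry table")
    return df


def assemble_dataset(
    spectra: Sequence[Spectrum],
    reference: pd.DataFrame,
    fraction: str,
    analyte: str,
    grid: WavelengthGrid | None = None,
) -> Dataset:
    """Inner-join averaged spectra with one analyte/fraction column.

    Samples missing the requested analyte/fraction are dropped with a logged
    warning giving the count.  Row order is the spectra order.
    """
    grid = grid or (spectra[0].grid if spectra else DEFAULT_GRID)
    sel = reference[
        (reference["fraction"] == fraction) & (reference["analyte"] == analyte)
    ]
    values = dict(zip(sel["sample_id"].astype(str), sel["value_mg_per_100g"]))
    ids, rows, y = [], [], []
    n_dropped = 0
    for s in spectra:
        if s.sample_id in values:
            ids.append(s.sample_id)
            rows.append(s.absorbance)
            y.append(values[s.sample_id])
        else:
            n_dropped += 1
    if not ids:
        raise AssemblyError(
            f"no sample has both a spectrum and a {fraction}/{analyte} value"
        )
    if n_dropped:
        logger.warning(
            "assemble_dataset: dropped %d spectra without %s/%s chemistry",
            n_dropped, fraction, analyte,
        )
    return Dataset(grid=grid, X=np.vstack(rows), y=np.array(y, dtype=float),
                   sample_ids=ids, fraction=fraction, analyte=analyte)
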