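"""Spectral dataset containers and plain-text readers/writers.

The on-disk layout is deliberately simple and inspectable:

* spectra CSV — first column ``wavenumber_cm-1``, one column per technical
  scan, named ``<sample_id>__scan<k>``;
* metadata CSV — ``column,sample_id,genotype,dpa,replicate`` mapping each
  scan column to its sample;
* cellulose CSV — ``sample_id,cellulose_pct``.

Wavenumbers are stored ascending internally; instrument exports commonly run
4000 -> 600 cm^-1 and are flipped on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SampleRecord",
    "SpectralDataset",
    "read_spectra",
    "read_cellulose",
    "write_spectra",
    "write_cellulose",
    "write_index_table",
    "read_index_table",
    "INDEX_COLUMNS",
]

GENOTYPES = ("TM-1", "im")

#: Canonical column order of an index table (one row per sample).
INDEX_COLUMNS = [
    "sample_id",
    "genotype",
    "dpa",
    "r_value",
    "ci_ir",
    "ratio_1372_2900",
    "area_895",
    "area_664",
]


class FormatError(ValueError):
    """Malformed spectral table (ragged columns, bad header...)."""


class ParseError(ValueError):
    """Non-numeric cell where a number was expected."""


class DuplicationError(ValueError):
    """Duplicate (sample_id, scan) pair in metadata."""


class GridError(ValueError):
    """Spectra that should share a wavenumber grid do not."""


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum on a strictly monotonic wavenumber grid.

    Parameters
    ----------
    wavenumbers : array-like of float
        Grid positions in cm^-1.  May be ascending or descending on input;
        stored ascending.
    absorbance : array-like of float
        Dimensionless absorbance, same length as ``wavenumbers``.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1:
            raise FormatError("wavenumbers and absorbance must be 1-D")
        if wn.shape != ab.shape:
            raise FormatError(
                f"length mismatch: {wn.size} wavenumbers vs {ab.size} absorbances"
            )
        if wn.size == 0:
            raise FormatError("empty spectrum")
        if np.isnan(wn).any() or np.isnan(ab).any():
            raise ParseError("missing values in spectrum")
        d = np.diff(wn)
        if (d > 0).all():
            pass
        elif (d < 0).all():  # canonicalize descending instrument order
            wn, ab = wn[::-1], ab[::-1]
        elif wn.size > 1:
            raise FormatError("wavenumbers are not strictly monotonic")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def span(self) -> tuple[float, float]:
        """(min, max) wavenumber covered."""
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def isclose(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return (
            self.wavenumbers.shape == other.wavenumbers.shape
            and np.allclose(self.wavenumbers, other.wavenumbers, atol=atol)
            and np.allclose(self.absorbance, other.absorbance, atol=atol)
        )


@dataclass
class SampleRecord:
    """One fiber sample: metadata plus its technical re-sampling scans."""

    sample_id: str
    genotype: str
    dpa: int
    replicate: int
    scans: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dpa <= 0:
            raise ValueError(f"dpa must be positive, got {self.dpa}")
        if not self.scans:
            raise ValueError(f"sample {self.sample_id!r} has no scans")
        grid = self.scans[0].wavenumbers
        for s in self.scans[1:]:
            if s.wavenumbers.shape != grid.shape or not np.allclose(
                s.wavenumbers, grid
            ):
                raise GridError(
                    f"scans of sample {self.sample_id!r} are on different grids"
                )

    @property
    def grid(self) -> np.ndarray:
        return self.scans[0].wavenumbers


@dataclass
class SpectralDataset:
    """A collection of samples sharing one wavenumber grid."""

    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("dataset has no samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicationError(f"duplicate sample_ids: {dupes}")
        grid = self.samples[0].grid
        for s in self.samples[1:]:
            if s.grid.shape != grid.shape or not np.allclose(s.grid, grid):
                raise GridError(f"sample {s.sample_id!r} is not on the shared grid")

    @property
    def grid(self) -> np.ndarray:
        return self.samples[0].grid

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "genotype": [s.genotype for s in self.samples],
                "dpa": [s.dpa for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_numeric_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected wavenumber column plus >=1 scan column")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ParseError(f"{path}: non-numeric value at row {row}, column {col!r}")
        df[col] = coerced
    return df


def read_spectra(path, metadata_path) -> SpectralDataset:
    """Read a spectra CSV plus its metadata sidecar into a dataset.

    Scan columns are grouped by ``sample_id`` (in metadata order); scan
    columns missing from the metadata are rejected.
    """
    df = _read_numeric_table(path)
    meta = pd.read_csv(
        metadata_path, dtype={"column": str, "sample_id": str, "genotype": str}
    )
    required = {"column", "sample_id", "genotype", "dpa", "replicate"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"{metadata_path}: metadata must have columns {sorted(required)}"
        )
    if meta["column"].duplicated().any():
        dupes = meta.loc[meta["column"].duplicated(), "column"].tolist()
        raise DuplicationError(f"duplicate scan columns in metadata: {dupes}")

    wn_col = df.columns[0]
    scan_cols = list(df.columns[1:])
    known = set(meta["column"])
    unknown = [c for c in scan_cols if c not in known]
    if unknown:
        raise FormatError(f"{path}: scan columns absent from metadata: {unknown}")

    wn = df[wn_col].to_numpy()
    samples: list[SampleRecord] = []
    for sample_id, group in meta.groupby("sample_id", sort=False):
        genotypes = group["genotype"].unique()
        dpas = group["dpa"].unique()
        reps = group["replicate"].unique()
        if len(genotypes) > 1 or len(dpas) > 1 or len(reps) > 1:
            raise FormatError(
                f"{metadata_path}: inconsistent metadata for sample {sample_id!r}"
            )
        scans = [
            Spectrum(wn, df[c].to_numpy())
            for c in group["column"]
            if c in scan_cols
        ]
        if not scans:
            continue  # metadata rows with no matching column are ignored
        samples.append(
            SampleRecord(
                sample_id=str(sample_id),
                genotype=str(genotypes[0]),
                dpa=int(dpas[0]),
                replicate=int(reps[0]),
                scans=scans,
            )
        )
    return SpectralDataset(samples)


def write_spectra(dataset: SpectralDataset, path, metadata_path) -> None:
    """Write a dataset to the spectra CSV + metadata CSV pair."""
    cols: dict[str, np.ndarray] = {"wavenumber_cm-1": dataset.grid}
    meta_rows = []
    for s in dataset:
        for k, scan in enumerate(s.scans, start=1):
            name = f"{s.sample_id}__scan{k}"
            cols[name] = scan.absorbance
            meta_rows.append(
                {
                    "column": name,
                    "sample_id": s.sample_id,
                    "genotype": s.genotype,
                    "dpa": s.dpa,
                    "replicate": s.replicate,
                }
            )
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    pd.DataFrame(meta_rows).to_csv(metadata_path, index=False)


def read_cellulose(path) -> pd.Series:
    """Read a ``sample_id,cellulose_pct`` CSV into a Series keyed by sample."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if not {"sample_id", "cellulose_pct"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns sample_id,cellulose_pct")
    vals = pd.to_numeric(df["cellulose_pct"], errors="coerce")
    if vals.isna().any():
        raise ParseError(f"{path}: non-numeric cellulose_pct")
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError(f"{path}: cellulose_pct outside [0, 100]")
    return pd.Series(vals.to_numpy(), index=df["sample_id"], name="cellulose_pct")


def write_cellulose(cellulose: pd.Series, path) -> None:
    df = pd.DataFrame(
        {"sample_id": cellulose.index, "cellulose_pct": cellulose.to_numpy()}
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_index_table(table: pd.DataFrame, path) -> None:
    """Write a per-sample index table at full float precision.

    Raises ``ValueError`` on an empty table; no file is created in that case.
    """
    if table.empty:
        raise ValueError("refusing to write an empty index table")
    missing = [c for c in INDEX_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"index table missing columns: {missing}")
    table[INDEX_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_index_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "genotype": str})
    missing = [c for c in INDEX_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: index table missing columns: {missing}")
    return df
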