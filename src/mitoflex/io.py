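"""Delimited-text readers/writers and table validation.

All tabular I/O is tab-separated plain text with a single header row;
comment lines starting with '#' may carry unit declarations and are
ignored on read.  The sample sheet is the single source of group labels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .ogtt import OGTTSeries
from .omics import OmicsTable

PathLike = Union[str, Path]


def _check_exists(path: PathLike) -> Path:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    return path


def read_table(
    path: PathLike,
    required_columns: Sequence[str] = (),
    index_column: Optional[str] = None,
    numeric_columns: Union[Sequence[str], bool] = (),
    unique_index: bool = True,
) -> pd.DataFrame:
    """Read a TSV with schema checks (column presence, numeric cells,
    duplicate identifiers); errors carry row/column coordinates."""
    path = _check_exists(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if df.columns.size == 0 or all(str(c).startswith("Unnamed") for c in df.columns):
        raise ConfigurationError(f"{path}: missing header row")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing column(s) {missing}")
    if index_column is not None:
        df = df.set_index(index_column)
        if unique_index and df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ConfigurationError(f"{path}: duplicate identifier(s) {dupes}")
    cols = list(df.columns) if numeric_columns is True else list(numeric_columns)
    for col in cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()].tolist()[:3]
            raise ConfigurationError(
                f"{path}: non-numeric value(s) in column {col!r} at row(s) {bad}"
            ) from exc
    return df


def write_table(
    df: pd.DataFrame,
    path: PathLike,
    index: bool = True,
    units: Optional[Mapping[str, str]] = None,
) -> None:
    """Write a TSV, optionally preceded by '# column: unit' comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if units:
            for col, unit in units.items():
                fh.write(f"# {col}: {unit}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    """Sample sheet: columns sample, age, diet."""
    df = read_table(path, required_columns=("sample", "age", "diet"),
                    index_column="sample")
    bad_age = set(df["age"]) - {"young", "old"}
    bad_diet = set(df["diet"]) - {"LFD", "HFD"}
    if bad_age or bad_diet:
        raise ConfigurationError(
            f"{path}: unknown labels age={sorted(bad_age)} diet={sorted(bad_diet)}"
        )
    return df


def read_matrix(path: PathLike, index_name: str = "analyte") -> pd.DataFrame:
    """Analyte x sample matrix: first column is the identifier."""
    df = pd.read_csv(_check_exists(path), sep="\t", comment="#")
    if df.columns.size < 2:
        raise ConfigurationError(f"{path}: expected identifier plus sample columns")
    df = df.set_index(df.columns[0])
    df.index.name = index_name
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ConfigurationError(f"{path}: duplicate identifier(s) {dupes}")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(f"{path}: non-numeric cell: {exc}") from exc
    return df


def write_matrix(df: pd.DataFrame, path: PathLike,
                 units: Optional[Mapping[str, str]] = None) -> None:
    write_table(df, path, index=True, units=units)


def read_omics(
    matrix_path: PathLike,
    samples_path: PathLike,
    classes_path: Optional[PathLike] = None,
) -> OmicsTable:
    values = read_matrix(matrix_path)
    samples = read_sample_sheet(samples_path)
    classes = None
    if classes_path is not None:
        cls = read_table(classes_path, required_columns=("analyte", "class"),
                         index_column="analyte")
        classes = cls["class"]
    return OmicsTable(values=values, samples=samples, classes=classes)


def read_standards(path: PathLike) -> dict:
    """Per-class internal-standard intensities: columns class, intensity."""
    df = read_table(path, required_columns=("class", "intensity"),
                    index_column="class", numeric_columns=("intensity",))
    return df["intensity"].to_dict()


def write_standards(standards: Mapping[str, float], path: PathLike) -> None:
    df = pd.DataFrame(
        {"class": list(standards), "intensity": list(standards.values())}
    )
    write_table(df, path, index=False)


# -- OGTT long format -------------------------------------------------------

OGTT_COLUMNS = ("animal", "time_min", "analyte", "value", "unit")


def write_ogtt(series: Iterable[OGTTSeries], path: PathLike) -> None:
    rows = []
    for s in series:
        for t, v in zip(s.glucose_times, s.glucose):
            rows.append({"animal": s.animal, "time_min": t, "analyte": "glucose",
                         "value": v, "unit": "mM"})
        for t, v in zip(s.insulin_times, s.insulin):
            rows.append({"animal": s.animal, "time_min": t, "analyte": "insulin",
                         "value": v, "unit": s.insulin_unit})
    write_table(pd.DataFrame(rows, columns=list(OGTT_COLUMNS)), path, index=False)


def read_ogtt(path: PathLike) -> list[OGTTSeries]:
    df = read_table(path, required_columns=OGTT_COLUMNS,
                    numeric_columns=("time_min", "value"))
    bad = set(df["analyte"]) - {"glucose", "insulin"}
    if bad:
        raise ConfigurationError(f"{path}: unknown analyte(s) {sorted(bad)}")
    series = []
    for animal, group in df.groupby("animal", sort=True):
        glu = group[group["analyte"] == "glucose"].sort_values("time_min")
        ins = group[group["analyte"] == "insulin"].sort_values("time_min")
        units = set(ins["unit"])
        if len(units) > 1:
            raise ConfigurationError(f"{path}: mixed insulin units for {animal}")
        series.append(
            OGTTSeries(
                animal=str(animal),
                glucose_times=glu["time_min"].to_numpy(),
                glucose=glu["value"].to_numpy(),
                insulin_times=ins["time_min"].to_numpy(),
                insulin=ins["value"].to_numpy(),
                insulin_unit=units.pop() if units else "ng/mL",
            )
        )
    return series
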