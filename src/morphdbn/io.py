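"""Reading and writing region-wise morphometry data.

Two text dialects are supported: the FreeSurfer per-subject statistics
files (``stats/aseg.stats`` for structure volumes and per-hemisphere
``?h.aparc.stats`` for Desikan-Killiany mean thickness), and a flat
comma-delimited subject x feature table used as the interchange format
between all pipeline stages.

FreeSurfer stats files carry no inline column header on data rows, so
the parsers are column-position based, matching FreeSurfer's own
convention: ``aseg.stats`` data rows have Volume_mm3 in column 4 and
StructName in column 5 (1-based); ``aparc.stats`` rows have StructName
in column 1 and ThickAvg in column 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, LABELS, FeatureSchema


class ParseError(ValueError):
    """A stats stream violated the expected FreeSurfer dialect."""


class AssemblyError(ValueError):
    """A subject record could not be completed against the schema."""


# aseg.stats: 1-based column positions of Volume_mm3 and StructName
_ASEG_VOLUME_COL = 3
_ASEG_NAME_COL = 4
# aparc.stats: StructName first, ThickAvg fifth
_APARC_NAME_COL = 0
_APARC_THICK_COL = 4


@dataclass
class MorphometryTable:
    """Subjects x 113 morphometric features plus covariates and labels.

    ``features`` rows follow ``subject_ids``; columns follow
    ``schema.canonical_order``.  ``sex`` is coded 0 = female, 1 = male.
    ``provenance`` records the processing state of the feature values
    (``raw``, ``residualized``, ``zscored`` or ``synthetic``).
    """

    subject_ids: list[str]
    labels: list[str]
    age: np.ndarray
    sex: np.ndarray
    features: np.ndarray
    provenance: str = "raw"
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        self.features = np.asarray(self.features, dtype=float)
        n = len(self.subject_ids)
        if not (len(self.labels) == self.age.shape[0] == self.sex.shape[0] == n):
            raise ValueError("subject_ids, labels, age and sex must have equal length")
        if self.features.shape != (n, self.schema.n_features):
            raise ValueError(
                f"features must be {n} x {self.schema.n_features}, "
                f"got {self.features.shape}"
            )
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def with_features(self, features: np.ndarray, provenance: str) -> "MorphometryTable":
        """Copy of the table with replaced feature values and provenance."""
        return replace(self, features=np.asarray(features, dtype=float),
                       provenance=provenance)

    def subset(self, rows: np.ndarray | list[int]) -> "MorphometryTable":
        rows = np.asarray(rows)
        return MorphometryTable(
            subject_ids=[self.subject_ids[i] for i in rows],
            labels=[self.labels[i] for i in rows],
            age=self.age[rows],
            sex=self.sex[rows],
            features=self.features[rows],
            provenance=self.provenance,
            schema=self.schema,
        )

    def binary_labels(self, positive: str = "SCZ", negative: str = "HC") -> np.ndarray:
        """0/1 vector over subjects; raises if any other label is present."""
        out = np.empty(self.n_subjects, dtype=int)
        for i, lab in enumerate(self.labels):
            if lab == positive:
                out[i] = 1
            elif lab == negative:
                out[i] = 0
            else:
                raise ValueError(
                    f"subject {self.subject_ids[i]} has label {lab!r}; "
                    f"expected {negative!r} or {positive!r}"
                )
        return out

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.schema.canonical_order))
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        df.insert(2, "age", self.age)
        df.insert(3, "sex", self.sex)
        return df


def _data_lines(stream: Iterable[str]) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line) for non-comment rows."""
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def parse_aseg_stats(stream: Iterable[str]) -> dict[str, float]:
    """Parse an ``aseg.stats`` stream into {structure name: volume_mm3}.

    Header lines start with ``#`` and may appear anywhere.  Structure
    names are returned verbatim, in file order.
    """
    out: dict[str, float] = {}
    for lineno, line in _data_lines(stream):
        cols = line.split()
        if len(cols) <= _ASEG_NAME_COL:
            raise ParseError(
                f"line {lineno}: expected >= {_ASEG_NAME_COL + 1} columns, "
                f"got {len(cols)}"
            )
        name = cols[_ASEG_NAME_COL]
        try:
            volume = float(cols[_ASEG_VOLUME_COL])
        except ValueError:
            raise ParseError(
                f"line {lineno}: non-numeric volume {cols[_ASEG_VOLUME_COL]!r}"
            ) from None
        if name in out:
            raise ParseError(f"line {lineno}: duplicate structure {name!r}")
        out[name] = volume
    return out


def parse_aparc_stats(stream: Iterable[str], hemisphere: str) -> dict[str, float]:
    """Parse an ``aparc.stats`` stream into {``<hemi>_<region>``: ThickAvg}.

    ``hemisphere`` must be ``"lh"`` or ``"rh"``; the returned keys carry
    the hemisphere prefix so that both hemispheres can be merged.
    """
    if hemisphere not in ("lh", "rh"):
        raise ValueError(f"hemisphere must be 'lh' or 'rh', got {hemisphere!r}")
    out: dict[str, float] = {}
    for lineno, line in _data_lines(stream):
        cols = line.split()
        if len(cols) <= _APARC_THICK_COL:
            raise ParseError(
                f"line {lineno}: expected >= {_APARC_THICK_COL + 1} columns, "
                f"got {len(cols)}"
            )
        key = f"{hemisphere}_{cols[_APARC_NAME_COL]}"
        try:
            thick = float(cols[_APARC_THICK_COL])
        except ValueError:
            raise ParseError(
                f"line {lineno}: non-numeric ThickAvg {cols[_APARC_THICK_COL]!r}"
            ) from None
        if key in out:
            raise ParseError(f"line {lineno}: duplicate region {key!r}")
        out[key] = thick
    return out


def assemble_table(
    records: Mapping[str, Mapping[str, float]],
    covariates: Mapping[str, tuple[float, int]],
    labels: Mapping[str, str],
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> MorphometryTable:
    """Assemble per-subject parsed feature mappings into a table.

    ``records`` maps subject id -> {feature name: value}; ``covariates``
    maps subject id -> (age, sex).  Every subject must supply a value
    for every schema feature; otherwise an :class:`AssemblyError` names
    the subject and the missing features.
    """
    subject_ids = sorted(records)
    n = len(subject_ids)
    features = np.empty((n, schema.n_features))
    for i, sid in enumerate(subject_ids):
        rec = records[sid]
        missing = [name for name in schema.canonical_order if name not in rec]
        if missing:
            raise AssemblyError(
                f"subject {sid!r} is missing features: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        features[i] = [rec[name] for name in schema.canonical_order]
    try:
        age = np.array([covariates[s][0] for s in subject_ids], dtype=float)
        sex = np.array([covariates[s][1] for s in subject_ids], dtype=int)
        labs = [labels[s] for s in subject_ids]
    except KeyError as exc:
        raise AssemblyError(f"missing covariates or label for subject {exc}") from None
    return MorphometryTable(subject_ids, labs, age, sex, features,
                            provenance="raw", schema=schema)


_META_COLUMNS = ("subject_id", "label", "age", "sex")


def write_table(table: MorphometryTable, path: str | Path | IO[str]) -> None:
    """Write the table as comma-delimited UTF-8 text.

    The provenance string is stored in a ``# provenance:`` comment on
    the first line, followed by a header row of the canonical columns.
    Numeric values are written with 17 significant digits so that a
    write/read cycle is the identity well past 12 significant digits.
    """
    df = table.to_dataframe()
    if hasattr(path, "write"):
        handle = path
        handle.write(f"# provenance: {table.provenance}\n")
        df.to_csv(handle, index=False, float_format="%.17g")
    else:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(f"# provenance: {table.provenance}\n")
            df.to_csv(handle, index=False, float_format="%.17g")


def read_table(path: str | Path | IO[str],
               schema: FeatureSchema = DEFAULT_SCHEMA) -> MorphometryTable:
    """Read a table written by :func:`write_table`."""
    provenance = "raw"
    if hasattr(path, "read"):
        first = path.readline()
        if first.startswith("# provenance:"):
            provenance = first.split(":", 1)[1].strip()
            df = pd.read_csv(path)
        else:
            import io as _io
            df = pd.read_csv(_io.StringIO(first + path.read()))
    else:
        with open(path, "r", encoding="utf-8") as handle:
            first = handle.readline()
            if first.startswith("# provenance:"):
                provenance = first.split(":", 1)[1].strip()
                df = pd.read_csv(handle)
            else:
                handle.seek(0)
                df = pd.read_csv(handle)
    expected = list(_META_COLUMNS) + list(schema.canonical_order)
    if list(df.columns) != expected:
        raise ValueError(
            "table header does not match the canonical schema; "
            f"first differing column: "
            f"{next((a for a, b in zip(df.columns, expected) if a != b), 'column count')}"
        )
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown diagnosis labels in table: {sorted(bad)}")
    return MorphometryTable(
        subject_ids=[str(s) for s in df["subject_id"]],
        labels=list(df["label"]),
        age=df["age"].to_numpy(dtype=float),
        sex=df["sex"].to_numpy(dtype=int),
        features=df[list(schema.canonical_order)].to_numpy(dtype=float),
        provenance=provenance,
        schema=schema,
    )


def write_aseg_stats(volumes: Mapping[str, float], path: str | Path | IO[str]) -> None:
    """Emit a minimal valid ``aseg.stats`` stream (fixture writer).

    Produces the dialect :func:`parse_aseg_stats` consumes: '#' headers
    and whitespace-delimited rows with Volume_mm3 in column 4 and
    StructName in column 5.
    """
    lines = ["# Title Segmentation Statistics", "# ColHeaders Index SegId "
             "NVoxels Volume_mm3 StructName normMean normStdDev"]
    for i, (name, vol) in enumerate(volumes.items(), start=1):
        lines.append(f" {i:3d} {10 + i:4d} {int(vol):7d} {vol:10.1f}  "
                     f"{name:30s} {0.0:8.4f} {0.0:8.4f}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


def write_aparc_stats(thickness: Mapping[str, float],
                      path: str | Path | IO[str]) -> None:
    """Emit a minimal valid ``aparc.stats`` stream (fixture writer).

    Keys must be bare region names (no hemisphere prefix); the row
    layout puts StructName in column 1 and ThickAvg in column 5.
    """
    lines = ["# Table of FreeSurfer cortical parcellation anatomical statistics",
             "# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg "
             "ThickStd MeanCurv GausCurv FoldInd CurvInd"]
    for name, thick in thickness.items():
        lines.append(f"{name:30s} {1000:6d} {700:6d} {2500:6d} {thick:6.3f} "
                     f"{0.5:6.3f} {0.1:6.3f} {0.02:6.3f} {10:4d} {1.0:5.1f}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")
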