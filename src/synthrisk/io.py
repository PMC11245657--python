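"""File formats: coefficient tables, fixtures, configs, atomic writes.

A fitted sex-specific model is serialised as a comma-separated coefficient
table with columns (predictor, coefficient, odds_ratio, p_value), a final
``Constant`` row, and a small ``# key: value`` metadata header (sex,
training period, control sampling fraction) — the shape of a published
risk-model table.  Display columns (odds ratio, p value) are rounded for
presentation; the coefficient column carries full precision.

The package ships two reference coefficient tables,
``male_model_2002_2010`` (20 predictors) and ``female_model_2002_2010``
(22 predictors), plus the training-data characteristics table.

All writes are atomic (write to a temp file, then rename), so a partial
output never parses as a valid table.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import math
import os
import tempfile
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .model import ModelSpec

_HEADER_MAGIC = "# synthrisk coefficient table v1"
_COLUMNS = ["predictor", "coefficient", "odds_ratio", "p_value"]
# typographic minus signs normalised to ASCII on ingest
_MINUS = {"–": "-", "−": "-", "—": "-"}


def atomic_write_text(text: str, path) -> None:
    """Write-then-rename so readers never observe a partial file."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_csv(df: pd.DataFrame, path) -> None:
    atomic_write_text(df.to_csv(index=False), path)


def coefficient_to_or(coefficient: float) -> float:
    """Odds ratio exp(coefficient), display-rounded to 2 decimals."""
    c = float(coefficient)
    if not math.isfinite(c):
        raise ValueError("coefficient must be finite")
    return round(math.exp(c), 2)


class SchemaError(ValueError):
    """Malformed coefficient-table file."""


def _normalise(s: str) -> str:
    for bad, good in _MINUS.items():
        s = s.replace(bad, good)
    return s


def read_model(path) -> ModelSpec:
    """Parse a coefficient table into a :class:`ModelSpec`.

    The verbatim body rows are retained so that ``write_model`` of an
    unmodified spec is byte-identical; typographic minus signs are
    normalised to ASCII on ingest.
    """
    with open(path, encoding="utf-8") as fh:
        raw = _normalise(fh.read())
    meta: dict[str, str] = {}
    body: list[tuple[int, str]] = []  # (file line number, line)
    for fileno, line in enumerate(raw.splitlines(), start=1):
        if line.startswith("#"):
            stripped = line.lstrip("# ").strip()
            if ":" in stripped:
                k, v = stripped.split(":", 1)
                meta[k.strip()] = v.strip()
        elif line.strip():
            body.append((fileno, line))
    if not body:
        raise SchemaError(f"{path}: empty coefficient table")
    linenos = [n for n, _ in body]
    rows = list(csv.reader(_io.StringIO("\n".join(l for _, l in body))))
    header, rows = rows[0], rows[1:]
    if header != _COLUMNS:
        raise SchemaError(f"{path}: expected columns {_COLUMNS}, got {header}")
    coefficients: dict[str, float] = {}
    p_values: dict[str, float] = {}
    display_rows: list[tuple[str, str, str, str]] = []
    intercept = None
    for lineno, row in zip(linenos[1:], rows):
        if len(row) != 4:
            raise SchemaError(f"{path} line {lineno}: expected 4 fields, got {len(row)}")
        name, coef_s, or_s, p_s = row
        try:
            coef = float(coef_s)
        except ValueError as exc:
            raise SchemaError(
                f"{path} line {lineno}: non-numeric coefficient {coef_s!r}"
            ) from exc
        if name == "Constant":
            if intercept is not None:
                raise SchemaError(f"{path} line {lineno}: duplicate Constant row")
            intercept = coef
        else:
            if name in coefficients:
                raise SchemaError(f"{path} line {lineno}: duplicate predictor {name!r}")
            coefficients[name] = coef
            if or_s:
                stated = float(or_s)
                if abs(coefficient_to_or(coef) - stated) > 0.005 + 1e-12:
                    raise SchemaError(
                        f"{path} line {lineno}: odds ratio {stated} inconsistent "
                        f"with exp({coef})"
                    )
            if p_s and not p_s.startswith("<"):
                try:
                    p_values[name] = float(p_s)
                except ValueError:
                    pass
        display_rows.append((name, coef_s, or_s, p_s))
    if intercept is None:
        raise SchemaError(f"{path}: missing Constant row")
    period = None
    if "training_period" in meta and "-" in meta["training_period"]:
        a, b = meta["training_period"].split("-", 1)
        period = (int(a), int(b))
    return ModelSpec(
        sex=meta.get("sex", "unspecified"),
        intercept=intercept,
        coefficients=coefficients,
        control_sampling_fraction=float(meta.get("control_sampling_fraction", 1.0)),
        training_period=period,
        p_values=p_values,
        metadata={k: v for k, v in meta.items() if k not in
                  ("sex", "training_period", "control_sampling_fraction")},
        display_rows=display_rows,
    )


def _format_p(p: float | None) -> str:
    if p is None:
        return ""
    if p < 0.001:
        return "<.001"
    s = f"{p:.2f}"
    return s[1:] if s.startswith("0.") else s


def write_model(spec: ModelSpec, path) -> None:
    """Serialise a :class:`ModelSpec` as a coefficient table (atomic)."""
    buf = _io.StringIO()
    buf.write(_HEADER_MAGIC + "\n")
    buf.write(f"# sex: {spec.sex}\n")
    period = (
        f"{spec.training_period[0]}-{spec.training_period[1]}"
        if spec.training_period
        else "unknown"
    )
    buf.write(f"# training_period: {period}\n")
    buf.write(f"# control_sampling_fraction: {spec.control_sampling_fraction:g}\n")
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_COLUMNS)
    if spec.display_rows is not None:
        for row in spec.display_rows:
            w.writerow(row)
    else:
        for name, coef in spec.coefficients.items():
            w.writerow(
                [name, repr(coef), f"{coefficient_to_or(coef):.2f}",
                 _format_p(spec.p_values.get(name))]
            )
        w.writerow(["Constant", repr(spec.intercept), "", ""])
    atomic_write_text(buf.getvalue(), path)


# ---------------------------------------------------------------------------
# packaged fixtures


def _dataset_path(name: str):
    return resources.files("synthrisk.datasets").joinpath(name)


def load_fixture_model(sex: str) -> ModelSpec:
    """The packaged reference coefficient table for one sex (2002-2010)."""
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    with resources.as_file(_dataset_path(f"{sex}_model_2002_2010.csv")) as p:
        return read_model(p)


def load_training_characteristics() -> pd.DataFrame:
    """Counts and percentages of the reference training data by subgroup."""
    with resources.as_file(
        _dataset_path("training_characteristics_2002_2010.csv")
    ) as p:
        return pd.read_csv(p)


# ---------------------------------------------------------------------------
# run configuration


_RUNCONFIG_KEYS = {
    "seed", "simulation", "paths", "split_year", "control_fraction",
    "metric_unit", "top_k", "stages",
}


@dataclass
class RunConfig:
    """Declarative pipeline configuration (YAML key-value file)."""

    seed: int
    simulation: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    split_year: int = 2011
    control_fraction: float = 0.01
    metric_unit: str = "per_1000"
    top_k: int = 5
    stages: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ValueError("config must set a seed (stochastic stages require it)")
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
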