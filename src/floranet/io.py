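"""Plain-text file formats: tidy time-course TSV, parameter sidecars,
comparison-report tables, and the YAML run configuration.

The tidy time-course dialect has exactly the columns
``time  gene  value  replicate  genotype`` (tab-separated, one measurement
per row).  All outputs are diff-able text; no binary formats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .models import Formalism, ParameterVector
from .simulate import TimeCourse
from .selection import ComparisonReport
from .synthetic import SyntheticConfig

TIDY_COLUMNS = ("time", "gene", "value", "replicate", "genotype")

_FLOAT_FORMAT = "%.10g"


def write_timecourses(path, timecourses: Sequence[TimeCourse]) -> None:
    """Write a panel to the tidy TSV dialect (deterministic formatting)."""
    frames = [tc.to_frame() for tc in timecourses]
    df = pd.concat(frames, ignore_index=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_timecourses(path) -> list[TimeCourse]:
    """Parse a tidy TSV into one TimeCourse per (genotype, replicate).

    Malformed rows are reported with 1-based file line numbers (header =
    line 1); negative values are rejected; unsorted times are sorted with a
    warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("time", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] + 2
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col!r} at line(s) {list(bad[:10])}"
            )
        df[col] = coerced
    if df[["time", "gene", "value"]].isna().any().any():
        bad = df.index[df[["time", "gene", "value"]].isna().any(axis=1)] + 2
        raise ValueError(f"{path}: missing fields at line(s) {list(bad[:10])}")
    neg = df.index[df["value"] < 0] + 2
    if len(neg):
        raise ValueError(f"{path}: negative value(s) at line(s) {list(neg[:10])}")

    out: list[TimeCourse] = []
    for (genotype, rep), grp in df.groupby(["genotype", "replicate"], sort=True):
        wide = grp.pivot_table(index="time", columns="gene", values="value", sort=True)
        if wide.isna().any().any():
            raise ValueError(
                f"{path}: incomplete time x gene grid for genotype={genotype!r}, "
                f"replicate={rep}"
            )
        if any(
            np.any(np.diff(gg["time"].to_numpy()) < 0)
            for _, gg in grp.groupby("gene", sort=False)
        ):
            warnings.warn(f"{path}: times were not sorted; returning them sorted")
        genes = [g for g in grp["gene"].unique() if g in wide.columns]
        wide = wide[genes]  # preserve file ordering of genes
        out.append(
            TimeCourse(
                wide.index.to_numpy(dtype=float),
                tuple(wide.columns),
                wide.to_numpy(dtype=float),
                str(genotype),
                meta={"replicate": int(rep), "source": str(path)},
            )
        )
    return out


# -- parameter sidecar ------------------------------------------------------

def write_parameters(path, params: ParameterVector, **extra) -> None:
    """JSON sidecar: formalism, names, values, bounds (+ free-form extras)."""
    doc = {
        "formalism": params.formalism.value,
        "names": list(params.names),
        "values": [float(v) for v in params.values],
        "lower": [float(v) for v in params.lower],
        "upper": [float(v) for v in params.upper],
    }
    doc.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_parameters(path) -> ParameterVector:
    doc = json.loads(Path(path).read_text())
    return ParameterVector(
        tuple(doc["names"]),
        np.asarray(doc["values"], float),
        np.asarray(doc["lower"], float),
        np.asarray(doc["upper"], float),
        Formalism.coerce(doc["formalism"]),
    )


# -- comparison report ------------------------------------------------------

def report_frame(report: ComparisonReport) -> pd.DataFrame:
    rows = [
        {
            "formalism": r.formalism,
            "dataset": r.dataset,
            "objective": r.objective,
            "rss": r.rss,
            "mre_mean": r.mre.mean,
            "mre_sd": r.mre.sd,
            "mre_overall": r.mre.overall,
            "k": r.k,
            "n_points": r.n_points,
            "aic": r.aic,
        }
        for r in report.rows
    ]
    return pd.DataFrame(rows)


def write_report(path_tsv, report: ComparisonReport, path_txt=None) -> None:
    """Machine TSV plus an optional aligned human-readable table."""
    df = report_frame(report)
    Path(path_tsv).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path_tsv, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    if path_txt is not None:
        Path(path_txt).write_text(format_report(report))


def format_report(report: ComparisonReport) -> str:
    df = report_frame(report)
    lines = [df.to_string(index=False, float_format=lambda v: f"{v:.4f}")]
    for crit, order in report.ranking.items():
        lines.append(f"ranking by {crit} (best first): " + " < ".join(order))
    return "\n".join(lines) + "\n"


# -- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Whole-pipeline configuration; round-trips through YAML unchanged."""

    formalisms: list[str] = field(
        default_factory=lambda: [f.value for f in Formalism]
    )
    genotypes: list[str] = field(default_factory=lambda: ["col", "ler", "co", "ft"])
    optimizer: str = "pso"
    optimizer_settings: dict = field(default_factory=dict)
    seed: int = 0
    bounds_overrides: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    outdir: str = "results"
    verbosity: int = 1

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def synthetic_config(self, formalism: str | Formalism) -> SyntheticConfig:
        kwargs = dict(self.synthetic)
        kwargs.setdefault("seed", self.seed)
        return SyntheticConfig(formalism=formalism, **kwargs)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]
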