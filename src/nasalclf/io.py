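"""Delimited-file I/O, model persistence and run configuration.

Matrices travel as TSV (rows = genes/probes, columns = samples, first
column = identifier), phenotypes as CSV with a header, probe maps as
two-column TSV, gene sets as one id per line, models as a versioned JSON
envelope.  A RunConfig (YAML) captures every path and pipeline parameter
plus the master seed, and is copied into each output directory so a run
can be reproduced from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .classify import FittedModel
from .containers import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    CountMatrix,
    ExpressionMatrix,
    PhenotypeTable,
)
from .selection import FULL_SCALE, PipelineConfig

#: accepted spellings for the two class labels
LABEL_SYNONYMS = {
    "asthma": POSITIVE_LABEL,
    "case": POSITIVE_LABEL,
    "1": POSITIVE_LABEL,
    "no asthma": NEGATIVE_LABEL,
    "no_asthma": NEGATIVE_LABEL,
    "control": NEGATIVE_LABEL,
    "0": NEGATIVE_LABEL,
}


def _read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = int(np.flatnonzero(df.index == dup)[-1]) + 2  # + header line
        raise ValueError(f"duplicate identifier {dup!r} (line {line}) in {path}")
    non_numeric = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(non_numeric):
        raise ValueError(f"non-numeric cells in columns {list(non_numeric)[:5]} of {path}")
    return df


def read_count_matrix(path: str) -> CountMatrix:
    df = _read_matrix(path)
    vals = df.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        bad = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise ValueError(
            f"non-integer count at gene {df.index[bad[0]]!r} "
            f"(line {bad[0] + 2}), sample {df.columns[bad[1]]!r} in {path}"
        )
    return CountMatrix(df.astype(np.int64))


def write_count_matrix(cm: CountMatrix, path: str) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression_matrix(path: str, role: str = "development") -> ExpressionMatrix:
    return ExpressionMatrix(_read_matrix(path), role=role)


def write_expression_matrix(em: ExpressionMatrix, path: str) -> None:
    em.values.rename_axis("gene_id").to_csv(path, sep="\t")


def read_phenotype(path: str) -> PhenotypeTable:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path} needs 'sample_id' and 'label' columns")
    df = df.set_index("sample_id")
    mapped = df["label"].astype(str).str.strip().str.lower().map(LABEL_SYNONYMS)
    bad = df["label"][mapped.isna()]
    if len(bad):
        raise ValueError(
            f"unrecognized labels {sorted(set(bad))[:5]} in {path}; "
            f"accepted: {sorted(LABEL_SYNONYMS)}"
        )
    df["label"] = mapped
    return PhenotypeTable(df)


def write_phenotype(pheno: PhenotypeTable, path: str) -> None:
    pheno.table.rename_axis("sample_id").to_csv(path)


def read_probe_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path} needs 'probe_id' and 'gene_id' columns")
    return df[["probe_id", "gene_id"]]


def write_probe_map(pm: pd.DataFrame, path: str) -> None:
    pm.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path: str) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{g}\n" for g in genes)


def save_model(model: FittedModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path: str) -> FittedModel:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt or truncated model file {path}: {exc}") from exc
    return FittedModel.from_dict(d)


# ---------------------------------------------------------------------------
# Run configuration

PRESETS = {"desk": PipelineConfig(), "full": FULL_SCALE}


@dataclass
class RunConfig:
    """Paths + pipeline parameters + master seed for one reproducible run."""

    counts: str = ""
    phenotype: str = ""
    test_counts: str = ""
    test_phenotype: str = ""
    probe_matrix: str = ""
    probe_map: str = ""
    output_dir: str = "out"
    preset: str = "desk"
    seed: int = 0
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        pipe_raw = raw.pop("pipeline", {}) or {}
        preset = raw.get("preset", "desk")
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        pipe_known = {f.name for f in dataclasses.fields(PipelineConfig)}
        pipe_unknown = set(pipe_raw) - pipe_known
        if pipe_unknown:
            raise ValueError(f"unknown pipeline keys: {sorted(pipe_unknown)}")
        pipeline = dataclasses.replace(PRESETS[preset], **pipe_raw)
        return cls(pipeline=pipeline, **raw)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["pipeline"]["rankers"] = list(d["pipeline"]["rankers"])
        d["pipeline"]["algorithms"] = list(d["pipeline"]["algorithms"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def snapshot(self) -> None:
        """Write the resolved config into the output directory."""
        os.makedirs(self.output_dir, exist_ok=True)
        self.to_yaml(os.path.join(self.output_dir, "run_config.yaml"))
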