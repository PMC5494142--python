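"""Readers and writers: expression TSV, covariate CSV, simplified RCC files,
target tables, GMT gene sets and ground-truth JSON.

Expression TSV layout: first column ``feature_id``, remaining columns sample
ids, empty cells meaning missing. The RCC dialect is a documented
simplification of the vendor's per-sample file: a ``<Header>`` block of
``key,value`` lines followed by a ``<CodeSummary>`` block of
``class,name,count`` lines, with classes Endogenous (measurements) and
Negative (background probes).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .simulate import GroundTruth


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="")


def read_expression_tsv(path, feature_class: str = "mirna",
                        batch: pd.Series | None = None,
                        state: str = "raw") -> ExpressionMatrix:
    """Parse an expression TSV; empty cells become missing values.

    Raises on duplicate ids, ragged rows and non-numeric cells, naming the
    offending line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        samples = header[1:]
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids in header")
        fids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ValueError(f"{path.name}:{lineno}: ragged row "
                                 f"({len(parts)} fields, expected {n_cols})")
            fids.append(parts[0])
            vals = []
            for j, cell in enumerate(parts[1:], start=2):
                if cell == "":
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise ValueError(
                            f"{path.name}:{lineno}: non-numeric cell "
                            f"{cell!r} in column {j}") from None
            rows.append(vals)
    if len(set(fids)) != len(fids):
        raise ValueError("duplicate feature ids")
    values = pd.DataFrame(rows, index=pd.Index(fids, name="feature_id"),
                          columns=samples, dtype=float)
    return ExpressionMatrix(values=values, feature_class=feature_class,
                            batch=batch, state=state)


# ---------------------------------------------------------------------------
# covariate / cohort CSV
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index_label="sample_id")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in cohort table")
    return df


# ---------------------------------------------------------------------------
# simplified RCC-like per-sample files
# ---------------------------------------------------------------------------

def write_rcc_like(m: ExpressionMatrix, background: pd.Series, directory) -> None:
    """One sectioned text file per sample: header, then CodeSummary lines.

    Endogenous rows carry the sample's counts; Negative rows carry the
    per-feature background levels (shared across samples, as probe-level
    attributes).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid in m.sample_ids:
        lines = ["<Header>", f"ID,{sid}", "GeneRLF,synthetic_probeset",
                 "</Header>", "<CodeSummary>"]
        for fid in m.feature_ids:
            v = m.values.at[fid, sid]
            if not np.isnan(v):
                lines.append(f"Endogenous,{fid},{v:g}")
        for fid in m.feature_ids:
            lines.append(f"Negative,NEG_{fid},{background[fid]:g}")
        lines.append("</CodeSummary>")
        (directory / f"{sid}.rcc").write_text("\n".join(lines) + "\n")


def read_rcc_like(directory) -> tuple[ExpressionMatrix, pd.Series]:
    """Assemble a raw feature x sample matrix and per-feature backgrounds.

    Sample order in the matrix is sorted by sample id, so the result is
    independent of file enumeration order.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.rcc"))
    if not files:
        raise FileNotFoundError(f"no .rcc files in {directory}")
    per_sample: dict = {}
    background: dict = {}
    for f in files:
        sid = None
        counts: dict = {}
        section = None
        saw_code = False
        for lineno, line in enumerate(f.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            if line in ("<Header>", "<CodeSummary>"):
                section = line
                saw_code = saw_code or line == "<CodeSummary>"
                continue
            if line in ("</Header>", "</CodeSummary>"):
                section = None
                continue
            parts = line.split(",")
            if section == "<Header>":
                if parts[0] == "ID":
                    sid = parts[1]
            elif section == "<CodeSummary>":
                cls, name, count = parts
                try:
                    value = float(count)
                except ValueError:
                    raise ValueError(f"{f.name}:{lineno}: count {count!r} "
                                     "is not numeric") from None
                if cls == "Endogenous":
                    counts[name] = value
                elif cls == "Negative":
                    background[name.removeprefix("NEG_")] = value
        if not saw_code:
            raise ValueError(f"{f.name}: missing <CodeSummary> section")
        if sid is None:
            raise ValueError(f"{f.name}: missing sample ID in header")
        per_sample[sid] = counts
    if not background:
        raise ValueError("no Negative-class background probes found")
    values = pd.DataFrame(per_sample).sort_index(axis=1)
    values.index.name = "feature_id"
    bg = pd.Series(background, name="background").reindex(values.index)
    matrix = ExpressionMatrix(values=values, feature_class="mirna", state="raw")
    return matrix, bg


# ---------------------------------------------------------------------------
# targets, GMT, ground truth
# ---------------------------------------------------------------------------

def write_target_table(targets: pd.DataFrame, path) -> None:
    targets[["mirna_id", "gene_id"]].to_csv(path, sep="\t", index=False)


def read_target_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"mirna_id", "gene_id"} <= set(df.columns):
        raise ValueError("target table needs columns mirna_id, gene_id")
    return df


def write_gmt(pathways: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> dict:
    """Parse a GMT file: name, description, then tab-separated gene ids."""
    pathways: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: needs name, "
                                 "description and at least one gene")
            name = parts[0]
            if name in pathways:
                raise ValueError(f"duplicate pathway name {name!r} at "
                                 f"line {lineno}")
            pathways[name] = [g for g in parts[2:] if g]
    return pathways


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2) + "\n")


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
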