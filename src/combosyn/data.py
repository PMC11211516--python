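"""Input tables, filtering rules and dataset assembly.

Three tables feed the model: a cell-line × landmark-gene expression matrix,
a drug → SMILES map, and a combination table carrying four synergy scores
(Loewe, Bliss, HSA, ZIP) per (drug A, drug B, cell line) triple.

A combination enters the training set only when all four scores agree:
every score above its threshold → positive, every score below → negative,
anything else (including missing values) → excluded. Duplicate triples are
collapsed after canonicalizing the unordered drug pair, and records with
missing fields are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import DrugGraph, build_drug_graph
from .kde_features import DKPETensor, ExpressionVector, featurize_expression

logger = logging.getLogger(__name__)

__all__ = [
    "SCORE_NAMES",
    "CombinationRecord",
    "DatasetConfig",
    "AssembledDataset",
    "consensus_label",
    "dedup_and_filter",
    "assemble_dataset",
    "read_expression_table",
    "read_drug_table",
    "read_combination_table",
    "normalize_expression",
]

SCORE_NAMES = ("loewe", "bliss", "hsa", "zip")
COMBO_COLUMNS = ("drug_a", "drug_b", "cell_line") + SCORE_NAMES

POSITIVE = "positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class CombinationRecord:
    drug_a_id: str
    drug_b_id: str
    cell_line_id: str
    scores: tuple  # (loewe, bliss, hsa, zip)
    label: str = EXCLUDED


@dataclass(frozen=True)
class DatasetConfig:
    """Assembly options: featurization settings and consensus thresholds."""

    grid_size: int = 64
    bandwidth: float | str = "auto"
    normalize_density: bool = True
    normalize_expression: bool = True
    thresholds: tuple = (0.0, 0.0, 0.0, 0.0)
    drop_unresolvable: bool = False


def consensus_label(scores, thresholds=(0.0, 0.0, 0.0, 0.0)) -> str:
    """Unanimity rule over the four synergy scores.

    positive iff every score exceeds its threshold, negative iff every score
    falls below; disagreement or any missing score excludes the sample.
    """
    scores = list(scores)
    thresholds = list(thresholds)
    if len(scores) != 4 or len(thresholds) != 4:
        raise ValueError("exactly four scores and four thresholds are required")
    arr = np.array(scores, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        logger.debug("sample excluded: missing or non-finite synergy score")
        return EXCLUDED
    th = np.array(thresholds, dtype=np.float64)
    if np.all(arr > th):
        return POSITIVE
    if np.all(arr < th):
        return NEGATIVE
    return EXCLUDED


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    return isinstance(x, str) and not x.strip()


def dedup_and_filter(records: list[CombinationRecord]) -> list[CombinationRecord]:
    """One record per unordered (drug A, drug B, cell line) triple.

    Records with missing identifiers or scores are dropped; the drug pair is
    canonicalized lexicographically, and the first occurrence of each triple
    wins. Idempotent.
    """
    kept: list[CombinationRecord] = []
    seen: set[tuple] = set()
    n_incomplete = n_dup = 0
    for rec in records:
        if (
            _is_missing(rec.drug_a_id)
            or _is_missing(rec.drug_b_id)
            or _is_missing(rec.cell_line_id)
            or len(rec.scores) != 4
            or any(_is_missing(s) for s in rec.scores)
        ):
            n_incomplete += 1
            continue
        a, b = sorted((str(rec.drug_a_id), str(rec.drug_b_id)))
        key = (a, b, str(rec.cell_line_id))
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        if (a, b) != (rec.drug_a_id, rec.drug_b_id):
            rec = replace(rec, drug_a_id=a, drug_b_id=b)
        kept.append(rec)
    logger.info(
        "dedup_and_filter: kept %d, dropped %d incomplete, %d duplicates",
        len(kept), n_incomplete, n_dup,
    )
    return kept


# ---------------------------------------------------------------------------
# table readers


def _read_table(path, sep=None) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def normalize_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across cell lines (zero-variance genes map to 0)."""
    vals = df.to_numpy(dtype=np.float64)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mu) / sd, index=df.index, columns=df.columns)


def read_expression_table(path, normalize: bool = True) -> pd.DataFrame:
    """Expression matrix: first column cell_line_id, remaining columns numeric."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError("expression table needs an id column plus gene columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise ValueError("duplicate cell_line_id entries in expression table")
    values = df.apply(pd.to_numeric, errors="raise")
    if not np.all(np.isfinite(values.to_numpy())):
        raise ValueError("expression table contains missing or non-finite values")
    return normalize_expression(values) if normalize else values


def read_drug_table(path) -> pd.DataFrame:
    """Two-column table drug_id → SMILES."""
    df = _read_table(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if len(cols) < 2 or cols[0] != "drug_id" or cols[1] != "smiles":
        raise ValueError(f"drug table must have columns drug_id, smiles; got {list(df.columns)}")
    df.columns = cols
    df["drug_id"] = df["drug_id"].astype(str)
    if df["drug_id"].duplicated().any():
        raise ValueError("duplicate drug_id entries in drug table")
    return df.set_index("drug_id")


def read_combination_table(path) -> pd.DataFrame:
    df = _read_table(path)
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in COMBO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"combination table missing columns: {missing}")
    return df


def records_from_frame(df: pd.DataFrame, thresholds=(0.0, 0.0, 0.0, 0.0)) -> list[CombinationRecord]:
    records = []
    for row in df.itertuples(index=False):
        scores = tuple(float(getattr(row, s)) for s in SCORE_NAMES)
        records.append(
            CombinationRecord(
                drug_a_id=str(row.drug_a),
                drug_b_id=str(row.drug_b),
                cell_line_id=str(row.cell_line),
                scores=scores,
                label=consensus_label(scores, thresholds),
            )
        )
    return records


# ---------------------------------------------------------------------------
# assembly


@dataclass
class AssembledDataset:
    """Model-ready samples plus the shared per-entity feature caches."""

    samples: list  # (cell_line_id, drug_a_id, drug_b_id, label01, mean_score)
    tensors: dict[str, DKPETensor]
    graphs: dict[str, DrugGraph]
    config: DatasetConfig
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s[3] for s in self.samples], dtype=int)

    def subset(self, idx) -> "AssembledDataset":
        return AssembledDataset(
            samples=[self.samples[i] for i in idx],
            tensors=self.tensors,
            graphs=self.graphs,
            config=self.config,
            provenance=dict(self.provenance, subset_of=len(self.samples)),
        )


def assemble_dataset(
    expression: pd.DataFrame,
    drugs: pd.DataFrame,
    combinations: pd.DataFrame,
    config: DatasetConfig | None = None,
) -> AssembledDataset:
    """Join the three tables into labeled, featurized samples.

    Applies deduplication, the completeness filter and consensus labeling;
    excluded records never reach the sample list. Unresolvable drug or cell
    references raise (listing the offending identifiers) unless
    ``config.drop_unresolvable`` is set.
    """
    config = config or DatasetConfig()
    records = dedup_and_filter(records_from_frame(combinations, config.thresholds))

    known_cells = set(expression.index)
    known_drugs = set(drugs.index)
    bad_cells = sorted({r.cell_line_id for r in records} - known_cells)
    bad_drugs = sorted(
        {r.drug_a_id for r in records} | {r.drug_b_id for r in records} - known_drugs
    )
    bad_drugs = sorted(set(bad_drugs) - known_drugs)
    if (bad_cells or bad_drugs) and not config.drop_unresolvable:
        raise KeyError(
            f"unresolvable references — cell lines: {bad_cells}, drugs: {bad_drugs}"
        )
    records = [
        r
        for r in records
        if r.cell_line_id in known_cells
        and r.drug_a_id in known_drugs
        and r.drug_b_id in known_drugs
    ]

    n_excluded = sum(1 for r in records if r.label == EXCLUDED)
    labeled = [r for r in records if r.label != EXCLUDED]

    needed_cells = sorted({r.cell_line_id for r in labeled})
    needed_drugs = sorted({r.drug_a_id for r in labeled} | {r.drug_b_id for r in labeled})

    tensors = {
        c: featurize_expression(
            ExpressionVector(c, expression.loc[c].to_numpy(dtype=np.float64)),
            bandwidth_h=config.bandwidth,
            grid_size=config.grid_size,
            normalize_density=config.normalize_density,
        )
        for c in needed_cells
    }
    graphs = {d: build_drug_graph(d, drugs.loc[d, "smiles"]) for d in needed_drugs}

    samples = [
        (
            r.cell_line_id,
            r.drug_a_id,
            r.drug_b_id,
            1 if r.label == POSITIVE else 0,
            float(np.mean(r.scores)),
        )
        for r in labeled
    ]
    logger.info(
        "assemble_dataset: %d samples (%d positive), %d excluded by consensus",
        len(samples), sum(s[3] for s in samples), n_excluded,
    )
    return AssembledDataset(
        samples=samples,
        tensors=tensors,
        graphs=graphs,
        config=config,
        provenance={
            "n_labeled": len(samples),
            "n_excluded": n_excluded,
            "n_cells": len(needed_cells),
            "n_drugs": len(needed_drugs),
        },
    )
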