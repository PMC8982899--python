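"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are plain text: tab-separated (expression matrices, edge
lists, rankings) or comma-separated (GR tables, dose-response matrices), UTF-8,
'.' decimal, mandatory header row.  Floats are written with 10 significant
digits so that every writer/reader pair is a lossless round trip at that
precision.  Drug, sample, TF and gene identifiers are case-sensitive opaque
strings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("omu_synergy")

FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    One column per condition: the untreated control and one column per drug.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                "missing/non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


def _check_unique(ids, kind: str) -> None:
    seen, dupes = set(), []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise FormatError(f"duplicate {kind} id(s): {sorted(set(dupes))}")


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        # locate the offending cell for the error message
        for gi, g in enumerate(genes):
            for si, s in enumerate(samples):
                try:
                    float(df.iat[gi, si])
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric expression value at gene {g!r}, sample {s!r}: "
                        f"{df.iat[gi, si]!r}"
                    ) from exc
        raise
    if df.isna().any().any():
        bad_rows = [g for g, isna in df.isna().any(axis=1).items() if isna]
        raise FormatError(f"missing values in gene row(s): {bad_rows}")
    m = ExpressionMatrix(genes, samples, values)
    logger.info("read expression %s: %d genes x %d samples", path, len(genes), len(samples))
    return m


def write_expression(path, matrix: ExpressionMatrix) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


# ---------------------------------------------------------------------------
# edge lists


@dataclass
class EdgeList:
    """Directed (prior) or symmetric (PPI) weighted edge records."""

    records: list[tuple[str, str, float]] = field(default_factory=list)
    symmetric: bool = False

    def __post_init__(self) -> None:
        for s, t, w in self.records:
            if not np.isfinite(w):
                raise FormatError(f"non-finite weight on edge ({s}, {t})")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["source", "target", "weight"])

    def sources(self) -> list[str]:
        return sorted({s for s, _, _ in self.records})

    def targets(self) -> list[str]:
        return sorted({t for _, t, _ in self.records})

    def weight_matrix(self, row_ids: list[str], col_ids: list[str]) -> np.ndarray:
        ridx = {r: i for i, r in enumerate(row_ids)}
        cidx = {c: i for i, c in enumerate(col_ids)}
        w = np.zeros((len(row_ids), len(col_ids)))
        for s, t, wt in self.records:
            if s in ridx and t in cidx:
                w[ridx[s], cidx[t]] = wt
        return w


def read_edge_list(path, symmetric: bool = False) -> EdgeList:
    """Read a source/target[/weight] TSV; missing weight column defaults to 1.

    With ``symmetric=True`` (PPI mode) each edge (a, b, w) implies (b, a, w)
    and self-loops are dropped with a warning (counted in the log).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = [c.lower() for c in df.columns]
    if len(df.columns) < 2 or cols[0] != "source" or cols[1] != "target":
        raise FormatError(f"{path}: expected header 'source<TAB>target[<TAB>weight]'")
    if "weight" in cols:
        weights = pd.to_numeric(df[df.columns[cols.index("weight")]], errors="coerce")
        if weights.isna().any():
            row = int(weights.isna().idxmax())
            raise FormatError(f"{path}: malformed weight on data line {row + 1}")
        weights = weights.to_numpy(dtype=float)
    else:
        weights = np.ones(len(df))
    if df[df.columns[:2]].isna().any().any():
        raise FormatError(f"{path}: malformed line with missing source/target")
    seen: dict[tuple[str, str], float] = {}
    n_loops = 0
    for (_, row), w in zip(df.iterrows(), weights):
        s, t = str(row.iloc[0]), str(row.iloc[1])
        if symmetric and s == t:
            n_loops += 1
            continue
        seen[(s, t)] = float(w)
        if symmetric:
            seen[(t, s)] = float(w)
    if n_loops:
        logger.warning("read_edge_list %s: dropped %d self-loop(s)", path, n_loops)
    records = [(s, t, w) for (s, t), w in sorted(seen.items())]
    return EdgeList(records=records, symmetric=symmetric)


def write_edge_list(path, edges: EdgeList) -> None:
    df = edges.to_frame()
    if edges.symmetric:  # store each undirected edge once
        df = df[df["source"] <= df["target"]]
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# GR tables


@dataclass
class GRTable:
    """Per-drug maximal growth-rate-inhibition effect, GRmax in [-1, 1]."""

    records: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, gr in self.records.items():
            if not (-1.0 <= gr <= 1.0):
                raise FormatError(f"GRmax for {drug!r} is {gr}, outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, drug: str) -> float:
        return self.records[drug]

    def __contains__(self, drug: str) -> bool:
        return drug in self.records

    def drugs(self) -> list[str]:
        return list(self.records)


def read_gr_table(path) -> GRTable:
    """Read a CSV with columns drug,grmax (one record per drug)."""
    df = pd.read_csv(path, dtype={"drug": str})
    cols = [c.lower() for c in df.columns]
    if "drug" not in cols or "grmax" not in cols:
        raise FormatError(f"{path}: expected CSV header 'drug,grmax'")
    drugs = df[df.columns[cols.index("drug")]].astype(str)
    if drugs.duplicated().any():
        raise FormatError(f"{path}: duplicate drug id(s): "
                          f"{sorted(drugs[drugs.duplicated()].unique())}")
    grmax = pd.to_numeric(df[df.columns[cols.index("grmax")]])
    return GRTable(records=dict(zip(drugs, grmax.astype(float))))


def write_gr_table(path, table: GRTable) -> None:
    pd.DataFrame(
        {"drug": list(table.records), "grmax": list(table.records.values())}
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# candidate rankings


def write_ranking(path, ranking: pd.DataFrame) -> None:
    """Write a candidate table sorted ascending by DGIS (ties: pair lexicographic).

    ``ranking`` needs columns drug_1, drug_2, gis, dgis and optionally zip.
    """
    required = {"drug_1", "drug_2", "gis", "dgis"}
    missing = required - set(ranking.columns)
    if missing:
        raise FormatError(f"ranking is missing column(s): {sorted(missing)}")
    out = ranking.sort_values(
        ["dgis", "drug_1", "drug_2"], kind="mergesort"
    ).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ranking(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"drug_1": str, "drug_2": str})


# ---------------------------------------------------------------------------
# dose-response matrices (long CSV) and JSON helpers


def read_dose_response(path) -> pd.DataFrame:
    """Read a long-format combination CSV: drug1,conc1,drug2,conc2,response."""
    df = pd.read_csv(path, dtype={"drug1": str, "drug2": str})
    required = {"drug1", "conc1", "drug2", "conc2", "response"}
    missing = required - set(c.lower() for c in df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    df.columns = [c.lower() for c in df.columns]
    return df


def write_dose_response(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
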