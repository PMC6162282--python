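"""File formats of the pipeline.

RPPA matrices travel as a TSV (first column ``protein_id``, remaining
columns sample identifiers) plus a sample sheet TSV mapping each sample
column to (cell_line, timepoint, hours, baseline flag, scale). Networks
travel as SIF (``node<TAB>relation<TAB>node``, optional 4th ``directed``
column) or a 4-column edge-list TSV. Screen tables, flow logs and score
tables are TSV; provenance and truth sidecars are JSON.

All writers format floats with ``%.10g`` so repeated runs with the same
seed and configuration produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import IngestionError
from .matrix import NormalizedMatrix, RppaMatrix
from .network import Edge, SignalingNetwork

__all__ = [
    "read_rppa",
    "write_rppa",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_network",
    "write_network_sif",
    "write_network_tsv",
    "write_table",
    "write_json",
]

FLOAT_FORMAT = "%.10g"

SAMPLE_SHEET_COLUMNS = ["sample", "cell_line", "timepoint", "hours", "baseline", "scale"]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a TSV with deterministic float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample sheet."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str, "timepoint": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise IngestionError(f"sample sheet {path}: missing column(s) {missing}")
    if sheet["baseline"].isna().any():
        rows = sheet.index[sheet["baseline"].isna()].tolist()
        raise IngestionError(f"sample sheet {path}: baseline flag missing in row(s) {rows}")
    if sheet["sample"].duplicated().any():
        raise IngestionError(f"sample sheet {path}: duplicate sample identifiers")
    return sheet


def write_sample_sheet(matrix: RppaMatrix, path: str | Path) -> Path:
    sheet = pd.DataFrame(
        {
            "sample": matrix.timepoints,
            "cell_line": matrix.cell_line,
            "timepoint": matrix.timepoints,
            "hours": [matrix.hours.get(tp, float("nan")) for tp in matrix.timepoints],
            "baseline": [int(tp == matrix.baseline) for tp in matrix.timepoints],
            "scale": matrix.scale,
        }
    )
    return write_table(sheet, path)


def read_rppa(path: str | Path, sample_sheet_path: str | Path, cell_line: str | None = None) -> RppaMatrix:
    """Ingest an RPPA matrix TSV plus its sample sheet into an RppaMatrix.

    The sample sheet selects (and orders) the matrix columns belonging to
    one cell line; when the sheet covers several cell lines, ``cell_line``
    picks which one to load.
    """
    sheet = read_sample_sheet(sample_sheet_path)
    if cell_line is not None:
        sheet = sheet[sheet["cell_line"] == cell_line]
        if sheet.empty:
            raise IngestionError(f"sample sheet has no rows for cell line {cell_line!r}")
    lines = sheet["cell_line"].unique().tolist()
    if len(lines) != 1:
        raise IngestionError(
            f"sample sheet covers cell lines {lines}; pass cell_line= to pick one"
        )
    scales = sheet["scale"].unique().tolist()
    if len(scales) != 1:
        raise IngestionError(f"inconsistent scale annotations {scales} for one cell line")
    baselines = sheet.loc[sheet["baseline"].astype(int) == 1, "timepoint"].tolist()
    if len(baselines) != 1:
        raise IngestionError(
            f"expected exactly one baseline sample for {lines[0]}, found {len(baselines)}"
        )

    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, dtype={0: str})
    if table.columns[0] != "protein_id":
        raise IngestionError(f"{path}: first column must be 'protein_id', got {table.columns[0]!r}")
    table = table.set_index("protein_id")
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise IngestionError(f"{path}: duplicate antibody row(s) {dupes}")
    absent = [s for s in sheet["sample"] if s not in table.columns]
    if absent:
        raise IngestionError(f"{path}: sample column(s) {absent} not found")
    values = table[list(sheet["sample"])].astype(float)
    values.columns = list(sheet["timepoint"])
    hours = dict(zip(sheet["timepoint"], sheet["hours"].astype(float)))
    return RppaMatrix(
        cell_line=lines[0],
        values=values,
        baseline=baselines[0],
        scale=scales[0],
        hours=hours,
    )


def write_rppa(matrix: RppaMatrix, path: str | Path, sample_sheet_path: str | Path | None = None) -> Path:
    """Write a matrix (and optionally its sample sheet) in the pipeline dialect."""
    df = matrix.values.copy()
    df.insert(0, "protein_id", df.index)
    out = write_table(df, path)
    if sample_sheet_path is not None:
        write_sample_sheet(matrix, sample_sheet_path)
    return out


def write_normalized(matrix: NormalizedMatrix, path: str | Path, provenance_path: str | Path | None = None) -> Path:
    out = write_rppa(matrix, path)
    if provenance_path is not None:
        write_json(matrix.provenance, provenance_path)
    return out


def _parse_directed(token: str, line_no: int, path) -> bool:
    token = token.strip().lower()
    if token in ("1", "true", "directed", "yes"):
        return True
    if token in ("0", "false", "undirected", "no"):
        return False
    raise IngestionError(f"{path} line {line_no}: bad directed flag {token!r}")


def read_network(path: str | Path, format: str | None = None) -> SignalingNetwork:
    """Parse a SIF or edge-list TSV into a cleaned SignalingNetwork.

    SIF rows are ``source<TAB>relation<TAB>target`` with an optional fourth
    ``directed`` column; without it, ``interaction`` edges are undirected
    and control edges directed. The edge-list TSV has a header row
    ``source  target  relation  directed``. Unknown relation labels are a
    parse error naming the offending line.
    """
    path = Path(path)
    if format is None:
        format = "sif" if path.suffix == ".sif" else "tsv"
    if format not in ("sif", "tsv"):
        raise IngestionError(f"unknown network format {format!r}; expected sif or tsv")
    edges: list[Edge] = []
    lines = path.read_text().splitlines()
    start = 0
    if format == "tsv":
        header = lines[0].split("\t") if lines else []
        if header[:4] != ["source", "target", "relation", "directed"]:
            raise IngestionError(
                f"{path}: edge-list header must be source/target/relation/directed"
            )
        start = 1
    for line_no, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if format == "sif":
            if len(parts) not in (3, 4):
                raise IngestionError(f"{path} line {line_no}: expected 3 or 4 columns")
            src, rel, tgt = parts[0], parts[1], parts[2]
            directed = (
                _parse_directed(parts[3], line_no, path)
                if len(parts) == 4
                else rel != "interaction"
            )
        else:
            if len(parts) != 4:
                raise IngestionError(f"{path} line {line_no}: expected 4 columns")
            src, tgt, rel = parts[0], parts[1], parts[2]
            directed = _parse_directed(parts[3], line_no, path)
        if rel not in ("interaction", "direct", "indirect"):
            raise IngestionError(f"{path} line {line_no}: unknown relation {rel!r}")
        edges.append(Edge(src, tgt, rel, directed=directed))
    return SignalingNetwork(edges=edges)


def write_network_sif(network: SignalingNetwork, path: str | Path) -> Path:
    """Write a network as 4-column SIF (with explicit directed flags)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = sorted(
        (e.source, e.relation, e.target, "1" if e.directed else "0")
        for e in network.edges
    )
    path.write_text("".join("\t".join(r) + "\n" for r in rows))
    return path


def write_network_tsv(network: SignalingNetwork, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = sorted(
        (e.source, e.target, e.relation, "1" if e.directed else "0")
        for e in network.edges
    )
    header = "source\ttarget\trelation\tdirected\n"
    path.write_text(header + "".join("\t".join(r) + "\n" for r in rows))
    return path
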