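"""Directed gene-regulatory-network assembly from protein-DNA interaction evidence.

A GRN is a directed graph in which an edge runs from a transcription factor
(TF) to a gene whose regulatory region it binds.  Evidence arrives either as
an explicit TF→target edge list (one row per protein-DNA interaction, PDI)
or as ChIP-style binding peaks that are assigned to genes whose TSS lies
within a fixed window of the peak.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_SOURCES = frozenset({"chip_seq", "chip_chip", "y1h", "dap_seq", "other"})


@dataclass(frozen=True)
class PDIRecord:
    """One protein-DNA interaction: a TF bound to a target gene."""

    tf_id: str
    target_id: str
    source: str | None = None
    tissue: str | None = None

    def __post_init__(self) -> None:
        if not self.tf_id or not self.target_id:
            raise ValueError("tf_id and target_id must be non-empty")
        if self.source is not None and self.source not in VALID_SOURCES:
            raise ValueError(
                f"unknown source {self.source!r}; valid: {sorted(VALID_SOURCES)}"
            )


@dataclass(frozen=True)
class DegreeSequence:
    """Positive node degrees in one direction (out = targets per TF)."""

    values: np.ndarray
    direction: str = "out"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        if v.size and v.min() < 1:
            raise ValueError("degree sequence must contain positive integers only")
        if self.direction not in ("out", "in"):
            raise ValueError("direction must be 'out' or 'in'")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass
class DirectedGRN:
    """Directed TF→target graph with de-duplicated edges.

    ``node_ids`` are sorted, unique gene identifiers; ``edges`` is an
    (m, 2) integer array of (tf_index, target_index) pairs, unique and
    lexicographically sorted so that graph assembly is order-independent.
    Self-loops (a TF binding its own gene) are permitted.
    """

    node_ids: np.ndarray
    edges: np.ndarray
    edge_sources: list[frozenset[str]] | None = None
    edge_tissues: list[frozenset[str]] | None = None
    _out: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def out_degree_counts(self) -> np.ndarray:
        """Out-degree per node index (zeros included)."""
        if self._out is None:
            self._out = np.bincount(self.edges[:, 0], minlength=self.n_nodes)
        return self._out

    def in_degree_counts(self) -> np.ndarray:
        return np.bincount(self.edges[:, 1], minlength=self.n_nodes)

    @property
    def is_tf(self) -> np.ndarray:
        """Role flag: a node is a TF iff it has at least one out-going edge."""
        return self.out_degree_counts() > 0

    @property
    def n_tfs(self) -> int:
        return int(self.is_tf.sum())

    def tf_ids(self) -> np.ndarray:
        return self.node_ids[self.is_tf]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        tf = self.is_tf
        for i, name in enumerate(self.node_ids):
            g.add_node(str(name), is_tf=bool(tf[i]))
        for a, b in self.edges:
            g.add_edge(str(self.node_ids[a]), str(self.node_ids[b]))
        return g


def read_edge_list(
    path, delimiter: str = "\t", strict: bool = True
) -> list[PDIRecord]:
    """Read a delimited TF→target table into PDI records.

    The first row is treated as a header when its first two cells are the
    literal column names ``tf``/``target`` (extra ``source``/``tissue``
    columns are honored).  Malformed lines (< 2 columns) raise in strict
    mode with their 1-based line number, otherwise they are collected into
    a warning.
    """
    path = Path(path)
    records: list[PDIRecord] = []
    bad: list[int] = []
    src_col = tis_col = None
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].strip().lower() == "tf":
                header = [c.strip().lower() for c in row]
                src_col = header.index("source") if "source" in header else None
                tis_col = header.index("tissue") if "tissue" in header else None
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                if strict:
                    raise ValueError(f"{path}: malformed line {lineno}: {row!r}")
                bad.append(lineno)
                continue
            records.append(
                PDIRecord(
                    tf_id=row[0].strip(),
                    target_id=row[1].strip(),
                    source=row[src_col].strip() or None
                    if src_col is not None and len(row) > src_col
                    else None,
                    tissue=row[tis_col].strip() or None
                    if tis_col is not None and len(row) > tis_col
                    else None,
                )
            )
    if bad:
        warnings.warn(f"{path}: skipped {len(bad)} malformed line(s): {bad[:10]}")
    if not records:
        raise ValueError(f"{path}: no PDI records found")
    return records


def read_gene_table(path) -> pd.DataFrame:
    """Gene TSS table: TSV with columns gene_id, chrom, tss (1-based), strand."""
    genes = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = {"gene_id", "chrom", "tss"} - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return genes


def read_gff_genes(path) -> pd.DataFrame:
    """Extract gene TSS (5' end, 1-based) from a GFF3 file's ``gene`` features."""
    cols = ["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attr"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                     dtype={"chrom": str})
    df = df[df["type"] == "gene"].copy()
    ids = df["attr"].str.extract(r"ID=([^;]+)")[0]
    tss = np.where(df["strand"] == "-", df["end"], df["start"])
    return pd.DataFrame(
        {"gene_id": ids.values, "chrom": df["chrom"].values, "tss": tss,
         "strand": df["strand"].values}
    )


def read_peaks(path) -> pd.DataFrame:
    """BED3+name peaks (0-based half-open); optional 5th column = summit coord.

    When no summit column is present the interval midpoint is used as the
    summit.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 4:
        raise ValueError("peak file needs at least 4 columns (chrom,start,end,name)")
    peaks = pd.DataFrame(
        {"chrom": df[0].astype(str), "start": df[1].astype(int),
         "end": df[2].astype(int), "tf_id": df[3].astype(str)}
    )
    if df.shape[1] >= 5 and pd.api.types.is_numeric_dtype(df[4]):
        peaks["summit"] = df[4].astype(int)
    else:
        peaks["summit"] = (peaks["start"] + peaks["end"] - 1) // 2
    return peaks


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 2000,
    source: str = "chip_seq",
) -> list[PDIRecord]:
    """Assign each binding peak to every gene whose TSS is within ``window`` bp.

    Distance is |summit − TSS| on the same chromosome, strand-ignored, with
    an inclusive boundary; all qualifying genes are assigned (no
    nearest-gene tie-break) and duplicate (TF, gene) pairs are collapsed.
    Peak summits are 0-based and TSS 1-based; coordinates are reconciled
    before the distance test.
    """
    p = peaks.copy()
    p["pos"] = p["summit"].astype(int) + 1  # 0-based summit -> 1-based
    pc, gc = set(p["chrom"]), set(genes["chrom"])
    if not (pc & gc):
        warnings.warn(
            f"no shared chromosomes between peaks ({len(pc)}) and genes ({len(gc)})"
        )
    elif pc - gc or gc - pc:
        warnings.warn(
            f"chromosome name mismatch: {len(pc - gc)} peak-only, "
            f"{len(gc - pc)} gene-only"
        )
    merged = p.merge(genes[["gene_id", "chrom", "tss"]], on="chrom", how="inner")
    hit = merged[(merged["pos"] - merged["tss"]).abs() <= window]
    pairs = hit[["tf_id", "gene_id"]].drop_duplicates()
    return [
        PDIRecord(tf_id=t, target_id=g, source=source)
        for t, g in pairs.itertuples(index=False)
    ]


def build_grn(records: list[PDIRecord]) -> DirectedGRN:
    """Assemble a directed GRN; duplicate edges collapse, provenance merges."""
    if not records:
        raise ValueError("cannot build a GRN from zero records")
    tf = np.array([r.tf_id for r in records])
    tg = np.array([r.target_id for r in records])
    node_ids = np.unique(np.concatenate([tf, tg]))
    idx = {name: i for i, name in enumerate(node_ids)}
    e = np.empty((len(records), 2), dtype=np.int64)
    e[:, 0] = [idx[t] for t in tf]
    e[:, 1] = [idx[t] for t in tg]
    uniq, inv = np.unique(e, axis=0, return_inverse=True)
    has_annot = any(r.source or r.tissue for r in records)
    sources = tissues = None
    if has_annot:
        sources = [set() for _ in range(uniq.shape[0])]
        tissues = [set() for _ in range(uniq.shape[0])]
        for j, r in enumerate(records):
            if r.source:
                sources[inv[j]].add(r.source)
            if r.tissue:
                tissues[inv[j]].add(r.tissue)
        sources = [frozenset(s) for s in sources]
        tissues = [frozenset(t) for t in tissues]
    return DirectedGRN(node_ids=node_ids, edges=uniq,
                       edge_sources=sources, edge_tissues=tissues)


def degree_sequence(grn: DirectedGRN, direction: str = "out") -> DegreeSequence:
    """Degrees of nodes with >= 1 edge in the given direction.

    Zero-degree nodes are excluded: a pure target contributes no out-degree
    value.  Summed over nodes, out- and in-degrees both equal the edge count.
    """
    counts = (
        grn.out_degree_counts() if direction == "out" else grn.in_degree_counts()
    )
    return DegreeSequence(values=counts[counts > 0], direction=direction)


def filter_by_provenance(
    records: list[PDIRecord],
    source: str | None = None,
    tissue: str | None = None,
) -> list[PDIRecord]:
    """Subset PDI records by experimental source and/or tissue annotation."""
    if source is not None and source not in VALID_SOURCES:
        raise ValueError(
            f"unknown source {source!r}; valid: {sorted(VALID_SOURCES)}"
        )
    out = [
        r
        for r in records
        if (source is None or r.source == source)
        and (tissue is None or r.tissue == tissue)
    ]
    if not out:
        warnings.warn("provenance filter matched no records")
    return out
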