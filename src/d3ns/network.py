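"""Gene-interaction network: loading, confidence filtering, propagation operator.

Interaction databases (STRING, HumanNet, Mentha exports) are consumed as a
three-column edge list (geneA, geneB, confidence score).  Only the 10% most
confident interactions are retained by default, after which the network is
treated as unweighted and undirected.  The propagation operator W is the
degree-normalized (row-stochastic) adjacency matrix restricted to the analysis
gene universe; genes without any edge inside the universe receive a self-loop
so W stays row-stochastic and leaves their signal in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .data_io import EmptyInputError, FormatError, MutationMatrix

__all__ = [
    "GeneNetwork",
    "TransitionMatrix",
    "load_network",
    "filter_top_confidence",
    "build_transition_matrix",
    "align_gene_universe",
]


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class GeneNetwork:
    """Undirected scored gene graph; edges stored under canonical pair order."""

    edges: dict[tuple[str, str], float]

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def add_edge(self, a: str, b: str, score: float) -> None:
        if a == b:
            return  # self-loops are never stored
        key = _canonical(a, b)
        prev = self.edges.get(key)
        if prev is None or score > prev:
            self.edges[key] = float(score)


@dataclass
class TransitionMatrix:
    """Normalized genes x genes operator W used for mutation diffusion.

    With row-walk normalization every row sums to 1 and W[i, j] > 0 only on
    network edges or isolated-node self-loops.
    """

    genes: list[str]
    values: sp.csr_matrix
    normalization: str = "rowwalk"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.genes), len(self.genes)):
            raise ValueError("transition matrix shape does not match gene list")

    def toarray(self) -> np.ndarray:
        return self.values.toarray()


def load_network(path: str | Path, score_column: str | None = None) -> GeneNetwork:
    """Load a three-column (geneA, geneB, score) edge list.

    A header line is auto-detected (non-numeric third field).  Duplicate pairs
    keep the maximum score; self-loops are dropped; edges are canonicalized as
    unordered pairs.
    """
    path = Path(path)
    net = GeneNetwork(edges={})
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path} is empty")

    start = 0
    header = lines[0].split("\t")
    score_idx = 2
    if score_column is not None and score_column in header:
        score_idx = header.index(score_column)
        start = 1
    else:
        try:
            float(header[2])
        except (ValueError, IndexError):
            start = 1  # treat first line as header

    for row_no, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        if len(fields) <= score_idx:
            raise FormatError(f"{path} row {row_no}: expected at least 3 columns")
        a, b = fields[0].strip(), fields[1].strip()
        try:
            score = float(fields[score_idx])
        except ValueError:
            raise FormatError(
                f"{path} row {row_no}: non-numeric score {fields[score_idx]!r}"
            ) from None
        net.add_edge(a, b, score)
    return net


def filter_top_confidence(
    net: GeneNetwork,
    keep_fraction: float = 0.10,
    prefilter_min_score: float | None = None,
) -> GeneNetwork:
    """Retain the most confident fraction of edges, then drop the weights.

    Edges scoring at or above the (1 - keep_fraction) quantile are kept; ties
    at the threshold are all retained, so the result may slightly exceed the
    nominal fraction but is deterministic.  ``prefilter_min_score`` optionally
    drops low-confidence edges before the quantile is taken (the two-stage
    convention some databases use).  Surviving edges get score 1.0
    (unweighted network).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    edges = net.edges
    if prefilter_min_score is not None:
        edges = {k: s for k, s in edges.items() if s >= prefilter_min_score}
    if not edges:
        raise EmptyInputError("cannot filter an empty network")
    scores = np.fromiter(edges.values(), dtype=float)
    threshold = np.quantile(scores, 1.0 - keep_fraction)
    kept = {k: 1.0 for k, s in edges.items() if s >= threshold}
    return GeneNetwork(edges=kept)


def build_transition_matrix(
    net: GeneNetwork,
    gene_universe: Sequence[str],
    normalization: str = "rowwalk",
) -> TransitionMatrix:
    """Degree-normalize the adjacency restricted to ``gene_universe``.

    ``rowwalk`` gives W = D^-1 A (random-walk convention; row-stochastic);
    ``symmetric`` gives W = D^-1/2 A D^-1/2 for sensitivity analysis.  Genes
    with zero degree inside the universe get W[i, i] = 1.
    """
    if len(gene_universe) == 0:
        raise EmptyInputError("gene_universe must be non-empty")
    if normalization not in ("rowwalk", "symmetric"):
        raise ValueError(f"unknown normalization {normalization!r}")
    genes = list(gene_universe)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rows, cols = [], []
    for (a, b) in net.edges:
        ia, ib = idx.get(a), idx.get(b)
        if ia is None or ib is None:
            continue
        rows.extend((ia, ib))
        cols.extend((ib, ia))
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=float
    )
    A.sum_duplicates()
    A.data[:] = 1.0  # duplicate input edges collapse to a single link
    deg = np.asarray(A.sum(axis=1)).ravel()
    isolated = deg == 0

    if normalization == "rowwalk":
        inv = np.where(isolated, 0.0, 1.0 / np.where(isolated, 1.0, deg))
        W = sp.diags(inv) @ A
    else:
        inv_sqrt = np.where(isolated, 0.0, 1.0 / np.sqrt(np.where(isolated, 1.0, deg)))
        W = sp.diags(inv_sqrt) @ A @ sp.diags(inv_sqrt)
    if isolated.any():
        W = W + sp.diags(isolated.astype(float))
    return TransitionMatrix(genes=genes, values=W.tocsr(), normalization=normalization)


def align_gene_universe(
    M: MutationMatrix,
    net: GeneNetwork,
    policy: str = "intersect",
) -> tuple[MutationMatrix, dict]:
    """Reconcile mutation-matrix genes with network nodes.

    ``intersect`` drops matrix columns absent from the network (diffusion is
    undefined for them); ``keep_unmapped`` retains them — they become isolated
    self-loop nodes in W and pass through smoothing unchanged.  Returns the
    aligned matrix and a report of what was dropped/kept.
    """
    if policy not in ("intersect", "keep_unmapped"):
        raise ValueError(f"unknown policy {policy!r}")
    nodes = net.nodes
    mapped = [g for g in M.genes if g in nodes]
    unmapped = [g for g in M.genes if g not in nodes]
    report = {
        "policy": policy,
        "n_genes_in": len(M.genes),
        "n_mapped": len(mapped),
        "n_unmapped": len(unmapped),
        "dropped": len(unmapped) if policy == "intersect" else 0,
    }
    if policy == "intersect":
        if not mapped:
            raise EmptyInputError(
                "no overlap between mutation-matrix genes and network nodes"
            )
        return M.restrict_genes(mapped), report
    return M, report
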