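"""Assemble extracted connections into species-specific matrices.

Each accepted prediction contributes one supporting statement to the
undirected pair of its two standardized region concepts, in the matrix
of every species tagged on its source document (a document studying two
species supports both matrices) and once — regardless of how many
species — in the pooled ``"all"`` matrix.  Mentions that failed to
normalize, or normalized ambiguously to several concepts, are excluded
and itemized in a skip report: the assembly is precision-first.

Support counts can be thresholded (``filter_by_support``), trading
recall for precision by requiring a connection to recur across the
corpus.  Matrices export to labeled TSV and to RDF N-Triples with one
connects-with triple per supported pair plus one provenance triple per
supporting statement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExtractedConnection:
    """One predicted positive pair, after normalization and species tagging."""

    doc_id: str
    sentence_index: int
    concepts_a: tuple[str, ...]   # candidate concept ids for mention A
    concepts_b: tuple[str, ...]
    species: tuple[str, ...]      # taxon ids tagged on the document
    score: float = 0.0


@dataclass
class ConnectivityMatrix:
    species: str                              # taxon id or "all"
    index: list[str]                          # sorted concept ids
    counts: np.ndarray                        # symmetric, non-negative ints
    provenance: dict[tuple[str, str], list[tuple[str, int, float]]] = field(
        default_factory=dict
    )

    def validate(self) -> None:
        n = len(self.index)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match index")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts not symmetric")
        if np.diag(self.counts).any():
            raise ValueError("self-connections present")
        pos = {i: c for i, c in enumerate(self.index)}
        for (a, b), items in self.provenance.items():
            i, j = self.index.index(a), self.index.index(b)
            if self.counts[i, j] != len(items):
                raise ValueError(f"count/provenance mismatch for {(a, b)}")
        del pos

    def count(self, concept_a: str, concept_b: str) -> int:
        i = self.index.index(concept_a)
        j = self.index.index(concept_b)
        return int(self.counts[i, j])

    def n_connections(self) -> int:
        """Number of distinct supported pairs."""
        return int((np.triu(self.counts, k=1) > 0).sum())

    def n_statements(self) -> int:
        """Total supporting statements across pairs."""
        return int(np.triu(self.counts, k=1).sum())


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def aggregate(
    predictions: list[ExtractedConnection],
) -> tuple[dict[str, ConnectivityMatrix], dict]:
    """Species -> matrix (plus pooled "all"), and a skip report."""
    skipped = {"unnormalized": 0, "ambiguous": 0, "self_pair": 0}
    support: dict[str, dict[tuple[str, str], list[tuple[str, int, float]]]] = {}

    def add(species: str, pair: tuple[str, str], prov: tuple[str, int, float]) -> None:
        support.setdefault(species, {}).setdefault(pair, []).append(prov)

    for pred in predictions:
        if not pred.concepts_a or not pred.concepts_b:
            skipped["unnormalized"] += 1
            continue
        if len(pred.concepts_a) > 1 or len(pred.concepts_b) > 1:
            skipped["ambiguous"] += 1
            continue
        a, b = pred.concepts_a[0], pred.concepts_b[0]
        if a == b:
            skipped["self_pair"] += 1
            continue
        pair = _canonical_pair(a, b)
        prov = (pred.doc_id, pred.sentence_index, pred.score)
        for taxon in pred.species:
            add(taxon, pair, prov)
        add("all", pair, prov)  # document counted once in the pooled matrix

    matrices = {
        species: _build_matrix(species, pairs) for species, pairs in support.items()
    }
    if "all" not in matrices:
        matrices["all"] = _build_matrix("all", {})
    return matrices, skipped


def _build_matrix(
    species: str, pairs: dict[tuple[str, str], list[tuple[str, int, float]]]
) -> ConnectivityMatrix:
    concepts = sorted({c for pair in pairs for c in pair})
    pos = {c: i for i, c in enumerate(concepts)}
    counts = np.zeros((len(concepts), len(concepts)), dtype=int)
    for (a, b), items in pairs.items():
        counts[pos[a], pos[b]] += len(items)
        counts[pos[b], pos[a]] += len(items)
    matrix = ConnectivityMatrix(
        species=species, index=concepts, counts=counts, provenance=dict(pairs)
    )
    matrix.validate()
    return matrix


def filter_by_support(matrix: ConnectivityMatrix, min_count: int) -> ConnectivityMatrix:
    """Zero out pairs supported by fewer than ``min_count`` statements."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = matrix.counts.copy()
    counts[counts < min_count] = 0
    provenance = {
        pair: list(items)
        for pair, items in matrix.provenance.items()
        if len(items) >= min_count
    }
    out = ConnectivityMatrix(
        species=matrix.species,
        index=list(matrix.index),
        counts=counts,
        provenance=provenance,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Export


def export_matrix(
    matrix: ConnectivityMatrix, path: str | Path, format: str = "tsv"
) -> None:
    matrix.validate()
    path = Path(path)
    if format == "tsv":
        frame = pd.DataFrame(matrix.counts, index=matrix.index, columns=matrix.index)
        frame.to_csv(path, sep="\t", index_label="region")
        return
    if format == "rdf_ntriples":
        _export_rdf(matrix, path)
        return
    raise ValueError(f"unknown export format {format!r}")


def read_matrix_tsv(path: str | Path, species: str = "all") -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="region")
    return ConnectivityMatrix(
        species=species,
        index=[str(c) for c in frame.index],
        counts=frame.to_numpy(dtype=int),
        provenance={},
    )


_NS = "http://connectomine.example.org/"


def _export_rdf(matrix: ConnectivityMatrix, path: Path) -> None:
    from rdflib import Graph, Literal, Namespace, URIRef

    ns = Namespace(_NS)
    graph = Graph()
    connects_with = ns["connectsWith"]
    evidence = ns["evidence"]
    for (a, b), items in sorted(matrix.provenance.items()):
        ua = URIRef(_NS + "region/" + a.replace(" ", "_"))
        ub = URIRef(_NS + "region/" + b.replace(" ", "_"))
        graph.add((ua, connects_with, ub))
        stmt = URIRef(_NS + "connection/" + f"{a}__{b}".replace(" ", "_"))
        for doc_id, sent_idx, score in items:
            graph.add(
                (stmt, evidence, Literal(f"{doc_id}:s{sent_idx}:score={score:.4f}"))
            )
    graph.serialize(destination=str(path), format="nt", encoding="utf-8")


def export_provenance_tsv(
    matrices: dict[str, ConnectivityMatrix], path: str | Path
) -> None:
    rows = []
    for species, matrix in sorted(matrices.items()):
        for (a, b), items in sorted(matrix.provenance.items()):
            for doc_id, sent_idx, score in items:
                rows.append(
                    {
                        "species": species,
                        "region_a": a,
                        "region_b": b,
                        "doc_id": doc_id,
                        "sentence": sent_idx,
                        "score": score,
                    }
                )
    pd.DataFrame(
        rows,
        columns=["species", "region_a", "region_b", "doc_id", "sentence", "score"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Published corpus summary data

_SUMMARY_FILE = "corpus_summary.tsv"


def load_corpus_summary() -> pd.DataFrame:
    """Bundled summary statistics of the project's curated and predicted
    corpora (abstract, region-pair and connection counts per corpus)."""
    from importlib import resources

    with resources.as_file(
        resources.files("connectomine.data") / _SUMMARY_FILE
    ) as p:
        return pd.read_csv(p, sep="\t")


def merged_connection_count(summary: pd.DataFrame, corpora: list[str]) -> int:
    """Connectivity statements available after merging the named corpora."""
    rows = summary[summary["corpus"].isin(corpora)]
    if len(rows) != len(corpora):
        missing = set(corpora) - set(rows["corpus"])
        raise KeyError(f"unknown corpora: {sorted(missing)}")
    return int(rows["connections"].sum())


def positive_pair_percentage(summary: pd.DataFrame, corpus: str) -> float:
    """Connections as a percentage of annotated region pairs."""
    row = summary[summary["corpus"] == corpus]
    if row.empty:
        raise KeyError(corpus)
    return float(row["connections"].iloc[0]) / float(row["region_pairs"].iloc[0]) * 100.0
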