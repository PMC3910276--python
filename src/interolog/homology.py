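"""Homology-transfer (interolog) inference of unigene interactions.

A reference interactome (STRING-like edge table) for one or more
well-annotated species is projected onto a de novo transcriptome:
reference protein sequences are searched against the unigene set
(TBLASTN direction: protein query, translated nucleotide subject), hits
are filtered on E-value, percent identity and query coverage, each
reference protein is assigned its single best unigene homolog, and every
reference interaction whose two endpoints are assigned is transferred as
an edge between the corresponding unigenes.

Default thresholds: E-value < 1e-6, identity > 50%, query coverage > 80%
— all strict inequalities.  Query coverage is the aligned fraction of the
reference protein, computed as 100*(qend-qstart+1)/qlen per hit when a
``qcovs`` column is not supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BLAST_COLUMNS",
    "HomologyHit",
    "OrthologAssignment",
    "read_blast_tab",
    "ensure_coverage",
    "filter_hits",
    "assign_orthologs",
    "transfer_interactions",
    "read_reference_edges",
    "write_assignment_tsv",
    "write_edge_set_tsv",
]

#: standard 12-column BLAST tabular layout (outfmt 6)
BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()
#: common extensions, in the order they appear after the standard columns
BLAST_EXTENSIONS = ["qlen", "slen", "qcovs"]


@dataclass(frozen=True)
class HomologyHit:
    """One alignment record between a reference protein and a unigene."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    evalue: float
    bitscore: float
    query_length: int | None = None
    query_coverage: float | None = None


@dataclass
class OrthologAssignment:
    """Best-hit mapping reference protein -> unigene for one species.

    Each reference protein maps to at most one unigene; several proteins
    may share a unigene (paralogs collapsed in the assembly).
    ``provenance`` keeps the winning hit rows.
    """

    species: str
    mapping: dict[str, str]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# table io


def read_blast_tab(path) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt 6) TSV, tolerating qlen/slen/qcovs extras.

    Lines starting with '#' are ignored.  Column names follow the standard
    dialect; extra columns beyond the known extensions raise.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    n_extra = df.shape[1] - len(BLAST_COLUMNS)
    if n_extra < 0 or n_extra > len(BLAST_EXTENSIONS):
        raise ValueError(
            f"hit table {path!r} has {df.shape[1]} columns; expected "
            f"{len(BLAST_COLUMNS)} to {len(BLAST_COLUMNS) + len(BLAST_EXTENSIONS)}"
        )
    df.columns = BLAST_COLUMNS + BLAST_EXTENSIONS[:n_extra]
    for col in df.columns:
        if col not in ("qseqid", "sseqid"):
            df[col] = pd.to_numeric(df[col])
    return df


def ensure_coverage(hits: pd.DataFrame) -> pd.DataFrame:
    """Return hits with a ``qcovs`` (query coverage, percent) column.

    Uses the supplied qcovs when present, else 100*(qend-qstart+1)/qlen.
    Missing ``qlen`` when coverage must be derived is a per-table error.
    """
    if "qcovs" in hits.columns:
        return hits
    if "qlen" not in hits.columns:
        raise ValueError(
            "cannot compute query coverage: hit table has neither 'qcovs' nor 'qlen'"
        )
    out = hits.copy()
    span = (out["qend"] - out["qstart"]).abs() + 1
    out["qcovs"] = 100.0 * span / out["qlen"]
    return out


def read_reference_edges(path) -> pd.DataFrame:
    """Read a STRING-like edge table: protein_a, protein_b[, combined_score]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"reference edge table {path!r} needs >= 2 columns")
    cols = ["protein_a", "protein_b"] + (["score"] if df.shape[1] >= 3 else [])
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


# ---------------------------------------------------------------------------
# filtering


def filter_hits(
    hits: pd.DataFrame,
    evalue_max: float = 1e-6,
    identity_min: float = 50.0,
    coverage_min: float = 80.0,
) -> pd.DataFrame:
    """Keep hits with evalue < evalue_max, identity > identity_min and
    query coverage > coverage_min (all strict); input order preserved.

    Idempotent: filtering a filtered table changes nothing.
    """
    hits = ensure_coverage(hits)
    mask = (
        (hits["evalue"] < evalue_max)
        & (hits["pident"] > identity_min)
        & (hits["qcovs"] > coverage_min)
    )
    return hits.loc[mask]


# ---------------------------------------------------------------------------
# ortholog assignment


def assign_orthologs(filtered: pd.DataFrame, species: str) -> OrthologAssignment:
    """Best hit per reference protein: lowest evalue, then highest bitscore,
    then lexicographically smallest subject id.  Deterministic under any
    permutation of the input rows.
    """
    if filtered.empty:
        return OrthologAssignment(species=species, mapping={}, provenance=filtered)
    ranked = filtered.sort_values(
        by=["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates(subset="qseqid", keep="first")
    mapping = dict(zip(best["qseqid"], best["sseqid"]))
    return OrthologAssignment(species=species, mapping=mapping, provenance=best)


# ---------------------------------------------------------------------------
# interaction transfer


def transfer_interactions(
    assignments: Iterable[OrthologAssignment],
    reference_edges: Mapping[str, pd.DataFrame],
    min_score: float = 0.0,
) -> set[tuple[str, str]]:
    """Project reference interactions onto unigenes via the ortholog maps.

    For each species' edge (A, B) with both endpoints assigned (A->u, B->v),
    the unordered unigene pair {u, v} is emitted.  Self-pairs are dropped
    and duplicates within and across species collapse to one edge, so the
    result is a simple undirected edge set (sorted 2-tuples).

    Reference edges with a score column are kept when score >= min_score;
    the default 0 applies no score filtering.
    """
    edges: set[tuple[str, str]] = set()
    for asg in assignments:
        table = reference_edges.get(asg.species)
        if table is None:
            raise KeyError(f"no reference edge table for species {asg.species!r}")
        if min_score > 0 and "score" in table.columns:
            table = table.loc[table["score"] >= min_score]
        mapping = asg.mapping
        for a, b in zip(table["protein_a"], table["protein_b"]):
            u = mapping.get(a)
            v = mapping.get(b)
            if u is None or v is None or u == v:
                continue
            edges.add((u, v) if u <= v else (v, u))
    return edges


# ---------------------------------------------------------------------------
# writers


def write_assignment_tsv(assignments: Iterable[OrthologAssignment], path) -> None:
    frames = []
    for asg in assignments:
        prov = ensure_coverage(asg.provenance) if not asg.provenance.empty else asg.provenance
        for protein, unigene in sorted(asg.mapping.items()):
            row = {"species": asg.species, "protein": protein, "unigene": unigene}
            if not prov.empty:
                hit = prov.loc[prov["qseqid"] == protein].iloc[0]
                row.update(
                    evalue=hit["evalue"], identity=hit["pident"], coverage=hit["qcovs"]
                )
            frames.append(row)
    pd.DataFrame(frames).to_csv(path, sep="\t", index=False)


def write_edge_set_tsv(edges: set[tuple[str, str]], path) -> None:
    pd.DataFrame(sorted(edges), columns=["unigene_a", "unigene_b"]).to_csv(
        path, sep="\t", index=False
    )
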