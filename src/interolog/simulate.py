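"""Synthetic inputs with retained ground truth for the whole pipeline.

Real inputs to homology-transfer network inference are large and
external: reference interactomes, TBLASTN hit tables, RSEM isoform
quantifications and raw Illumina reads.  This module fabricates all of
them at configurable scale so every downstream stage can be tested
against a known answer:

* reference interactomes drawn from ER/WS/BA generators (BA giving the
  heavy-tailed degree distributions typical of curated interactomes),
* an ortholog map covering a configurable fraction of reference
  proteins, with the induced ground-truth unigene edge set,
* hit tables containing one filter-passing hit per true ortholog pair
  plus decoys that each violate exactly one threshold at its boundary
  value (E-value 1e-5, identity 50.0, coverage 80.0), pinning down the
  strict-inequality semantics,
* isoform tables whose per-gene isoform percents sum to 100,
* FASTQ reads with planted >5% N content and 3' adapter contamination,
  provenance labels retained.

All outputs are deterministic, byte-for-byte, for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .homology import BLAST_COLUMNS
from .nullmodels import MODELS, random_graph
from .unigenes import READ1_ADAPTER

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "generate_reference_interactome",
    "generate_ortholog_scenario",
    "generate_isoform_table",
    "generate_fastq_reads",
    "generate_unigene_sequences",
    "write_fastq",
    "write_fasta",
    "write_hits_tsv",
    "write_edges_tsv",
    "write_isoform_tsv",
    "write_ground_truth_json",
]

DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic homology-transfer scenario."""

    n_reference_proteins: int = 200
    n_unigenes: int = 300
    ortholog_fraction: float = 0.8
    n_species: int = 2
    reference_model: str = "BA"
    reference_edges: int = 800
    decoy_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.ortholog_fraction <= 1:
            raise ValueError("ortholog_fraction must be in [0, 1]")
        if not 0 <= self.decoy_rate <= 1:
            raise ValueError("decoy_rate must be in [0, 1]")
        for name in ("n_reference_proteins", "n_unigenes", "n_species", "reference_edges"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.reference_model.upper() not in MODELS:
            raise ValueError(f"reference_model must be one of {MODELS}")


@dataclass
class GroundTruth:
    """What the pipeline should recover from a synthetic scenario."""

    ortholog_map: dict[str, str]  # reference protein id -> unigene id
    expected_edges: set[tuple[str, str]]  # sorted unigene-id pairs, no self-pairs


@dataclass
class Scenario:
    """A complete synthetic scenario: inputs plus retained truth.

    ``hits[species]`` is a BLAST-tabular DataFrame (with qlen/slen);
    ``hit_labels[species]`` marks each row "true", "decoy_evalue",
    "decoy_identity" or "decoy_coverage".  The ortholog map is shared
    across species; decoys are drawn independently per species.
    """

    config: ScenarioConfig
    truth: GroundTruth
    proteins: list[str]
    unigenes: list[str]
    reference_edges: dict[str, pd.DataFrame]
    hits: dict[str, pd.DataFrame]
    hit_labels: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference interactome


def generate_reference_interactome(
    model: str, n: int, e: int, seed: int = 0, prefix: str = "P"
) -> tuple[pd.DataFrame, list[str]]:
    """Labelled simple interactome with exactly n proteins and e edges.

    The topology comes from the requested null-model generator; node
    integers are relabelled to zero-padded protein ids.  The edge table
    carries a STRING-like combined score in [150, 999].
    """
    g = random_graph(model, n, e, seed=seed)
    width = len(str(n - 1))
    ids = [f"{prefix}{i:0{width}d}" for i in range(n)]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    rows = sorted(
        (ids[u], ids[v]) if ids[u] <= ids[v] else (ids[v], ids[u])
        for u, v in g.edges()
    )
    scores = rng.integers(150, 1000, size=len(rows))
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b"])
    df["score"] = scores
    return df, ids


# ---------------------------------------------------------------------------
# ortholog scenario with hit tables


def _passing_hit(rng, protein, unigene):
    qlen = int(rng.integers(100, 1001))
    cov_frac = rng.uniform(0.81, 1.0)
    qend = min(qlen, int(np.ceil(cov_frac * qlen)))
    pident = round(rng.uniform(50.5, 99.9), 2)
    evalue = float(10.0 ** rng.uniform(-50, -7))
    span = qend  # qstart = 1
    return _hit_row(rng, protein, unigene, pident, span, 1, qend, evalue, qlen)


def _hit_row(rng, protein, unigene, pident, align_len, qstart, qend, evalue, qlen):
    mismatch = int(round(align_len * (100 - pident) / 100))
    bitscore = round(float(rng.uniform(80, 500)), 1)
    slen = 3 * qlen + int(rng.integers(0, 500))
    sstart = 1
    send = min(slen, 3 * align_len)
    return [
        protein, unigene, pident, align_len, mismatch, 0,
        qstart, qend, sstart, send, evalue, bitscore, qlen, slen,
    ]


def _decoy_hit(rng, protein, unigene, kind):
    """A hit violating exactly ``kind`` at its boundary, passing the others."""
    if kind == "decoy_coverage":
        qlen = int(rng.integers(20, 200)) * 5
        qend = int(0.8 * qlen)  # coverage exactly 80.0 -> fails strict >80
        pident = round(rng.uniform(50.5, 99.9), 2)
        evalue = float(10.0 ** rng.uniform(-50, -7))
    else:
        qlen = int(rng.integers(100, 1001))
        qend = min(qlen, int(np.ceil(rng.uniform(0.81, 1.0) * qlen)))
        if kind == "decoy_evalue":
            pident = round(rng.uniform(50.5, 99.9), 2)
            evalue = 1e-5  # not < 1e-6
        elif kind == "decoy_identity":
            pident = 50.0  # not > 50
            evalue = float(10.0 ** rng.uniform(-50, -7))
        else:
            raise ValueError(kind)
    return _hit_row(rng, protein, unigene, pident, qend, 1, qend, evalue, qlen)


def generate_ortholog_scenario(config: ScenarioConfig) -> Scenario:
    """Build reference interactomes, an ortholog map, and noisy hit tables.

    Postconditions: every true ortholog pair has exactly one hit passing
    all three filters; each decoy violates exactly one filter at its
    boundary value; ``truth.expected_edges`` is the image of the reference
    edges under the ortholog map with self-pairs dropped and duplicates
    collapsed.  Filtering + assignment + transfer on these tables must
    recover ``expected_edges`` exactly — that identity is the module's
    oracle.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_map, rng_net, *rng_species = [
        np.random.default_rng(s) for s in ss.spawn(2 + config.n_species)
    ]

    n_ref = config.n_reference_proteins
    wid_u = len(str(config.n_unigenes - 1)) if config.n_unigenes > 1 else 1
    unigenes = [f"UG{i:0{wid_u}d}" for i in range(config.n_unigenes)]

    # one shared topology, relabelled per species
    species_names = [f"SP{i + 1}" for i in range(config.n_species)]
    reference_edges: dict[str, pd.DataFrame] = {}
    proteins_by_species: dict[str, list[str]] = {}
    for i, sp in enumerate(species_names):
        edges, prots = generate_reference_interactome(
            config.reference_model,
            n_ref,
            config.reference_edges,
            seed=int(ss.generate_state(1)[0] % (2**31)) + i,
            prefix=f"{sp}_",
        )
        reference_edges[sp] = edges
        proteins_by_species[sp] = prots

    # shared ortholog map defined on protein index, applied per species
    n_map = int(round(config.ortholog_fraction * n_ref))
    mapped_idx = np.sort(rng_map.choice(n_ref, size=n_map, replace=False))
    if n_map <= config.n_unigenes:
        targets = rng_map.choice(config.n_unigenes, size=n_map, replace=False)
    else:
        targets = rng_map.choice(config.n_unigenes, size=n_map, replace=True)
    index_map = {int(i): unigenes[int(t)] for i, t in zip(mapped_idx, targets)}

    ortholog_map: dict[str, str] = {}
    for sp in species_names:
        prots = proteins_by_species[sp]
        for i, u in index_map.items():
            ortholog_map[prots[i]] = u

    # expected unigene edges: union over species of mapped reference edges
    expected: set[tuple[str, str]] = set()
    for sp in species_names:
        for a, b in zip(
            reference_edges[sp]["protein_a"], reference_edges[sp]["protein_b"]
        ):
            u, v = ortholog_map.get(a), ortholog_map.get(b)
            if u is None or v is None or u == v:
                continue
            expected.add((u, v) if u <= v else (v, u))

    hits: dict[str, pd.DataFrame] = {}
    hit_labels: dict[str, list[str]] = {}
    cols = BLAST_COLUMNS + ["qlen", "slen"]
    for sp, rng in zip(species_names, rng_species):
        rows, labels = [], []
        prots = proteins_by_species[sp]
        for i, u in index_map.items():
            protein = prots[i]
            rows.append(_passing_hit(rng, protein, u))
            labels.append("true")
            for kind in ("decoy_evalue", "decoy_identity", "decoy_coverage"):
                if rng.random() < config.decoy_rate:
                    target = unigenes[int(rng.integers(config.n_unigenes))]
                    rows.append(_decoy_hit(rng, protein, target, kind))
                    labels.append(kind)
        hits[sp] = pd.DataFrame(rows, columns=cols)
        hit_labels[sp] = labels

    truth = GroundTruth(ortholog_map=ortholog_map, expected_edges=expected)
    return Scenario(
        config=config,
        truth=truth,
        proteins=[p for sp in species_names for p in proteins_by_species[sp]],
        unigenes=unigenes,
        reference_edges=reference_edges,
        hits=hits,
        hit_labels=hit_labels,
    )


# ---------------------------------------------------------------------------
# isoform tables


def generate_isoform_table(
    n_genes: int, max_isoforms: int = 5, seed: int = 0
) -> pd.DataFrame:
    """RSEM-like isoform table; per-gene isoform percents sum to 100."""
    if n_genes < 1 or max_isoforms < 1:
        raise ValueError("n_genes and max_isoforms must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for gi in range(n_genes):
        gene = f"GENE{gi:05d}"
        k = int(rng.integers(1, max_isoforms + 1))
        counts = rng.gamma(shape=2.0, scale=50.0, size=k) + 0.5
        pct = counts / counts.sum() * 100.0
        for ti in range(k):
            rows.append(
                {
                    "transcript_id": f"{gene}_i{ti + 1}",
                    "gene_id": gene,
                    "length": int(rng.integers(200, 3001)),
                    "expected_count": round(float(counts[ti]), 2),
                    "isoform_percent": float(pct[ti]),
                }
            )
    df = pd.DataFrame(rows)
    # re-derive percents from the rounded counts so the table is self-consistent
    totals = df.groupby("gene_id")["expected_count"].transform("sum")
    df["isoform_percent"] = df["expected_count"] / totals * 100.0
    return df


# ---------------------------------------------------------------------------
# reads


def generate_fastq_reads(
    n_reads: int,
    read_len: int = 100,
    n_rate: float = 0.1,
    adapter_rate: float = 0.1,
    seed: int = 0,
    adapter: str = READ1_ADAPTER,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Reads with planted defects and a provenance table.

    A ``n_rate`` fraction of reads gets >5% N bases (relative to its
    post-trimming length); an ``adapter_rate`` fraction carries a >= 8 nt
    prefix of the 3' adapter at its end.  Qualities are constant Phred 40.
    The returned frame has columns read_id, high_n, adapter, expected_kept.
    """
    if not (0 <= n_rate <= 1 and 0 <= adapter_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records, meta = [], []
    for i in range(n_reads):
        bases = DNA[rng.integers(0, 4, size=read_len)]
        has_adapter = bool(rng.random() < adapter_rate)
        a_len = 0
        if has_adapter:
            a_len = int(rng.integers(8, min(len(adapter), read_len) + 1))
            bases[read_len - a_len :] = list(adapter[:a_len])
        kept_len = read_len - a_len
        high_n = bool(rng.random() < n_rate) and kept_len > 0
        if high_n:
            n_needed = int(np.floor(0.05 * kept_len)) + 1
            pos = rng.choice(kept_len, size=min(n_needed, kept_len), replace=False)
            bases[pos] = "N"
            high_n = len(pos) / kept_len > 0.05
        read_id = f"read{i:06d}"
        rec = SeqRecord(Seq("".join(bases)), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * read_len
        records.append(rec)
        meta.append(
            {
                "read_id": read_id,
                "high_n": high_n,
                "adapter": has_adapter,
                "expected_kept": not high_n,
            }
        )
    return records, pd.DataFrame(meta)


def generate_unigene_sequences(
    n: int, seed: int = 0, min_len: int = 301, max_len: int = 3000
) -> list[SeqRecord]:
    """Random nucleotide unigene sequences (uniform composition)."""
    rng = np.random.default_rng(seed)
    wid = len(str(n - 1)) if n > 1 else 1
    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(DNA[rng.integers(0, 4, size=length)])
        out.append(SeqRecord(Seq(seq), id=f"UG{i:0{wid}d}", description=""))
    return out


# ---------------------------------------------------------------------------
# writers


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_hits_tsv(hits: pd.DataFrame, path) -> None:
    # BLAST outfmt-6 dialect: no header line
    hits.to_csv(path, sep="\t", index=False, header=False)


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_isoform_tsv(table: pd.DataFrame, path) -> None:
    out = table.rename(columns={"isoform_percent": "IsoPct"})
    out.to_csv(path, sep="\t", index=False)


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "ortholog_map": dict(sorted(truth.ortholog_map.items())),
        "expected_edges": sorted(list(e) for e in truth.expected_edges),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
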