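"""Plain-text readers and writers for every pipeline artefact.

All tabular formats are tab-separated with a header row; FASTA goes
through Biopython; the ontology is a minimal OBO subset (id / name /
namespace / is_a stanzas). Writers sort or preserve deterministic
orderings so identical inputs yield byte-identical files.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import HITS_COLUMNS, AlignmentHit, dataframe_to_hits, hits_to_dataframe
from .config import SimulationConfig
from .simulate import (
    PlantedTruth,
    generate_alignment_table,
    generate_counts,
    generate_reference,
)

FLOAT_FORMAT = "%.6g"


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_hits(hits: Iterable[AlignmentHit], path) -> None:
    write_tsv(hits_to_dataframe(hits), path)


def read_hits(path) -> list[AlignmentHit]:
    df = read_tsv(path, dtype={c: str for c in ("query_id", "subject_id", "subject_db", "orientation")})
    return dataframe_to_hits(df)


def write_counts(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = "transcript_id"
    write_tsv(out, path, index=True)


def read_counts(path) -> pd.DataFrame:
    return read_tsv(path, index_col="transcript_id")


def write_gene_map(gene_map: Mapping[str, str], path) -> None:
    df = pd.DataFrame(
        sorted(gene_map.items()), columns=["transcript_id", "gene_id"]
    )
    write_tsv(df, path)


def read_gene_map(path) -> dict[str, str]:
    df = read_tsv(path, dtype=str)
    return dict(zip(df["transcript_id"], df["gene_id"]))


def read_ortholog_map(path) -> dict[str, str]:
    df = read_tsv(path, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_ortholog_map(mapping: Mapping[str, str], path) -> None:
    df = pd.DataFrame(sorted(mapping.items()), columns=["gene_id", "ortholog_group"])
    write_tsv(df, path)


def truth_to_dataframe(truth: PlantedTruth, config: SimulationConfig) -> pd.DataFrame:
    contrasts = [
        g for g in config.design.groups() if g[0] != config.design.unconditioned_label
    ]
    rows = []
    for tid in truth.transcripts():
        cds = truth.cds_interval.get(tid)
        row = {
            "transcript_id": tid,
            "gene_id": truth.gene_map[tid],
            "planted_class": truth.planted_class[tid],
            "structural_class": truth.transcript_class[tid],
            "gene_role": truth.gene_role.get(truth.gene_map[tid], ""),
            "decoy": tid in truth.decoy_cov,
            "length": truth.transcript_length[tid],
            "cds_start": cds[0] if cds else -1,
            "cds_end": cds[1] if cds else -1,
            "sense_partner": truth.sense_partner.get(tid, ""),
            "zones": ",".join(sorted(truth.zone_truth.get(tid, frozenset()))),
        }
        for ct, tp in contrasts:
            row[f"lfc_{ct}@{tp}"] = truth.log2fc(tid, (ct, tp))
        rows.append(row)
    return pd.DataFrame(rows)


def write_bundle(config: SimulationConfig, outdir) -> PlantedTruth:
    """Generate and write the full fixture bundle for one species."""
    os.makedirs(outdir, exist_ok=True)
    proteins, transcripts, gene_map, truth = generate_reference(config)
    hits = generate_alignment_table(truth, config)
    counts, meta = generate_counts(truth, config)

    write_fasta(proteins, os.path.join(outdir, "proteins.fasta"))
    write_fasta(transcripts, os.path.join(outdir, "transcripts.fasta"))
    write_gene_map(gene_map, os.path.join(outdir, "genes.tsv"))
    write_hits(hits, os.path.join(outdir, "hits.tsv"))
    write_counts(counts, os.path.join(outdir, "counts.tsv"))
    write_tsv(meta, os.path.join(outdir, "samples.tsv"))
    write_tsv(truth_to_dataframe(truth, config), os.path.join(outdir, "truth.tsv"))

    obo, annotations, slim = make_synthetic_ontology(config, truth)
    with open(os.path.join(outdir, "ontology.obo"), "w") as fh:
        fh.write(obo)
    ann_rows = [
        {"gene_id": g, "term_id": t}
        for g in sorted(annotations)
        for t in sorted(annotations[g])
    ]
    write_tsv(
        pd.DataFrame(ann_rows, columns=["gene_id", "term_id"]),
        os.path.join(outdir, "annotations.tsv"),
    )
    with open(os.path.join(outdir, "slim.txt"), "w") as fh:
        fh.write("\n".join(slim) + "\n")
    return truth


def read_annotations_tsv(path) -> dict[str, set[str]]:
    df = read_tsv(path, dtype=str)
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term_id"]):
        out.setdefault(g, set()).add(t)
    return out


_SLIM_NAMES = [
    ("biological_process", "signal transduction"),
    ("biological_process", "ion transport"),
    ("biological_process", "carbohydrate metabolic process"),
    ("biological_process", "homeostatic process"),
    ("molecular_function", "kinase activity"),
    ("molecular_function", "transmembrane transporter activity"),
    ("molecular_function", "electron carrier activity"),
    ("molecular_function", "cytoskeletal protein binding"),
]


def make_synthetic_ontology(
    config: SimulationConfig, truth: PlantedTruth, n_leaves_per_slim: int = 4
) -> tuple[str, dict[str, set[str]], list[str]]:
    """A small GO-like DAG: two namespace roots, eight slim terms and a
    layer of leaf terms, each leaf is_a one or two slim terms. Sense
    genes are annotated with one to three leaves; genes carrying a
    planted expression role are biased toward the first slim branch so
    the enrichment stage has signal to find."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    roots = {
        "biological_process": "SYN:0000001",
        "molecular_function": "SYN:0000002",
    }
    lines = ["format-version: 1.2", "ontology: synthetic-slim", ""]

    def stanza(tid, name, ns, parents):
        out = ["[Term]", f"id: {tid}", f"name: {name}", f"namespace: {ns}"]
        out += [f"is_a: {p}" for p in parents]
        out.append("")
        return out

    for ns, tid in roots.items():
        lines += stanza(tid, f"{ns} root", ns, [])
    slim_ids = []
    for k, (ns, name) in enumerate(_SLIM_NAMES):
        tid = f"SYN:{1000 + k:07d}"
        slim_ids.append(tid)
        lines += stanza(tid, name, ns, [roots[ns]])
    leaf_ids = []
    leaf_parent: dict[str, list[str]] = {}
    for k, slim in enumerate(slim_ids):
        for j in range(n_leaves_per_slim):
            tid = f"SYN:{2000 + k * n_leaves_per_slim + j:07d}"
            parents = [slim]
            if rng.random() < 0.25:
                other = slim_ids[int(rng.integers(0, len(slim_ids)))]
                if other != slim:
                    parents.append(other)
            leaf_ids.append(tid)
            leaf_parent[tid] = parents
            lines += stanza(tid, f"leaf term {k}.{j}", _SLIM_NAMES[k][0], parents)

    sense_genes = sorted(
        {g for t, g in truth.gene_map.items() if truth.planted_class[t] == "sense"}
    )
    first_branch = leaf_ids[:n_leaves_per_slim]
    annotations: dict[str, set[str]] = {}
    for g in sense_genes:
        n_terms = int(rng.integers(1, 4))
        if truth.gene_role.get(g):
            # planted-role genes concentrate in the first slim branch
            terms = {first_branch[int(rng.integers(0, len(first_branch)))]}
            extra = rng.choice(len(leaf_ids), size=n_terms - 1, replace=False)
            terms |= {leaf_ids[i] for i in extra}
        else:
            picks = rng.choice(len(leaf_ids), size=n_terms, replace=False)
            terms = {leaf_ids[i] for i in picks}
        annotations[g] = terms
    return "\n".join(lines) + "\n", annotations, slim_ids
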