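"""Reading and writing the pipeline's on-disk formats.

Everything tabular is TSV; gene sets are GMT (name, description, members,
tab-separated — the description column carries the provenance string, which
is why reading goes through this module rather than a collection-oriented
GMT reader that discards it); simulated reads are FASTA via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import ConfigError, CountMatrix, GeneSet

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_fasta_reads",
    "write_fasta_reads",
    "write_provenance",
]


def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Load a count matrix (gene_id, length_bp, sample columns) and its
    sample metadata TSV (sample_id, genotype[, region, stage])."""
    try:
        df = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ConfigError(f"malformed counts TSV {counts_path}: {exc}") from exc
    if "length_bp" not in df.columns:
        raise ConfigError(f"{counts_path}: missing 'length_bp' column")
    lengths = df.pop("length_bp")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return CountMatrix(counts=df, lengths=lengths, samples=meta)


def write_counts(cm: CountMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length_bp", cm.lengths)
    out.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ConfigError(f"{path}:{lineno}: GMT line needs name and description")
            name, desc, *members = parts
            sets.append(GeneSet(name, frozenset(m for m in members if m),
                                {"source": str(path), "description": desc}))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            desc = json.dumps(dict(gs.provenance), sort_keys=True, default=str)
            fh.write("\t".join([gs.name, desc, *sorted(gs.members)]) + "\n")


def read_fasta_reads(path: str | Path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta_reads(reads: Iterable[str], path: str | Path) -> None:
    records = (SeqRecord(Seq(r), id=f"read_{i}", description="")
               for i, r in enumerate(reads))
    SeqIO.write(records, str(path), "fasta")


def write_provenance(path: str | Path, record: Mapping[str, object]) -> None:
    """Machine-readable record of inputs, thresholds and seed for a run."""
    with open(path, "w") as fh:
        json.dump(dict(record), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
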