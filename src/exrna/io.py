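"""Readers and writers for the pipeline's on-disk formats.

FASTA headers carry ``species_id|library_class``; FASTQ is Phred+33 with a
constant quality; Cq matrices are TSV with rows = samples, columns = assays
and the sentinel ``ND`` for non-detects.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import ReferenceSet, RefEntry, SimulatedReadSet

ND_SENTINEL = "ND"
FASTQ_QUALITY = 40  # constant per-base quality


def write_reference_fasta(refset: ReferenceSet, path) -> None:
    records = [
        SeqRecord(
            Seq(e.sequence),
            id=f"{e.species_id}|{e.library_class}",
            description="",
        )
        for e in refset.entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path, class_order=None) -> ReferenceSet:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species_id, _, cls = rec.id.partition("|")
        if not cls:
            raise ValueError(
                f"{rec.id}: FASTA header must be 'species_id|class'"
            )
        entries.append(RefEntry(species_id, cls, str(rec.seq).upper()))
    if class_order is None:
        # canonical ordering restricted to the classes actually present
        from .synthetic_data import DEFAULT_CLASS_ORDER, SCREEN_CLASSES

        present = {e.library_class for e in entries}
        class_order = tuple(
            c for c in DEFAULT_CLASS_ORDER if c in present
        ) + tuple(
            sorted(present - set(DEFAULT_CLASS_ORDER) - set(SCREEN_CLASSES))
        )
    return ReferenceSet(entries, class_order=tuple(class_order))


def write_fastq(readset: SimulatedReadSet, path) -> None:
    records = []
    for rid, seq in readset.reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [FASTQ_QUALITY] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path),
                                                              "fastq")
    ]


def write_cq_tsv(cq: pd.DataFrame, path) -> None:
    out = cq.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=ND_SENTINEL)


def read_cq_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col="sample_id", na_values=[ND_SENTINEL]
    )
    return df.astype(float)


def write_truth_tsv(truth: dict[str, str], path, key="read_id",
                    value="species_id") -> None:
    pd.Series(truth, name=value).rename_axis(key).to_csv(path, sep="\t")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("sample_id").to_csv(path, sep="\t")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_flat_config(path) -> dict:
    """Flat key/value config: YAML-compatible ``key: value`` lines."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected flat key/value mapping")
    return cfg


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
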