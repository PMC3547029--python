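"""File formats: FASTA/FASTQ input, BED/TSV output, config echo.

Sequence input goes through Biopython with transparent gzip support;
array tables round-trip through TSV so downstream stages can run from
files as well as in memory.  BED output is 0-based half-open (standard
BED); RepeatMasker ``.out`` input is converted from its 1-based
inclusive convention at parse time (see :mod:`microsat.te`).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from .arrays import RepeatArray
from .motifs import canonical_class

__all__ = [
    "read_fasta",
    "read_fastq",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "arrays_to_frame",
    "write_arrays_tsv",
    "read_arrays_tsv",
    "write_arrays_bed",
    "read_chrom_sizes",
    "read_recomb_map",
    "echo_config",
    "write_run_log",
]

ARRAY_COLUMNS = [
    "seq_id",
    "start",
    "end",
    "canonical",
    "period",
    "observed_strand_kmer",
    "start_kmer",
    "end_kmer",
    "length_bp",
    "unit_count",
    "edge",
]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA file (gzip transparent)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ file; qualities are ignored."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def read_sequences(path) -> Iterator[tuple[str, str]]:
    """FASTA or FASTQ by extension (``.fq``/``.fastq`` -> FASTQ)."""
    stem = Path(path).name.removesuffix(".gz")
    if stem.endswith((".fq", ".fastq")):
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(path, records: Mapping[str, str] | Iterable[tuple[str, str]]):
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(path, reads: Iterable[tuple[str, str]], quality_char: str = "I"):
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def arrays_to_frame(arrays: Iterable[RepeatArray]) -> pd.DataFrame:
    rows = [
        {
            "seq_id": a.seq_id,
            "start": a.start,
            "end": a.end,
            "canonical": a.motif_class.canonical,
            "period": a.period,
            "observed_strand_kmer": a.observed_strand_kmer,
            "start_kmer": a.start_kmer,
            "end_kmer": a.end_kmer,
            "length_bp": a.length_bp,
            "unit_count": a.unit_count,
            "edge": a.edge,
        }
        for a in arrays
    ]
    return pd.DataFrame(rows, columns=ARRAY_COLUMNS)


def write_arrays_tsv(path, arrays: Iterable[RepeatArray]) -> None:
    arrays_to_frame(arrays).to_csv(path, sep="\t", index=False)


def read_arrays_tsv(path) -> list[RepeatArray]:
    """Inverse of :func:`write_arrays_tsv`; reconstructs RepeatArray records."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            RepeatArray(
                seq_id=row.seq_id,
                start=int(row.start),
                end=int(row.end),
                motif_class=canonical_class(row.canonical),
                observed_strand_kmer=row.observed_strand_kmer,
                start_kmer=row.start_kmer,
                end_kmer=row.end_kmer,
                length_bp=int(row.length_bp),
                unit_count=int(row.unit_count),
                edge=row.edge,
            )
        )
    return out


def write_arrays_bed(path, arrays: Iterable[RepeatArray]) -> None:
    """BED6-like output: name holds class and start/end k-mers, score is
    the array length, strand column carries the observed-strand motif's
    orientation relative to the canonical representative."""
    with open(path, "w") as fh:
        for a in arrays:
            strand = (
                "+"
                if _same_strand(a.observed_strand_kmer, a.motif_class.canonical)
                else "-"
            )
            name = f"{a.motif_class.canonical}|{a.start_kmer}|{a.end_kmer}"
            fh.write(
                f"{a.seq_id}\t{a.start}\t{a.end}\t{name}\t{a.length_bp}\t{strand}\n"
            )


def _same_strand(kmer: str, canonical: str) -> bool:
    rots = {canonical[i:] + canonical[:i] for i in range(len(canonical))}
    return kmer in rots


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, size = line.split()[:2]
                sizes[name] = int(size)
    return sizes


def read_recomb_map(path) -> pd.DataFrame:
    """Tab-separated (chrom, pos, rate in cM/Mb), header optional."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [str(c).lower() for c in df.columns]
    if "pos" in cols and "rate" in cols:
        df.columns = cols
    else:
        try:
            df = pd.read_csv(
                path, sep="\t", header=None,
                names=["chrom", "pos", "rate"], comment="#",
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"malformed recombination map {path}: {exc}")
    try:
        out = df[["chrom", "pos", "rate"]].copy()
        out["pos"] = pd.to_numeric(out["pos"])
        out["rate"] = pd.to_numeric(out["rate"])
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"malformed recombination map {path}: {exc}")
    return out


def echo_config(out_dir, config: Mapping) -> Path:
    """Write the run configuration verbatim into the output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
    return path


def write_run_log(out_dir, **entries) -> Path:
    """Machine-readable run log (inputs, version, seed, thresholds)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_log.json"
    payload = {"microsat_version": __version__}
    payload.update(entries)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path
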