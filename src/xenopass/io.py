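"""Readers, writers and configuration.

Coordinate conventions, centralized here: BED is 0-based half-open; the
ortholog/gene/exon TSV dialects are 1-based inclusive at the file boundary
and converted to the internal 0-based half-open representation on read.
QUAL companions use classic space-separated phred integers; FASTQ with
phred+33 qualities is accepted as an alternative read input.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mutcall import TraceRead
from .synteny import OrthologMap

# -- coordinate conversions (single source of truth) -------------------------

def to_file_coords(start0: int, end0: int) -> tuple[int, int]:
    """Internal 0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def to_internal_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> internal 0-based half-open."""
    return start1 - 1, end1


# -- FASTA + QUAL -------------------------------------------------------------

def _orientation_from_id(record_id: str) -> str:
    return "reverse" if record_id.endswith((".r", "/2", ".rev")) else "forward"


def read_fasta_qual(fasta_path: str | Path, qual_path: str | Path) -> list[TraceRead]:
    """Paired FASTA/QUAL records -> TraceReads (ids must correspond 1:1).

    Orientation is taken from the id suffix (``.r``, ``.rev`` or ``/2`` mean
    reverse).  Mismatched ids or base/quality length disagreement raise with
    the offending record named.
    """
    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    quals = list(SeqIO.parse(str(qual_path), "qual"))
    if len(seqs) != len(quals):
        raise ValueError(
            f"{fasta_path} has {len(seqs)} records but {qual_path} has {len(quals)}"
        )
    reads = []
    for s, q in zip(seqs, quals):
        if s.id != q.id:
            raise ValueError(f"record id mismatch: {s.id!r} (fasta) vs {q.id!r} (qual)")
        phred = q.letter_annotations["phred_quality"]
        if len(phred) != len(s.seq):
            raise ValueError(
                f"record {s.id!r}: {len(s.seq)} bases but {len(phred)} quality values"
            )
        reads.append(
            TraceRead(s.id, _orientation_from_id(s.id), str(s.seq).upper(), np.asarray(phred, int))
        )
    return reads


def write_fasta_qual(reads: Sequence[TraceRead], fasta_path: str | Path, qual_path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        records.append(rec)
    SeqIO.write(records, str(fasta_path), "fasta")
    SeqIO.write(records, str(qual_path), "qual")


def read_fastq(path: str | Path) -> list[TraceRead]:
    return [
        TraceRead(
            rec.id,
            _orientation_from_id(rec.id),
            str(rec.seq).upper(),
            np.asarray(rec.letter_annotations["phred_quality"], int),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


# -- BED ----------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """3+ column BED (0-based half-open) -> frame with chrom/start/end[/name/score/strand].

    The optional 4th column is reused as the repeat ``family`` label by the
    synteny module.
    """
    names = ["chrom", "start", "end", "name", "score", "strand"]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            row = dict(zip(names, parts[:6]))
            row["start"], row["end"] = int(row["start"]), int(row["end"])
            if row["start"] > row["end"]:
                raise ValueError(f"{path}:{lineno}: start > end")
            rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty and "name" in frame.columns:
        frame = frame.rename(columns={"name": "family"})
    return frame


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"]
    extra = [c for c in ("family", "name", "score", "strand") if c in frame.columns]
    frame[cols + extra].to_csv(path, sep="\t", header=False, index=False)


# -- ortholog / exon tables ---------------------------------------------------

def read_ortholog_table(path: str | Path) -> OrthologMap:
    """TSV with columns gene_id, genome, chrom, start, end, strand
    (1-based inclusive) -> OrthologMap (internal 0-based half-open)."""
    frame = pd.read_csv(path, sep="\t")
    frame = frame.copy()
    starts, ends = zip(*(to_internal_coords(s, e) for s, e in zip(frame["start"], frame["end"])))
    frame["start"], frame["end"] = starts, ends
    return OrthologMap.from_frame(frame)


def write_ortholog_table(omap: OrthologMap, path: str | Path) -> None:
    frame = omap.to_frame()
    file_coords = [to_file_coords(s, e) for s, e in zip(frame["start"], frame["end"])]
    frame["start"] = [c[0] for c in file_coords]
    frame["end"] = [c[1] for c in file_coords]
    frame.to_csv(path, sep="\t", index=False)


def read_exon_table(path: str | Path) -> pd.DataFrame:
    """Exon models TSV: gene, ordinal, chrom, start, end, strand, coding,
    cds_offset (1-based inclusive coordinates, converted on read)."""
    frame = pd.read_csv(path, sep="\t")
    starts, ends = zip(*(to_internal_coords(s, e) for s, e in zip(frame["start"], frame["end"])))
    frame = frame.copy()
    frame["start"], frame["end"] = starts, ends
    frame["coding"] = frame["coding"].astype(bool)
    return frame


# -- config -------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
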