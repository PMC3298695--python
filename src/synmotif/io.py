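"""FASTA ingestion with frame policing, and tabular/report output.

Input sequences must be in-frame CDS: hanging 3' bases are truncated (or the
record rejected, by policy), records with non-ACGT characters or internal
stop codons are dropped with a logged warning, and a terminal stop codon is
detached from the modeled sequence — it fixes the 3' boundary base to 'T'
and motifs are never sought overlapping it.  Coordinates are 0-based
half-open internally and 1-based inclusive in human-readable logs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .engine import CodingSequence
from .errors import AdmissionError, FrameError
from .genetic_code import BASES, STANDARD_CODE, STOP_SYMBOL
from .stats import MotifResult

logger = logging.getLogger("synmotif")

_ACGT = set(BASES)


@dataclass
class RunConfig:
    """Configuration of one scoring run (mirrors the CLI options)."""

    reference_path: str
    query_path: str
    motif_specs: list[str] = field(default_factory=list)
    motif_file: str | None = None
    model_choice: str = "dcm"
    pseudocount: float = 0.0
    include_revcomp: bool = False
    emit_distribution: bool = False
    min_mean_for_ratio: float = 0.0
    frame_policy: str = "truncate"
    rng_seed: int | None = None
    output_path: str | None = None


def read_coding_fasta(
    path: str, frame_policy: str = "truncate"
) -> list[CodingSequence]:
    """Read a multi-FASTA of CDS into validated :class:`CodingSequence`\\ s.

    ``frame_policy='truncate'`` trims the 3' remainder of out-of-frame
    records (with a warning); ``'reject'`` raises instead.
    """
    if frame_policy not in ("truncate", "reject"):
        raise ValueError(f"unknown frame policy {frame_policy!r}")
    out: list[CodingSequence] = []
    for record in SeqIO.parse(path, "fasta"):
        nt = str(record.seq).upper()
        rem = len(nt) % 3
        if rem:
            if frame_policy == "reject":
                raise FrameError(
                    f"sequence {record.id!r} length {len(nt)} is not a "
                    "multiple of 3"
                )
            logger.warning(
                "sequence %r: trimming %d hanging 3' base(s)", record.id, rem
            )
            nt = nt[: len(nt) - rem]
        if not nt:
            logger.warning("sequence %r: empty after trimming; dropped", record.id)
            continue
        if not set(nt) <= _ACGT:
            logger.warning(
                "sequence %r: non-ACGT characters; dropped", record.id
            )
            continue
        aa = STANDARD_CODE.translate_cds(nt)
        core = aa[:-1] if aa.endswith(STOP_SYMBOL) else aa
        if STOP_SYMBOL in core:
            logger.warning(
                "sequence %r: internal stop codon at codon %d; dropped",
                record.id,
                core.index(STOP_SYMBOL) + 1,
            )
            continue
        out.append(CodingSequence.from_cds(record.id, nt))
    if not out:
        raise AdmissionError(f"no admissible coding sequences in {path}")
    return out


def write_fasta(seqs: Iterable[CodingSequence], path: str,
                append_stop: bool = False) -> None:
    records = [
        SeqRecord(
            Seq(s.nt + ("TAA" if append_stop and s.has_terminal_stop else "")),
            id=s.id,
            description="",
        )
        for s in seqs
    ]
    SeqIO.write(records, path, "fasta")


def _fmt(x: float | None, digits: int = 6) -> str:
    return "NA" if x is None else f"{x:.{digits}g}"


def write_results_tsv(results: Iterable[MotifResult], fh: TextIO) -> None:
    """Report table: motif, observed, mean, z, count_ratio, p_over, p_under."""
    fh.write("motif\tobserved\tmean\tz\tcount_ratio\tp_over\tp_under\n")
    for r in results:
        fh.write(
            f"{r.motif_label}\t{r.observed}\t{_fmt(r.mean)}\t{_fmt(r.z)}\t"
            f"{_fmt(r.count_ratio)}\t{_fmt(r.p_over)}\t{_fmt(r.p_under)}\n"
        )


def write_distribution_tsv(result: MotifResult, path: str) -> None:
    if result.distribution is None:
        raise ValueError("result carries no distribution")
    with open(path, "w") as fh:
        fh.write("count\tprobability\n")
        for k, p in enumerate(result.distribution.probs):
            fh.write(f"{k}\t{p:.12g}\n")


def write_manifest(path: str, **fields) -> None:
    """JSON run manifest (seeds, parameters) for reproducibility."""
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True)
        fh.write("\n")
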