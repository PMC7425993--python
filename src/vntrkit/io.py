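"""Read-stream input: FASTQ files (plain or gzip) and BAM region extraction.

The callers themselves are alignment-free; a BAM is only ever a container
from which reads near the locus are pulled before text matching.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import pysam

__all__ = ["iter_fastq", "extract_bam_region"]


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences (uppercase) from a FASTQ/FASTA file, gz or plain."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.sequence.upper()


def extract_bam_region(
    path: str | Path,
    chrom: str,
    start: int,
    end: int,
    pad: int = 10_000,
) -> list[str]:
    """Read sequences mapping within ``pad`` bases of [start, end] (1-based).

    Requires a coordinate-sorted, indexed BAM.  Secondary and supplementary
    records are skipped so each read is returned once.
    """
    lo = max(0, start - 1 - pad)
    hi = end + pad
    out = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(chrom, lo, hi):
            if rec.is_secondary or rec.is_supplementary or rec.query_sequence is None:
                continue
            out.append(rec.query_sequence.upper())
    return out
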