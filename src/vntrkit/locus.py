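"""Locus model: the tandem-repeat definition and allele sequence construction.

A :class:`VNTRLocus` is the single source of truth for the repeat unit, the
flanking sequences and the genomic coordinates of the reference repeat array.
Every other module builds its sequences (allele haplotypes, k-mer panels,
spanning-read patterns, PCR amplicons) from this object.

Coordinates in configs are 1-based inclusive; all internal arithmetic is
0-based half-open.  :func:`load_locus_config` and the ``start``/``end``
fields are the only place the two conventions meet.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VNTRLocus",
    "AlleleSequence",
    "build_allele_sequence",
    "predict_amplicon_length",
    "find_care_motifs",
    "load_locus_config",
    "synthetic_locus",
    "reverse_complement",
]

_VALID = re.compile(r"^[ACGTN]*$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Degenerate C/EBP-ATF response element on the sense strand.
CARE_MOTIF = re.compile(r"TT[GA]CATCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VNTRLocus:
    """Definition of a variable-number tandem repeat locus.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        1-based inclusive coordinates of the reference repeat array.
    unit_seq : str
        Repeat-unit sequence (length ``U``); no ambiguity codes.
    ref_copies : int
        Copy number of the array in the reference genome.
    left_flank_seq, right_flank_seq : str
        Sequence immediately 5' / 3' of the array.  At least ~200 nt each
        is recommended so k-mer normalisation windows and simulated reads
        have room to work with.
    """

    chrom: str
    start: int
    end: int
    unit_seq: str
    ref_copies: int
    left_flank_seq: str
    right_flank_seq: str

    def __post_init__(self) -> None:
        if not self.unit_seq or len(self.unit_seq) < 7:
            raise ValueError(
                f"repeat unit must be >= 7 bp (VNTR definition), got {len(self.unit_seq)}"
            )
        if "N" in self.unit_seq or not _VALID.match(self.unit_seq):
            raise ValueError("unit_seq must contain only A/C/G/T")
        for name in ("left_flank_seq", "right_flank_seq"):
            if not _VALID.match(getattr(self, name)):
                raise ValueError(f"{name} must contain only A/C/G/T/N")
        if self.ref_copies < 1:
            raise ValueError("ref_copies must be >= 1")
        span = self.end - self.start + 1
        expected = len(self.unit_seq) * self.ref_copies
        if span != expected:
            raise ValueError(
                f"coordinate span {span} != unit length x ref copies "
                f"({len(self.unit_seq)} x {self.ref_copies} = {expected})"
            )

    @property
    def unit_len(self) -> int:
        return len(self.unit_seq)

    def array_seq(self, copies: int | None = None) -> str:
        """The bare repeat array for ``copies`` copies (reference by default)."""
        c = self.ref_copies if copies is None else copies
        if c < 0:
            raise ValueError("copy number must be non-negative")
        return self.unit_seq * c


@dataclass(frozen=True)
class AlleleSequence:
    """A constructed allele: left flank + ``copy_number`` units + right flank."""

    copy_number: int
    seq: str
    left_len: int = field(default=0)
    right_len: int = field(default=0)


def build_allele_sequence(
    locus: VNTRLocus, c: int, left_len: int, right_len: int
) -> AlleleSequence:
    """Construct the sequence of a ``c``-copy allele with trimmed flanks.

    Takes the trailing ``left_len`` bases of the left flank, ``c`` copies of
    the unit, and the leading ``right_len`` bases of the right flank.
    """
    if c < 0:
        raise ValueError("copy number must be non-negative")
    if left_len < 0 or left_len > len(locus.left_flank_seq):
        raise ValueError(
            f"left_len={left_len} outside available flank "
            f"(0..{len(locus.left_flank_seq)})"
        )
    if right_len < 0 or right_len > len(locus.right_flank_seq):
        raise ValueError(
            f"right_len={right_len} outside available flank "
            f"(0..{len(locus.right_flank_seq)})"
        )
    left = locus.left_flank_seq[len(locus.left_flank_seq) - left_len :] if left_len else ""
    right = locus.right_flank_seq[:right_len]
    return AlleleSequence(
        copy_number=c,
        seq=left + locus.unit_seq * c + right,
        left_len=left_len,
        right_len=right_len,
    )


def predict_amplicon_length(locus: VNTRLocus, c: int, up: int = 23, down: int = 33) -> int:
    """Predicted PCR product length for a ``c``-copy allele.

    ``up``/``down`` are the non-repeat portions amplified upstream and
    downstream of the array; defaults match the assay used to validate
    the genotype calls on agarose gels.
    """
    if c < 0:
        raise ValueError("copy number must be non-negative")
    return locus.unit_len * c + up + down


def find_care_motifs(unit: str) -> list[int]:
    """0-based offsets of the TT(G/A)CATCA motif on the forward strand."""
    if not unit:
        raise ValueError("unit must be non-empty")
    return [m.start() for m in CARE_MOTIF.finditer(unit)]


def _read_single_fasta(path: str | Path) -> str:
    """Read the single record of a FASTA file as an uppercase string."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    return str(records[0].seq).upper()


def load_locus_config(path: str | Path) -> VNTRLocus:
    """Load a locus from a JSON config referencing per-part FASTA files.

    Expected fields: ``chrom``, ``start``, ``end`` (1-based inclusive),
    ``ref_copies``, ``unit_fasta``, ``left_flank_fasta``, ``right_flank_fasta``.
    Relative FASTA paths are resolved against the config file's directory.
    """
    path = Path(path)
    cfg = json.loads(path.read_text())
    missing = {"chrom", "start", "end", "ref_copies", "unit_fasta",
               "left_flank_fasta", "right_flank_fasta"} - cfg.keys()
    if missing:
        raise ValueError(f"locus config missing fields: {sorted(missing)}")

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else path.parent / q

    return VNTRLocus(
        chrom=cfg["chrom"],
        start=int(cfg["start"]),
        end=int(cfg["end"]),
        ref_copies=int(cfg["ref_copies"]),
        unit_seq=_read_single_fasta(resolve(cfg["unit_fasta"])),
        left_flank_seq=_read_single_fasta(resolve(cfg["left_flank_fasta"])),
        right_flank_seq=_read_single_fasta(resolve(cfg["right_flank_fasta"])),
    )


def write_locus_config(locus: VNTRLocus, outdir: str | Path, stem: str = "locus") -> Path:
    """Write a locus as JSON + FASTA files; returns the config path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    parts = {
        "unit": locus.unit_seq,
        "left_flank": locus.left_flank_seq,
        "right_flank": locus.right_flank_seq,
    }
    for name, seq in parts.items():
        with open(outdir / f"{stem}_{name}.fa", "w") as fh:
            fh.write(f">{stem}_{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    cfg = {
        "chrom": locus.chrom,
        "start": locus.start,
        "end": locus.end,
        "ref_copies": locus.ref_copies,
        "unit_fasta": f"{stem}_unit.fa",
        "left_flank_fasta": f"{stem}_left_flank.fa",
        "right_flank_fasta": f"{stem}_right_flank.fa",
    }
    cfg_path = outdir / f"{stem}.json"
    cfg_path.write_text(json.dumps(cfg, indent=2) + "\n")
    return cfg_path


def synthetic_locus(
    seed: int = 7,
    unit_len: int = 33,
    flank_len: int = 2000,
    ref_copies: int = 3,
    motif_offset: int = 13,
    start: int = 100_000,
) -> VNTRLocus:
    """A reproducible synthetic locus for tests and demos.

    The unit is random except for a TTGCATCA regulatory motif placed at
    ``motif_offset``; flanks are random.  The real promoter sequence is not
    embedded in this package — users supply it via FASTA + JSON config.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    motif = "TTGCATCA"
    if motif_offset + len(motif) > unit_len:
        raise ValueError("motif does not fit in unit")

    def rand_seq(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    from ._edit import global_edit_distance

    while True:
        unit = list(rand_seq(unit_len))
        unit[motif_offset : motif_offset + len(motif)] = motif
        unit = "".join(unit)
        left = rand_seq(flank_len)
        right = rand_seq(flank_len)
        # Reject pathological draws where a flank terminus resembles the unit
        # periphery (would blur the spanning caller's partial-vs-flank guard).
        if (
            global_edit_distance(unit[:6], right[:6]) > 2
            and global_edit_distance(unit[-6:], left[-6:]) > 2
        ):
            break
    return VNTRLocus(
        chrom="chrSim",
        start=start,
        end=start + unit_len * ref_copies - 1,
        unit_seq=unit,
        ref_copies=ref_copies,
        left_flank_seq=left,
        right_flank_seq=right,
    )
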