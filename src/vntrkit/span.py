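"""Discrete allele calling from reads spanning the repeat array.

A read fully spans a ``c``-copy allele when it contains, within an edit
tolerance, ``anchor_len`` bases of left flank + ``c`` unit copies +
``anchor_len`` bases of right flank.  Alleles too long to span are detected
from partial coverage: a read carrying the maximum fully-spannable number of
unit copies plus an adjacent repeat fragment (that cannot be explained as
flank sequence) is evidence for the open class ``C_max + 1``.

Per-sample calls aggregate read evidence with two filters: alleles
supported by fewer than ``min_allele_reads`` reads are dropped, and samples
retaining more than two alleles are excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._edit import (
    end_positions_within,
    global_edit_distance,
    min_edit_distance,
    min_hamming_distance,
)
from .locus import VNTRLocus, reverse_complement

__all__ = [
    "SpanConfig",
    "ReadCall",
    "SampleGenotype",
    "max_fully_spannable",
    "approx_contains",
    "call_read",
    "genotype_sample",
    "scan_six_plus",
]


@dataclass(frozen=True)
class SpanConfig:
    """Tolerances and filters for the spanning-read caller."""

    max_edit: int = 2
    anchor_len: int = 6
    min_partial_fragment: int = 6
    min_allele_reads: int = 2
    read_length: int = 150
    #: "edit" = full Levenshtein; "hamming" = substitution-only sensitivity mode.
    distance_mode: str = "edit"
    #: require repeat partials at BOTH ends of the 4-unit run in the >=6x scan
    #: (a single-ended partial is already explained by a C_max+1 allele).
    six_plus_both_ends: bool = True

    def __post_init__(self) -> None:
        if self.max_edit < 0 or self.min_partial_fragment < 0 or self.min_allele_reads < 0:
            raise ValueError("tolerances must be non-negative")
        if self.anchor_len < 1:
            raise ValueError("anchor_len must be >= 1")
        if self.read_length <= 2 * self.anchor_len:
            raise ValueError("read_length must exceed 2 * anchor_len")
        if self.distance_mode not in ("edit", "hamming"):
            raise ValueError("distance_mode must be 'edit' or 'hamming'")


@dataclass(frozen=True)
class ReadCall:
    """Evidence from one read: allele label, distance, and evidence kind."""

    allele: int
    edit_distance: int
    kind: str  # "full_span" or "partial"


@dataclass(frozen=True)
class SampleGenotype:
    """Filtered per-sample call.

    ``status`` is ``"called"``, ``"no_call"`` or ``"excluded_multiallelic"``.
    A called genotype carries 1 or 2 distinct allele labels; a single
    surviving label is flagged ``single_allele`` (treated as homozygous by
    the frequency code downstream).
    """

    sample: str
    status: str
    alleles: tuple[int, ...] = ()
    read_counts: dict[int, int] = field(default_factory=dict)
    raw_evidence: dict[int, int] = field(default_factory=dict)

    @property
    def single_allele(self) -> bool:
        return self.status == "called" and len(self.alleles) == 1

    def as_diploid(self) -> tuple[int, int]:
        if self.status != "called":
            raise ValueError(f"sample {self.sample} has no called genotype ({self.status})")
        if len(self.alleles) == 1:
            return (self.alleles[0], self.alleles[0])
        return (self.alleles[0], self.alleles[1])

    @property
    def diploid_mean(self) -> float:
        a, b = self.as_diploid()
        return (a + b) / 2.0


def max_fully_spannable(read_length: int, locus: VNTRLocus, cfg: SpanConfig) -> int:
    """Largest copy number whose full-span pattern fits in one read."""
    if read_length <= 2 * cfg.anchor_len:
        raise ValueError("read_length must exceed 2 * anchor_len")
    return (read_length - 2 * cfg.anchor_len) // locus.unit_len


def approx_contains(
    read: str, pattern: str, max_edit: int, mode: str = "edit"
) -> Optional[int]:
    """Best semi-global distance of ``pattern`` in ``read`` over both strands.

    Returns the distance if <= ``max_edit``, else ``None``.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    search = min_edit_distance if mode == "edit" else min_hamming_distance
    d_fwd, _ = search(pattern, read)
    if d_fwd == 0:
        return 0
    d_rev, _ = search(pattern, reverse_complement(read))
    best = min(d_fwd, d_rev)
    return best if best <= max_edit else None


def _unit_seeds(unit: str, max_edit: int) -> list[str]:
    """Exact seeds for prefiltering: max_edit+1 chunks of the unit, both strands.

    Any read carrying >= 1 full unit copy within ``max_edit`` edits must
    contain at least one chunk exactly (pigeonhole), so the prefilter never
    drops a read the caller could use.
    """
    n_chunks = max_edit + 1
    size = len(unit) // n_chunks
    chunks = [unit[i * size : (i + 1) * size] for i in range(n_chunks)]
    return chunks + [reverse_complement(c) for c in chunks]


def _passes_prefilter(seq: str, seeds: list[str]) -> bool:
    return any(s in seq for s in seeds)


def _partial_side_evidence(
    oriented: str,
    locus: VNTRLocus,
    cfg: SpanConfig,
    c_core: int,
) -> bool:
    """True if the read holds ``c_core`` full units plus a non-flank repeat
    fragment of >= ``min_partial_fragment`` bases on at least one side."""
    return bool(
        _partial_placements(oriented, locus, cfg, c_core, require_both_ends=False)
    )


def _placements(core: str, text: str, max_edit: int) -> list[tuple[int, int, int]]:
    """All (start, end, distance) placements of ``core`` in ``text``.

    Starts come from scanning the reversed strings, ends from the forward
    scan; pairs are joined on plausible span length.
    """
    ends = end_positions_within(core, text, max_edit)
    rev = end_positions_within(core[::-1], text[::-1], max_edit)
    starts = [(len(text) - e, d) for e, d in rev]
    out = []
    for e, de in ends:
        for s, ds in starts:
            if abs((e - s) - len(core)) <= max_edit and s < e:
                out.append((s, e, max(de, ds)))
    return out


def _fragment_ok(frag: str, repeat_piece: str, flank_piece: str, budget: int, max_edit: int) -> bool:
    """Fragment must look like continued repeat (within the edit budget left
    over after placing the core) and must not be explainable as the
    corresponding flank sequence (within the full tolerance)."""
    if len(frag) < len(repeat_piece):
        return False
    if global_edit_distance(frag, repeat_piece) > budget:
        return False
    if global_edit_distance(frag, flank_piece) <= max_edit:
        return False
    return True


def _partial_placements(
    oriented: str,
    locus: VNTRLocus,
    cfg: SpanConfig,
    c_core: int,
    require_both_ends: bool,
) -> list[tuple[int, int]]:
    """Placements of ``c_core`` full units with qualifying repeat partials.

    ``require_both_ends=False`` accepts a partial on either side (open-class
    allele evidence); ``True`` demands both sides (the >=6x scan).
    """
    unit = locus.unit_seq
    f = cfg.min_partial_fragment
    core = unit * c_core
    left_repeat = unit[-f:]
    right_repeat = unit[:f]
    left_flank = locus.left_flank_seq[-f:]
    right_flank = locus.right_flank_seq[:f]
    hits = []
    for s, e, d in _placements(core, oriented, cfg.max_edit):
        budget = cfg.max_edit - d
        left_ok = s >= f and _fragment_ok(
            oriented[s - f : s], left_repeat, left_flank, budget, cfg.max_edit
        )
        right_ok = e + f <= len(oriented) and _fragment_ok(
            oriented[e : e + f], right_repeat, right_flank, budget, cfg.max_edit
        )
        if require_both_ends:
            if left_ok and right_ok:
                hits.append((s, e))
        elif left_ok or right_ok:
            hits.append((s, e))
    return hits


def call_read(read: str, locus: VNTRLocus, cfg: SpanConfig) -> Optional[ReadCall]:
    """Classify one read into allele evidence, or ``None``.

    Full-span pass first (alleles ``1..C_max``); if that fails, the
    open-class pass looks for ``C_max`` full units plus an adjacent
    unexplained repeat fragment, yielding the label ``C_max + 1``.
    """
    c_max = max_fully_spannable(cfg.read_length, locus, cfg)
    unit = locus.unit_seq
    left_anchor = locus.left_flank_seq[-cfg.anchor_len :]
    right_anchor = locus.right_flank_seq[: cfg.anchor_len]

    matches: list[tuple[int, int]] = []  # (distance, allele)
    for c in range(1, c_max + 1):
        pattern = left_anchor + unit * c + right_anchor
        if len(pattern) > cfg.read_length:
            break
        d = approx_contains(read, pattern, cfg.max_edit, cfg.distance_mode)
        if d is not None:
            matches.append((d, c))
    if matches:
        # Patterns for distinct c differ by >= U - max_edit edits, so at most
        # one c can match; if degenerate input produces a tie, stay silent.
        matches.sort()
        if len(matches) > 1 and matches[0][0] == matches[1][0]:
            return None
        d, c = matches[0]
        return ReadCall(allele=c, edit_distance=d, kind="full_span")

    if c_max * locus.unit_len + cfg.min_partial_fragment <= cfg.read_length:
        for oriented in (read, reverse_complement(read)):
            if _partial_side_evidence(oriented, locus, cfg, c_max):
                return ReadCall(allele=c_max + 1, edit_distance=cfg.max_edit, kind="partial")
    return None


def genotype_sample(
    reads: Iterable,
    locus: VNTRLocus,
    cfg: SpanConfig,
    sample: str = "sample",
) -> SampleGenotype:
    """Aggregate read evidence into a filtered diploid call."""
    seeds = _unit_seeds(locus.unit_seq, cfg.max_edit)
    evidence: Counter[int] = Counter()
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        if not _passes_prefilter(seq, seeds):
            continue
        call = call_read(seq, locus, cfg)
        if call is not None:
            evidence[call.allele] += 1
    raw = dict(evidence)
    surviving = {a: n for a, n in raw.items() if n >= cfg.min_allele_reads}
    if not surviving:
        return SampleGenotype(sample=sample, status="no_call", raw_evidence=raw)
    if len(surviving) > 2:
        return SampleGenotype(
            sample=sample,
            status="excluded_multiallelic",
            read_counts=surviving,
            raw_evidence=raw,
        )
    alleles = tuple(sorted(surviving))
    return SampleGenotype(
        sample=sample,
        status="called",
        alleles=alleles,
        read_counts=surviving,
        raw_evidence=raw,
    )


def scan_six_plus(
    reads: Iterable,
    locus: VNTRLocus,
    cfg: SpanConfig,
    core_copies: int = 4,
) -> list[str]:
    """Flag reads indicating alleles beyond the open class.

    A read is flagged when it carries ``core_copies`` consecutive full units
    with repeat-consistent partial matches (>= ``min_partial_fragment``
    bases, within ``max_edit``) at both ends, neither explainable as flank
    sequence.  With the defaults this is evidence of >= 6 distinct copies.
    Returns flagged read names (or ``read:<index>`` for bare strings).
    """
    needed = core_copies * locus.unit_len + 2 * cfg.min_partial_fragment
    if cfg.read_length < needed:
        raise ValueError(
            f"read_length {cfg.read_length} < {needed} required for the scan"
        )
    seeds = _unit_seeds(locus.unit_seq, cfg.max_edit)
    flagged = []
    for i, read in enumerate(reads):
        seq = read if isinstance(read, str) else read.seq
        name = f"read:{i}" if isinstance(read, str) else read.name
        if not _passes_prefilter(seq, seeds):
            continue
        for oriented in (seq, reverse_complement(seq)):
            if _partial_placements(
                oriented, locus, cfg, core_copies,
                require_both_ends=cfg.six_plus_both_ends,
            ):
                flagged.append(name)
                break
    return flagged
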