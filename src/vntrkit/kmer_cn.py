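"""Alignment-free diploid-average copy-number estimation by k-mer counting.

The estimator compares the read-count depth of k-mers drawn from the repeat
unit against k-mers drawn from fixed windows of the two flanks:

    copy number = median(repeat k-mer counts)
                  / max(median(5' flank counts), median(3' flank counts))

Counting is strand-agnostic: every k-mer is stored and queried in canonical
orientation (lexicographic minimum of itself and its reverse complement).

Note on panel size: a 33-bp unit yields only ``33 - 25 + 1 = 9`` 25-mers
that lie fully inside one unit copy.  A 10-k-mer repeat panel therefore
includes one junction k-mer spanning a unit-unit boundary, which occurs
``c - 1`` times per ``c``-copy haplotype rather than ``c``.  The panel
records the per-copy multiplicity of every entry so this bias is auditable;
``n_repeat=9`` gives the strictly per-copy panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .locus import VNTRLocus, reverse_complement

__all__ = [
    "KmerPanel",
    "KmerCounts",
    "CNEstimate",
    "InsufficientFlankCoverageError",
    "build_panel",
    "count_kmers",
    "estimate_cn",
    "estimate_cohort",
    "canonical",
]


class InsufficientFlankCoverageError(ValueError):
    """Raised when both flank medians are zero (estimate undefined)."""


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerPanel:
    """Fixed k-mer sets for the estimator, in canonical orientation.

    ``repeat_multiplicity`` maps each repeat k-mer to its per-copy
    multiplicity rule: ``"per_copy"`` (occurs ``c`` times in a ``c``-copy
    array) or ``"junction"`` (occurs ``c - 1`` times).
    """

    k: int
    repeat_kmers: tuple[str, ...]
    flank5_kmers: tuple[str, ...]
    flank3_kmers: tuple[str, ...]
    repeat_multiplicity: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = {
            "repeat": self.repeat_kmers,
            "flank5": self.flank5_kmers,
            "flank3": self.flank3_kmers,
        }
        seen: dict[str, str] = {}
        offenders = []
        for cls, kmers in groups.items():
            if len(set(kmers)) != len(kmers):
                raise ValueError(f"duplicate k-mers within {cls} list")
            for km in kmers:
                if len(km) != self.k:
                    raise ValueError(f"{cls} k-mer {km!r} has length != k={self.k}")
                if km in seen:
                    offenders.append((km, seen[km], cls))
                seen[km] = cls
        if offenders:
            raise ValueError(f"canonical k-mers shared across lists: {offenders}")

    @property
    def all_kmers(self) -> tuple[str, ...]:
        return self.repeat_kmers + self.flank5_kmers + self.flank3_kmers

    def lookup_table(self) -> dict[str, str]:
        """Raw k-mer (either orientation) -> canonical panel k-mer."""
        table: dict[str, str] = {}
        for km in self.all_kmers:
            table[km] = km
            table[reverse_complement(km)] = km
        return table

    def to_table(self) -> pd.DataFrame:
        """Audit dump: one row per panel k-mer with class and multiplicity rule."""
        rows = []
        for km in self.repeat_kmers:
            rows.append((km, "repeat", self.repeat_multiplicity.get(km, "per_copy")))
        for km in self.flank5_kmers:
            rows.append((km, "flank5", "single"))
        for km in self.flank3_kmers:
            rows.append((km, "flank3", "single"))
        return pd.DataFrame(rows, columns=["kmer", "class", "multiplicity"])


@dataclass(frozen=True)
class KmerCounts:
    """Observed counts for every panel k-mer (0 if never seen)."""

    panel: KmerPanel
    counts: Mapping[str, int]

    def class_counts(self, cls: str) -> np.ndarray:
        kmers = {
            "repeat": self.panel.repeat_kmers,
            "flank5": self.panel.flank5_kmers,
            "flank3": self.panel.flank3_kmers,
        }[cls]
        return np.array([self.counts[k] for k in kmers], dtype=float)


@dataclass(frozen=True)
class CNEstimate:
    """Diploid-average copy-number estimate plus its median components."""

    value: float
    median_repeat: float
    median_flank5: float
    median_flank3: float


def build_panel(
    locus: VNTRLocus,
    k: int = 25,
    n_repeat: int = 10,
    flank_window: int = 53,
) -> KmerPanel:
    """Construct the estimator's k-mer panel from a locus definition.

    Flank lists take every k-mer (step 1) of the terminal ``flank_window``
    bases adjacent to the array on each side (``flank_window - k + 1``
    k-mers per side; the defaults give 29).  The repeat list takes the
    ``U - k + 1`` within-unit k-mers and, if ``n_repeat`` exceeds that,
    junction k-mers spanning unit-unit boundaries (flagged ``junction``,
    per-copy multiplicity ``c - 1``).  K-mers violating cross-class
    uniqueness are dropped with a warning.
    """
    unit = locus.unit_seq
    U = len(unit)
    if k > U:
        raise ValueError(f"k={k} exceeds unit length {U}: no within-unit k-mer exists")
    if flank_window < k:
        raise ValueError("flank_window must be >= k")
    if len(locus.left_flank_seq) < flank_window or len(locus.right_flank_seq) < flank_window:
        raise ValueError("flanks shorter than flank_window")
    if n_repeat < 1:
        raise ValueError("n_repeat must be >= 1")

    doubled = unit + unit
    n_within = U - k + 1
    repeat_raw: list[tuple[str, str]] = [
        (doubled[i : i + k], "per_copy") for i in range(min(n_repeat, n_within))
    ]
    if n_repeat > U:
        raise ValueError(f"n_repeat={n_repeat} exceeds the {U} distinct unit-phase k-mers")
    # Junction k-mers span a unit-unit boundary; most-centered offsets first,
    # so a junction k-mer is never recreated by a short chance match at the
    # array/flank boundary.
    junction_offsets = sorted(
        range(n_within, U), key=lambda i: min(U - i, i + k - U), reverse=True
    )
    for i in junction_offsets[: max(0, n_repeat - n_within)]:
        repeat_raw.append((doubled[i : i + k], "junction"))

    window5 = locus.left_flank_seq[-flank_window:]
    window3 = locus.right_flank_seq[:flank_window]
    flank5_raw = [window5[i : i + k] for i in range(flank_window - k + 1)]
    flank3_raw = [window3[i : i + k] for i in range(flank_window - k + 1)]

    # Cross-class uniqueness: a panel k-mer must be diagnostic for exactly
    # one class; offenders are removed from every class they appear in.
    repeat_context = unit * (max(locus.ref_copies, 2) + 1)
    contexts = {"repeat": repeat_context, "flank5": window5, "flank3": window3}

    def occurs_in(km: str, text: str) -> bool:
        return km in text or reverse_complement(km) in text

    kept: dict[str, list] = {"repeat": [], "flank5": [], "flank3": []}
    raw_lists = {
        "repeat": [(km, mult) for km, mult in repeat_raw],
        "flank5": [(km, None) for km in flank5_raw],
        "flank3": [(km, None) for km in flank3_raw],
    }
    for cls, items in raw_lists.items():
        for km, mult in items:
            foreign = [
                other
                for other, text in contexts.items()
                if other != cls and occurs_in(km, text)
            ]
            if "N" in km:
                foreign.append("ambiguous")
            if foreign:
                warnings.warn(
                    f"dropping {cls} k-mer {km} (also occurs in {foreign})",
                    stacklevel=2,
                )
                continue
            kept[cls].append((km, mult))
    for cls in ("repeat", "flank5", "flank3"):
        if not kept[cls]:
            raise ValueError(f"no usable {cls} k-mers after uniqueness filtering")

    multiplicity = {canonical(km): mult for km, mult in kept["repeat"]}
    return KmerPanel(
        k=k,
        repeat_kmers=tuple(canonical(km) for km, _ in kept["repeat"]),
        flank5_kmers=tuple(canonical(km) for km, _ in kept["flank5"]),
        flank3_kmers=tuple(canonical(km) for km, _ in kept["flank3"]),
        repeat_multiplicity=multiplicity,
    )


def _seq_of(read) -> str:
    return read if isinstance(read, str) else read.seq


def count_kmers(reads: Iterable, panel: KmerPanel) -> KmerCounts:
    """Count panel k-mer occurrences over a read stream (both orientations).

    Single pass; memory proportional to panel size.  Substrings containing
    N never match (the panel is N-free).  An empty stream yields all-zero
    counts with a warning.
    """
    lookup = panel.lookup_table()
    counts = dict.fromkeys(panel.all_kmers, 0)
    k = panel.k
    n_reads = 0
    for read in reads:
        seq = _seq_of(read)
        n_reads += 1
        for i in range(len(seq) - k + 1):
            hit = lookup.get(seq[i : i + k])
            if hit is not None:
                counts[hit] += 1
    if n_reads == 0:
        warnings.warn("empty read stream: all k-mer counts are zero", stacklevel=2)
    return KmerCounts(panel=panel, counts=counts)


def estimate_cn(counts: KmerCounts) -> CNEstimate:
    """Apply the median-ratio formula to a set of panel counts.

    Medians use the midpoint convention for even-length lists.  Raises
    :class:`InsufficientFlankCoverageError` when both flank medians are 0.
    """
    med_r = float(np.median(counts.class_counts("repeat")))
    med_5 = float(np.median(counts.class_counts("flank5")))
    med_3 = float(np.median(counts.class_counts("flank3")))
    denom = max(med_5, med_3)
    if denom == 0:
        raise InsufficientFlankCoverageError(
            "both flank k-mer medians are zero: insufficient flank coverage"
        )
    return CNEstimate(
        value=med_r / denom,
        median_repeat=med_r,
        median_flank5=med_5,
        median_flank3=med_3,
    )


def estimate_cohort(
    samples: Mapping[str, Iterable],
    panel: KmerPanel,
) -> pd.DataFrame:
    """Estimate every sample; returns a table sorted by estimate, descending.

    Per-sample failures (e.g. no flank coverage) are recorded as missing
    values and do not abort the run.
    """
    rows = []
    for sample, reads in samples.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            counts = count_kmers(reads, panel)
        try:
            est = estimate_cn(counts)
            rows.append(
                (sample, est.median_repeat, est.median_flank5, est.median_flank3, est.value)
            )
        except InsufficientFlankCoverageError:
            rows.append((sample, np.nan, np.nan, np.nan, np.nan))
    df = pd.DataFrame(
        rows,
        columns=["sample", "median_repeat", "median_flank5", "median_flank3", "cn_estimate"],
    )
    return df.sort_values("cn_estimate", ascending=False, na_position="last").reset_index(
        drop=True
    )
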