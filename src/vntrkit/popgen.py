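"""Population summaries: allele frequencies and multi-allelic fixation index.

The fixation index uses the heterozygosity partition
``F_ST = (H_T - H_S) / H_T`` with ``H = 1 - sum(p_i^2)``, where ``H_S`` is
the (equal- or sample-size-weighted) mean within-population expected
heterozygosity and ``H_T`` the expected heterozygosity of the corresponding
mean frequency vector.  No small-sample bias correction is applied by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .span import SampleGenotype

__all__ = [
    "AlleleFreqTable",
    "FstResult",
    "allele_frequencies",
    "expected_heterozygosity",
    "pairwise_fst",
    "fst_matrix",
]


@dataclass(frozen=True)
class AlleleFreqTable:
    """Per-population allele frequencies plus the number of called samples."""

    freqs: Mapping[str, Mapping[int, float]]
    sample_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for pop, p in self.freqs.items():
            vals = np.array(list(p.values()), dtype=float)
            if np.any(vals < 0):
                raise ValueError(f"negative frequency in population {pop!r}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"frequencies for population {pop!r} sum to {vals.sum()!r}, not 1"
                )

    @property
    def populations(self) -> list[str]:
        return list(self.freqs)

    @property
    def alleles(self) -> list[int]:
        out: set[int] = set()
        for p in self.freqs.values():
            out.update(p)
        return sorted(out)

    def vector(self, pop: str, alleles: Sequence[int] | None = None) -> np.ndarray:
        """Frequency vector over ``alleles`` (union of all labels by default)."""
        alleles = self.alleles if alleles is None else alleles
        return np.array([self.freqs[pop].get(a, 0.0) for a in alleles])

    def to_frame(self) -> pd.DataFrame:
        alleles = self.alleles
        return pd.DataFrame(
            {pop: self.vector(pop, alleles) for pop in self.populations},
            index=alleles,
        ).T


@dataclass(frozen=True)
class FstResult:
    """Pairwise fixation index with its heterozygosity components."""

    pop_pair: tuple[str, str]
    h_s: float
    h_t: float
    fst: float | None  # None when H_T == 0 (undefined, not 0/0)

    @property
    def defined(self) -> bool:
        return self.fst is not None


def allele_frequencies(
    genotypes_by_pop: Mapping[str, Iterable[SampleGenotype]],
) -> AlleleFreqTable:
    """Count alleles over called samples per population.

    Excluded / no-call samples are dropped.  A single-allele call
    contributes two copies of that allele (homozygote convention).
    Populations with no called samples are dropped with a warning.
    """
    freqs: dict[str, dict[int, float]] = {}
    sizes: dict[str, int] = {}
    for pop, genotypes in genotypes_by_pop.items():
        counts: dict[int, int] = {}
        n_called = 0
        for g in genotypes:
            if g.status != "called":
                continue
            n_called += 1
            for allele in g.as_diploid():
                counts[allele] = counts.get(allele, 0) + 1
        if n_called == 0:
            warnings.warn(f"population {pop!r} has no called samples; dropped", stacklevel=2)
            continue
        total = 2 * n_called
        freqs[pop] = {a: c / total for a, c in sorted(counts.items())}
        sizes[pop] = n_called
    return AlleleFreqTable(freqs=freqs, sample_sizes=sizes)


def expected_heterozygosity(p: Sequence[float] | np.ndarray) -> float:
    """``1 - sum(p_i^2)`` for a normalized allele-frequency vector."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1 (got {p.sum()!r})")
    return float(1.0 - np.sum(p**2))


def pairwise_fst(
    table: AlleleFreqTable,
    pop_a: str,
    pop_b: str,
    weighting: str = "equal",
) -> FstResult:
    """Fixation index between two populations over the union of alleles.

    ``weighting="equal"`` averages the two populations equally;
    ``"by_n"`` weights by called sample size.
    """
    if weighting not in ("equal", "by_n"):
        raise ValueError("weighting must be 'equal' or 'by_n'")
    for pop in (pop_a, pop_b):
        if pop not in table.freqs:
            raise KeyError(f"population {pop!r} not in table")
    alleles = table.alleles
    pa = table.vector(pop_a, alleles)
    pb = table.vector(pop_b, alleles)
    if weighting == "equal":
        wa = wb = 0.5
    else:
        na = table.sample_sizes.get(pop_a, 0)
        nb = table.sample_sizes.get(pop_b, 0)
        if na + nb == 0:
            raise ValueError("sample sizes unavailable for by_n weighting")
        wa, wb = na / (na + nb), nb / (na + nb)
    h_s = wa * expected_heterozygosity(pa) + wb * expected_heterozygosity(pb)
    p_bar = wa * pa + wb * pb
    h_t = expected_heterozygosity(p_bar)
    fst = None if h_t == 0 else (h_t - h_s) / h_t
    return FstResult(pop_pair=(pop_a, pop_b), h_s=h_s, h_t=h_t, fst=fst)


def fst_matrix(table: AlleleFreqTable, weighting: str = "equal") -> pd.DataFrame:
    """Symmetric matrix of pairwise fixation indices (diagonal 0).

    Undefined pairs (both populations fixed for the same allele) appear
    as NaN.
    """
    pops = table.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            res = pairwise_fst(table, a, b, weighting)
            val = np.nan if res.fst is None else res.fst
            mat.loc[a, b] = val
            mat.loc[b, a] = val
    return mat
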