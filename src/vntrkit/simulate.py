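"""Synthetic cohorts: diploid repeat genotypes, reads, linked SNPs, expression.

Everything here is driven by :class:`numpy.random.Generator` streams derived
from a single integer seed.  Per-individual substreams are keyed by cohort
index (``SeedSequence(seed, spawn_key=(index,))``), so enlarging a cohort
never perturbs the reads of already-simulated individuals.

The generators deliberately produce the statistical structure the analysis
modules assume: Hardy-Weinberg diploid genotypes at configurable allele
frequencies, uniform-coverage substitution-error reads from both haplotypes
with random strand, haplotype-linked biallelic SNPs with controllable
coupling, and expression matrices where a single causal gene's log
expression is linear in the diploid-average copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .locus import VNTRLocus, build_allele_sequence, reverse_complement

__all__ = [
    "Individual",
    "ReadSimConfig",
    "ExpressionSimConfig",
    "SimulatedRead",
    "sample_cohort",
    "simulate_reads",
    "simulate_cohort_reads",
    "simulate_linked_snp",
    "simulate_expression",
    "calibrate_sigma",
    "cohort_truth_table",
    "write_fastq",
    "individual_rng",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class Individual:
    """One synthetic diploid individual with known truth."""

    id: str
    hap1_copies: int
    hap2_copies: int
    hap1_snp: dict[str, int] = field(default_factory=dict)
    hap2_snp: dict[str, int] = field(default_factory=dict)

    @property
    def diploid_mean(self) -> float:
        return (self.hap1_copies + self.hap2_copies) / 2.0


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation parameters (uniform coverage, substitution errors)."""

    read_length: int = 150
    coverage: float = 30.0
    error_rate: float = 0.0
    flank_len: int = 2000

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise ValueError("read_length too short")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.flank_len < 1:
            raise ValueError("flank_len must be positive")


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Expression-simulation parameters.

    The first gene is causal: its log2 expression is
    ``baseline + beta * diploid_mean + Normal(0, sigma)``.  The remaining
    ``n_genes - 1`` genes are i.i.d. ``Normal(baseline, sigma)`` noise,
    independent of genotype.  The returned matrix is on the linear scale
    (``2 ** log2``), so downstream log transforms are exercised.
    """

    n_genes: int = 1000
    beta: float = 0.5
    sigma: float = 1.0
    baseline: float = 8.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class SimulatedRead:
    """A simulated read plus its provenance (truth for recovery tests)."""

    name: str
    seq: str
    hap: int      # 1 or 2
    start: int    # 0-based start on the haplotype window
    strand: str   # '+' or '-'


def individual_rng(seed: int, index: int) -> np.random.Generator:
    """Independent substream for cohort member ``index``; stable under cohort growth."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _check_freqs(freqs: Mapping[int, float]) -> tuple[list[int], np.ndarray]:
    alleles = sorted(freqs)
    p = np.array([freqs[a] for a in alleles], dtype=float)
    if np.any(p < 0):
        raise ValueError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies must sum to 1 (got {p.sum()!r})")
    return alleles, p


def sample_cohort(freqs: Mapping[int, float], n: int, seed: int) -> list[Individual]:
    """Draw ``n`` diploid individuals with i.i.d. haplotypes (Hardy-Weinberg)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    alleles, p = _check_freqs(freqs)
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n)))
    haps = rng.choice(alleles, size=(n, 2), p=p)
    return [
        Individual(id=f"S{i:0{width}d}", hap1_copies=int(h1), hap2_copies=int(h2))
        for i, (h1, h2) in enumerate(haps)
    ]


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_reads(
    individual: Individual,
    locus: VNTRLocus,
    cfg: ReadSimConfig,
    rng: np.random.Generator | int,
) -> list[SimulatedRead]:
    """Simulate uniform-coverage reads from both haplotype windows.

    Each haplotype window is the allele sequence with ``cfg.flank_len`` of
    flank on each side.  Reads per haplotype =
    ``round(coverage * window_length / read_length)``; starts are uniform;
    each base is substituted with probability ``error_rate``; each read is
    reverse-complemented with probability 0.5.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    flank = min(cfg.flank_len, len(locus.left_flank_seq), len(locus.right_flank_seq))
    reads: list[SimulatedRead] = []
    for hap, copies in ((1, individual.hap1_copies), (2, individual.hap2_copies)):
        window = build_allele_sequence(locus, copies, flank, flank).seq
        if len(window) <= cfg.read_length:
            raise ValueError(
                f"haplotype window ({len(window)} nt) must exceed read length"
            )
        n_reads = int(round(cfg.coverage * len(window) / cfg.read_length))
        starts = rng.integers(0, len(window) - cfg.read_length + 1, size=n_reads)
        flips = rng.random(n_reads) < 0.5
        for i, (s, flip) in enumerate(zip(starts, flips)):
            seq = window[s : s + cfg.read_length]
            if cfg.error_rate > 0:
                seq = _mutate(seq, rng, cfg.error_rate)
            strand = "-" if flip else "+"
            if flip:
                seq = reverse_complement(seq)
            reads.append(
                SimulatedRead(
                    name=f"{individual.id}:h{hap}:{int(s)}:{strand}:{i}",
                    seq=seq,
                    hap=hap,
                    start=int(s),
                    strand=strand,
                )
            )
    return reads


def simulate_cohort_reads(
    cohort: Sequence[Individual],
    locus: VNTRLocus,
    cfg: ReadSimConfig,
    seed: int,
):
    """Yield ``(individual, reads)`` with an independent substream per member."""
    for i, ind in enumerate(cohort):
        yield ind, simulate_reads(ind, locus, cfg, individual_rng(seed, i))


def simulate_linked_snp(
    cohort: Sequence[Individual],
    hap_freqs: Mapping[tuple[int, int], float],
    seed: int,
    snp_id: str = "snp1",
) -> pd.Series:
    """Assign a biallelic SNP to each haplotype conditional on its repeat allele.

    ``hap_freqs`` maps ``(vntr_allele, snp_allele)`` to haplotype frequency;
    the table must sum to 1 and must give positive marginal probability to
    every repeat allele present in the cohort.  Returns the per-individual
    dosage (0/1/2) as a Series indexed by individual id; the per-haplotype
    alleles are also recorded on each :class:`Individual`.
    """
    total = float(sum(hap_freqs.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"haplotype frequencies must sum to 1 (got {total!r})")
    if any(p < 0 for p in hap_freqs.values()):
        raise ValueError("haplotype frequencies must be non-negative")
    marginals: dict[int, float] = {}
    for (v, s), p in hap_freqs.items():
        if s not in (0, 1):
            raise ValueError("snp alleles must be 0/1")
        marginals[v] = marginals.get(v, 0.0) + p
    cohort_alleles = {ind.hap1_copies for ind in cohort} | {ind.hap2_copies for ind in cohort}
    missing = {v for v in cohort_alleles if marginals.get(v, 0.0) <= 0}
    if missing:
        raise ValueError(
            f"haplotype table gives zero probability to cohort alleles {sorted(missing)}"
        )
    rng = np.random.default_rng(seed)
    dosages = {}
    for ind in cohort:
        dosage = 0
        for hap_attr, copies in (("hap1_snp", ind.hap1_copies), ("hap2_snp", ind.hap2_copies)):
            p1 = hap_freqs.get((copies, 1), 0.0) / marginals[copies]
            allele = int(rng.random() < p1)
            getattr(ind, hap_attr)[snp_id] = allele
            dosage += allele
        dosages[ind.id] = dosage
    return pd.Series(dosages, name=snp_id)


def simulate_expression(
    cohort: Sequence[Individual],
    cfg: ExpressionSimConfig,
    seed: int,
) -> pd.DataFrame:
    """Samples x genes expression matrix on the linear scale.

    Column 0 (named ``g000000``) is the causal gene; all other columns are
    genotype-independent noise genes.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    dm = np.array([ind.diploid_mean for ind in cohort])
    log2x = rng.normal(cfg.baseline, cfg.sigma, size=(n, cfg.n_genes))
    log2x[:, 0] = cfg.baseline + cfg.beta * dm + rng.normal(0.0, cfg.sigma, size=n)
    width = len(str(cfg.n_genes))
    cols = [f"g{j:06d}" for j in range(cfg.n_genes)]
    return pd.DataFrame(
        np.exp2(log2x), index=[ind.id for ind in cohort], columns=cols
    )


def calibrate_sigma(beta: float, dm_values: Iterable[float], target_r: float) -> float:
    """Residual SD giving population correlation ``target_r`` for the causal gene.

    From ``r = beta * sd(dm) / sqrt(beta^2 var(dm) + sigma^2)``.
    """
    if not (0 < abs(target_r) < 1):
        raise ValueError("target_r must be in (0, 1)")
    sd = float(np.std(np.asarray(list(dm_values), dtype=float)))
    if sd == 0:
        raise ValueError("copy-number values are constant; correlation undefined")
    return abs(beta) * sd * np.sqrt(1.0 / target_r**2 - 1.0)


def cohort_truth_table(cohort: Sequence[Individual]) -> pd.DataFrame:
    """Truth table: individual, haplotype copies, diploid mean."""
    return pd.DataFrame(
        {
            "individual": [ind.id for ind in cohort],
            "hap1_copies": [ind.hap1_copies for ind in cohort],
            "hap2_copies": [ind.hap2_copies for ind in cohort],
            "diploid_mean": [ind.diploid_mean for ind in cohort],
        }
    )


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path, qual_char: str = "I") -> int:
    """Write reads as FASTQ with constant placeholder qualities; returns count."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{qual_char * len(r.seq)}\n")
            n += 1
    return n
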