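"""Percentile-rank handling, promiscuity scoring and HLA coverage.

MHC-II binding predictions are consumed as *percentile ranks*: a rank of ``r``
means the peptide scores among the top ``r`` percent of random peptides for
that allele, so lower values mean stronger predicted binding. Ranks below 10
are conventionally treated as high-affinity binding.

The *promiscuity score* of a peptide is the sum of population allele
frequencies of the alleles it binds with high affinity (rank strictly below a
threshold, default 10). It is a population-level surrogate of immunogenic
potential: a score of 0.35 means peptide-presenting alleles are carried, per
haplotype, by 35% of the population's allele pool.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    AlleleLookupError,
    CoverageError,
)

DR_LOCI = ("DRB1", "DRB3", "DRB4", "DRB5")
KNOWN_LOCI = DR_LOCI + ("DQB1",)


def normalize_allele(name: str) -> str:
    """Normalize an HLA allele name to locus + two fields.

    Typing tables mix resolutions ("04:01" vs "04:01:01:01", "4:02:01" vs
    "04:02") and may or may not carry the locus prefix. Names are compared on
    their first two numeric fields, zero-padded to two digits, keeping any
    locus prefix: ``"DRB1*4:2:1" -> "DRB1*04:02"``.
    """
    name = name.strip()
    locus = ""
    body = name
    if "*" in name:
        locus, body = name.split("*", 1)
        locus = locus.strip().upper() + "*"
    fields = [f.strip() for f in body.split(":") if f.strip()]
    if not fields or not all(re.fullmatch(r"\d+[A-Z]?", f) for f in fields):
        raise ValueError(f"unparseable allele name {name!r}")
    norm = ":".join(f.zfill(2) for f in fields[:2])
    return locus + norm


class PercentileRankMatrix:
    """Peptide x allele table of binding percentile ranks.

    Backed by a pandas DataFrame (rows = peptides in insertion order, columns
    = normalized allele names, values in [0, 100], NaN = not predicted).
    Peptide row order is meaningful: for matrices built from overlapping
    k-mers it is positional, which is what variant-vs-variant comparison
    relies on.
    """

    def __init__(self, frame: pd.DataFrame, starts: list[int] | None = None):
        frame = frame.copy()
        frame.columns = [normalize_allele(a) for a in frame.columns]
        if frame.columns.duplicated().any():
            dupes = frame.columns[frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate allele columns after normalization: {dupes}")
        if frame.index.duplicated().any():
            dupes = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate peptides: {dupes[:5]}")
        vals = frame.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("percentile ranks must lie in [0, 100]")
        self.frame = frame
        self.starts = list(starts) if starts is not None else None
        if self.starts is not None and len(self.starts) != len(frame):
            raise ValueError("starts must align with peptide rows")

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str, float]]
    ) -> "PercentileRankMatrix":
        """Build from long-format ``(peptide, allele, rank)`` triples."""
        seen: dict[tuple[str, str], float] = {}
        peptides: list[str] = []
        alleles: list[str] = []
        for pep, allele, rank in records:
            allele = normalize_allele(allele)
            key = (pep, allele)
            if key in seen:
                raise ValueError(f"duplicate (peptide, allele) entry {key}")
            seen[key] = float(rank)
            if pep not in peptides:
                peptides.append(pep)
            if allele not in alleles:
                alleles.append(allele)
        frame = pd.DataFrame(np.nan, index=peptides, columns=alleles)
        for (pep, allele), rank in seen.items():
            frame.loc[pep, allele] = rank
        return cls(frame)

    @property
    def peptides(self) -> list[str]:
        return list(self.frame.index)

    @property
    def alleles(self) -> list[str]:
        return list(self.frame.columns)

    def rank(self, peptide: str, allele: str) -> float:
        allele = normalize_allele(allele)
        try:
            value = self.frame.at[peptide, allele]
        except KeyError:
            raise AlleleLookupError(
                f"no rank for peptide {peptide!r}, allele {allele!r}"
            ) from None
        if pd.isna(value):
            raise AlleleLookupError(
                f"no rank for peptide {peptide!r}, allele {allele!r}"
            )
        return float(value)

    def ranks_for(self, peptide: str) -> dict[str, float]:
        row = self.frame.loc[peptide]
        return {a: float(r) for a, r in row.items() if pd.notna(r)}

    def to_long(self) -> pd.DataFrame:
        long = (
            self.frame.reset_index(names="peptide")
            .melt(id_vars="peptide", var_name="allele", value_name="rank")
            .dropna(subset=["rank"])
        )
        return long.reset_index(drop=True)


@dataclass
class AlleleFrequencyTable:
    """Population allele frequencies (per-haplotype, in [0, 1])."""

    frequencies: dict[str, float]
    population: str = ""

    def __post_init__(self) -> None:
        norm: dict[str, float] = {}
        for allele, freq in self.frequencies.items():
            key = normalize_allele(allele)
            if key in norm:
                raise ValueError(f"duplicate allele {key!r} after normalization")
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"frequency of {key!r} outside [0, 1]: {freq}")
            norm[key] = float(freq)
        total = sum(norm.values())
        if total > 1.0 + 1e-6:
            raise ValueError(f"frequencies sum to {total:.4f} > 1")
        self.frequencies = norm

    def __contains__(self, allele: str) -> bool:
        return normalize_allele(allele) in self.frequencies

    def frequency(self, allele: str) -> float:
        key = normalize_allele(allele)
        try:
            return self.frequencies[key]
        except KeyError:
            raise AlleleLookupError(
                f"allele {key!r} absent from frequency table "
                f"({self.population or 'unnamed population'})"
            ) from None

    @property
    def alleles(self) -> list[str]:
        return list(self.frequencies)

    def total(self) -> float:
        return sum(self.frequencies.values())


@dataclass(frozen=True)
class PromiscuityScore:
    peptide: str
    score: float
    tau: float = 10.0
    contributing_alleles: tuple[str, ...] = ()


@dataclass
class DonorGenotype:
    """Typed class-II alleles for one donor, keyed by locus.

    Up to two alleles per locus; homozygotes list the allele twice; untyped
    loci are simply absent.
    """

    donor_id: str
    alleles: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, list[str]] = {}
        for locus, names in self.alleles.items():
            locus = locus.upper()
            if len(names) > 2:
                raise ValueError(
                    f"donor {self.donor_id}: {len(names)} alleles at {locus}"
                )
            cleaned = []
            for n in names:
                if not n or not str(n).strip():
                    continue
                n = str(n).strip()
                # typing tables often omit the locus prefix inside a locus
                # column; restore it so names match prefixed rank matrices
                if "*" not in n:
                    n = f"{locus}*{n}"
                cleaned.append(normalize_allele(n))
            if cleaned:
                norm[locus] = cleaned
        self.alleles = norm

    def alleles_at(self, loci) -> list[str]:
        out: list[str] = []
        for locus in loci:
            out.extend(self.alleles.get(locus.upper(), []))
        return out


def promiscuity_score(
    peptide: str,
    ranks: dict[str, float],
    freqs: AlleleFrequencyTable,
    tau: float = 10.0,
) -> PromiscuityScore:
    """Sum of frequencies of alleles binding the peptide with rank < tau.

    The inequality is strict: an allele at exactly ``tau`` does not count.
    Every allele in ``ranks`` must be present in the frequency table.
    """
    contributing = []
    score = 0.0
    for allele, rank in ranks.items():
        freq = freqs.frequency(allele)  # raises AlleleLookupError if absent
        if rank < tau:
            score += freq
            contributing.append(normalize_allele(allele))
    return PromiscuityScore(peptide, score, tau, tuple(sorted(contributing)))


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    pvalue: float
    test: str
    n: int


def compare_promiscuity(
    scores_a,
    scores_b,
    test: str = "wilcoxon",
    alternative: str = "two-sided",
) -> PairedTestResult:
    """Paired nonparametric comparison of two per-peptide score lists.

    Defaults to the Wilcoxon signed-rank test (paired, non-normal, small n);
    ``test="sign"`` gives the sign test. When every pair is tied the
    difference carries no evidence, and both tests report p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("score lists must be non-empty")
    if a.size != b.size:
        raise ValueError(f"paired test needs equal lengths, got {a.size} != {b.size}")
    if a.size < 2:
        raise ValueError("paired test undefined for a single pair")
    diffs = a - b
    if test == "wilcoxon":
        if np.all(diffs == 0):
            return PairedTestResult(0.0, 1.0, "wilcoxon", a.size)
        res = stats.wilcoxon(a, b, alternative=alternative)
        return PairedTestResult(float(res.statistic), float(res.pvalue), "wilcoxon", a.size)
    if test == "sign":
        pos = int(np.sum(diffs > 0))
        neg = int(np.sum(diffs < 0))
        n = pos + neg
        if n == 0:
            return PairedTestResult(0.0, 1.0, "sign", a.size)
        res = stats.binomtest(pos, n, 0.5, alternative=alternative)
        return PairedTestResult(float(pos), float(res.pvalue), "sign", a.size)
    raise ValueError(f"unknown test {test!r}")


def min_percent_rank(
    peptide: str,
    genotype: DonorGenotype,
    matrix: PercentileRankMatrix,
    loci=DR_LOCI,
) -> float:
    """Minimum rank of a peptide over a donor's alleles at the given loci.

    This is the donor-specific "best binding" summary used for density plots:
    a peptide is as presentable as its best allele. Defaults to all DR loci
    because DR is what an HLA-DR immunoprecipitation captures.
    """
    alleles = genotype.alleles_at(loci)
    ranks = []
    for allele in alleles:
        try:
            ranks.append(matrix.rank(peptide, allele))
        except AlleleLookupError:
            continue
    if not ranks:
        raise CoverageError(
            f"donor {genotype.donor_id}: none of {alleles or '(no typed alleles)'} "
            f"at loci {tuple(loci)} have ranks for peptide {peptide!r}"
        )
    return min(ranks)


def min_rank_over_windows(
    peptide: str,
    genotype: DonorGenotype,
    matrix: PercentileRankMatrix,
    k: int = 15,
    loci=DR_LOCI,
) -> float:
    """Donor-minimum rank of a variable-length peptide via its k-mer windows.

    Eluted ligands vary in length while rank matrices are computed over
    fixed k-mers, so a peptide is scored by its best (minimum-rank)
    contained k-mer over the donor's alleles — the best-binding-window
    convention. Peptides shorter than ``k`` have no contained window and
    raise :class:`CoverageError`; the exact peptide is used when it is
    itself a matrix row.
    """
    if peptide in matrix.frame.index:
        return min_percent_rank(peptide, genotype, matrix, loci)
    windows = [peptide[i : i + k] for i in range(len(peptide) - k + 1)]
    windows = [w for w in windows if w in matrix.frame.index]
    if not windows:
        raise CoverageError(
            f"peptide {peptide!r}: no length-{k} window present in the rank matrix"
        )
    return min(min_percent_rank(w, genotype, matrix, loci) for w in windows)


def rank_density(
    min_ranks, bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-peptide minimum percentile ranks over [0, 100].

    Bins are half-open ``[lo, hi)`` with the final bin closed (numpy
    convention), so counts always sum to the number of inputs.
    """
    ranks = np.asarray(min_ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("rank_density requires at least one value")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if ranks.min() < 0 or ranks.max() > 100:
        raise ValueError("ranks must lie in [0, 100]")
    n_bins = int(np.ceil(100.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 100.0)
    counts, edges = np.histogram(ranks, bins=edges)
    return edges, counts


def cohort_allele_frequencies(
    genotypes: list[DonorGenotype], locus: str = "DRB1"
) -> dict[str, float]:
    """Observed allele frequencies at one locus across a donor cohort.

    Denominator is the number of typed allele slots at the locus (two per
    fully typed donor), so frequencies sum to 1 whenever every contributing
    donor carries two typed alleles.
    """
    locus = locus.upper()
    counts: dict[str, int] = {}
    slots = 0
    for g in genotypes:
        for allele in g.alleles.get(locus, []):
            counts[allele] = counts.get(allele, 0) + 1
            slots += 1
    if slots == 0:
        raise CoverageError(f"no donor typed at locus {locus}")
    return {a: c / slots for a, c in sorted(counts.items())}


def cumulative_population_coverage(
    alleles, freqs: AlleleFrequencyTable
) -> float:
    """Percent of the population allele pool covered by an allele set."""
    return 100.0 * sum(freqs.frequency(a) for a in set(normalize_allele(a) for a in alleles))


def delta_rank(
    matrix_a: PercentileRankMatrix, matrix_b: PercentileRankMatrix
) -> pd.DataFrame:
    """Positional rank difference ``b - a`` between two aligned matrices.

    The matrices must come from homologous constructs k-merized identically,
    so row *i* of each is the k-mer at the same start. Positive values mean
    the second construct's peptide binds *worse* (higher rank = lower
    affinity) — the sign convention used to show deimmunization as an
    increase.
    """
    if set(matrix_a.alleles) != set(matrix_b.alleles):
        only_a = set(matrix_a.alleles) - set(matrix_b.alleles)
        only_b = set(matrix_b.alleles) - set(matrix_a.alleles)
        raise AlignmentError(
            f"allele sets differ (only in a: {sorted(only_a)}, only in b: {sorted(only_b)})"
        )
    if len(matrix_a.frame) != len(matrix_b.frame):
        raise AlignmentError(
            f"peptide counts differ: {len(matrix_a.frame)} vs {len(matrix_b.frame)}"
        )
    a = matrix_a.frame.to_numpy(dtype=float)
    b = matrix_b.frame[matrix_a.alleles].to_numpy(dtype=float)
    starts = matrix_a.starts or list(range(1, len(matrix_a.frame) + 1))
    return pd.DataFrame(b - a, index=pd.Index(starts, name="position"), columns=matrix_a.alleles)
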