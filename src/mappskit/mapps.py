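"""Eluted-peptide mapping, epitope clusters and cohort statistics.

An eluate is the set of peptides recovered from immunopurified MHC-II
complexes for one donor and one test protein. This module places those
peptides on their construct, merges overlapping placements into *clusters*
(contiguous presented regions, the operational definition of an epitope
region), and computes the donor/cohort statistics a MAPPs readout is
summarized by:

* per-donor peptide yield and length summaries,
* cluster frequency = percent of cohort donors presenting >= 1 peptide from
  a cluster,
* within-donor cluster percentage = percent of a donor's peptides that fall
  in a cluster,
* percent inhibition of cluster frequency between a reference construct and
  a variant, and the derived responder rate,
* per-donor peptide-count decreases between constructs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constructs import ProteinConstruct, RegionWindow
from .errors import ConsistencyError, CoverageError, OutOfBoundsError
from .rounding import round_half_away

#: Sentinel distinguishing "no data" from an observed 0 percent. A donor with
#: no peptides at all for a construct has no defined within-donor percentage;
#: a donor with peptides but none in the cluster has 0.
ABSENT = None


@dataclass(frozen=True)
class EluateRecord:
    """One eluted-peptide observation (donor x construct x sequence)."""

    donor_id: str
    construct_id: str
    peptide: str
    count: int = 1

    def __post_init__(self) -> None:
        pep = self.peptide.upper()
        object.__setattr__(self, "peptide", pep)
        if not pep:
            raise ValueError("empty peptide")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class MappedPeptide:
    """An eluate record placed on its construct (1-based inclusive)."""

    record: EluateRecord
    start: int
    end: int
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.record.peptide):
            raise ConsistencyError(
                f"interval [{self.start}, {self.end}] does not match peptide "
                f"length {len(self.record.peptide)}"
            )

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class Cluster:
    """A maximal contiguous region covered by overlapping mapped peptides."""

    id: int
    start: int
    end: int
    members: list[MappedPeptide] = field(default_factory=list)
    spanning_sequence: str = ""

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class DonorConstructSummary:
    """Peptide yield and length summary for one donor x construct."""

    donor_id: str
    construct_id: str
    total_peptides: int
    unique_peptides: int
    mean_length: float
    min_length: int
    max_length: int
    empty: bool = False

    @property
    def mean_length_report(self) -> int:
        return round_half_away(self.mean_length)


def _il_fold(s: str) -> str:
    return s.replace("I", "L")


def map_peptides(
    records: list[EluateRecord],
    constructs: dict[str, ProteinConstruct],
    il_equivalent: bool = False,
) -> tuple[list[MappedPeptide], list[EluateRecord]]:
    """Place each eluate record on its own construct by exact substring search.

    All occurrences are reported; a peptide matching at more than one
    position is flagged ``ambiguous`` at every occurrence. Records whose
    peptide does not occur in the construct are returned in the second list,
    never silently dropped. With ``il_equivalent`` the search treats I and L
    as identical (isobaric in mass spectrometry) and such matches are flagged
    ambiguous.
    """
    mapped: list[MappedPeptide] = []
    unmapped: list[EluateRecord] = []
    for rec in records:
        if rec.construct_id not in constructs:
            raise KeyError(f"unknown construct id {rec.construct_id!r}")
        seq = constructs[rec.construct_id].sequence
        pep = rec.peptide
        if il_equivalent:
            seq_s, pep_s = _il_fold(seq), _il_fold(pep)
        else:
            seq_s, pep_s = seq, pep
        hits = []
        pos = seq_s.find(pep_s)
        while pos != -1:
            hits.append(pos + 1)
            pos = seq_s.find(pep_s, pos + 1)
        if not hits:
            unmapped.append(rec)
            continue
        multi = len(hits) > 1
        for start in hits:
            exact = seq[start - 1 : start - 1 + len(pep)] == pep
            mapped.append(
                MappedPeptide(
                    rec, start, start + len(pep) - 1,
                    ambiguous=multi or (il_equivalent and not exact),
                )
            )
    return mapped, unmapped


def position_coverage(mapped: list[MappedPeptide], length: int) -> np.ndarray:
    """Per-position peptide counts over a construct of given length.

    ``coverage[p-1]`` is the number of mapped peptides whose interval
    contains position ``p``; total mass equals the summed peptide lengths.
    """
    cov = np.zeros(length, dtype=int)
    for mp in mapped:
        if mp.start < 1 or mp.end > length:
            raise OutOfBoundsError(
                f"interval [{mp.start}, {mp.end}] outside [1, {length}]"
            )
        cov[mp.start - 1 : mp.end] += 1
    return cov


def detect_clusters(
    mapped: list[MappedPeptide],
    construct: ProteinConstruct | None = None,
    min_overlap: int = 1,
    max_gap: int = 0,
) -> list[Cluster]:
    """Merge overlapping peptide placements into clusters.

    Clusters are the connected components of the interval-overlap graph
    (two peptides connect when they share >= ``min_overlap`` residues;
    ``max_gap`` > 0 switches to gap bridging, additionally connecting
    intervals separated by at most that many uncovered residues). For
    1-based inclusive intervals sorted by start, a sweep with the matching
    merge threshold is exactly component detection. Clusters are reported
    left to right with ids 1..n;
    bounds are the min start / max end of members; the spanning sequence is
    read off the construct when one is supplied.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not mapped:
        return []
    order = sorted(mapped, key=lambda m: (m.start, m.end))
    clusters: list[Cluster] = []
    current = [order[0]]
    cur_end = order[0].end
    # overlap regime: next.start <= cur_end + 1 - min_overlap;
    # gap bridging (max_gap > 0): next.start <= cur_end + 1 + max_gap
    threshold = (1 + max_gap) if max_gap > 0 else (1 - min_overlap)
    for mp in order[1:]:
        if mp.start <= cur_end + threshold:
            current.append(mp)
            cur_end = max(cur_end, mp.end)
        else:
            clusters.append(_finish_cluster(len(clusters) + 1, current, construct))
            current = [mp]
            cur_end = mp.end
    clusters.append(_finish_cluster(len(clusters) + 1, current, construct))
    return clusters


def _finish_cluster(
    cid: int, members: list[MappedPeptide], construct: ProteinConstruct | None
) -> Cluster:
    start = min(m.start for m in members)
    end = max(m.end for m in members)
    seq = construct.sequence[start - 1 : end] if construct is not None else ""
    return Cluster(cid, start, end, list(members), seq)


def peptides_overlapping(
    mapped: list[MappedPeptide], region: RegionWindow
) -> list[MappedPeptide]:
    """Mapped peptides whose interval shares >= 1 position with the region."""
    return [m for m in mapped if m.overlaps(region.start, region.end)]


def summarize_donor_construct(records: list[EluateRecord]) -> DonorConstructSummary:
    """Yield/length summary for one donor x construct eluate.

    Duplicate sequences are kept in the total and length statistics and
    collapsed only for the unique count. An empty eluate returns a zeroed
    summary flagged ``empty`` rather than an error: "no peptides detected"
    is a real observation.
    """
    if not records:
        return DonorConstructSummary("", "", 0, 0, 0.0, 0, 0, empty=True)
    donors = {r.donor_id for r in records}
    constructs = {r.construct_id for r in records}
    if len(donors) > 1 or len(constructs) > 1:
        raise ConsistencyError(
            f"records span donors {sorted(donors)} and constructs {sorted(constructs)}"
        )
    lengths = [len(r.peptide) for r in records]
    return DonorConstructSummary(
        donor_id=records[0].donor_id,
        construct_id=records[0].construct_id,
        total_peptides=len(records),
        unique_peptides=len({r.peptide for r in records}),
        mean_length=float(np.mean(lengths)),
        min_length=min(lengths),
        max_length=max(lengths),
    )


@dataclass
class DonorSummary:
    donor_id: str
    total_peptides: int
    unique_peptides: int | None  # None when raw records were unavailable
    mean_length: float
    min_length: int
    max_length: int

    @property
    def mean_length_report(self) -> int:
        return round_half_away(self.mean_length)


def summarize_donor(
    summaries: list[DonorConstructSummary],
    records: list[EluateRecord] | None = None,
) -> DonorSummary:
    """Aggregate one donor's per-construct summaries into a donor-level row.

    Totals add, length extremes take min-of-mins / max-of-maxes, and the
    pooled mean weights each construct by its peptide count. The pooled
    unique count needs raw sequences (the same peptide can appear for two
    constructs); when ``records`` are not supplied it is reported as None.
    """
    nonempty = [s for s in summaries if not s.empty]
    if not summaries:
        raise ValueError("summarize_donor requires at least one summary")
    donors = {s.donor_id for s in nonempty}
    if len(donors) > 1:
        raise ConsistencyError(f"summaries span donors {sorted(donors)}")
    if not nonempty:
        return DonorSummary(summaries[0].donor_id, 0, 0, 0.0, 0, 0)
    total = sum(s.total_peptides for s in nonempty)
    mean = sum(s.mean_length * s.total_peptides for s in nonempty) / total
    unique: int | None
    if records is not None:
        unique = len({r.peptide for r in records})
    else:
        unique = None
    return DonorSummary(
        donor_id=nonempty[0].donor_id,
        total_peptides=total,
        unique_peptides=unique,
        mean_length=mean,
        min_length=min(s.min_length for s in nonempty),
        max_length=max(s.max_length for s in nonempty),
    )


def cluster_presence(
    mapped: list[MappedPeptide], cluster: Cluster, donor_id: str, construct_id: str
) -> bool:
    """True iff the donor has >= 1 mapped peptide overlapping the cluster."""
    return any(
        m.record.donor_id == donor_id
        and m.record.construct_id == construct_id
        and m.overlaps(cluster.start, cluster.end)
        for m in mapped
    )


def cluster_frequency(presence: dict[str, bool], n_donors: int) -> float:
    """Percent of cohort donors presenting the cluster.

    cluster frequency = (donors common to the cluster / total donors) x 100.
    The exact value is returned; report tables round half away from zero.
    """
    if n_donors < 1:
        raise ValueError(f"n_donors must be >= 1, got {n_donors}")
    return 100.0 * sum(bool(v) for v in presence.values()) / n_donors


def within_donor_cluster_pct(
    n_cluster_peptides: int, n_total_peptides: int
) -> float | None:
    """Percent of a donor's eluate falling inside one cluster.

    Returns ABSENT (None) — not 0 — when the donor yielded no peptides at
    all, so downstream responder/inhibition denominators can exclude
    no-data donors.
    """
    if n_total_peptides < 0 or n_cluster_peptides < 0:
        raise ValueError("counts must be non-negative")
    if n_cluster_peptides > n_total_peptides:
        raise ConsistencyError(
            f"cluster peptides ({n_cluster_peptides}) exceed total ({n_total_peptides})"
        )
    if n_total_peptides == 0:
        return ABSENT
    return 100.0 * n_cluster_peptides / n_total_peptides


def percent_inhibition(f_ref: float | None, f_var: float | None) -> float | None:
    """Percent inhibition of a frequency relative to a reference.

    ``100 * (f_ref - f_var) / f_ref``; negative when the variant exceeds the
    reference. Undefined (ABSENT) when the reference is 0 or missing.
    """
    if f_ref is None:
        return ABSENT
    for name, v in (("f_ref", f_ref), ("f_var", f_var)):
        if v is not None and not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} outside [0, 100]: {v}")
    if f_ref == 0:
        return ABSENT
    f_var = 0.0 if f_var is None else f_var
    return 100.0 * (f_ref - f_var) / f_ref


def cluster_responder_rate(
    ref_pct: dict[str, float | None], var_pct: dict[str, float | None]
) -> tuple[float, int]:
    """Percent of evaluable donors whose cluster percentage decreased.

    A donor is evaluable when the reference value is present and > 0 (a
    donor who never presented the cluster under the reference cannot show a
    decrease). A responder shows a *strict* decrease; a missing variant
    value counts as 0 (nothing presented). Returns (rate percent, number of
    evaluable donors); the exact rate is returned, reports round it.
    """
    if set(ref_pct) != set(var_pct):
        raise ValueError("donor key sets differ between reference and variant")
    evaluable = [d for d, v in ref_pct.items() if v is not None and v > 0]
    if not evaluable:
        raise CoverageError("no evaluable donors (reference all absent or zero)")
    responders = sum(
        1 for d in evaluable if (var_pct[d] or 0.0) < ref_pct[d]  # type: ignore[operator]
    )
    return 100.0 * responders / len(evaluable), len(evaluable)


@dataclass
class PeptideCountDecrease:
    """Per-donor percent decreases in peptide counts between constructs."""

    per_donor: dict[str, float]       # evaluable donors only
    excluded: list[str]               # reference count 0 -> no defined decrease
    mean_decrease: float
    pct_any_decrease: float
    pct_ge50_decrease: float
    pct_full_decrease: float


def peptide_count_decrease(
    n_ref: dict[str, int], n_var: dict[str, int]
) -> PeptideCountDecrease:
    """Percent decrease in per-donor peptide counts, variant vs reference.

    Donors with a reference count of 0 are excluded from every denominator
    (no decrease is computable for them). Decrease is
    ``100 * (n_ref - n_var) / n_ref`` and may be negative.
    """
    if set(n_ref) != set(n_var):
        raise ValueError("donor key sets differ")
    for d in n_ref:
        if n_ref[d] < 0 or n_var[d] < 0:
            raise ValueError(f"negative count for donor {d}")
    per_donor = {
        d: 100.0 * (n_ref[d] - n_var[d]) / n_ref[d] for d in n_ref if n_ref[d] > 0
    }
    excluded = sorted(d for d in n_ref if n_ref[d] == 0)
    if not per_donor:
        raise CoverageError("no evaluable donors (all reference counts are 0)")
    vals = np.array(list(per_donor.values()))
    n = len(vals)
    return PeptideCountDecrease(
        per_donor=per_donor,
        excluded=excluded,
        mean_decrease=float(vals.mean()),
        pct_any_decrease=100.0 * float((vals > 0).sum()) / n,
        pct_ge50_decrease=100.0 * float((vals >= 50).sum()) / n,
        pct_full_decrease=100.0 * float((vals >= 100).sum()) / n,
    )
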