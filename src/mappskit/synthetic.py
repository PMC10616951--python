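"""Synthetic study generator.

Emulates the statistical structure of a MAPPs immunogenicity study so every
downstream stage is testable without wet-lab data:

* an 11-donor cohort with two DRB1 alleles each, drawn from a population
  allele-frequency table;
* peptide x allele percentile-rank matrices where k-mers containing a planted
  *binding core* score low for that core's alleles (and a configurable
  *deimmunization shift* raises those ranks on variant constructs), all other
  entries uniform on [0, 100];
* per-donor eluates of roughly 10-80 peptides per construct, built as nested
  sets of length 10-26 (mean ~17) around presented cores, with presentation
  probability decreasing in the donor's minimum rank;
* triplicate lognormal cpm data with a planted responder effect.

Randomness is split into named streams keyed by (seed, stream id, entity
keys). Donor streams are independent, so enlarging the cohort never perturbs
earlier donors. Eluate streams are keyed per donor x core but *not* per
construct: constructs share random draws and differ only through their rank
matrices. This common-random-numbers pairing is what makes variant-vs-
reference contrasts reflect the planted deimmunization effect rather than
simulation noise.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .binding import AlleleFrequencyTable, DonorGenotype, PercentileRankMatrix
from .constructs import ProteinConstruct, Substitution, apply_substitutions, generate_kmers
from .errors import CoverageError, OutOfBoundsError
from .mapps import EluateRecord

# Stream ids (second entropy word after the user seed).
_S_COHORT = 10
_S_BACKGROUND = 11
_S_CORE = 12
_S_PRESENT = 21
_S_NESTED = 22
_S_CPM = 31

#: Representative common-DRB1 frequency table for simulation defaults.
#: Synthetic stand-in resembling a North-American-like distribution of the
#: most frequent DRB1 alleles; not a published table. Sums to ~0.87 — real
#: tables truncate the long tail of rare alleles the same way.
DEFAULT_DRB1_FREQUENCIES: dict[str, float] = {
    "DRB1*01:01": 0.070,
    "DRB1*01:02": 0.015,
    "DRB1*03:01": 0.085,
    "DRB1*04:01": 0.065,
    "DRB1*04:02": 0.014,
    "DRB1*04:03": 0.012,
    "DRB1*04:04": 0.030,
    "DRB1*04:07": 0.012,
    "DRB1*07:01": 0.105,
    "DRB1*08:01": 0.026,
    "DRB1*09:01": 0.022,
    "DRB1*10:01": 0.010,
    "DRB1*11:01": 0.055,
    "DRB1*11:04": 0.020,
    "DRB1*12:01": 0.018,
    "DRB1*13:01": 0.048,
    "DRB1*13:02": 0.036,
    "DRB1*14:01": 0.024,
    "DRB1*15:01": 0.100,
    "DRB1*15:02": 0.012,
    "DRB1*16:01": 0.013,
    "DRB1*03:02": 0.010,
    "DRB1*08:02": 0.012,
    "DRB1*11:02": 0.010,
    "DRB1*13:03": 0.010,
    "DRB1*14:02": 0.010,
    "DRB1*08:04": 0.012,
    "DRB1*04:05": 0.014,
}


@dataclass(frozen=True)
class BindingCore:
    """A planted MHC-II binding core.

    ``start`` is the 1-based local start of the 9-mer core; ``alleles`` are
    the alleles that bind it; planted ranks are uniform on
    [rank_low, rank_high] (degenerate when equal).
    """

    start: int
    alleles: tuple[str, ...]
    rank_low: float = 0.5
    rank_high: float = 6.0
    length: int = 9


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions."""

    seed: int
    n_donors: int = 11
    allele_freqs: AlleleFrequencyTable = field(
        default_factory=lambda: AlleleFrequencyTable(
            dict(DEFAULT_DRB1_FREQUENCIES), population="synthetic-NA"
        )
    )
    constructs: dict[str, ProteinConstruct] = field(default_factory=dict)
    cores: dict[str, tuple[BindingCore, ...]] = field(default_factory=dict)
    #: (construct id, core start) -> additive percentile-rank shift.
    deimm_shifts: dict[tuple[str, int], float] = field(default_factory=dict)
    reference_id: str = "VA"
    k: int = 15
    # eluate model
    tau_present: float = 10.0
    presentation_midpoint: float = 5.0
    presentation_slope: float = 2.0
    min_length: int = 10
    max_length: int = 26
    flank_geometric_p: float = 0.2
    nested_mean: float = 4.0
    max_nested: int = 8
    per_donor_yield: dict[str, float] = field(default_factory=dict)
    # cpm model
    control_cpm: float = 500.0
    cpm_sigma: float = 0.25
    responder_effect: float = 4.0
    nonresponder_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 10 <= self.min_length <= self.max_length <= 26:
            raise ValueError("length bounds must satisfy 10 <= min <= max <= 26")
        if not 0 < self.flank_geometric_p <= 1:
            raise ValueError("flank_geometric_p must be in (0, 1]")
        if self.cpm_sigma < 0 or self.control_cpm <= 0:
            raise ValueError("cpm parameters must be positive")


def _donor_key(donor_id: str) -> int:
    """Stable non-negative integer key (< 2^31) for a donor id."""
    digits = "".join(ch for ch in donor_id if ch.isdigit())
    if digits:
        return int(digits) % (2**31)
    return zlib.crc32(donor_id.encode()) % (2**31)


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in keys])


# ---------------------------------------------------------------------------
# default construct panel

def _default_panel() -> tuple[dict[str, ProteinConstruct], dict[str, tuple[BindingCore, ...]], dict[tuple[str, int], float], dict[str, list[Substitution]]]:
    """Four-construct panel with shared cores and a mutated central core.

    A fixed internal generator (independent of the user seed) builds one
    ~300-residue protein; the panel mirrors a deimmunization campaign: WT,
    an immunogenic variant ("VA") carrying two substitutions inside the
    central core that broaden its binding, and two deimmunized analogs of VA
    with one further substitution each plus a planted rank shift on that
    core.
    """
    rng = np.random.default_rng(20230777)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    length = 300
    while True:
        seq = "".join(rng.choice(aas, size=length))
        kmers = [seq[i : i + 15] for i in range(length - 15 + 1)]
        if len(set(kmers)) == len(kmers):
            break
    wt = ProteinConstruct("WT", seq)

    alleles = list(DEFAULT_DRB1_FREQUENCIES)
    core_starts = (15, 50, 85, 120, 155, 192, 228, 264)
    mut_core = 155
    cores_wt: list[BindingCore] = []
    for cs in core_starts:
        n_bind = 12 if cs == mut_core else 6
        chosen = tuple(rng.choice(alleles, size=n_bind, replace=False))
        cores_wt.append(BindingCore(start=cs, alleles=chosen))

    def _alt(ref: str, preferred: str) -> str:
        return preferred if ref != preferred else "Q" if ref != "Q" else "V"

    # two substitutions inside the central core make the "VA" analog foreign
    p1, p2 = mut_core + 3, mut_core + 5
    va_subs = [
        Substitution(p1, wt.residue_at(p1), _alt(wt.residue_at(p1), "V")),
        Substitution(p2, wt.residue_at(p2), _alt(wt.residue_at(p2), "Q")),
    ]
    va = apply_substitutions(wt, va_subs, new_id="VA")
    p3 = mut_core + 6
    di1 = apply_substitutions(
        va, [Substitution(p3, va.residue_at(p3), _alt(va.residue_at(p3), "D"))],
        new_id="DI-1",
    )
    di2 = apply_substitutions(
        va, [Substitution(p3, va.residue_at(p3), _alt(va.residue_at(p3), "E"))],
        new_id="DI-2",
    )
    constructs = {c.id: c for c in (wt, va, di1, di2)}
    cores = {cid: tuple(cores_wt) for cid in constructs}
    # WT is self/tolerized: its central core is weakly presented; the
    # deimmunized analogs push the core's ranks back up by design.
    shifts = {
        ("WT", mut_core): 12.0,
        ("DI-1", mut_core): 8.0,
        ("DI-2", mut_core): 5.0,
    }
    subs = {"VA": va_subs, "DI-1": va_subs + [Substitution(p3, va.residue_at(p3), di1.residue_at(p3))], "DI-2": va_subs + [Substitution(p3, va.residue_at(p3), di2.residue_at(p3))]}
    return constructs, cores, shifts, subs


#: Local start of the mutated central core in the default panel.
DEFAULT_MUTATION_CORE_START = 155


def default_config(seed: int, n_donors: int = 11, **overrides) -> SimulationConfig:
    """Study-condition defaults: 4 constructs, 8 shared cores, 11 donors."""
    constructs, cores, shifts, _ = _default_panel()
    cfg = SimulationConfig(
        seed=seed,
        n_donors=n_donors,
        constructs=constructs,
        cores=cores,
        deimm_shifts=shifts,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    return cfg


def default_substitutions() -> dict[str, list[Substitution]]:
    """Substitutions defining each default variant relative to WT."""
    return _default_panel()[3]


# ---------------------------------------------------------------------------
# generators

def sample_cohort(cfg: SimulationConfig) -> list[DonorGenotype]:
    """Draw two DRB1 alleles per donor from the population frequencies."""
    freqs = cfg.allele_freqs
    alleles = freqs.alleles
    total = freqs.total()
    if not alleles or total <= 0:
        raise ValueError("degenerate allele frequency table")
    probs = np.array([freqs.frequencies[a] for a in alleles]) / total
    rng = _rng(cfg.seed, _S_COHORT)
    cohort = []
    for i in range(cfg.n_donors):
        pair = list(rng.choice(alleles, size=2, p=probs, replace=True))
        cohort.append(DonorGenotype(f"D{i + 1}", {"DRB1": pair}))
    return cohort


def _core_window_starts(core: BindingCore, k: int, n_kmers: int) -> range:
    """K-mer starts whose peptide fully contains the core."""
    lo = max(1, core.start + core.length - k)
    hi = min(core.start, n_kmers)
    return range(lo, hi + 1)


def plant_rank_matrix(
    cfg: SimulationConfig, construct: ProteinConstruct
) -> PercentileRankMatrix:
    """Percentile ranks for every construct k-mer x population allele.

    Background entries are uniform on [0, 100]; k-mers containing a planted
    core get that core's planted rank (plus any deimmunization shift for
    this construct, capped at 100) for the core's alleles. Background and
    core draws are keyed by position and allele only, so homologous
    constructs share them and differ exactly where shifts differ.
    """
    kmers = generate_kmers(construct, cfg.k)
    if not kmers:
        raise OutOfBoundsError(f"construct {construct.id!r} shorter than k={cfg.k}")
    alleles = cfg.allele_freqs.alleles
    allele_idx = {a: i for i, a in enumerate(alleles)}
    n = len(kmers)
    ranks = np.empty((n, len(alleles)))
    for row, (start, _pep) in enumerate(kmers):
        rng = _rng(cfg.seed, _S_BACKGROUND, start)
        ranks[row] = rng.uniform(0.0, 100.0, size=len(alleles))
    for core in cfg.cores.get(construct.id, ()):  # planted cores override
        if core.start < 1 or core.start + core.length - 1 > len(construct):
            raise OutOfBoundsError(
                f"core at {core.start} outside construct {construct.id!r}"
            )
        shift = cfg.deimm_shifts.get((construct.id, core.start), 0.0)
        rng = _rng(cfg.seed, _S_CORE, core.start)
        planted = rng.uniform(core.rank_low, core.rank_high, size=len(core.alleles))
        for j, allele in enumerate(core.alleles):
            col = allele_idx[allele]
            value = min(100.0, max(0.0, planted[j] + shift))
            for start in _core_window_starts(core, cfg.k, n):
                ranks[start - 1, col] = value
    frame = pd.DataFrame(ranks, index=[p for _s, p in kmers], columns=alleles)
    return PercentileRankMatrix(frame, starts=[s for s, _p in kmers])


def _presentation_prob(min_rank: float, cfg: SimulationConfig) -> float:
    """Logistic presentation probability, gated at tau_present.

    Decreasing in rank; 0 at and above tau_present. The logistic form is a
    modelling choice (midpoint/slope configurable), standing in for the
    unknown true relation between predicted rank and elution probability.
    """
    if min_rank >= cfg.tau_present:
        return 0.0
    return 1.0 / (1.0 + math.exp((min_rank - cfg.presentation_midpoint) / cfg.presentation_slope))


def donor_core_min_rank(
    cfg: SimulationConfig,
    construct: ProteinConstruct,
    genotype: DonorGenotype,
    matrix: PercentileRankMatrix,
    core: BindingCore,
) -> float:
    """Donor's minimum rank for the k-mer centred on a core."""
    starts = _core_window_starts(core, cfg.k, len(matrix.frame))
    s0 = starts[len(starts) // 2]
    peptide = matrix.peptides[s0 - 1]
    alleles = genotype.alleles_at(("DRB1",))
    ranks = [matrix.rank(peptide, a) for a in alleles if a in matrix.frame.columns]
    if not ranks:
        raise CoverageError(
            f"donor {genotype.donor_id}: alleles {alleles} not in rank matrix"
        )
    return min(ranks)


def simulate_eluate(
    cfg: SimulationConfig,
    construct: ProteinConstruct,
    genotype: DonorGenotype,
    matrix: PercentileRankMatrix,
) -> list[EluateRecord]:
    """One donor's eluate for one construct.

    Each planted core whose donor-minimum rank clears the presentation gate
    spawns a nested set of 1-8 length-variant peptides by geometric flank
    extension around the 9-mer core. Streams are keyed per donor x core
    (not per construct): paired constructs share draws, so a core presented
    under both yields identical intervals and differences reflect only the
    planted rank shifts.
    """
    dkey = _donor_key(genotype.donor_id)
    seq = construct.sequence
    records: list[EluateRecord] = []
    yield_mult = cfg.per_donor_yield.get(genotype.donor_id, 1.0)
    for core in cfg.cores.get(construct.id, ()):
        min_rank = donor_core_min_rank(cfg, construct, genotype, matrix, core)
        p = _presentation_prob(min_rank, cfg)
        u = _rng(cfg.seed, _S_PRESENT, dkey, core.start).uniform()
        if u >= p:
            continue
        rng = _rng(cfg.seed, _S_NESTED, dkey, core.start)
        m = 1 + int(rng.poisson(max(cfg.nested_mean - 1.0, 0.0)))
        m = max(1, min(cfg.max_nested, int(round(m * yield_mult))))
        core_end = core.start + core.length - 1
        for _ in range(m):
            left = int(rng.geometric(cfg.flank_geometric_p)) - 1
            right = int(rng.geometric(cfg.flank_geometric_p)) - 1
            start = max(1, core.start - left)
            end = min(len(seq), core_end + right)
            # enforce the configured length envelope
            while end - start + 1 < cfg.min_length:
                if end < len(seq):
                    end += 1
                elif start > 1:
                    start -= 1
                else:
                    break
            while end - start + 1 > cfg.max_length:
                if end > core_end:
                    end -= 1
                else:
                    start += 1
            records.append(
                EluateRecord(genotype.donor_id, construct.id, seq[start - 1 : end])
            )
    return records


def simulate_cpm(
    cfg: SimulationConfig,
    is_responder: bool,
    donor_key: int = 0,
    stimulus_key: int = 0,
    n_replicates: int = 3,
) -> tuple[list[float], list[float]]:
    """Triplicate (test, control) cpm draws for one donor x stimulus.

    Control replicates are lognormal around the baseline cpm; test
    replicates are lognormal around baseline x planted effect (> threshold
    for responders, ~1 for non-responders). Zero dispersion gives SI exactly
    equal to the planted effect.
    """
    if cfg.control_cpm <= 0:
        raise ValueError("control_cpm must be positive")
    effect = cfg.responder_effect if is_responder else cfg.nonresponder_effect
    if effect <= 0:
        raise ValueError("planted effect must be positive")
    rng = _rng(cfg.seed, _S_CPM, int(donor_key), int(stimulus_key), int(is_responder))
    control = rng.lognormal(math.log(cfg.control_cpm), cfg.cpm_sigma, n_replicates)
    test = rng.lognormal(math.log(cfg.control_cpm * effect), cfg.cpm_sigma, n_replicates)
    return list(map(float, test)), list(map(float, control))


@dataclass
class StudyData:
    """A complete simulated MAPPs study."""

    config: SimulationConfig
    genotypes: list[DonorGenotype]
    matrices: dict[str, PercentileRankMatrix]
    eluates: dict[str, list[EluateRecord]]  # construct id -> pooled records


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Cohort + rank matrices + per-donor eluates for every construct."""
    genotypes = sample_cohort(cfg)
    matrices = {cid: plant_rank_matrix(cfg, c) for cid, c in cfg.constructs.items()}
    eluates: dict[str, list[EluateRecord]] = {cid: [] for cid in cfg.constructs}
    for genotype in genotypes:
        for cid, construct in cfg.constructs.items():
            eluates[cid].extend(
                simulate_eluate(cfg, construct, genotype, matrices[cid])
            )
    return StudyData(cfg, genotypes, matrices, eluates)
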