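"""Readers, writers, run configuration and the end-to-end pipeline.

Interchange dialect is header-carrying TSV (comma CSV accepted on read via
``sep=","``); FASTA for construct sequences; YAML for run configuration.
Every table writer prepends a ``# coordinates: 1-based inclusive`` comment
where intervals appear, and readers skip ``#`` comment lines. Outputs are
written under an output directory guarded by a ``.incomplete`` marker: the
marker exists while a run is in flight and is removed only on success, so a
crashed run is never mistaken for a finished one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .binding import (
    AlleleFrequencyTable,
    DonorGenotype,
    PercentileRankMatrix,
    min_rank_over_windows,
    promiscuity_score,
    rank_density,
)
from .constructs import (
    ProteinConstruct,
    RegionWindow,
    Substitution,
    mutation_window,
)
from .errors import ConfigError, MappsKitError, ParseError
from .mapps import (
    EluateRecord,
    cluster_frequency,
    cluster_responder_rate,
    detect_clusters,
    map_peptides,
    peptide_count_decrease,
    peptides_overlapping,
    percent_inhibition,
    position_coverage,
    summarize_donor,
    summarize_donor_construct,
    within_donor_cluster_pct,
)
from .rounding import round_half_away
from .tcell import ProliferationRecord, SIResult, percent_responders, stimulation_index

COORD_COMMENT = "# coordinates: 1-based inclusive"


# ---------------------------------------------------------------------------
# low-level table helpers

def _read_table(path: str | Path, required: tuple[str, ...], sep: str = "\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=sep, comment="#", dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"cannot parse table: {exc}", str(path)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"missing required columns {missing}; found {list(df.columns)}",
            str(path), 1,
        )
    return df


def _row_line(df: pd.DataFrame, i: int) -> int:
    # header is line 1; pandas index i is data row i (0-based)
    return int(i) + 2


def _to_float(value, df, i, col, path) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric value {value!r} in column {col!r}", str(path), _row_line(df, i)
        ) from None


# ---------------------------------------------------------------------------
# typed readers / writers

def read_constructs_fasta(path: str | Path, numbering_offsets: dict[str, int] | None = None) -> dict[str, ProteinConstruct]:
    """Constructs from FASTA; record id = construct id."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    offsets = numbering_offsets or {}
    out: dict[str, ProteinConstruct] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate construct id {rec.id!r}", str(path))
        out[rec.id] = ProteinConstruct(rec.id, str(rec.seq), offsets.get(rec.id, 0))
    if not out:
        raise ParseError("no FASTA records found", str(path))
    return out


def write_constructs_fasta(constructs: dict[str, ProteinConstruct], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=cid, description=f"numbering_offset={c.numbering_offset}")
        for cid, c in constructs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_substitutions_tsv(path: str | Path, sep: str = "\t") -> dict[str, list[Substitution]]:
    """Substitutions from TSV with columns construct, position, ref, alt."""
    df = _read_table(path, ("construct", "position", "ref", "alt"), sep)
    out: dict[str, list[Substitution]] = {}
    for i, row in df.iterrows():
        try:
            sub = Substitution(int(row["position"]), row["ref"], row["alt"])
        except (TypeError, ValueError) as exc:
            raise ParseError(str(exc), str(path), _row_line(df, i)) from exc
        out.setdefault(str(row["construct"]), []).append(sub)
    return out


def write_substitutions_tsv(subs: dict[str, list[Substitution]], path: str | Path) -> None:
    rows = [
        {"construct": cid, "position": s.position, "ref": s.ref_aa, "alt": s.alt_aa}
        for cid, ss in subs.items()
        for s in ss
    ]
    pd.DataFrame(rows, columns=["construct", "position", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


def read_eluates_tsv(path: str | Path, sep: str = "\t") -> list[EluateRecord]:
    """Eluate records from TSV (donor, construct, peptide[, count])."""
    df = _read_table(path, ("donor", "construct", "peptide"), sep)
    records = []
    for i, row in df.iterrows():
        count = 1
        if "count" in df.columns and pd.notna(row.get("count")):
            count = int(_to_float(row["count"], df, i, "count", path))
        try:
            records.append(
                EluateRecord(str(row["donor"]), str(row["construct"]), str(row["peptide"]), count)
            )
        except ValueError as exc:
            raise ParseError(str(exc), str(path), _row_line(df, i)) from exc
    return records


def write_eluates_tsv(records: list[EluateRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"donor": r.donor_id, "construct": r.construct_id, "peptide": r.peptide, "count": r.count}
            for r in records
        ],
        columns=["donor", "construct", "peptide", "count"],
    ).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path, sep: str = "\t") -> list[DonorGenotype]:
    """Genotypes from TSV (donor, locus, allele1, allele2); allele2 optional per row."""
    df = _read_table(path, ("donor", "locus", "allele1"), sep)
    by_donor: dict[str, dict[str, list[str]]] = {}
    order: list[str] = []
    for i, row in df.iterrows():
        donor = str(row["donor"])
        locus = str(row["locus"]).upper()
        if donor not in by_donor:
            by_donor[donor] = {}
            order.append(donor)
        if locus in by_donor[donor]:
            raise ParseError(
                f"duplicate locus {locus} for donor {donor}", str(path), _row_line(df, i)
            )
        alleles = [str(row["allele1"])]
        if "allele2" in df.columns and pd.notna(row.get("allele2")) and str(row["allele2"]).strip():
            alleles.append(str(row["allele2"]))
        by_donor[donor][locus] = alleles
    out = []
    for donor in order:
        try:
            out.append(DonorGenotype(donor, by_donor[donor]))
        except ValueError as exc:
            raise ParseError(str(exc), str(path)) from exc
    return out


def write_genotypes_tsv(genotypes: list[DonorGenotype], path: str | Path) -> None:
    rows = []
    for g in genotypes:
        for locus, alleles in g.alleles.items():
            rows.append(
                {
                    "donor": g.donor_id,
                    "locus": locus,
                    "allele1": alleles[0],
                    "allele2": alleles[1] if len(alleles) > 1 else "",
                }
            )
    pd.DataFrame(rows, columns=["donor", "locus", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


def read_allele_frequencies_tsv(path: str | Path, population: str = "", sep: str = "\t") -> AlleleFrequencyTable:
    df = _read_table(path, ("allele", "frequency"), sep)
    freqs: dict[str, float] = {}
    for i, row in df.iterrows():
        f = _to_float(row["frequency"], df, i, "frequency", path)
        if not 0.0 <= f <= 1.0:
            raise ParseError(f"frequency {f} outside [0, 1]", str(path), _row_line(df, i))
        freqs[str(row["allele"])] = f
    try:
        return AlleleFrequencyTable(freqs, population)
    except ValueError as exc:
        raise ParseError(str(exc), str(path)) from exc


def write_allele_frequencies_tsv(table: AlleleFrequencyTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"allele": a, "frequency": f} for a, f in table.frequencies.items()]
    ).to_csv(path, sep="\t", index=False)


def read_rank_matrix_tsv(path: str | Path, dialect: str = "long", sep: str = "\t") -> PercentileRankMatrix:
    """Percentile-rank matrix from TSV.

    ``dialect="long"`` expects columns (peptide, allele, rank).
    ``dialect="predictor"`` accepts the whitespace-separated tabular output
    of common MHC-II binding predictors: one row per peptide x allele with
    columns including ``Peptide``, ``Allele`` (or ``MHC``) and ``Rank``.
    """
    if dialect == "long":
        df = _read_table(path, ("peptide", "allele", "rank"), sep)
        pep_col, allele_col, rank_col = "peptide", "allele", "rank"
    elif dialect == "predictor":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"input file not found: {path}")
        df = pd.read_csv(path, sep=r"\s+", comment="#", dtype=str)
        allele_col = "Allele" if "Allele" in df.columns else "MHC"
        for col in ("Peptide", allele_col, "Rank"):
            if col not in df.columns:
                raise ParseError(f"predictor table missing column {col!r}", str(path), 1)
        pep_col, rank_col = "Peptide", "Rank"
    else:
        raise ValueError(f"unknown rank-table dialect {dialect!r}")
    triples = []
    for i, row in df.iterrows():
        rank = _to_float(row[rank_col], df, i, rank_col, path)
        if not 0.0 <= rank <= 100.0:
            raise ParseError(f"rank {rank} outside [0, 100]", str(path), _row_line(df, i))
        triples.append((str(row[pep_col]), str(row[allele_col]), rank))
    try:
        return PercentileRankMatrix.from_records(triples)
    except ValueError as exc:
        raise ParseError(str(exc), str(path)) from exc


def write_rank_matrix_tsv(matrix: PercentileRankMatrix, path: str | Path) -> None:
    matrix.to_long().to_csv(path, sep="\t", index=False)


def read_cpm_tsv(path: str | Path, sep: str = "\t") -> list[ProliferationRecord]:
    """Proliferation records from TSV (donor, stimulus, day, rep1, rep2, rep3)."""
    df = _read_table(path, ("donor", "stimulus", "day", "rep1"), sep)
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    out = []
    for i, row in df.iterrows():
        cpm = [
            _to_float(row[c], df, i, c, path)
            for c in rep_cols
            if pd.notna(row.get(c)) and str(row[c]).strip()
        ]
        try:
            out.append(
                ProliferationRecord(str(row["donor"]), str(row["stimulus"]), int(float(row["day"])), tuple(cpm))
            )
        except ValueError as exc:
            raise ParseError(str(exc), str(path), _row_line(df, i)) from exc
    return out


def write_cpm_tsv(records: list[ProliferationRecord], path: str | Path) -> None:
    n_rep = max(len(r.cpm) for r in records) if records else 3
    rows = []
    for r in records:
        row = {"donor": r.donor_id, "stimulus": r.stimulus_id, "day": r.day}
        for j in range(n_rep):
            row[f"rep{j + 1}"] = r.cpm[j] if j < len(r.cpm) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    output_dir: Path
    seed: int = 0
    # input paths; any may be None, stages run only when their inputs exist
    constructs: Path | None = None
    substitutions: Path | None = None
    eluates: Path | None = None
    genotypes: Path | None = None
    frequencies: Path | None = None
    ranks: Path | None = None
    cpm: Path | None = None
    # parameters
    k: int = 15
    tau: float = 10.0
    si_threshold: float = 2.0
    si_day: int = 8
    control_stimulus: str = "medium"
    reference_construct: str = "VA"
    min_overlap: int = 1
    max_gap: int = 0
    bin_width: float = 5.0
    loci: tuple[str, ...] = ("DRB1", "DRB3", "DRB4", "DRB5")
    rank_dialect: str = "long"
    table_sep: str = "\t"
    numbering_offsets: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if "output_dir" not in raw:
            raise ConfigError("config must set output_dir")
        inputs = raw.get("inputs", {})
        params = raw.get("parameters", {})
        kwargs: dict = {"output_dir": Path(raw["output_dir"]), "seed": int(raw.get("seed", 0))}
        for key in ("constructs", "substitutions", "eluates", "genotypes", "frequencies", "ranks", "cpm"):
            if inputs.get(key):
                kwargs[key] = Path(inputs[key])
        allowed = {
            "k", "tau", "si_threshold", "si_day", "control_stimulus",
            "reference_construct", "min_overlap", "max_gap", "bin_width",
            "loci", "rank_dialect", "table_sep", "numbering_offsets",
        }
        for key, value in params.items():
            if key not in allowed:
                raise ConfigError(f"unknown parameter {key!r}")
            if key == "loci":
                value = tuple(value)
            kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not 0 <= self.tau <= 100:
            raise ConfigError("tau must lie in [0, 100]")
        if self.si_threshold <= 0 or self.bin_width <= 0:
            raise ConfigError("si_threshold and bin_width must be positive")
        for name in ("constructs", "substitutions", "eluates", "genotypes", "frequencies", "ranks", "cpm"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured input does not exist: {name} = {p}")


class OutputSession:
    """Guards an output directory with a ``.incomplete`` marker."""

    def __init__(self, outdir: str | Path):
        self.outdir = Path(outdir)
        self.marker = self.outdir / ".incomplete"

    def __enter__(self) -> Path:
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.marker.write_text("run in progress\n")
        return self.outdir

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None and self.marker.exists():
            self.marker.unlink()


# ---------------------------------------------------------------------------
# pipeline

def _fmt_pct(v: float | None) -> str:
    return "" if v is None else str(round_half_away(v))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage whose inputs are configured; write result tables.

    Stages: peptide mapping / coverage / clusters / donor and cluster
    statistics (constructs + eluates); promiscuity scores (ranks +
    frequencies); min-rank densities (ranks + genotypes + eluates);
    stimulation indices (cpm). Missing inputs skip the stage and are
    recorded in the log and manifest. Outputs are deterministic functions of
    the inputs, so rerunning a run reproduces them byte for byte.
    """
    cfg.validate()
    results: dict = {"skipped": [], "outputs": []}
    log_lines: list[str] = [f"mappskit {__version__}", f"seed: {cfg.seed}"]

    def _log(msg: str) -> None:
        log_lines.append(msg)

    with OutputSession(cfg.output_dir) as outdir:
        sep = cfg.table_sep
        constructs = read_constructs_fasta(cfg.constructs, cfg.numbering_offsets) if cfg.constructs else None
        substitutions = read_substitutions_tsv(cfg.substitutions, sep) if cfg.substitutions else {}

        if constructs and cfg.eluates:
            _run_mapps_stage(cfg, constructs, substitutions, outdir, results, _log)
        else:
            results["skipped"].append("mapps")
            _log("skip mapps stage: constructs and/or eluates not configured")

        if cfg.ranks and cfg.frequencies:
            _run_promiscuity_stage(cfg, outdir, results, _log)
        else:
            results["skipped"].append("promiscuity")
            _log("skip promiscuity stage: ranks and/or frequencies not configured")

        if cfg.ranks and cfg.genotypes and cfg.eluates:
            _run_density_stage(cfg, outdir, results, _log)
        else:
            results["skipped"].append("density")
            _log("skip density stage: ranks, genotypes and/or eluates not configured")

        if cfg.cpm:
            _run_tcell_stage(cfg, outdir, results, _log)
        else:
            results["skipped"].append("tcell")
            _log("skip tcell stage: cpm not configured")

        manifest = {
            "package": "mappskit",
            "version": __version__,
            "seed": cfg.seed,
            "parameters": {
                "k": cfg.k, "tau": cfg.tau, "si_threshold": cfg.si_threshold,
                "si_day": cfg.si_day, "control_stimulus": cfg.control_stimulus,
                "reference_construct": cfg.reference_construct,
                "min_overlap": cfg.min_overlap, "max_gap": cfg.max_gap,
                "bin_width": cfg.bin_width, "loci": list(cfg.loci),
                "rounding": "half away from zero",
                "coordinates": "1-based inclusive",
            },
            "inputs": {
                name: str(getattr(cfg, name))
                for name in ("constructs", "substitutions", "eluates", "genotypes", "frequencies", "ranks", "cpm")
                if getattr(cfg, name) is not None
            },
            "skipped_stages": results["skipped"],
            "outputs": results["outputs"],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def _write(outdir: Path, name: str, text: str, results: dict) -> None:
    (outdir / name).write_text(text)
    results["outputs"].append(name)


def _df_tsv(df: pd.DataFrame, comment: str | None = None) -> str:
    body = df.to_csv(sep="\t", index=False)
    return (comment + "\n" + body) if comment else body


def _run_mapps_stage(cfg, constructs, substitutions, outdir, results, log) -> None:
    records = read_eluates_tsv(cfg.eluates, cfg.table_sep)
    unknown = sorted({r.construct_id for r in records} - set(constructs))
    if unknown:
        raise ConfigError(f"eluate references unknown construct ids: {unknown}")
    donors = sorted({r.donor_id for r in records}, key=lambda d: (len(d), d))
    n_donors = len(donors)
    log(f"mapps stage: {len(records)} eluate rows, {n_donors} donors, {len(constructs)} constructs")

    mapped_all, unmapped = map_peptides(records, constructs)
    if unmapped:
        log(f"  {len(unmapped)} records did not map and were excluded from placement outputs")
        _write(outdir, "unmapped.tsv",
               _df_tsv(pd.DataFrame([{"donor": r.donor_id, "construct": r.construct_id, "peptide": r.peptide} for r in unmapped])),
               results)

    # per-construct coverage matrix (rows = constructs, columns = positions)
    max_len = max(len(c) for c in constructs.values())
    cov_rows = []
    cluster_rows = []
    stats_rows = []
    mutation_clusters: dict[str, object] = {}
    within_by_construct: dict[str, dict[str, float | None]] = {}
    region_counts: dict[str, dict[str, int]] = {}
    for cid, construct in constructs.items():
        mapped = [m for m in mapped_all if m.record.construct_id == cid]
        cov = np.zeros(max_len, dtype=int)
        cov[: len(construct)] = position_coverage(mapped, len(construct))
        cov_rows.append([cid] + cov.tolist())
        clusters = detect_clusters(mapped, construct, cfg.min_overlap, cfg.max_gap)
        log(f"  {cid}: {len(mapped)} mapped peptides, {len(clusters)} clusters")
        region = None
        if substitutions.get(cid):
            region = mutation_window(substitutions[cid], construct, cfg.k)
        for cl in clusters:
            cluster_rows.append({"construct": cid, "start": cl.start, "end": cl.end,
                                 "cluster": cl.id, "n_peptides": len(cl.members),
                                 "sequence": cl.spanning_sequence})
            presence = {}
            within: dict[str, float | None] = {}
            for donor in donors:
                donor_total = sum(1 for m in mapped if m.record.donor_id == donor)
                donor_in = sum(
                    1 for m in mapped
                    if m.record.donor_id == donor and m.overlaps(cl.start, cl.end)
                )
                within[donor] = within_donor_cluster_pct(donor_in, donor_total)
                presence[donor] = donor_in > 0
            freq = cluster_frequency(presence, n_donors)
            row = {"construct": cid, "cluster": cl.id, "start": cl.start, "end": cl.end,
                   "cohort_frequency_pct": round_half_away(freq),
                   "cohort_frequency_exact": freq,
                   "in_mutation_region": bool(region and cl.overlaps(region.start, region.end))}
            for donor in donors:
                row[f"within_{donor}"] = _fmt_pct(within[donor])
            stats_rows.append(row)
            if row["in_mutation_region"] and cid not in mutation_clusters:
                mutation_clusters[cid] = cl
                within_by_construct[cid] = within
        if region is not None:
            region_counts[cid] = {
                d: sum(1 for m in peptides_overlapping(mapped, region) if m.record.donor_id == d)
                for d in donors
            }

    cov_df = pd.DataFrame(cov_rows, columns=["construct"] + [str(i) for i in range(1, max_len + 1)])
    _write(outdir, "coverage_matrix.tsv", _df_tsv(cov_df, COORD_COMMENT), results)
    _write(outdir, "clusters.tsv", _df_tsv(pd.DataFrame(cluster_rows), COORD_COMMENT), results)
    _write(outdir, "cluster_stats.tsv", _df_tsv(pd.DataFrame(stats_rows), COORD_COMMENT), results)

    # donor summary tables
    dc_rows, donor_rows = [], []
    for donor in donors:
        donor_summaries, donor_records = [], []
        for cid in constructs:
            recs = [r for r in records if r.donor_id == donor and r.construct_id == cid]
            if not recs:
                continue
            s = summarize_donor_construct(recs)
            donor_summaries.append(s)
            donor_records.extend(recs)
            dc_rows.append({"donor": donor, "construct": cid, "total": s.total_peptides,
                            "unique": s.unique_peptides, "mean_length": s.mean_length_report,
                            "min_length": s.min_length, "max_length": s.max_length})
        d = summarize_donor(donor_summaries, donor_records)
        donor_rows.append({"donor": donor, "total": d.total_peptides, "unique": d.unique_peptides,
                           "mean_length": d.mean_length_report, "min_length": d.min_length,
                           "max_length": d.max_length})
    _write(outdir, "donor_construct_summary.tsv", _df_tsv(pd.DataFrame(dc_rows)), results)
    _write(outdir, "donor_summary.tsv", _df_tsv(pd.DataFrame(donor_rows)), results)

    # variant-vs-reference cluster statistics (inhibition, responders, count decreases)
    ref = cfg.reference_construct
    if ref in within_by_construct:
        ref_within = within_by_construct[ref]
        resp_rows, inh_rows = [], []
        for cid in constructs:
            if cid == ref or cid not in within_by_construct:
                continue
            var_within = within_by_construct[cid]
            rate, n_eval = cluster_responder_rate(ref_within, var_within)
            resp_rows.append({"construct": cid, "reference": ref,
                              "responder_rate_pct": round_half_away(rate),
                              "responder_rate_exact": rate, "n_evaluable": n_eval})
            for donor in donors:
                inh = percent_inhibition(ref_within[donor], var_within[donor])
                inh_rows.append({"construct": cid, "donor": donor,
                                 "pct_inhibition": "" if inh is None else f"{inh:.1f}"})
        if resp_rows:
            _write(outdir, "cluster_responders.tsv", _df_tsv(pd.DataFrame(resp_rows)), results)
            _write(outdir, "cluster_inhibition.tsv", _df_tsv(pd.DataFrame(inh_rows)), results)
    if ref in region_counts:
        dec_rows = []
        for cid, counts in region_counts.items():
            if cid == ref:
                continue
            dec = peptide_count_decrease(region_counts[ref], counts)
            dec_rows.append({"construct": cid, "reference": ref,
                             "mean_decrease_pct": f"{dec.mean_decrease:.1f}",
                             "pct_donors_any_decrease": f"{dec.pct_any_decrease:.1f}",
                             "pct_donors_ge50_decrease": f"{dec.pct_ge50_decrease:.1f}",
                             "pct_donors_full_decrease": f"{dec.pct_full_decrease:.1f}",
                             "n_excluded": len(dec.excluded)})
        if dec_rows:
            _write(outdir, "region_count_decreases.tsv", _df_tsv(pd.DataFrame(dec_rows)), results)


def _run_promiscuity_stage(cfg, outdir, results, log) -> None:
    matrix = read_rank_matrix_tsv(cfg.ranks, cfg.rank_dialect, cfg.table_sep)
    freqs = read_allele_frequencies_tsv(cfg.frequencies, sep=cfg.table_sep)
    rows = []
    for pep in matrix.peptides:
        ranks = {a: r for a, r in matrix.ranks_for(pep).items() if a in freqs}
        score = promiscuity_score(pep, ranks, freqs, cfg.tau)
        rows.append({"peptide": pep, "promiscuity_score": f"{score.score:.4f}",
                     "n_high_affinity_alleles": len(score.contributing_alleles)})
    log(f"promiscuity stage: {len(rows)} peptides, tau={cfg.tau}")
    _write(outdir, "promiscuity.tsv", _df_tsv(pd.DataFrame(rows)), results)


def _run_density_stage(cfg, outdir, results, log) -> None:
    matrix = read_rank_matrix_tsv(cfg.ranks, cfg.rank_dialect, cfg.table_sep)
    genotypes = {g.donor_id: g for g in read_genotypes_tsv(cfg.genotypes, cfg.table_sep)}
    records = read_eluates_tsv(cfg.eluates, cfg.table_sep)
    rows = []
    skipped = 0
    for rec in records:
        if rec.donor_id not in genotypes:
            skipped += 1
            continue
        try:
            mr = min_rank_over_windows(
                rec.peptide, genotypes[rec.donor_id], matrix, cfg.k, cfg.loci
            )
        except MappsKitError:
            skipped += 1
            continue
        rows.append({"donor": rec.donor_id, "construct": rec.construct_id,
                     "peptide": rec.peptide, "min_rank": mr})
    log(f"density stage: {len(rows)} peptide min-ranks ({skipped} unscoreable records skipped)")
    _write(outdir, "min_ranks.tsv", _df_tsv(pd.DataFrame(rows)), results)
    if rows:
        edges, counts = rank_density([r["min_rank"] for r in rows], cfg.bin_width)
        dens = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts})
        _write(outdir, "rank_density.tsv", _df_tsv(dens), results)


def _run_tcell_stage(cfg, outdir, results, log) -> None:
    records = read_cpm_tsv(cfg.cpm, cfg.table_sep)
    controls = {(r.donor_id, r.day): r for r in records if r.stimulus_id == cfg.control_stimulus}
    si_rows: list[dict] = []
    by_stim: dict[str, list[SIResult]] = {}
    for r in records:
        if r.stimulus_id == cfg.control_stimulus or r.day != cfg.si_day:
            continue
        control = controls.get((r.donor_id, r.day))
        if control is None:
            raise ConfigError(
                f"no {cfg.control_stimulus!r} control for donor {r.donor_id}, day {r.day}"
            )
        res = stimulation_index(r, control, cfg.si_threshold)
        si_rows.append({"donor": res.donor_id, "stimulus": res.stimulus_id, "day": res.day,
                        "si": f"{res.si:.3f}", "responder": int(res.responder)})
        by_stim.setdefault(res.stimulus_id, []).append(res)
    _write(outdir, "stimulation_index.tsv", _df_tsv(pd.DataFrame(si_rows)), results)
    resp = [{"stimulus": s, "pct_responders": round_half_away(percent_responders(rs)),
             "pct_responders_exact": percent_responders(rs), "n_donors": len(rs)}
            for s, rs in by_stim.items()]
    _write(outdir, "percent_responders.tsv", _df_tsv(pd.DataFrame(resp)), results)
    log(f"tcell stage: {len(si_rows)} SI results on day {cfg.si_day}")
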