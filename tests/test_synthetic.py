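"""Synthetic study generator: determinism, planted structure, envelopes."""

import numpy as np
import pytest

from mappskit import synthetic
from mappskit.binding import AlleleFrequencyTable, min_rank_over_windows
from mappskit.constructs import ProteinConstruct
from mappskit.errors import CoverageError, OutOfBoundsError
from mappskit.synthetic import (
    BindingCore,
    SimulationConfig,
    default_config,
    plant_rank_matrix,
    sample_cohort,
    simulate_cpm,
    simulate_eluate,
    simulate_study,
)
from mappskit.tcell import ProliferationRecord, stimulation_index


class TestSampleCohort:
    def test_same_seed_identical(self):
        cfg = default_config(42)
        assert sample_cohort(cfg) == sample_cohort(cfg)

    def test_different_seeds_differ(self):
        a = sample_cohort(default_config(1))
        b = sample_cohort(default_config(2))
        assert a != b

    def test_single_allele_table_all_homozygous(self):
        cfg = default_config(3)
        cfg.allele_freqs = AlleleFrequencyTable({"DRB1*07:01": 1.0})
        for g in sample_cohort(cfg):
            assert g.alleles["DRB1"] == ["DRB1*07:01", "DRB1*07:01"]

    def test_degenerate_table_rejected(self):
        cfg = default_config(3)
        cfg.allele_freqs = AlleleFrequencyTable({})
        with pytest.raises(ValueError):
            sample_cohort(cfg)

    def test_large_cohort_matches_population(self):
        """Law of large numbers: 5000 donors recover common allele freqs."""
        cfg = default_config(11, n_donors=5000)
        cohort = sample_cohort(cfg)
        total = cfg.allele_freqs.total()
        counts: dict[str, int] = {}
        for g in cohort:
            for a in g.alleles["DRB1"]:
                counts[a] = counts.get(a, 0) + 1
        for allele, freq in cfg.allele_freqs.frequencies.items():
            if freq < 0.05:
                continue
            observed = counts.get(allele, 0) / (2 * len(cohort))
            assert observed == pytest.approx(freq / total, abs=0.02)

    def test_donor_streams_independent_of_cohort_size(self):
        small = sample_cohort(default_config(5, n_donors=4))
        large = sample_cohort(default_config(5, n_donors=11))
        assert large[:4] == small


class TestPlantRankMatrix:
    def test_background_is_marginally_uniform(self):
        cfg = default_config(9)
        construct = ProteinConstruct("plain", cfg.constructs["WT"].sequence)
        cfg.constructs = {"plain": construct}
        cfg.cores = {"plain": ()}
        m = plant_rank_matrix(cfg, construct)
        vals = m.frame.to_numpy().ravel()
        assert vals.size >= 1000
        assert np.mean(vals) == pytest.approx(50.0, abs=3.0)

    def test_degenerate_core_rank_exact(self):
        cfg = default_config(9)
        wt = cfg.constructs["WT"]
        core = BindingCore(50, ("DRB1*01:01",), rank_low=1.0, rank_high=1.0)
        cfg.cores = {"WT": (core,)}
        cfg.deimm_shifts = {}
        m = plant_rank_matrix(cfg, wt)
        # every 15-mer fully containing the 9-mer core carries the planted rank
        for start in range(50 + 9 - 15, 51):
            assert m.rank(m.peptides[start - 1], "DRB1*01:01") == 1.0

    def test_deimmunization_shift_is_additive(self):
        cfg = default_config(9)
        wt = cfg.constructs["WT"]
        core = BindingCore(50, ("DRB1*01:01",), rank_low=5.0, rank_high=5.0)
        cfg.cores = {"WT": (core,)}
        cfg.deimm_shifts = {("WT", 50): 40.0}
        m = plant_rank_matrix(cfg, wt)
        assert m.rank(m.peptides[49], "DRB1*01:01") == 45.0

    def test_core_outside_sequence_rejected(self):
        cfg = default_config(9)
        wt = cfg.constructs["WT"]
        cfg.cores = {"WT": (BindingCore(len(wt) - 2, ("DRB1*01:01",)),)}
        with pytest.raises(OutOfBoundsError):
            plant_rank_matrix(cfg, wt)

    def test_shared_background_across_constructs(self):
        """Homologous constructs share background draws; only shifted cores differ."""
        cfg = default_config(9)
        m_va = plant_rank_matrix(cfg, cfg.constructs["VA"])
        m_di1 = plant_rank_matrix(cfg, cfg.constructs["DI-1"])
        a = m_va.frame.to_numpy()
        b = m_di1.frame.to_numpy()
        diff_rows = np.where(np.any(a != b, axis=1))[0]
        core = synthetic.DEFAULT_MUTATION_CORE_START
        window = set(range(core + 9 - cfg.k, core + 1))
        assert set(diff_rows + 1) <= window


class TestSimulateEluate:
    def test_tau_present_zero_gives_empty_eluate(self):
        cfg = default_config(4, tau_present=0.0)
        study = simulate_study(cfg)
        assert all(not recs for recs in study.eluates.values())

    def test_forced_nested_set_size(self):
        """One certain core with set size capped at 3 yields exactly 3 records."""
        cfg = default_config(4)
        wt = cfg.constructs["WT"]
        core = BindingCore(50, tuple(cfg.allele_freqs.alleles), rank_low=0.0, rank_high=0.0)
        cfg.constructs = {"WT": wt}
        cfg.cores = {"WT": (core,)}
        cfg.deimm_shifts = {}
        cfg.presentation_midpoint = 1000.0  # probability ~1 below the gate
        cfg.nested_mean = 50.0
        cfg.max_nested = 3
        genotype = sample_cohort(cfg)[0]
        matrix = plant_rank_matrix(cfg, wt)
        records = simulate_eluate(cfg, wt, genotype, matrix)
        assert len(records) == 3
        for rec in records:
            start = wt.sequence.find(rec.peptide) + 1
            end = start + len(rec.peptide) - 1
            assert start <= 50 + 8 and end >= 50  # overlaps the core window

    def test_every_peptide_is_substring_with_valid_length(self, default_study):
        cfg = default_study.config
        for cid, recs in default_study.eluates.items():
            seq = cfg.constructs[cid].sequence
            for rec in recs:
                assert rec.peptide in seq
                assert cfg.min_length <= len(rec.peptide) <= cfg.max_length

    def test_pooled_length_mean_matches_envelope(self):
        """200 donors: pooled peptide length mean lands in [16, 18]."""
        cfg = default_config(8, n_donors=200)
        study = simulate_study(cfg)
        lengths = [len(r.peptide) for recs in study.eluates.values() for r in recs]
        assert 16.0 <= float(np.mean(lengths)) <= 18.0

    def test_genotype_outside_matrix_raises(self):
        cfg = default_config(4)
        wt = cfg.constructs["WT"]
        matrix = plant_rank_matrix(cfg, wt)
        from mappskit.binding import DonorGenotype

        stranger = DonorGenotype("DX", {"DRB1": ["99:99", "98:98"]})
        with pytest.raises(CoverageError):
            simulate_eluate(cfg, wt, stranger, matrix)

    def test_presented_min_ranks_left_skewed(self, default_study):
        """Presented peptides pile up below rank 10, mirroring elution bias."""
        cfg = default_study.config
        genotypes = {g.donor_id: g for g in default_study.genotypes}
        min_ranks = []
        for cid, recs in default_study.eluates.items():
            matrix = default_study.matrices[cid]
            for rec in recs:
                try:
                    min_ranks.append(
                        min_rank_over_windows(rec.peptide, genotypes[rec.donor_id], matrix, cfg.k)
                    )
                except CoverageError:
                    continue
        min_ranks = np.asarray(min_ranks)
        assert min_ranks.size > 100
        frac_low = np.mean(min_ranks < 10)
        frac_mid = np.mean((min_ranks > 10) & (min_ranks <= 20))
        assert frac_low > frac_mid


class TestSimulateCpm:
    def test_zero_dispersion_si_exact(self):
        cfg = default_config(6, cpm_sigma=0.0, responder_effect=3.0)
        test, control = simulate_cpm(cfg, is_responder=True)
        si = stimulation_index(
            ProliferationRecord("d", "s", 8, tuple(test)),
            ProliferationRecord("d", "m", 8, tuple(control)),
        ).si
        assert si == pytest.approx(3.0)
        test, control = simulate_cpm(cfg, is_responder=False)
        assert np.mean(test) / np.mean(control) == pytest.approx(1.0)

    def test_deterministic_per_key(self):
        cfg = default_config(6)
        assert simulate_cpm(cfg, True, 3, 1) == simulate_cpm(cfg, True, 3, 1)
        assert simulate_cpm(cfg, True, 3, 1) != simulate_cpm(cfg, True, 4, 1)

    def test_invalid_parameters(self):
        cfg = default_config(6)
        cfg.responder_effect = -1.0
        with pytest.raises(ValueError):
            simulate_cpm(cfg, True)

    def test_responder_call_sensitivity(self):
        """500 planted responders at effect 3: >= 95% are called (SI > 2)."""
        cfg = default_config(13, responder_effect=3.0)
        called = 0
        for d in range(500):
            test, control = simulate_cpm(cfg, True, donor_key=d)
            si = float(np.mean(test) / np.mean(control))
            called += si > 2.0
        assert called / 500 >= 0.95


class TestStudyDeterminism:
    def test_bit_reproducible(self, default_study):
        again = simulate_study(default_config(1))
        assert again.genotypes == default_study.genotypes
        for cid in default_study.eluates:
            assert again.eluates[cid] == default_study.eluates[cid]
            assert again.matrices[cid].frame.equals(default_study.matrices[cid].frame)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, min_length=5)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, flank_geometric_p=0.0)
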