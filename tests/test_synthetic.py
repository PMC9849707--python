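"""Wright-Fisher generator, sampling, sequence simulation, ambiguity noise."""

from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from haplochron.datasets import saimaa_grouping
from haplochron.seqio import (
    AMBIGUITY_CODES,
    InputError,
    collapse_haplotypes,
    mask_unreplicated,
)
from haplochron.seqio import Alignment
from haplochron.synthetic_data import (
    SimConfig,
    SimulationError,
    TrajectorySpec,
    default_trajectory,
    evolve_sequences,
    inject_ambiguities,
    sample_table,
    wf_simulate,
    write_fasta_metadata,
)
from haplochron.haplonet import pairwise_distance


def partition(membership):
    groups = defaultdict(set)
    for k, v in membership.items():
        groups[v].add(k)
    return {frozenset(g) for g in groups.values()}


class TestTrajectory:
    def test_default_anchors_match_census_history(self):
        traj = default_trajectory()
        assert traj.census(1890) == pytest.approx(1000)
        assert traj.census(1985) < 150
        assert 420 <= traj.census(2011) <= 430

    def test_linear_interpolation(self):
        traj = TrajectorySpec(anchors=((2000, 100.0), (2010, 200.0)))
        assert traj.census(2005) == pytest.approx(150)

    def test_invalid_anchors(self):
        with pytest.raises(InputError):
            TrajectorySpec(anchors=((2000, 100.0), (1990, 50.0)))


class TestWrightFisher:
    def test_fixed_haplotype_stays_fixed(self):
        cfg = SimConfig(init_freqs={"H1": 1.0}, seed=1)
        res = wf_simulate(cfg)
        assert (res.freq_path["H1"] == 1.0).all()

    def test_frequencies_sum_to_one_each_generation(self):
        cfg = SimConfig(init_freqs={f"H{i}": 0.1 for i in range(10)}, seed=2)
        res = wf_simulate(cfg)
        np.testing.assert_allclose(res.freq_path.sum(axis=1), 1.0)

    def test_bit_reproducible(self):
        cfg = SimConfig(init_freqs={"a": 0.3, "b": 0.7}, seed=9)
        pd.testing.assert_frame_equal(
            wf_simulate(cfg).freq_path, wf_simulate(cfg).freq_path)

    def test_tiny_population_rejected(self):
        traj = TrajectorySpec(
            anchors=((2000, 2.0), (2020, 2.0)), female_effective_fraction=0.1)
        with pytest.raises(SimulationError):
            wf_simulate(SimConfig(init_freqs={"a": 1.0}, trajectory=traj))

    @pytest.mark.parametrize("n_f", [25, 100])
    def test_heterozygosity_decay_law(self, n_f):
        # E[H_t] = H_0 (1 - 1/N)^t for haploid drift at constant N
        traj = TrajectorySpec(
            anchors=((2000, float(n_f)), (2000 + 11 * 20, float(n_f))),
            female_effective_fraction=1.0)
        h = []
        for seed in range(400):
            cfg = SimConfig(init_freqs={"a": 0.5, "b": 0.5},
                            trajectory=traj, seed=seed)
            f = wf_simulate(cfg).freq_path.iloc[-1].to_numpy()
            h.append(1 - np.sum(f ** 2))
        t = 20
        expected = 0.5 * (1 - 1 / n_f) ** t
        se = np.std(h, ddof=1) / np.sqrt(len(h))
        assert abs(np.mean(h) - expected) < 4 * se


class TestSampleTable:
    def test_zero_sample_size_gives_zero_column(self):
        cfg = SimConfig(init_freqs={"a": 0.5, "b": 0.5}, seed=3)
        res = wf_simulate(cfg)
        tbl = sample_table(res, saimaa_grouping(),
                           {"TG1": 0, "TG5": 10}, seed=4)
        assert tbl.column("TG1").sum() == 0
        assert tbl.column("TG5").sum() == 10

    def test_column_sums_equal_configured_sizes(self):
        cfg = SimConfig(init_freqs={f"H{i}": 0.125 for i in range(8)}, seed=5)
        res = wf_simulate(cfg)
        sizes = {"TG1": 23, "TG2": 33, "TG3": 81, "TG4": 56, "TG5": 128}
        tbl = sample_table(res, saimaa_grouping(), sizes, seed=6)
        assert {p: int(tbl.column(p).sum()) for p in tbl.period_labels} == sizes

    def test_multinomial_moments(self):
        # fixed frequencies (single generation span): means match n*p
        traj = TrajectorySpec(anchors=((2000, 10000.0), (2011, 10000.0)),
                              female_effective_fraction=1.0)
        cfg = SimConfig(init_freqs={"a": 0.2, "b": 0.8}, trajectory=traj, seed=0)
        res = wf_simulate(cfg)
        p_a = res.freq_path["a"].iloc[-1]
        grouping = saimaa_grouping()
        n = 50
        draws = np.array([
            sample_table(res, grouping, {"TG5": n}, seed=s).column("TG5")["a"]
            for s in range(800)
        ])
        se = np.sqrt(p_a * (1 - p_a) * n / len(draws))
        assert abs(draws.mean() - n * p_a) < 4 * se

    def test_period_outside_range_rejected(self):
        traj = TrajectorySpec(anchors=((2000, 500.0), (2011, 500.0)))
        cfg = SimConfig(init_freqs={"a": 1.0}, trajectory=traj, seed=1)
        res = wf_simulate(cfg)
        with pytest.raises(InputError):
            sample_table(res, saimaa_grouping(), {"TG1": 5}, seed=0)


class TestEvolveSequences:
    SIZES = {"TG1": 23, "TG2": 33, "TG3": 81, "TG4": 56, "TG5": 128}

    def test_zero_variation_collapses_to_one_haplotype(self):
        cfg = SimConfig(init_freqs={"H1": 1.0}, sampling={"TG5": 10}, seed=1)
        res = evolve_sequences(cfg, saimaa_grouping(), root_length=50)
        cat = collapse_haplotypes(res.alignment)
        assert len(cat.haplotypes) == 1

    def test_deletion_lineage_distance(self):
        cfg = SimConfig(init_freqs={"H1": 0.5, "H2": 0.5},
                        sampling={"TG5": 30}, seed=2)
        res = evolve_sequences(cfg, saimaa_grouping(), root_length=300,
                               deletion=(100, 64))
        by_hap = {}
        for sid, hap in res.truth.items():
            by_hap[hap] = res.alignment.get(sid).seq
        if "H2" in by_hap and "H1" in by_hap:
            d = pairwise_distance(by_hap["H1"], by_hap["H2"], "fifth_state")
            assert d >= 64

    @pytest.mark.parametrize("seed", range(25))
    def test_collapse_recovers_truth(self, seed):
        cfg = SimConfig(init_freqs={f"H{i}": 0.125 for i in range(1, 9)},
                        sampling=self.SIZES, seed=seed)
        res = evolve_sequences(cfg, saimaa_grouping(), root_length=120,
                               deletion=(30, 64) if seed % 2 else None)
        cat = collapse_haplotypes(res.alignment)
        assert partition(cat.membership) == partition(res.truth)

    def test_invalid_deletion_span(self):
        cfg = SimConfig(init_freqs={"H1": 1.0}, sampling={"TG5": 5}, seed=0)
        with pytest.raises(InputError):
            evolve_sequences(cfg, saimaa_grouping(), root_length=50,
                             deletion=(20, 64))

    def test_drift_loses_haplotypes_through_bottleneck(self):
        # mean richness in the last period < first period across replicates
        first, last = [], []
        for seed in range(60):
            cfg = SimConfig(init_freqs={f"H{i}": 0.125 for i in range(1, 9)},
                            sampling=self.SIZES, seed=seed)
            res = wf_simulate(cfg)
            tbl = sample_table(res, saimaa_grouping(), self.SIZES, seed=seed + 1)
            first.append(int((tbl.column("TG1") > 0).sum()))
            last.append(int((tbl.column("TG5") > 0).sum()))
        assert np.mean(last) < np.mean(first)


class TestPowerSurface:
    """The resampling test detects large simulated shifts and stays quiet
    under the null."""

    @staticmethod
    def _flag_rate(true_p, ref_count, n_ref=128, n=30, reps=500, seed=0):
        import pandas as pd
        from scipy import stats as sps
        from haplochron.temporal_stats import TestConfig, exact_test_oracle
        rng = np.random.default_rng(seed)
        # precompute the per-observation flag under the exact two-tailed rule
        from haplochron.seqio import HaplotypeTable
        xs = np.arange(n + 1)
        f_ref = ref_count / n_ref
        lo = sps.binom.cdf(xs, n, f_ref)
        up = sps.binom.sf(xs - 1, n, f_ref)
        flags = (lo < 0.025) | (up < 0.025)
        draws = rng.binomial(n, true_p, size=reps)
        # sanity: the lookup reproduces the oracle on one table
        obs = int(draws[0])
        tbl = HaplotypeTable(pd.DataFrame(
            {"P1": [obs, n - obs], "REF": [ref_count, n_ref - ref_count]},
            index=["H1", "H2"]))
        res = exact_test_oracle(tbl, TestConfig(reference_period="REF"))
        assert bool(res.cell("H1", "P1")["significant"]) == bool(flags[obs])
        return float(np.mean(flags[draws]))

    def test_large_shift_detected_in_majority_of_replicates(self):
        # true frequency 0.5 vs reference 0.2: shift of 0.3 at n = 30
        power = self._flag_rate(true_p=0.5, ref_count=26, seed=1)
        assert power > 0.5

    def test_null_flag_rate_at_most_nominal(self):
        rate = self._flag_rate(true_p=26 / 128, ref_count=26, seed=2)
        assert rate <= 0.05


class TestInjectAmbiguities:
    def _clean_alignment(self, n=20, length=80, seed=0):
        cfg = SimConfig(init_freqs={"H1": 0.5, "H2": 0.5},
                        sampling={"TG5": n}, seed=seed)
        return evolve_sequences(cfg, saimaa_grouping(), root_length=length)

    def test_rate_zero_identity(self):
        res = self._clean_alignment()
        assert inject_ambiguities(res.alignment, 0.0, seed=1) is res.alignment

    def test_expected_fraction_of_ambiguous_cells(self):
        res = self._clean_alignment(n=40, length=200)
        rate = 0.02
        fracs = []
        for seed in range(30):
            noisy = inject_ambiguities(res.alignment, rate, seed=seed)
            cells = sum(
                sum(c in AMBIGUITY_CODES for c in rec.seq) for rec in noisy)
            total = len(noisy) * noisy.length
            fracs.append(cells / total)
        assert np.mean(fracs) == pytest.approx(rate, rel=0.15)

    def test_noisy_cells_marked_unreplicated(self):
        res = self._clean_alignment()
        noisy = inject_ambiguities(res.alignment, 0.05, seed=3)
        for rec in noisy:
            for c, ok in zip(rec.seq, rec.replicated):
                if c in AMBIGUITY_CODES:
                    assert not ok

    def test_masking_then_strict_collapse_recovers_monomorphic_truth(self):
        # single true haplotype + noise: after replicate-aware masking every
        # ambiguity sits at a monomorphic column, so strict collapsing keeps all
        cfg = SimConfig(init_freqs={"H1": 1.0}, sampling={"TG5": 15}, seed=4)
        res = evolve_sequences(cfg, saimaa_grouping(), root_length=60)
        noisy = inject_ambiguities(res.alignment, 0.03, seed=5)
        masked = Alignment(tuple(
            mask_unreplicated(rec, noisy) for rec in noisy))
        cat = collapse_haplotypes(masked, "strict_remove")
        assert not cat.excluded
        assert len(cat.haplotypes) >= 1

    def test_fasta_round_trip(self, tmp_path):
        from haplochron.seqio import read_alignment
        res = self._clean_alignment(n=10, length=40)
        noisy = inject_ambiguities(res.alignment, 0.05, seed=7)
        write_fasta_metadata(noisy, tmp_path / "a.fasta", tmp_path / "m.tsv")
        back = read_alignment(tmp_path / "a.fasta", tmp_path / "m.tsv")
        assert [r.seq for r in back] == [r.seq for r in noisy]
        assert [r.replicated for r in back] == [r.replicated for r in noisy]
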