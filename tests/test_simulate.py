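"""Generators: reference sequences, kinetics, gradients, reads, qPCR, survey."""

import io

import numpy as np
import pytest
from scipy import stats
from shapely.geometry import Polygon

from sipseek import _seq
from sipseek.simulate import (
    GENOTYPES,
    ScenarioConfig,
    make_reference_db,
    simulate_amplicon_reads,
    simulate_gradient,
    simulate_microcosm,
    simulate_qpcr,
    simulate_survey,
)
from sipseek.taxonomy import p_distance


class TestReferenceDB:
    def test_zero_within_divergence_gives_identical_references(self):
        db = make_reference_db(genotypes=["only"], divergence=(0.0, 0.2), seed=1)
        assert len(set(db.sequences["only"])) == 1

    def test_realized_divergences_match_configuration(self):
        db = make_reference_db(divergence=(0.02, 0.15), seed=2)
        within = []
        for seqs in db.sequences.values():
            within += [p_distance(a, b) for i, a in enumerate(seqs) for b in seqs[i + 1:]]
        between = []
        names = list(db.sequences)
        for i, ga in enumerate(names):
            for gb in names[i + 1:]:
                between += [p_distance(db.sequences[ga][0], db.sequences[gb][0])]
        assert abs(np.mean(within) - 0.02) < 0.03
        assert abs(np.mean(between) - 0.15) < 0.03
        assert np.mean(within) < np.mean(between)

    def test_same_seed_reproduces_fasta_byte_for_byte(self, tmp_path):
        paths = []
        for name in ("a.fasta", "b.fasta"):
            db = make_reference_db(seed=3)
            p = tmp_path / name
            db.to_fasta(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_invalid_divergence_order_rejected(self):
        with pytest.raises(ValueError):
            make_reference_db(divergence=(0.2, 0.1))
        with pytest.raises(ValueError):
            make_reference_db(genotypes=[])


def _degenerate_config(**kw):
    base = dict(label="flat", in_situ_profile={}, activities={},
                heavy_mob_composition={}, mob_share_heavy={})
    base.update(kw)
    return ScenarioConfig(**base)


class TestMicrocosm:
    def test_threshold_consumed_fraction_is_eighty_percent(self):
        curve = simulate_microcosm(ScenarioConfig.gas_well())
        assert curve.threshold_consumed_fraction == 0.8

    def test_zero_rate_curve_is_flat_and_terminates_at_cap(self):
        cfg = _degenerate_config(max_rate_ppmv_per_day=0.0,
                                 max_consumed_fraction=0.0, max_days=42)
        curve = simulate_microcosm(cfg)
        assert np.all(curve.ch4_ppmv == curve.initial_ppmv)
        assert curve.termination_day == 42
        assert not curve.terminated_by_threshold
        assert curve.consumed_fraction(42) == 0.0

    def test_gas_preset_terminates_before_dry_preset(self):
        gas = simulate_microcosm(ScenarioConfig.gas_well())
        dry = simulate_microcosm(ScenarioConfig.dry_well())
        assert gas.terminated_by_threshold
        assert gas.termination_day < dry.termination_day

    def test_concentration_non_increasing_without_noise(self):
        curve = simulate_microcosm(ScenarioConfig.gas_well())
        assert np.all(np.diff(curve.ch4_ppmv) <= 0)

    def test_non_positive_initial_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_microcosm(_degenerate_config(initial_ppmv=0.0))


class TestGradient:
    profile = {"Methylocystis": 60.0, "RPC-2": 40.0}

    def test_inactive_13c_profile_matches_12c_control(self):
        zero = {g: 0.0 for g in self.profile}
        c13 = simulate_gradient(self.profile, zero, "13C", seed=5)
        c12 = simulate_gradient(self.profile, zero, "12C", seed=5)
        assert abs(c13.weighted_mean_density() - c12.weighted_mean_density()) < 0.002

    def test_fully_labelled_modal_density_in_heavy_window(self):
        ones = {g: 1.0 for g in self.profile}
        c13 = simulate_gradient(self.profile, ones, "13C", seed=6)
        assert 1.740 <= c13.modal_density() <= 1.748

    def test_12c_modal_density_in_light_window(self):
        ones = {g: 1.0 for g in self.profile}
        c12 = simulate_gradient(self.profile, ones, "12C", seed=7)
        assert 1.719 <= c12.modal_density() <= 1.728

    def test_mass_conserved_per_genotype(self):
        fs = simulate_gradient(self.profile, {g: 0.7 for g in self.profile}, seed=8)
        total = fs.abundance.sum(axis=0)
        for g, v in self.profile.items():
            assert abs(total[g] - v) <= 0.01 * v

    def test_mean_density_monotone_in_activity(self):
        means = []
        for a in np.linspace(0, 1, 11):
            fs = simulate_gradient(self.profile, {g: a for g in self.profile},
                                   "13C", seed=9)
            means.append(fs.weighted_mean_density())
        assert np.all(np.diff(means) >= 0)

    def test_activity_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            simulate_gradient(self.profile, {"Methylocystis": 1.5}, seed=10)


class TestAmpliconReads:
    def test_pure_composition_zero_error_reads_match_references(self, refdb):
        reads = simulate_amplicon_reads({"Methylocystis": 100.0}, refdb,
                                        depth=50, error_rate=0.0, seed=11)
        refs = set(refdb.sequences["Methylocystis"])
        assert all(s in refs for s in reads.sequences)
        assert set(reads.true_genotypes) == {"Methylocystis"}

    def test_read_fractions_within_multinomial_bounds(self, refdb):
        comp = {"Methylocystis": 26.93, "RPC-2": 50.4, "Methylosarcina": 19.43,
                "pmoA-2": 1.51, "USC-gamma": 0.61}
        depth = 50_000
        reads = simulate_amplicon_reads(comp, refdb, depth=depth, seed=12)
        total = sum(comp.values())
        for g, v in comp.items():
            p = v / total
            got = (reads.true_genotypes == g).mean()
            half_width = stats.norm.ppf(0.995) * np.sqrt(p * (1 - p) / depth)
            assert abs(got - p) < half_width + 1e-9

    def test_fixed_seed_reproduces_read_set(self, refdb):
        a = simulate_amplicon_reads({"RPC-2": 100.0}, refdb, depth=100, seed=13)
        b = simulate_amplicon_reads({"RPC-2": 100.0}, refdb, depth=100, seed=13)
        assert np.array_equal(a.codes, b.codes)
        assert a.ids == b.ids

    def test_empty_composition_rejected(self, refdb):
        with pytest.raises(ValueError):
            simulate_amplicon_reads({}, refdb, depth=10)
        with pytest.raises(ValueError):
            simulate_amplicon_reads({"Methylocystis": 0.0}, refdb, depth=10)

    def test_fasta_round_trip(self, refdb, tmp_path):
        from Bio import SeqIO

        reads = simulate_amplicon_reads({"RPCs": 100.0}, refdb, depth=5, seed=14)
        path = tmp_path / "reads.fasta"
        reads.to_fasta(path)
        parsed = list(SeqIO.parse(str(path), "fasta"))
        assert [r.id for r in parsed] == reads.ids
        assert [str(r.seq) for r in parsed] == reads.sequences


class TestQPCR:
    def test_noise_free_cq_closed_form(self):
        cq = simulate_qpcr(1e5, standard=(-3.3219, 38.0), noise_sd=0.0)
        assert cq == pytest.approx(21.3905, abs=1e-4)

    def test_tenfold_series_spacing_equals_slope_magnitude(self):
        series = 10.0 ** np.arange(2, 10)
        cq = simulate_qpcr(series, standard=(-3.3219, 38.0), noise_sd=0.0)
        assert np.allclose(np.diff(cq), -3.3219)

    def test_non_positive_copies_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr(0.0)


class TestSurvey:
    def test_inside_zone_mean_bi_calibrated(self):
        table = simulate_survey(n_sites=200,
                                polygon=Polygon([(-1e6, -1e6), (1e6, -1e6),
                                                 (1e6, 1e6), (-1e6, 1e6)]),
                                seed=15)
        bi = table.sites["bi_percent"].to_numpy()
        assert set(table.sites["zone"]) == {"gas_field"}
        se = bi.std(ddof=1) / np.sqrt(len(bi))
        assert abs(bi.mean() - 24.9) < 2 * se

    def test_zero_dispersion_gives_identical_bi_within_zone(self):
        table = simulate_survey(n_sites=30, bi_dispersion=0.0, seed=16)
        for zone, grp in table.sites.groupby("zone"):
            assert grp["bi_percent"].nunique() == 1

    def test_sites_far_from_polygon_all_background(self):
        poly = Polygon([(1e7, 1e7), (1e7 + 1, 1e7), (1e7 + 1, 1e7 + 1), (1e7, 1e7 + 1)])
        table = simulate_survey(n_sites=10, polygon=poly, seed=17)
        assert set(table.sites["zone"]) == {"background"}

    def test_site_ids_unique_and_profiles_consistent(self):
        table = simulate_survey(n_sites=25, seed=18)
        ids = table.sites["site_id"]
        assert ids.is_unique
        for sid, bi in zip(ids, table.sites["bi_percent"]):
            prof = table.profiles[sid]
            indicator_sum = prof.get("RPC-2", 0) + prof.get("Methylosarcina", 0)
            assert indicator_sum == pytest.approx(bi, abs=1e-9)
            assert sum(prof.values()) == pytest.approx(100.0, abs=1e-6)

    def test_bad_zone_mean_rejected(self):
        with pytest.raises(ValueError):
            simulate_survey(bi_means={"gas_field": 120.0, "background": 2.8})
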