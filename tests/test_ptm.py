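"""Modification-level estimator and bootstrap confidence intervals."""

import numpy as np
import pytest

from paleopept.ptm import (
    UndefinedEstimateError,
    bootstrap_ci,
    group_profile,
    modification_fraction,
)
from paleopept.simulate import SimulationConfig, simulate_evidence
from tests.conftest import make_record

DEAM = "deamidation"


def deamidated(seq, positions, intensity=1000.0, **kw):
    return make_record(seq, mods=[(p, DEAM) for p in positions],
                       intensity=intensity, **kw)


class TestModificationFraction:
    def test_symmetric_half(self):
        records = [deamidated("ANA", [2]), deamidated("ANA", [])]
        assert modification_fraction(records, "N", DEAM) == pytest.approx(50.0)

    def test_saturation(self):
        records = [deamidated("NNA", [1, 2]), deamidated("ANA", [2])]
        assert modification_fraction(records, "N", DEAM) == pytest.approx(100.0)

    def test_intensity_weighted_hand_example(self):
        # record A: intensity 300, 1 of 2 N deamidated; record B: 100, 0 of 1
        records = [
            deamidated("NAN", [1], intensity=300.0),
            deamidated("ANA", [], intensity=100.0),
        ]
        expected = 100.0 * 300.0 / (300.0 * 2 + 100.0 * 1)
        assert modification_fraction(records, "N", DEAM) == pytest.approx(expected)
        assert expected == pytest.approx(42.857, abs=1e-3)

    def test_residue_absent_is_undefined_not_zero(self):
        with pytest.raises(UndefinedEstimateError):
            modification_fraction([make_record("GAGA")], "N", DEAM)

    def test_scale_invariance(self):
        records = [
            deamidated("NAN", [1], intensity=300.0),
            deamidated("ANA", [], intensity=100.0),
        ]
        scaled = [
            deamidated("NAN", [1], intensity=300.0 * 7.5),
            deamidated("ANA", [], intensity=100.0 * 7.5),
        ]
        assert modification_fraction(records, "N", DEAM) == pytest.approx(
            modification_fraction(scaled, "N", DEAM)
        )

    def test_convex_combination_of_per_record_ratios(self):
        rng = np.random.default_rng(11)
        records = []
        for _ in range(30):
            n = int(rng.integers(1, 5))
            k = int(rng.integers(0, n + 1))
            seq = "N" * n + "A"
            records.append(
                deamidated(seq, list(range(1, k + 1)),
                           intensity=float(rng.lognormal(10, 1)))
            )
        est = modification_fraction(records, "N", DEAM)
        ratios = [
            100.0 * len([m for m in r.mod_list]) / r.peptide_seq.count("N")
            for r in records
        ]
        assert min(ratios) - 1e-9 <= est <= max(ratios) + 1e-9

    def test_unweighted_variant(self):
        records = [
            deamidated("NAN", [1], intensity=300.0),
            deamidated("ANA", [], intensity=100.0),
        ]
        assert modification_fraction(
            records, "N", DEAM, weighting="unweighted"
        ) == pytest.approx(100.0 * 1 / 3)

    def test_point_estimate_converges_to_site_probability(self):
        # |bias| < 2 percentage points at n=2000
        config = SimulationConfig(
            seed=123, n_ancient=2000, n_contaminant=0,
            deamidation_prob_ancient=0.40,
        )
        records = simulate_evidence(config).records
        est = modification_fraction(records, "NQ", DEAM)
        assert abs(est - 40.0) < 2.0


class TestBootstrapCI:
    def test_degenerate_single_record(self):
        est = bootstrap_ci([deamidated("AN", [2])], "N", DEAM, seed=0)
        assert (est.point_pct, est.ci_low_pct, est.ci_high_pct) == (100.0, 100.0, 100.0)

    def test_identical_records_zero_width(self):
        records = [deamidated("NAN", [1]) for _ in range(50)]
        est = bootstrap_ci(records, "N", DEAM, seed=0)
        assert est.ci_low_pct == est.ci_high_pct == pytest.approx(est.point_pct)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        records = [
            deamidated("NQNA", list(np.flatnonzero(rng.random(3) < 0.4) + 1),
                       intensity=float(rng.lognormal(10, 1)))
            for _ in range(40)
        ]
        a = bootstrap_ci(records, "N", DEAM, seed=42)
        b = bootstrap_ci(records, "N", DEAM, seed=42)
        assert (a.ci_low_pct, a.ci_high_pct) == (b.ci_low_pct, b.ci_high_pct)

    def test_ci_ordering_invariant(self):
        records = [deamidated("NQN", [1]), deamidated("NNA", [])]
        est = bootstrap_ci(records, "N", DEAM, seed=1)
        assert 0.0 <= est.ci_low_pct <= est.point_pct <= est.ci_high_pct <= 100.0

    def test_ci_contains_truth_in_most_seeded_replicates(self):
        # parameter recovery: true site probability 0.40, n=500
        hits = 0
        n_rep = 40
        for i in range(n_rep):
            config = SimulationConfig(
                seed=9000 + i, n_ancient=500, n_contaminant=0,
                deamidation_prob_ancient=0.40,
            )
            records = simulate_evidence(config).records
            est = bootstrap_ci(records, "NQ", DEAM, seed=i)
            hits += est.ci_low_pct <= 40.0 <= est.ci_high_pct
        assert hits >= int(0.9 * n_rep)


class TestGroupProfile:
    def test_groups_separate_on_contrasting_simulations(self):
        config = SimulationConfig(
            seed=77, deamidation_prob_ancient=0.5, deamidation_prob_modern=0.05
        )
        records = simulate_evidence(config).records
        profile = group_profile(records, panel=(("N", DEAM), ("Q", DEAM)), seed=3)
        for residue in ("N", "Q"):
            orig = profile.query("group == 'original' and residue == @residue").iloc[0]
            cont = profile.query("group == 'contaminant' and residue == @residue").iloc[0]
            assert orig.point_pct > cont.point_pct
            assert orig.ci_low_pct > cont.ci_high_pct

    def test_empty_contaminant_group_rows_absent(self):
        records = [deamidated("ANQ", [2], group="original")]
        profile = group_profile(records, panel=(("N", DEAM),), seed=0)
        assert set(profile.group) == {"original"}

    def test_panel_respected(self):
        records = [
            make_record("MNQK", mods=[(1, "oxidation")]),
            make_record("MNQK", group="contaminant"),
        ]
        profile = group_profile(records, panel=(("M", "oxidation"),), seed=0)
        assert set(profile.residue) == {"M"}

    def test_samples_not_pooled(self):
        records = [
            deamidated("AN", [2], sample_id="trunk"),
            deamidated("AN", [], sample_id="tip"),
        ]
        profile = group_profile(records, panel=(("N", DEAM),), seed=0)
        by_sample = profile.set_index("sample_id").point_pct
        assert by_sample["trunk"] == 100.0 and by_sample["tip"] == 0.0
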