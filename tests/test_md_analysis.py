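"""Hydrogen-bond counting, WHAM PMF estimation and free-energy extraction."""

import math

import numpy as np
import pytest

from cryptic_triage import synth
from cryptic_triage.md_analysis import (
    KB_KJ_MOL_K,
    HBondCriteria,
    HBondFrame,
    PMFProfile,
    UmbrellaWindow,
    WhamError,
    count_hbonds,
    pmf_delta_g,
    wham,
)


def _frame(donors, hydrogens, acceptors):
    return HBondFrame.from_arrays(
        np.array(donors, dtype=float),
        np.array(hydrogens, dtype=float),
        np.array(acceptors, dtype=float),
    )


def _random_frame(seed, n_donors=20, n_acceptors=20):
    rng = np.random.default_rng(seed)
    donors = rng.uniform(0, 1.2, size=(n_donors, 3))
    # hydrogens 0.1 nm from their donors in random directions
    directions = rng.standard_normal((n_donors, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    hydrogens = donors + 0.1 * directions
    acceptors = rng.uniform(0, 1.2, size=(n_acceptors, 3))
    return _frame(donors, hydrogens, acceptors)


class TestCountHbonds:
    def test_colinear_within_cutoffs(self):
        frame = _frame([[0, 0, 0]], [[0.1, 0, 0]], [[0.28, 0, 0]])
        assert count_hbonds(frame) == 1

    def test_distance_just_over_cutoff(self):
        frame = _frame([[0, 0, 0]], [[0.1, 0, 0]], [[0.36, 0, 0]])
        assert count_hbonds(frame) == 0

    def test_angle_over_cutoff(self):
        # acceptor at 45 degrees from the D-H axis, within distance
        frame = _frame([[0, 0, 0]], [[0.1, 0, 0]], [[0.2, 0.2, 0]])
        assert count_hbonds(frame) == 0

    def test_matches_triple_loop_oracle(self):
        criteria = HBondCriteria()
        for seed in (1, 2, 3):
            frame = _random_frame(seed)
            expected = 0
            for d, h in frame.donors:
                for a in frame.acceptors:
                    dist = math.dist(d, a)
                    if dist == 0 or dist > criteria.distance_cutoff:
                        continue
                    v_da = np.array(a) - np.array(d)
                    v_dh = np.array(h) - np.array(d)
                    cos = np.dot(v_da, v_dh) / (
                        np.linalg.norm(v_da) * np.linalg.norm(v_dh)
                    )
                    angle = math.degrees(math.acos(max(-1.0, min(1.0, cos))))
                    if angle <= criteria.angle_cutoff:
                        expected += 1
            assert count_hbonds(frame, criteria) == expected

    def test_permutation_invariant(self):
        frame = _random_frame(7)
        rng = np.random.default_rng(0)
        donors = list(frame.donors)
        acceptors = list(frame.acceptors)
        rng.shuffle(donors)
        rng.shuffle(acceptors)
        shuffled = HBondFrame(donors=tuple(donors), acceptors=tuple(acceptors))
        assert count_hbonds(frame) == count_hbonds(shuffled)

    def test_monotone_in_both_cutoffs(self):
        frame = _random_frame(11, n_donors=40, n_acceptors=40)
        by_dist = [
            count_hbonds(frame, HBondCriteria(distance_cutoff=d))
            for d in (0.2, 0.3, 0.35, 0.5)
        ]
        assert by_dist == sorted(by_dist)
        by_angle = [
            count_hbonds(frame, HBondCriteria(angle_cutoff=a))
            for a in (10.0, 30.0, 60.0, 180.0)
        ]
        assert by_angle == sorted(by_angle)

    def test_detached_hydrogen_rejected(self):
        with pytest.raises(ValueError, match="not bonded"):
            _frame([[0, 0, 0]], [[0.3, 0, 0]], [[0.5, 0, 0]])


class TestWham:
    def test_single_unbiased_window_flat_landscape(self):
        rng = np.random.default_rng(5)
        window = UmbrellaWindow(
            bias_center=0.5,
            spring_constant=0.0,
            temperature=298.0,
            samples=rng.uniform(0.0, 1.0, size=50_000),
        )
        profile = wham([window], bins=20)
        kt = KB_KJ_MOL_K * 298.0
        # against the direct histogram estimate, bin by bin
        counts = profile.counts.astype(float)
        direct = -kt * np.log(counts)
        direct -= direct.min()
        assert np.allclose(profile.free_energy, direct, atol=1e-9)
        # flat: the full spread stays within count-noise scale (~kT/sqrt(n_bin))
        assert profile.free_energy.max() < 6 * kt / np.sqrt(counts.min())

    def test_translation_invariance(self):
        def pot(x):
            return 25.0 * (x - 1.2) ** 2

        centers = np.linspace(0.8, 1.6, 9)
        wins = synth.gen_umbrella_windows(pot, centers, 500.0, 298.0, 2000, seed=13)
        shift = 2.0
        shifted = [
            UmbrellaWindow(
                bias_center=w.bias_center + shift,
                spring_constant=w.spring_constant,
                temperature=w.temperature,
                samples=w.samples + shift,
            )
            for w in wins
        ]
        p1 = wham(wins, bins=100)
        p2 = wham(shifted, bins=100)
        assert np.allclose(p2.grid, p1.grid + shift, atol=1e-9)
        mask = (p1.counts > 10) & (p2.counts > 10)
        assert np.allclose(
            p1.free_energy[mask], p2.free_energy[mask], atol=1e-6
        )

    def test_disjoint_windows_warn_or_error(self):
        w1 = UmbrellaWindow(0.0, 100.0, 298.0, np.linspace(0.0, 0.1, 50))
        w2 = UmbrellaWindow(5.0, 100.0, 298.0, np.linspace(4.9, 5.0, 50))
        with pytest.warns(UserWarning, match="no histogram overlap"):
            wham([w1, w2], bins=50)
        with pytest.raises(WhamError, match="no histogram overlap"):
            wham([w1, w2], bins=50, on_no_overlap="error")

    def test_mixed_temperatures_rejected(self):
        w1 = UmbrellaWindow(0.0, 100.0, 298.0, np.linspace(0, 1, 50))
        w2 = UmbrellaWindow(0.5, 100.0, 310.0, np.linspace(0, 1, 50))
        with pytest.raises(ValueError, match="one temperature"):
            wham([w1, w2])

    def test_no_windows_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            wham([])


class TestPmfDeltaG:
    def _profile(self, fe, counts=None):
        grid = np.linspace(0.5, 3.2, len(fe))
        fe = np.asarray(fe, dtype=float)
        counts = np.ones_like(fe, dtype=int) if counts is None else counts
        return PMFProfile(grid=grid, free_energy=fe, counts=counts, temperature=298.0)

    def test_constructed_binding_well(self):
        # well of depth 46.8 kJ/mol at xi ~ 1.15 nm, plateau at zero beyond 2.5
        grid = np.linspace(0.5, 3.2, 28)
        fe = np.where(np.abs(grid - 1.15) < 0.05, 0.0, 46.8)
        fe = 46.8 - (46.8 - fe)  # plateau level 46.8, min 0 after normalization
        profile = self._profile(fe - fe.min())
        dg = pmf_delta_g(profile, bound_region=(0.9, 1.5), plateau_region=(2.5, 3.2))
        assert dg == pytest.approx(-46.8)

    def test_flat_profile_gives_zero(self):
        profile = self._profile(np.zeros(30))
        assert pmf_delta_g(profile, (0.6, 1.0), (2.5, 3.0)) == 0.0

    def test_plateau_outside_grid(self):
        profile = self._profile(np.zeros(30))
        with pytest.raises(ValueError, match="outside the PMF grid"):
            pmf_delta_g(profile, (0.6, 1.0), (5.0, 6.0))

    def test_unoccupied_region_rejected(self):
        fe = np.zeros(30)
        counts = np.ones(30, dtype=int)
        counts[-10:] = 0
        profile = self._profile(fe, counts)
        with pytest.raises(ValueError, match="no occupied bins"):
            pmf_delta_g(profile, (0.6, 1.0), (2.9, 3.2))
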