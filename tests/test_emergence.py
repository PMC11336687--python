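import math

import numpy as np
import pytest

from altdyn.core_state import HostStrain, Params, SystemState, ViralStrain
from altdyn.emergence import (emergence_results, expected_p_star,
                              fraction_onsets_preceded, local_maxima,
                              p_star_first_order, p_star_zeroth, r0)
from altdyn.networks import build_match_phenotypes

from oracles import lineage_emergence_mc


def _state(hosts, viruses, **params):
    p = Params(**params)
    return SystemState(0.0, hosts, viruses, p)


class TestR0:
    def test_zero_susceptibles(self):
        s = _state([HostStrain(1, frozenset({1}), 100)],
                   [ViralStrain(2, tuple(range(1, 16)), 10)], g=15)
        (ph,) = build_match_phenotypes(s)
        assert r0(ph, s) == 0.0

    def test_hand_value(self):
        # beta=50, q=0, phi=1e-7, S=N=1e5, d=0.1 -> 50*0.01/0.11
        s = _state([HostStrain(1, frozenset(), 100_000)],
                   [ViralStrain(2, tuple(range(1, 16)), 10)],
                   beta=50, q=0.0, phi=1e-7, d=0.1, g=15)
        (ph,) = build_match_phenotypes(s)
        assert r0(ph, s) == pytest.approx(50 * 0.01 / 0.11, rel=1e-12)

    def test_strictly_increasing_in_extra_biomass(self):
        s = _state([HostStrain(1, frozenset(), 1000)],
                   [ViralStrain(2, tuple(range(1, 16)), 10)], g=15)
        (ph,) = build_match_phenotypes(s)
        vals = [r0(ph, s, extra_biomass=e) for e in (0, 10, 100, 1000)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_susceptible_only_denominator_larger(self):
        s = _state([HostStrain(1, frozenset(), 500),
                    HostStrain(3, frozenset({1}), 500)],
                   [ViralStrain(2, tuple(range(1, 16)), 10)], g=15)
        ph = [p for p in build_match_phenotypes(s)][0]
        assert r0(ph, s, denominator="susceptible") > r0(ph, s)


class TestPStarZeroth:
    def test_below_threshold_zero(self):
        for beta in (2, 10, 50):
            assert p_star_zeroth(1.0, beta) == 0.0

    @pytest.mark.parametrize("R0", [1.5, 2.0, 5.0])
    def test_lambert_fixed_point_identity(self, R0):
        beta = 50
        P = p_star_zeroth(R0, beta)
        sigma = R0 / (R0 + beta)
        assert abs(P - sigma * (1 - math.exp(-beta * P))) <= 1e-12
        assert P > 0

    def test_threshold_is_exact(self):
        beta = 50
        thr = beta / (beta - 1)
        assert p_star_zeroth(thr, beta) == 0.0
        assert p_star_zeroth(thr * 1.001, beta) > 0.0

    def test_large_r0_limit(self):
        assert p_star_zeroth(1e9, 50) == pytest.approx(1.0, abs=1e-6)


class TestPStarFirstOrder:
    def test_mu_zero_within_convention_gap_of_lambert(self):
        beta = 50
        for R0 in np.linspace(1.0, 5.0, 17):
            exact = p_star_first_order(R0, [], 0.0, beta, 15)
            lam = p_star_zeroth(R0, beta)
            assert abs(exact - lam) <= 2.0 / beta

    def test_no_escapes_independent_of_mu(self):
        a = p_star_first_order(2.0, [], 0.0, 50, 15)
        b = p_star_first_order(2.0, [], 1e-4, 50, 15)
        assert a == pytest.approx(b, abs=1e-12)

    def test_subcritical_with_supercritical_escape_is_positive(self):
        P = p_star_first_order(0.5, [3.0], 1e-5, 50, 15)
        assert p_star_zeroth(0.5, 50) == 0.0
        assert P > 0

    def test_monotone_in_r0_escapes_and_mu(self):
        base = p_star_first_order(2.0, [3.0], 1e-4, 50, 15)
        assert p_star_first_order(2.5, [3.0], 1e-4, 50, 15) > base
        assert p_star_first_order(2.0, [4.0], 1e-4, 50, 15) > base
        assert p_star_first_order(2.0, [3.0], 5e-4, 50, 15) > base
        assert p_star_first_order(2.0, [3.0, 3.0], 1e-4, 50, 15) > base

    def test_matches_lineage_simulation(self):
        rng = np.random.default_rng(11)
        analytic = p_star_first_order(2.0, [4.0], 2e-4, 50, 15)
        mc, se = lineage_emergence_mc(2.0, [4.0], 2e-4, 50, 15,
                                      200_000, rng)
        assert abs(analytic - mc) < 3 * se


class TestExpectedPStar:
    def _two_phenotype_state(self):
        # phenotype {1}: S=300 naive; phenotype {}: everything susceptible
        hosts = [HostStrain(1, frozenset(), 300),
                 HostStrain(2, frozenset({1}), 700)]
        viruses = [ViralStrain(3, (1,) + tuple(range(20, 34)), 40),
                   ViralStrain(4, tuple(range(40, 55)), 60)]
        return _state(hosts, viruses, g=15, beta=50, q=0.0, phi=1e-5, d=0.1)

    def test_single_phenotype_expectation_is_its_p_star(self):
        s = _state([HostStrain(1, frozenset(), 1000)],
                   [ViralStrain(2, tuple(range(1, 16)), 10)],
                   g=15, beta=50, phi=1e-5, d=0.1)
        EP, ER0, diffs = expected_p_star(s)
        (res,) = emergence_results(s)
        assert EP == pytest.approx(res.P_star, rel=1e-12)
        assert ER0 == pytest.approx(res.R0, rel=1e-12)
        assert diffs == [0.0, 0.0, 0.0]

    def test_two_phenotypes_hand_weights(self):
        s = self._two_phenotype_state()
        results = emergence_results(s)
        assert sum(r.weight for r in results) == pytest.approx(1.0)
        # w_i ~ V_i * S_i
        by_id = {r.phenotype_id: r for r in results}
        phenos = {p.phenotype_id: p for p in build_match_phenotypes(s)}
        raw = {i: phenos[i].V_i * phenos[i].S_i for i in phenos}
        tot = sum(raw.values())
        for i, r in by_id.items():
            assert r.weight == pytest.approx(raw[i] / tot)
        EP, ER0, diffs = expected_p_star(s)
        assert EP == pytest.approx(sum(r.weight * r.P_star for r in results))

    def test_escape_ranks_exceed_r0(self):
        s = self._two_phenotype_state()
        for r in emergence_results(s):
            for Rj in r.ranked_R:
                assert Rj >= r.R0
            assert r.ranked_R == sorted(r.ranked_R, reverse=True)

    def test_zero_virions_signal(self):
        s = _state([HostStrain(1, frozenset(), 10)], [], g=15)
        with pytest.raises(ValueError):
            expected_p_star(s)

    def test_abundance_fallback_when_no_susceptibles(self):
        hosts = [HostStrain(1, frozenset({1}), 500)]
        viruses = [ViralStrain(2, (1,) + tuple(range(20, 34)), 30)]
        s = _state(hosts, viruses, g=15)
        (res,) = emergence_results(s)
        assert res.weight == 1.0


class TestPeakHelpers:
    def test_local_maxima_with_plateau_and_floor(self):
        v = np.array([0, 1, 3, 3, 1, 0, 5, 0, 0.5])
        idx = local_maxima(v, floor=0.6)
        assert idx.tolist() == [2, 6]

    def test_onsets_preceded(self):
        t = np.arange(10.0)
        V = np.array([0, 0, 0, 10, 0, 0, 0, 20, 0, 0])
        ep = np.array([0, 0.5, 0.1, 0, 0, 0, 0, 0, 0, 0])
        nok, ntot = fraction_onsets_preceded(t, V, ep, v_floor=1.0, window=3)
        assert ntot == 2
        assert nok == 1  # only the first outbreak follows an <P*> maximum
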