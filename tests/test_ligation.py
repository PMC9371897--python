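"""Nick sealing, product enumeration and efficiency calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nicklattice import (
    CapacityError,
    designed_cycles,
    enumerate_products,
    estimate_efficiency,
    estimate_efficiency_from_lattice,
    outcome_from_sealed,
    predict_gel_pattern,
    product_distribution,
    seal_nicks,
)


def brute_force_species(lattice, outcome):
    """Independent oracle: union-find over strands joined by sealed nicks.

    A component is circular iff its sealed-nick count equals its strand
    count (every terminus consumed); returns a multiset of
    (length, circular, members)."""
    parent = {s: s for s in lattice.strands}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sealed_nicks = [lattice.nicks[n] for n, v in outcome.sealed.items() if v]
    for nick in sealed_nicks:
        parent[find(nick.upstream)] = find(nick.downstream)
    comps = {}
    for s in lattice.strands:
        comps.setdefault(find(s), set()).add(s)
    nick_count = {root: 0 for root in comps}
    for nick in sealed_nicks:
        nick_count[find(nick.upstream)] += 1
    out = []
    for root, members in comps.items():
        length = sum(lattice.strands[s].length for s in members)
        circular = nick_count[root] == len(members)
        out.append((length, circular, tuple(sorted(members))))
    return sorted(out)


class TestSealNicks:
    def test_p_one_seals_everything(self, j4_lattice):
        assert seal_nicks(j4_lattice, 1.0, seed=0).n_sealed == 120

    def test_p_zero_seals_nothing(self, j4_lattice):
        assert seal_nicks(j4_lattice, 0.0, seed=0).n_sealed == 0

    def test_seeded_reproducibility(self, j4_lattice):
        a = seal_nicks(j4_lattice, 0.5, seed=42)
        b = seal_nicks(j4_lattice, 0.5, seed=42)
        assert a.sealed == b.sealed

    def test_mean_sealed_count_matches_binomial(self, j4_lattice):
        """At p=0.89 the mean sealed count over reps is 120×0.89 = 106.8."""
        p, n_nicks, reps = 0.89, 120, 10_000
        rng = np.random.default_rng(7)
        counts = [seal_nicks(j4_lattice, p, rng=rng).n_sealed for _ in range(reps)]
        se = np.sqrt(n_nicks * p * (1 - p) / reps)
        assert abs(np.mean(counts) - 106.8) < 3 * se

    def test_non_ligatable_nicks_never_seal(self, j4_lattice):
        masked = j4_lattice.with_mask(list(j4_lattice.nicks)[:10])
        out = seal_nicks(masked, 1.0, seed=0)
        assert out.n_sealed == 10

    def test_invalid_p_rejected(self, j4_lattice):
        with pytest.raises(ValueError):
            seal_nicks(j4_lattice, 1.5, seed=0)


class TestEnumerateProducts:
    def test_no_sealing_returns_component_strands(self, small_lattice):
        out = outcome_from_sealed(small_lattice, [])
        species = enumerate_products(small_lattice, out)
        assert all(not sp.circular for sp in species)
        assert sorted(sp.length for sp in species) == sorted(
            s.length for s in small_lattice.strands.values()
        )

    def test_full_sealing_closes_designed_cycle(self, small_lattice):
        out = outcome_from_sealed(small_lattice, small_lattice.ligatable_nicks)
        circles = [sp for sp in enumerate_products(small_lattice, out) if sp.circular]
        assert len(circles) == 1
        assert circles[0].length == sum(
            small_lattice.strands[s].length for s in circles[0].member_strands
        )
        assert len(circles[0].member_strands) == 4

    @given(bits=st.integers(0, 255))
    @settings(max_examples=50, deadline=None)
    def test_matches_union_find_oracle(self, small_lattice, bits):
        """Chain-walking enumeration equals an independent union-find oracle."""
        lig = small_lattice.ligatable_nicks
        sealed = [n for i, n in enumerate(lig) if bits >> i & 1]
        out = outcome_from_sealed(small_lattice, sealed)
        species = sorted(
            (sp.length, sp.circular, sp.member_strands)
            for sp in enumerate_products(small_lattice, out)
        )
        assert species == brute_force_species(small_lattice, out)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_mass_conservation(self, j4_lattice, seed):
        out = seal_nicks(j4_lattice, 0.6, seed=seed)
        species = enumerate_products(j4_lattice, out)
        assert sum(sp.length * sp.count for sp in species) == j4_lattice.total_nt()


class TestProductDistribution:
    def test_point_mass_at_p_one(self, small_lattice):
        dist = product_distribution(small_lattice, 1.0, mode="exact")
        assert np.isclose(dist.table.mass_fraction.sum(), 1.0)
        assert (dist.table.frequency == 1.0).all()

    def test_toy_circle_circular_fraction_is_p_squared(self, toy_circle):
        lat = toy_circle
        p = 0.6
        dist = product_distribution(lat, p, mode="exact")
        circ = dist.table[dist.table.circular]
        assert len(circ) == 1
        # the 20-nt circle holds 2/3 of the 30-nt total mass when closed
        assert np.isclose(circ.frequency.iloc[0], p**2)
        assert np.isclose(circ.mass_fraction.iloc[0], p**2 * 20 / 30)

    @pytest.mark.parametrize("p", [0.3, 0.7, 0.9])
    def test_monte_carlo_matches_exact(self, small_lattice, p):
        """MC species frequencies agree with 2^8 enumeration within 3 SE."""
        n_reps = 20_000
        exact = product_distribution(small_lattice, p, mode="exact")
        mc = product_distribution(small_lattice, p, mode="monte_carlo", n_reps=n_reps, seed=5)
        exact_freq = exact.table.set_index(["length_nt", "circular", "members"]).frequency
        mc_freq = mc.table.set_index(["length_nt", "circular", "members"]).frequency
        for key, f in exact_freq.items():
            se = max(np.sqrt(f * (1 - f) / n_reps), 1e-12)
            got = mc_freq.get(key, 0.0)
            if f > 5 / n_reps:  # rare species may legitimately be unseen
                assert abs(got - f) < max(3 * se, 5 / n_reps)

    def test_exact_mode_capacity_error(self, j4_lattice):
        with pytest.raises(CapacityError):
            product_distribution(j4_lattice, 0.5, mode="exact")

    def test_mass_fractions_normalized(self, small_lattice):
        dist = product_distribution(small_lattice, 0.37, mode="exact")
        assert abs(dist.table.mass_fraction.sum() - 1.0) < 1e-9


class TestEfficiencyEstimate:
    def test_trivial_and_closed_form(self):
        assert estimate_efficiency(1.0, 4).p_hat == 1.0
        assert np.isclose(estimate_efficiency(0.25, 2).p_hat, 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_efficiency(-0.1, 4)
        with pytest.raises(ValueError):
            estimate_efficiency(0.5, 0)

    def test_round_trip_through_exact_distribution(self, small_lattice):
        """Inverting the exact circular fraction recovers the true p."""
        p = 0.8
        dist = product_distribution(small_lattice, p, mode="exact")
        f = float(dist.table[dist.table.circular].frequency.sum())
        est = estimate_efficiency_from_lattice(small_lattice, f)
        assert est.n_nicks == 4
        assert abs(est.p_hat - p) < 1e-9

    def test_designed_cycle_is_unique_on_2x2(self, small_lattice):
        cycles = designed_cycles(small_lattice)
        assert len(cycles) == 1
        strands, nicks = cycles[0]
        assert len(strands) == len(nicks) == 4


class TestGelPattern:
    def test_point_mass_single_band(self, small_lattice):
        dist = product_distribution(small_lattice, 1.0, mode="exact")
        bands = predict_gel_pattern(dist)
        assert np.isclose(bands.intensity.sum(), 1.0)

    def test_floor_suppresses_faint_bands(self, small_lattice):
        dist = product_distribution(small_lattice, 0.05, mode="exact")
        bands = predict_gel_pattern(dist, floor=0.005)
        assert (bands.intensity >= 0.005).all()

    def test_bands_merge_by_size_and_topology(self, small_lattice):
        dist = product_distribution(small_lattice, 0.6, mode="exact")
        bands = predict_gel_pattern(dist, floor=0.0)
        assert bands.set_index(["length_nt", "circular"]).index.is_unique
        assert np.isclose(bands.intensity.sum(), 1.0)
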