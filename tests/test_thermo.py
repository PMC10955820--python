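"""Thermodynamic backend: duplex free-energy DP against an exhaustive
enumeration oracle, the two-state equilibrium closed form against
root-finding, and physical sanity of the resulting yields."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import spearmanr

from hybriclass import nucleic, thermo
from hybriclass.nucleic import reverse_complement


@pytest.fixture(scope="module")
def params():
    return thermo.default_parameters()


@pytest.fixture(scope="module")
def conditions():
    return thermo.HybridizationConditions()


def brute_force_dg(a: str, b: str, params, temperature_celsius: float) -> float:
    """Independent oracle: enumerate every ungapped offset and every
    subset of the pairable positions as the paired set."""
    stack = params.stack_dg_table(temperature_celsius)
    init = params.init_dg(temperature_celsius)
    mm, lo, le = params.mismatch_penalty_dG, params.loop_open_dG, params.loop_extend_dG
    code = {bse: i for i, bse in enumerate("ATCG")}

    def gapcost(m):
        return min(mm * m, lo + le * (m - 1))

    brc = reverse_complement(b)
    best = np.inf
    la, lb = len(a), len(b)
    for shift in range(-(la - 1), lb):
        i0, i1 = max(0, -shift), min(la, lb - shift)
        comp = [i for i in range(i0, i1) if a[i] == brc[i + shift]]
        for bits in range(1, 1 << len(comp)):
            chosen = [comp[j] for j in range(len(comp)) if bits >> j & 1]
            e = 0.0
            for p, q in zip(chosen, chosen[1:]):
                e += stack[code[a[p]], code[a[q]]] if q == p + 1 else gapcost(q - p - 1)
            best = min(best, init + e)
    return best


class TestDuplexFreeEnergy:
    def test_perfect_12mer_regression(self, params):
        # hand-summed from the bundled table at 25 C: 11 stacks + initiation
        a = "ATCGGATTCCAG"
        dg = thermo.duplex_free_energy(a, reverse_complement(a), params, 25.0)
        assert dg == pytest.approx(-16.2551, abs=1e-4)
        stack = params.stack_dg_table(25.0)
        code = {b: i for i, b in enumerate("ATCG")}
        expected = params.init_dg(25.0) + sum(
            stack[code[x], code[y]] for x, y in zip(a, a[1:])
        )
        assert dg == pytest.approx(expected, abs=1e-12)

    def test_poly_a_cannot_bind_poly_a(self):
        assert np.isinf(thermo.duplex_free_energy("A" * 10, "A" * 10))

    def test_too_short_is_no_binding(self):
        assert np.isinf(thermo.duplex_free_energy("A", "T"))

    def test_dp_equals_brute_force_on_200_random_pairs(self, params):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = nucleic.random_sequence(int(rng.integers(2, 13)), rng=rng)
            b = nucleic.random_sequence(int(rng.integers(2, 13)), rng=rng)
            dp = thermo.duplex_free_energy(a, b, params, 25.0)
            bf = brute_force_dg(a, b, params, 25.0)
            if np.isinf(bf):
                assert np.isinf(dp)
            else:
                assert dp == pytest.approx(bf, abs=1e-9), (a, b)

    def test_all_wc_stacks_stabilizing_at_37(self, params):
        for d in ("AA", "AT", "TA", "CA", "GT", "CT", "GA", "CG", "GC", "GG"):
            assert params.stack_dg(d, 37.0) < 0

    def test_stack_table_reverse_complement_symmetry(self, params):
        for d in ("AC", "TC", "AG", "TG", "CC", "TT"):
            rc = reverse_complement(d)
            assert params.stack_dg(d, 25.0) == pytest.approx(params.stack_dg(rc, 25.0))


class TestEquilibriumYield:
    def test_unit_keq_times_c0(self, conditions):
        # K*c0 = 1  =>  (1-y)^2 = y  =>  y = (3 - sqrt(5))/2
        rt = thermo.R_KCAL * (conditions.temperature_celsius + 273.15)
        dg = rt * np.log(conditions.initial_concentration_molar)
        y = thermo.equilibrium_yield(dg, conditions)
        assert y == pytest.approx((3 - np.sqrt(5)) / 2, abs=1e-12)

    def test_no_binding_sentinel_gives_zero(self, conditions):
        assert thermo.equilibrium_yield(np.inf, conditions) == 0.0

    def test_complete_binding_limit(self, conditions):
        assert thermo.equilibrium_yield(-200.0, conditions) == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_matches_bisection_to_1e9(self, conditions):
        rt = thermo.R_KCAL * (conditions.temperature_celsius + 273.15)
        c0 = conditions.initial_concentration_molar
        for dg in np.linspace(-80.0, 10.0, 181):
            y = thermo.equilibrium_yield(dg, conditions)
            x = np.exp(min(-dg / rt + np.log(c0), 700.0))
            if x > 1e14:  # root indistinguishable from 1 at solver precision
                assert y == pytest.approx(1.0, abs=1e-7)
                continue
            root = brentq(lambda t: x * (1 - t) ** 2 - t, 0.0, 1.0, xtol=1e-12)
            assert y == pytest.approx(root, abs=1e-9)

    def test_monotone_in_dg(self, conditions):
        dgs = np.linspace(-40, 10, 200)
        ys = [thermo.equilibrium_yield(d, conditions) for d in dgs]
        assert all(a >= b for a, b in zip(ys, ys[1:]))

    def test_monotone_in_concentration(self):
        ys = [
            thermo.equilibrium_yield(
                -12.0, thermo.HybridizationConditions(initial_concentration_molar=c)
            )
            for c in (1e-12, 1e-10, 1e-9, 1e-7, 1e-5)
        ]
        assert all(a <= b for a, b in zip(ys, ys[1:]))


class TestPredictYield:
    def test_perfect_complements_bind_completely(self, conditions):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = nucleic.random_sequence(59, rng=rng)
            assert thermo.predict_yield(s, reverse_complement(s), conditions) > 0.99

    def test_random_pairs_mostly_inert(self, conditions):
        rng = np.random.default_rng(8)
        a = [nucleic.random_sequence(59, rng=rng) for _ in range(200)]
        b = [nucleic.random_sequence(59, rng=rng) for _ in range(200)]
        ys = thermo.pair_yields(a, b, conditions)
        assert np.median(ys) < 0.05

    def test_symmetry(self, conditions):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a = nucleic.random_sequence(int(rng.integers(5, 30)), rng=rng)
            b = nucleic.random_sequence(int(rng.integers(5, 30)), rng=rng)
            assert thermo.predict_yield(a, b, conditions) == pytest.approx(
                thermo.predict_yield(b, a, conditions), abs=1e-12
            )

    def test_mutation_count_anticorrelates_with_yield(self, conditions):
        rng = np.random.default_rng(10)
        ks, ys = [], []
        for _ in range(50):
            s = nucleic.random_sequence(59, rng=rng)
            mate = list(reverse_complement(s))
            for k in range(0, 21, 5):
                m = mate.copy()
                for p in rng.choice(59, size=k, replace=False):
                    m[p] = "ATCG"[(("ATCG".index(m[p])) + int(rng.integers(1, 4))) % 4]
                ks.append(k)
                ys.append(thermo.predict_yield(s, "".join(m), conditions))
        assert spearmanr(ks, ys).statistic < 0

    def test_adapter_backend_requires_registration(self):
        cond = thermo.HybridizationConditions(backend="external_adapter")
        thermo.register_adapter(None)
        with pytest.raises(thermo.BackendError):
            thermo.predict_yield("ACGTACGT", "ACGTACGT", cond)

    def test_adapter_backend_forwards(self):
        cond = thermo.HybridizationConditions(backend="external_adapter")
        calls = []

        def fake(a, b, conditions):
            calls.append((a, b, conditions.temperature_celsius))
            return 0.42

        thermo.register_adapter(fake)
        try:
            assert thermo.predict_yield("ACGT", "ACGT", cond) == 0.42
            assert calls == [("ACGT", "ACGT", 25.0)]
        finally:
            thermo.register_adapter(None)


class TestYieldMatrix:
    def test_single_pair_consistency(self, conditions):
        a, b = "ATCGGATTCCAG", "GGATCCATTGCA"
        m = thermo.yield_matrix([a], [b], conditions)
        assert m.shape == (1, 1)
        assert m[0, 0] == pytest.approx(thermo.predict_yield(a, b, conditions))

    def test_symmetric_for_identical_lists(self, conditions):
        rng = np.random.default_rng(11)
        seqs = [nucleic.random_sequence(20, rng=rng) for _ in range(6)]
        m = thermo.yield_matrix(seqs, seqs, conditions)
        np.testing.assert_allclose(m, m.T, atol=1e-12)

    def test_entries_in_unit_interval(self, conditions):
        rng = np.random.default_rng(12)
        q = [nucleic.random_sequence(59, rng=rng) for _ in range(10)]
        t = [nucleic.random_sequence(59, rng=rng) for _ in range(50)]
        m = thermo.yield_matrix(q, t, conditions)
        assert m.shape == (10, 50)
        assert np.all((m >= 0) & (m <= 1))

    def test_empty_input_rejected(self, conditions):
        with pytest.raises(ValueError):
            thermo.yield_matrix([], ["ACGT"], conditions)


class TestConditionsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"temperature_celsius": -5},
            {"temperature_celsius": 150},
            {"initial_concentration_molar": 0.0},
            {"max_complex_size": 3},
            {"backend": "nupack"},
        ],
    )
    def test_invalid_conditions(self, kwargs):
        with pytest.raises(ValueError):
            thermo.HybridizationConditions(**kwargs)
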