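"""Abeles engine: Fresnel physics, oracle agreement, smearing, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slbnr.reflectivity import (
    SI_SLD,
    ReflectivityCurve,
    Slab,
    SlabStack,
    abeles_reflectivity,
    critical_q,
    effective_sld,
    smear,
    smeared_reflectivity,
)
from slbnr.scattering import D2O_SLD

from _parratt import parratt_reflectivity

Q = np.logspace(np.log10(0.005), np.log10(0.4), 120)


def to_parratt_args(stack: SlabStack, solvent_sld: float):
    resolved = stack.with_solvent(solvent_sld)
    layers = [(s.thickness, s.sld, s.roughness) for s in resolved.slabs]
    return (
        stack.fronting_sld,
        layers,
        solvent_sld,
        stack.backing_roughness,
    )


class TestEffectiveSld:
    def test_pure_solvent(self):
        assert effective_sld(Slab(10, 1.5, 1.0), 6.36) == 6.36

    def test_no_solvent(self):
        assert effective_sld(Slab(10, 1.5, 0.0), 6.36) == 1.5

    def test_hand_value(self):
        # 0.06*6.36 + 0.94*6.66 = 6.642
        assert effective_sld(Slab(41, 6.66, 0.06), 6.36) == pytest.approx(
            6.642, abs=1e-12
        )


class TestCriticalEdge:
    def test_total_reflection_below_si_d2o_edge(self):
        qc = critical_q(SI_SLD, D2O_SLD)
        assert qc == pytest.approx(np.sqrt(16 * np.pi * (D2O_SLD - 2.07) * 1e-6))
        q = np.linspace(0.002, qc * 0.999, 50)
        r = abeles_reflectivity(SlabStack(()), D2O_SLD, q)
        np.testing.assert_allclose(r, 1.0, atol=1e-10)

    def test_reflectivity_falls_above_edge(self):
        qc = critical_q(SI_SLD, D2O_SLD)
        r = abeles_reflectivity(SlabStack(()), D2O_SLD, np.array([2 * qc]))
        assert r[0] < 0.1


class TestOracleAgreement:
    def test_random_stacks_match_parratt(self):
        from conftest import random_stack_arrays

        rng = np.random.default_rng(20151211)
        for _ in range(100):
            fronting, layers, backing, back_sigma = random_stack_arrays(rng)
            stack = SlabStack(
                tuple(Slab(d, sld, 0.0, sig) for d, sld, sig in layers),
                fronting_sld=fronting,
                backing_roughness=back_sigma,
            )
            r_abeles = abeles_reflectivity(stack, backing, Q)
            r_parratt = parratt_reflectivity(*to_parratt_args(stack, backing), Q)
            np.testing.assert_allclose(r_abeles, r_parratt, rtol=1e-10, atol=1e-15)

    def test_single_slab_closed_form(self):
        """Zero-roughness one-slab stack vs the analytic two-interface result."""
        d, rho = 120.0, 4.5
        stack = SlabStack((Slab(d, rho, 0.0, 0.0),), fronting_sld=2.07)
        backing = 6.0
        k0 = Q / 2.0
        k1 = np.sqrt((k0**2 - 4e-6 * np.pi * (rho - 2.07)).astype(complex))
        k2 = np.sqrt((k0**2 - 4e-6 * np.pi * (backing - 2.07)).astype(complex))
        r01 = (k0 - k1) / (k0 + k1)
        r12 = (k1 - k2) / (k1 + k2)
        phase = np.exp(2j * k1 * d)
        r = (r01 + r12 * phase) / (1 + r01 * r12 * phase)
        np.testing.assert_allclose(
            abeles_reflectivity(stack, backing, Q), np.abs(r) ** 2, rtol=1e-10
        )


class TestStackInvariances:
    BILAYER = (
        Slab(12, 3.47, 0.0, 3.0),
        Slab(8, 0.0, 1.0, 4.0),
        Slab(7, 1.55, 0.35, 4.0),
        Slab(27, -0.55, 0.12, 4.0),
        Slab(7, 1.55, 0.35, 4.0),
    )

    def test_zero_thickness_slab_is_inert(self):
        base = SlabStack(self.BILAYER, backing_roughness=4.0)
        r0 = abeles_reflectivity(base, D2O_SLD, Q)
        for pos in range(len(self.BILAYER) + 1):
            slabs = list(self.BILAYER)
            slabs.insert(pos, Slab(0.0, 3.3, 0.0, 0.0))
            r = abeles_reflectivity(
                SlabStack(tuple(slabs), backing_roughness=4.0), D2O_SLD, Q
            )
            np.testing.assert_allclose(r, r0, rtol=0, atol=1e-12)

    def test_merging_identical_adjacent_slabs(self):
        split = (
            Slab(12, 3.47, 0.0, 3.0),
            Slab(15, -0.55, 0.12, 4.0),
            Slab(12, -0.55, 0.12, 0.0),  # zero roughness between the halves
        )
        merged = (
            Slab(12, 3.47, 0.0, 3.0),
            Slab(27, -0.55, 0.12, 4.0),
        )
        r_split = abeles_reflectivity(SlabStack(split), D2O_SLD, Q)
        r_merged = abeles_reflectivity(SlabStack(merged), D2O_SLD, Q)
        np.testing.assert_allclose(r_split, r_merged, rtol=1e-10, atol=1e-15)

    def test_no_contrast_means_no_reflection(self):
        slabs = (Slab(50, 4.0, 0.0, 0.0), Slab(30, 4.0, 0.0, 0.0))
        r = abeles_reflectivity(SlabStack(slabs, fronting_sld=4.0), 4.0, Q)
        np.testing.assert_allclose(r, 0.0, atol=1e-15)

    def test_fresnel_q4_envelope_at_large_q(self):
        """R·Q⁴ approaches the Born-limit constant 16π²Δρ² for any finite stack."""
        stack = SlabStack(self.BILAYER, backing_roughness=4.0)
        drho = (D2O_SLD - SI_SLD) * 1e-6
        born = 16 * np.pi**2 * drho**2
        q_hi = np.linspace(1.0, 1.5, 20)
        ratio = abeles_reflectivity(stack, D2O_SLD, q_hi) * q_hi**4 / born
        assert np.all(ratio < 3.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_reflectivity_bounded_unit_interval(self, seed):
        from conftest import random_stack_arrays

        rng = np.random.default_rng(seed)
        fronting, layers, backing, back_sigma = random_stack_arrays(rng)
        stack = SlabStack(
            tuple(Slab(d, sld, 0.0, sig) for d, sld, sig in layers),
            fronting_sld=fronting,
            backing_roughness=back_sigma,
        )
        r = abeles_reflectivity(stack, backing, Q)
        assert np.all(r >= 0.0) and np.all(r <= 1.0)

    def test_nonfinite_parameters_rejected(self):
        stack = SlabStack((Slab(10, np.nan, 0.0, 0.0),))
        with pytest.raises(ValueError, match="non-finite"):
            abeles_reflectivity(stack, 6.36, Q)

    def test_roughness_exceeding_neighbour_warns(self):
        with pytest.warns(UserWarning, match="roughness"):
            SlabStack((Slab(41, 6.66, 0.0, 1.0), Slab(5, 0.0, 1.0, 10.0)))


class TestSmearing:
    def test_zero_resolution_is_identity(self):
        r = np.exp(-Q * 10)
        np.testing.assert_array_equal(smear(Q, r, 0.0), r)
        stack = SlabStack(self.fringe_stack())
        np.testing.assert_array_equal(
            smeared_reflectivity(stack, D2O_SLD, Q, 0.0),
            abeles_reflectivity(stack, D2O_SLD, Q),
        )

    def test_constant_curve_unchanged(self):
        r = np.full(Q.size, 0.37)
        np.testing.assert_allclose(smear(Q, r, 0.08), r, rtol=1e-12)

    @staticmethod
    def fringe_stack():
        return (Slab(300.0, 4.5, 0.0, 0.0),)

    def test_kiessig_fringes_damped_at_every_extremum(self):
        """8% smearing must reduce the fringe amplitude of a thick slab."""
        stack = SlabStack(self.fringe_stack())
        q = np.linspace(0.05, 0.2, 600)
        exact = abeles_reflectivity(stack, D2O_SLD, q)
        smeared = smeared_reflectivity(stack, D2O_SLD, q, 0.08)
        log_e, log_s = np.log10(exact), np.log10(smeared)
        trend = np.poly1d(np.polyfit(np.log10(q), log_e, 2))(np.log10(q))
        interior = slice(20, -20)
        assert np.max(np.abs(log_s - trend)[interior]) < np.max(
            np.abs(log_e - trend)[interior]
        )

    def test_negative_resolution_rejected(self):
        with pytest.raises(ValueError):
            smear(Q, np.ones_like(Q), -0.1)


class TestCurveValidation:
    def test_requires_increasing_positive_q(self):
        with pytest.raises(ValueError):
            ReflectivityCurve([0.2, 0.1], [1, 1])
        with pytest.raises(ValueError):
            ReflectivityCurve([-0.1, 0.1], [1, 1])

    def test_dr_must_be_positive(self):
        with pytest.raises(ValueError):
            ReflectivityCurve([0.1, 0.2], [1, 1], [0.1, 0.0])
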