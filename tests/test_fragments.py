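"""Fragment-ion mass arithmetic and pair-relation predicates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cidcharge import (
    SimParams,
    Spectrum,
    Tolerance,
    by_ion_mz,
    doubly_charged_flags,
    enumerate_pair_relations,
    generate_dataset,
    is_cp11,
    is_cp12,
    is_doubly_charged_peak,
)
from cidcharge.fragments import basic_site_pair_mask

from oracles import (
    brute_force_basic_site_count,
    brute_force_doubly_charged,
    brute_force_relations,
    random_spectrum,
)


class TestByIonMz:
    def test_y1_of_lysine(self, constants):
        # residue K + water + proton
        assert by_ion_mz("K", "C", 1, constants) == pytest.approx(147.1128, abs=1e-4)

    def test_b1_of_glycine(self, constants):
        assert by_ion_mz("G", "N", 1, constants) == pytest.approx(58.02874, abs=1e-5)

    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25),
        st.sampled_from(["N", "C"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_charge2_is_charge1_plus_proton_halved(self, sequence, terminal):
        from cidcharge import DEFAULT_CONSTANTS as c

        single = by_ion_mz(sequence, terminal, 1, c)
        double = by_ion_mz(sequence, terminal, 2, c)
        assert double == pytest.approx((single + c.proton) / 2.0, rel=1e-12)

    def test_unknown_residue_rejected(self, constants):
        with pytest.raises(ValueError, match="residue"):
            by_ion_mz("GXZ", "N", 1, constants)


class TestPairPredicates:
    def test_cp11_constructed_identity(self, constants, tol_half):
        assert is_cp11(200.0, 800.0, 500.0, 2, constants, tol_half)

    def test_cp11_outside_window(self, constants, tol_half):
        assert not is_cp11(200.0, 800.6, 500.0, 2, constants, tol_half)

    def test_cp12_constructed_identity(self, constants, tol_half):
        # 300 + 2*450 = 1200 = 3*400
        assert is_cp12(300.0, 450.0, 400.0, 3, "high", constants, tol_half)

    def test_cp12_narrow_tolerance(self, constants):
        assert not is_cp12(300.0, 450.3, 400.0, 3, "high", constants, Tolerance(0.1))

    def test_member_order_enforced(self, constants, tol_half):
        with pytest.raises(ValueError):
            is_cp11(800.0, 200.0, 500.0, 2, constants, tol_half)
        with pytest.raises(ValueError):
            is_cp12(800.0, 200.0, 500.0, 2, "low", constants, tol_half)

    def test_generated_plus2_siblings_all_match_cp11(self, constants, tol_half):
        params = SimParams(
            n_spectra=20, frac_plus3=0.0, fragmentation_efficiency=1.0,
            noise_peaks_per_spectrum=0.0, mz_jitter_sd=0.0, seed=11,
        )
        collection, truths = generate_dataset(params)
        for spectrum, truth in zip(collection, truths):
            by_bond = {}
            for k, origin in enumerate(truth.peak_origins):
                if origin >= 0:
                    by_bond.setdefault(truth.ions[origin].bond_index, []).append(k)
            for members in by_bond.values():
                if len(members) != 2:
                    continue  # peaks merged or bond half-detected
                i, j = sorted(members, key=lambda k: spectrum.mz[k])
                assert is_cp11(
                    spectrum.mz[i], spectrum.mz[j], spectrum.precursor_mz, 2,
                    constants, tol_half,
                )

    def test_generated_plus3_siblings_all_match_cp12(self, constants, tol_half):
        params = SimParams(
            n_spectra=20, frac_plus3=1.0, plus12_fraction_for_3=1.0,
            fragmentation_efficiency=1.0, noise_peaks_per_spectrum=0.0,
            mz_jitter_sd=0.0, seed=11,
        )
        collection, truths = generate_dataset(params)
        checked = 0
        for spectrum, truth in zip(collection, truths):
            by_bond = {}
            for k, origin in enumerate(truth.peak_origins):
                if origin >= 0:
                    ion = truth.ions[origin]
                    by_bond.setdefault(ion.bond_index, []).append((k, ion.charge))
            for members in by_bond.values():
                if len(members) != 2:
                    continue
                (ka, za), (kb, zb) = members
                if {za, zb} != {1, 2}:
                    continue
                i, j = sorted((ka, kb), key=lambda k: spectrum.mz[k])
                charge_of_low = za if i == ka else zb
                which = "low" if charge_of_low == 2 else "high"
                assert is_cp12(
                    spectrum.mz[i], spectrum.mz[j], spectrum.precursor_mz, 3,
                    which, constants, tol_half,
                )
                checked += 1
        assert checked > 50


class TestDoublyChargedPeaks:
    def test_plus1_counterpart_flags_peak(self, constants, tol_half):
        s = Spectrum("s", 600.0, mz=[250.0, 499.0], intensity=[1.0, 1.0])
        assert is_doubly_charged_peak(0, s, constants, tol_half)

    def test_single_peak_never_flagged(self, constants, tol_half):
        s = Spectrum("s", 600.0, mz=[250.0], intensity=[1.0])
        assert not is_doubly_charged_peak(0, s, constants, tol_half)

    def test_out_of_range_index(self, constants, tol_half):
        s = Spectrum("s", 600.0, mz=[250.0], intensity=[1.0])
        with pytest.raises(IndexError):
            is_doubly_charged_peak(5, s, constants, tol_half)

    def test_agrees_with_brute_force(self, constants, tol_half, rng):
        for _ in range(100):
            s = random_spectrum(rng)
            expected = brute_force_doubly_charged(
                s.mz, s.precursor_mz, constants, tol_half.tol
            )
            np.testing.assert_array_equal(
                doubly_charged_flags(s, constants, tol_half), expected
            )


class TestEnumerateRelations:
    def test_single_exact_cp11(self, constants, tol_half):
        s = Spectrum("s", 500.0, mz=[200.0, 800.0], intensity=[1.0, 1.0])
        rels = enumerate_pair_relations(s, constants, tol_half, losses_enabled=False)
        assert len(rels) == 1
        assert (rels[0].kind, rels[0].charge_hypothesis, rels[0].loss_applied) == ("CP11", 2, None)

    def test_small_spectra_give_empty_list(self, constants, tol_half):
        s = Spectrum("s", 500.0, mz=[200.0], intensity=[1.0])
        assert enumerate_pair_relations(s, constants, tol_half) == []

    @pytest.mark.parametrize("losses", [False, True])
    def test_agrees_with_brute_force(self, constants, tol_half, rng, losses):
        for _ in range(100):
            s = random_spectrum(rng)
            got = sorted(
                (r.i, r.j, r.kind, r.charge_hypothesis)
                for r in enumerate_pair_relations(s, constants, tol_half, losses)
            )
            expected = brute_force_relations(
                s.mz, s.precursor_mz, constants, tol_half.tol, losses
            )
            assert got == expected

    def test_each_combination_appears_once(self, constants, tol_half, rng):
        s = random_spectrum(rng, n_peaks=25)
        rels = enumerate_pair_relations(s, constants, tol_half, True)
        keys = [(r.i, r.j, r.kind, r.charge_hypothesis) for r in rels]
        assert len(keys) == len(set(keys))

    def test_monotone_in_tolerance(self, constants, rng):
        s = random_spectrum(rng, n_peaks=20)
        narrow = {
            (r.i, r.j, r.kind, r.charge_hypothesis)
            for r in enumerate_pair_relations(s, constants, Tolerance(0.2), True)
        }
        wide = {
            (r.i, r.j, r.kind, r.charge_hypothesis)
            for r in enumerate_pair_relations(s, constants, Tolerance(0.8), True)
        }
        assert narrow <= wide

    def test_no_loss_subset_of_losses(self, constants, tol_half, rng):
        s = random_spectrum(rng, n_peaks=20)
        without = {
            (r.i, r.j, r.kind, r.charge_hypothesis)
            for r in enumerate_pair_relations(s, constants, tol_half, False)
        }
        with_losses = {
            (r.i, r.j, r.kind, r.charge_hypothesis)
            for r in enumerate_pair_relations(s, constants, tol_half, True)
        }
        assert without <= with_losses


class TestBasicSitePairs:
    def test_agrees_with_brute_force(self, constants, tol_half, rng):
        for _ in range(100):
            s = random_spectrum(rng)
            _, _, mask = basic_site_pair_mask(s, constants, tol_half, True)
            assert int(mask.sum()) == brute_force_basic_site_count(
                s.mz, constants, tol_half.tol, True
            )
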