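"""Strike-energy scenarios, velocity back-solving and the comparative table."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caudawhip import reference as ref
from caudawhip.energy import (
    ComparativeRow,
    back_solve_velocity,
    comparative_table,
    evaluate_scenarios,
    kinetic_energy,
    transferred_energy,
)
from caudawhip.errors import ValidationError
from caudawhip.mass import TailMassModel

positive = st.floats(1e-3, 1e4)


class TestKineticEnergy:
    def test_closed_forms(self):
        assert kinetic_energy(5.0, 0.0) == 0.0
        assert kinetic_energy(2.0, 3.0) == pytest.approx(9.0)

    def test_diplodocus_strike(self):
        assert kinetic_energy(33.2, 104.0) == pytest.approx(179_545.6)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValidationError):
            kinetic_energy(0.0, 3.0)

    @given(m=positive, v=positive)
    @settings(max_examples=50, deadline=None)
    def test_quadratic_in_velocity_linear_in_mass(self, m, v):
        e = kinetic_energy(m, v)
        assert kinetic_energy(m, 2 * v) == pytest.approx(4 * e, rel=1e-12)
        assert kinetic_energy(2 * m, v) == pytest.approx(2 * e, rel=1e-12)


class TestTransferredEnergy:
    def test_identity_at_full_efficiency(self):
        assert transferred_energy(123.0, 1.0) == 123.0

    @pytest.mark.parametrize(
        "total_kj, expected_kj",
        list(zip(ref.TABLE1["whole_tail_energy_kJ"], ref.TABLE1["transferred_energy_kJ"])),
    )
    def test_published_transferred_row_at_085(self, total_kj, expected_kj):
        assert round(transferred_energy(total_kj, 0.85), 3) == expected_kj

    def test_transferred_never_exceeds_total(self):
        assert transferred_energy(10.0, 0.85) < 10.0

    def test_efficiency_bounds(self):
        with pytest.raises(ValidationError):
            transferred_energy(10.0, 0.0)
        with pytest.raises(ValidationError):
            transferred_energy(10.0, 1.1)


class TestBackSolveVelocity:
    @given(m=positive, v=positive)
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, m, v):
        assert back_solve_velocity(kinetic_energy(m, v), m) == pytest.approx(
            v, rel=1e-12
        )

    def test_velocity_implied_by_published_whole_tail_energy(self):
        v = back_solve_velocity(56_136.0, 26.5)
        assert v == pytest.approx(math.sqrt(2 * 56_136.0 / 26.5))
        assert v == pytest.approx(65.1, abs=0.05)

    def test_velocity_implied_by_published_whiplash_energy(self):
        assert back_solve_velocity(537.0, 0.3) == pytest.approx(59.8, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            back_solve_velocity(0.0, 1.0)
        with pytest.raises(ValidationError):
            back_solve_velocity(1.0, 0.0)


class TestEvaluateScenarios:
    @staticmethod
    def _models(m_whole, m_whip):
        # cone dimensions chosen so the cone mass equals the requested mass
        def model(mass):
            # mass = (pi/3) r^2 l * 0.8/1000 with r=10 -> solve l
            l = mass * 1000 / 0.8 / ((math.pi / 3) * 100)
            return TailMassModel(radius_cm=10.0, length_cm=l)

        return model(m_whole), model(m_whip)

    def test_basic_arithmetic(self):
        whole, whip = self._models(1.0, 0.5)
        rep = evaluate_scenarios(
            whole,
            whip,
            whole_tail_velocity_m_s=2.0,
            whiplash_velocity_m_s=2.0,
            transfer_efficiency=0.5,
        )
        assert rep.energies_j["whole_tail"] == pytest.approx(2.0)
        assert rep.energies_j["whip_transferred"] == pytest.approx(1.0)
        assert rep.energies_j["quick_whiplash"] == pytest.approx(1.0)

    def test_published_masses_with_implied_velocities_regenerate_grid(self):
        # back-solved velocities + printed masses must reproduce the printed
        # kJ grid column by column, including the transferred row at 0.85
        for i, col in enumerate(ref.TABLE1_COLUMNS):
            m_tail = ref.TABLE1["tail_mass_kg"][i]
            m_whip = ref.TABLE1["whiplash_mass_kg"][i]
            v_tail = back_solve_velocity(
                ref.TABLE1["whole_tail_energy_kJ"][i] * 1000, m_tail
            )
            v_whip = back_solve_velocity(
                ref.TABLE1["quick_whiplash_energy_kJ"][i] * 1000, m_whip
            )
            whole, whip = self._models(m_tail, m_whip)
            rep = evaluate_scenarios(
                whole,
                whip,
                whole_tail_velocity_m_s=v_tail,
                whiplash_velocity_m_s=v_whip,
                transfer_efficiency=0.85,
            )
            kj = rep.energies_kj
            assert round(kj["whole_tail"], 3) == ref.TABLE1["whole_tail_energy_kJ"][i]
            assert round(kj["whip_transferred"], 3) == ref.TABLE1["transferred_energy_kJ"][i]
            assert round(kj["quick_whiplash"], 3) == ref.TABLE1["quick_whiplash_energy_kJ"][i]

    def test_stated_velocity_orders_of_magnitude_below_published(self):
        whole, whip = self._models(26.5, 0.3)
        rep = evaluate_scenarios(
            whole, whip, whole_tail_velocity_m_s=2.0, whiplash_velocity_m_s=2.0
        )
        assert rep.energies_j["whole_tail"] == pytest.approx(53.0)
        assert rep.energies_kj["whole_tail"] < ref.TABLE1["whole_tail_energy_kJ"][0] / 100


class TestComparativeTable:
    def test_diplodocus_row(self):
        row = ComparativeRow(
            specimen_id="NHMW 1904/0004/0003",
            taxon="Diplodocus carnegii",
            n_caudals=70,
            total_length_m=13.26,
            whip_length_m=7.28,
            energy_kj=kinetic_energy(33.2, 104.0) / 1000,
        )
        df = comparative_table([row])
        rec = df.iloc[0]
        assert rec["whip_pct"] == pytest.approx(54.90, abs=0.005)
        # the printed value is truncated: the cell may round to 179.55
        assert abs(rec["energy_kJ"] - 179.54) <= 0.01 + 1e-9

    def test_blank_whip_columns_when_no_segment(self):
        row = ComparativeRow(
            specimen_id="x", taxon="t", n_caudals=10,
            total_length_m=1.0, whip_length_m=None, energy_kj=None,
        )
        rec = comparative_table([row]).iloc[0]
        assert rec["whip_length_m"] is None or math.isnan(rec["whip_length_m"])
        assert rec["whip_pct"] is None or math.isnan(rec["whip_pct"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            comparative_table([])
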