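"""Morphologies, SWC I/O, compartmentalization and channel tables."""

import math

import numpy as np
import pytest

from retistim.cells import (
    assign_channels,
    bc_channel_table,
    build_bc_cell,
    build_rgc_cell,
    compartmentalize,
    load_channel_table,
    rgc_channel_table,
)
from retistim.morphology import (
    BCParams,
    Morphology,
    RGCParams,
    Section,
    build_a2_rgc,
    build_db4_bc,
    read_swc,
    write_swc,
)

# printed channel densities: DB4 spiking bipolar cell, mS/cm^2
TABLE2 = {
    "soma": {"g_Kslow": 0.6, "g_caT": 1.0},
    "dendrite": {"g_Kslow": 2.4, "g_caT": 1.0},
    "axon": {"g_Na": 1000.0, "g_Kfast": 2.0},
    "presynaptic_terminal": {"g_caL": 1.0, "g_HCN": 3.25},
    "terminal": {},
}
# printed channel densities: A2 RGC, S/cm^2 (with derived rows expanded)
TABLE3_S_CM2 = {
    "soma": {"g_Na": 0.35, "g_K": 0.12, "g_K_A": 0.36, "g_K_Ca": 0.00048,
             "g_Ca": 0.137, "g_T": 0.004},
    "dendrite": {"g_Na": 0.1, "g_K": 0.05, "g_K_A": 0.15, "g_K_Ca": 0.0002,
                 "g_Ca": 0.05},
    "AH": {"g_Na": 0.8, "g_K": 0.6, "g_K_A": 1.8},
    "SOCB": {"g_Na": 2.4, "g_K": 0.8, "g_K_A": 2.4},
    "NS": {"g_Na": 0.9, "g_K": 0.6, "g_K_A": 1.8},
    "DA": {"g_Na": 0.8, "g_K": 0.6, "g_K_A": 1.8},
}


class TestBipolarMorphology:
    def test_five_regions_present(self):
        m = build_db4_bc()
        assert m.regions == {"soma", "dendrite", "axon",
                             "presynaptic_terminal", "terminal"}

    def test_total_height_is_sum_of_sections(self):
        m = build_db4_bc()
        assert m.total_length_um() == pytest.approx(65.0)
        p = BCParams(axon_len=50.0)
        assert build_db4_bc(p).total_length_um() == pytest.approx(80.0)

    def test_rotation_leaves_areas_and_resistances_unchanged(self):
        m = build_db4_bc()
        rot = np.array([[0, 0, 1], [0, 1, 0], [-1, 0, 0]], dtype=float)
        m_rot = m.transformed(lambda p: rot @ p)
        a = compartmentalize(m, 5.0, 1.0, 100.0)
        b = compartmentalize(m_rot, 5.0, 1.0, 100.0)
        assert np.allclose(a.area_cm2, b.area_cm2)
        assert np.allclose(a.axial_r_ohm, b.axial_r_ohm)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            build_db4_bc(BCParams(axon_len=0.0))


class TestRGCMorphology:
    def test_soma_diameter(self):
        soma = [s for s in build_a2_rgc().sections if s.region == "soma"][0]
        assert soma.d0 == 20.0

    def test_axon_regions_sum_to_total(self):
        m = build_a2_rgc()
        axon_len = sum(s.length_um for s in m.sections
                       if s.region in ("AH", "SOCB", "NS", "DA"))
        assert axon_len == pytest.approx(1000.0)

    def test_mismatched_axon_segments_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            build_a2_rgc(RGCParams(da_len=800.0))

    def test_dendritic_span(self):
        m = build_a2_rgc()
        ys = [p[1] for s in m.sections if s.region == "dendrite"
              for p in (s.p0, s.p1)]
        span = max(ys) - min(ys)
        assert span == pytest.approx(320.0, abs=10.0)

    def test_axon_region_order_along_x(self):
        m = build_a2_rgc()
        starts = {s.region: s.p0[0] for s in m.sections
                  if s.region in ("AH", "SOCB", "NS", "DA")}
        assert starts["AH"] < starts["SOCB"] < starts["NS"] < starts["DA"]


class TestSWC:
    TOY = """# toy cell
1 1 0 0 0 5 -1
2 3 0 10 0 0.5 1
3 3 0 20 0 0.5 2
"""

    def test_read_toy_file(self, tmp_path):
        p = tmp_path / "toy.swc"
        p.write_text(self.TOY)
        m = read_swc(p)
        assert len(m.sections) == 3
        neurites = [s for s in m.sections if s.region == "dendrite"]
        assert len(neurites) == 2
        assert neurites[0].length_um == pytest.approx(10.0)
        # SWC radii are half-diameters
        assert neurites[0].d0 == pytest.approx(1.0)

    def test_round_trip_preserves_points_and_radii(self, tmp_path):
        p1, p2 = tmp_path / "a.swc", tmp_path / "b.swc"
        p1.write_text(self.TOY)
        m1 = read_swc(p1)
        write_swc(m1, p2)
        m2 = read_swc(p2)
        assert len(m2.sections) == len(m1.sections)
        assert [s.d1 for s in m2.sections] == pytest.approx(
            [s.d1 for s in m1.sections]
        )

    def test_cyclic_parents_rejected(self, tmp_path):
        p = tmp_path / "cyc.swc"
        p.write_text("1 1 0 0 0 1 2\n2 3 1 0 0 1 1\n")
        with pytest.raises(ValueError):
            read_swc(p)

    def test_unknown_type_without_mapping_rejected(self, tmp_path):
        p = tmp_path / "odd.swc"
        p.write_text("1 9 0 0 0 1 -1\n")
        with pytest.raises(ValueError, match="structure type"):
            read_swc(p)


class TestCompartmentalize:
    def cylinder(self, n=1):
        return Morphology(
            [Section("axon", (0, 0, 0), (0, 0, 100.0), 1.0, 1.0, -1)]
        ), n

    def test_single_compartment_axial_resistance(self):
        m, _ = self.cylinder()
        chain = compartmentalize(m, 100.0, 1.0, 100.0)
        # Ri * L / (pi r^2) = 100 ohm*cm * 0.01 cm / (pi (0.5e-4 cm)^2)
        expect = 100.0 * 0.01 / (math.pi * (0.5e-4) ** 2)
        assert chain.n == 1
        assert chain.axial_r_ohm[0] == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(1.273e8, rel=1e-3)

    def test_series_sum_matches_unsplit_cylinder(self):
        m, _ = self.cylinder()
        one = compartmentalize(m, 100.0, 1.0, 100.0)
        ten = compartmentalize(m, 10.0, 1.0, 100.0)
        assert ten.n == 10
        assert ten.axial_r_ohm.sum() == pytest.approx(
            one.axial_r_ohm[0], rel=1e-3
        )

    def test_membrane_area_pi_d_l(self):
        m, _ = self.cylinder()
        chain = compartmentalize(m, 100.0, 1.0, 100.0)
        assert chain.area_cm2[0] == pytest.approx(3.14e-6, rel=1e-3)

    def test_section_area_conserved_under_splitting(self):
        m, _ = self.cylinder()
        one = compartmentalize(m, 100.0, 1.0, 100.0)
        many = compartmentalize(m, 7.0, 1.0, 100.0)
        assert many.area_cm2.sum() == pytest.approx(one.area_cm2[0], rel=1e-2)

    def test_coupling_resistance_is_half_sum(self):
        m, _ = self.cylinder()
        ten = compartmentalize(m, 10.0, 1.0, 100.0)
        child, parent, g = ten.coupling_conductance_ms()
        r_mid = 0.5 * (ten.axial_r_ohm[child[0]] + ten.axial_r_ohm[parent[0]])
        assert g[0] == pytest.approx(1000.0 / r_mid)

    def test_nonpositive_max_length_rejected(self):
        m, _ = self.cylinder()
        with pytest.raises(ValueError):
            compartmentalize(m, 0.0, 1.0, 100.0)


class TestChannelTables:
    def test_bc_table_matches_printed_values(self):
        table = bc_channel_table()
        for region, row in TABLE2.items():
            for ch in ("g_Na", "g_Kslow", "g_Kfast", "g_caL", "g_caT", "g_HCN"):
                assert table.density(region, ch) == row.get(ch, 0.0), (region, ch)
        assert table.leak_ms_cm2 == 0.033

    def test_rgc_table_matches_printed_values(self):
        table = rgc_channel_table()
        for region, row in TABLE3_S_CM2.items():
            for ch in ("g_Na", "g_K", "g_K_A", "g_K_Ca", "g_Ca", "g_h", "g_T"):
                expect = row.get(ch, 0.0) * 1000.0  # S/cm^2 -> mS/cm^2
                assert table.density(region, ch) == pytest.approx(
                    expect, rel=1e-12
                ), (region, ch)

    def test_rgc_leak_printed_values(self):
        table = rgc_channel_table()
        assert table.leak_ms_cm2 == 0.05
        assert table.leak_erev_mv == -60.0

    def test_derived_rows_resolve_expressions(self):
        table = rgc_channel_table()
        for region in ("soma", "dendrite", "AH", "SOCB", "NS", "DA"):
            assert table.density(region, "g_K_A") == pytest.approx(
                3 * table.density(region, "g_K")
            )
        for region in ("soma", "dendrite"):
            assert table.density(region, "g_K_Ca") == pytest.approx(
                0.004 * table.density(region, "g_K")
            )

    def test_bad_expression_rejected(self):
        doc = {
            "units": "mS/cm2",
            "regions": ["soma"],
            "channels": {"g_X": {"soma": "3 * g_missing"}},
            "leak": {"density_ms_cm2": 0.05, "erev_mv": -60},
        }
        with pytest.raises(ValueError, match="g_missing"):
            load_channel_table(doc)


class TestAssignChannels:
    def test_bc_axon_densities(self):
        cell = build_bc_cell()
        j = {name: i for i, name in enumerate(cell.channel_names)}
        axon = cell.chain.compartments_in("axon")
        assert np.all(cell.gbar_ms_cm2[axon, j["g_Na"]] == 1000.0)
        assert np.all(cell.gbar_ms_cm2[axon, j["g_Kfast"]] == 2.0)
        others = [c for c in cell.channel_names if c not in ("g_Na", "g_Kfast")]
        for ch in others:
            assert np.all(cell.gbar_ms_cm2[axon, j[ch]] == 0.0)
        assert np.all(cell.leak_ms_cm2 == 0.033)

    def test_rgc_socb_densities(self):
        cell = build_rgc_cell()
        j = {name: i for i, name in enumerate(cell.channel_names)}
        socb = cell.chain.compartments_in("SOCB")
        assert np.all(cell.gbar_ms_cm2[socb, j["g_Na"]] == 2400.0)
        assert np.all(cell.gbar_ms_cm2[socb, j["g_K"]] == 800.0)
        assert np.all(cell.gbar_ms_cm2[socb, j["g_K_A"]] == pytest.approx(2400.0))

    def test_rgc_leak_uniform(self):
        cell = build_rgc_cell()
        assert np.all(cell.leak_ms_cm2 == 0.05)
        assert cell.leak_erev_mv == -60.0

    def test_unknown_region_rejected(self):
        chain = compartmentalize(
            Morphology([Section("mystery", (0, 0, 0), (0, 0, 10), 1, 1, -1)]),
            5.0, 1.0, 100.0,
        )
        with pytest.raises(KeyError, match="mystery"):
            assign_channels(chain, bc_channel_table(), "mystery")


class TestPlacement:
    def test_cells_inside_retina_shell(self, default_grid):
        ec = np.array(default_grid.meta["eye_center_m"])
        R = default_grid.meta["eye_radius_m"]
        for build in (build_bc_cell, build_rgc_cell):
            cell = build(default_grid)
            d = np.linalg.norm(cell.chain.midpoint_m - ec, axis=1)
            assert np.all(d < R), build.__name__
            assert np.all(d > R - 0.2e-3), build.__name__

    def test_bc_spans_retina_depth(self, default_grid):
        cell = build_bc_cell(default_grid)
        ec = np.array(default_grid.meta["eye_center_m"])
        d = np.linalg.norm(cell.chain.midpoint_m - ec, axis=1)
        # midpoint span = cell height minus the two terminal half-lengths
        half_ends = (cell.chain.length_um[0] + cell.chain.length_um[-1]) / 2
        assert (d.max() - d.min()) * 1e6 == pytest.approx(65.0 - half_ends,
                                                          rel=0.02)

    def test_refinement_of_compartment_length_converges(self):
        """Doubling the compartment count changes the passive somatic step
        response by a decreasing sup-norm amount."""
        from retistim.engine import CellModel, SimulationConfig, simulate
        from retistim.kinetics import rgc_kinetics

        traces = []
        for max_len in (40.0, 20.0, 10.0):
            cell = build_rgc_cell(max_compartment_um=max_len)
            model = CellModel(cell, rgc_kinetics()).passive()
            n = model.cell.n
            i_inj = np.zeros(n)
            soma_idx = model.cell.chain.compartments_in("soma")
            i_inj[soma_idx] = 1e-4 / len(soma_idx)  # 100 pA total
            cfg = SimulationConfig(settle_ms=0, pre_ms=0, post_ms=30,
                                   record_all=True)
            tr = simulate(model, 0.0, None, cfg, i_inj_ua=i_inj)
            soma = model.cell.chain.compartments_in("soma")[0]
            traces.append(tr.vm_mv[soma])
        d1 = np.abs(traces[1] - traces[0]).max()
        d2 = np.abs(traces[2] - traces[1]).max()
        assert d2 < d1
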