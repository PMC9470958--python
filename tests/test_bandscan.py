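"""Landscape assembly, region pooling and the waveguide-band criteria."""

import json

import numpy as np
import pytest
from scipy.optimize import brentq

from memdiel.bandscan import (
    BandThresholds,
    build_landscape,
    region_aggregate,
    report,
    waveguide_bands,
)
from memdiel.spectra import DielectricSpectrum
from memdiel.synthetic_data import analytic_dielectric


def _spec(f, imag, real=None, region=None, slab_id=None):
    return DielectricSpectrum(f_thz=np.asarray(f, float),
                              eps_imag=np.asarray(imag, float),
                              eps_real=None if real is None else np.asarray(real, float),
                              region=region, slab_id=slab_id)


class TestBuildLandscape:
    F = np.linspace(1.0, 10.0, 10)

    def test_midpoint_of_two_constant_slabs(self):
        a = _spec(self.F, np.full(10, 2.0), region="head")
        b = _spec(self.F, np.full(10, 4.0), region="tail")
        scape = build_landscape([a, b], np.array([0.0, 1.0]))
        interp = scape.interpolator("imag")
        assert interp([[0.5, 5.0]])[0] == pytest.approx(3.0)

    def test_single_slab_is_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            build_landscape([_spec(self.F, np.ones(10))], np.array([0.0]))

    def test_nodes_preserved_exactly(self):
        rng = np.random.default_rng(0)
        specs = [_spec(self.F, rng.normal(size=10), region="head") for _ in range(3)]
        z = np.array([0.0, 0.4, 1.1])
        scape = build_landscape(specs, z)
        interp = scape.interpolator("imag")
        for zi, s in zip(z, specs):
            got = interp(np.column_stack([np.full(10, zi), self.F]))
            np.testing.assert_allclose(got, s.eps_imag, rtol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = _spec(self.F, np.ones(10))
        b = _spec(self.F * 2, np.ones(10))
        with pytest.raises(ValueError, match="mismatched"):
            build_landscape([a, b], np.array([0.0, 1.0]))

    def test_symmetric_input_symmetric_output(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(2, 10))
        specs = [_spec(self.F, vals[0]), _spec(self.F, vals[1]),
                 _spec(self.F, vals[1]), _spec(self.F, vals[0])]
        z = np.array([-1.5, -0.5, 0.5, 1.5])
        scape = build_landscape(specs, z)
        np.testing.assert_allclose(scape.eps_imag, scape.eps_imag[::-1], atol=1e-15)


class TestRegionAggregate:
    F = np.linspace(1.0, 10.0, 16)

    def test_single_slab_per_region_is_identity(self):
        rng = np.random.default_rng(2)
        specs = [_spec(self.F, rng.normal(size=16), region=r)
                 for r in ("head", "tail", "water")]
        out = region_aggregate(specs)
        for s in specs:
            np.testing.assert_array_equal(out[s.region].eps_imag, s.eps_imag)

    def test_mirrored_slabs_average_like_single_leaflet(self):
        rng = np.random.default_rng(3)
        top = rng.normal(size=16)
        specs = [_spec(self.F, top, region="head"), _spec(self.F, top, region="head")]
        out = region_aggregate(specs)
        np.testing.assert_allclose(out["head"].eps_imag, top, rtol=1e-15)

    def test_unlabelled_spectrum_rejected(self):
        with pytest.raises(ValueError):
            region_aggregate([_spec(self.F, np.ones(16))])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            region_aggregate([])


def _toy_regions(f, toy_system):
    regions = {}
    for label in ("head", "tail", "water"):
        st = toy_system.stratum(label)
        V = st.span_volume_nm3(toy_system.area_nm2) * 1e-27
        er, ei = analytic_dielectric(st, V, f)
        regions[label] = _spec(f, ei, er, region=label)
    return regions


class TestWaveguideBands:
    def test_head_below_water_gives_empty_report(self):
        f = np.linspace(1, 50, 64)
        regions = {
            "head": _spec(f, np.zeros(64), np.full(64, 1.5), "head"),
            "tail": _spec(f, np.zeros(64), np.full(64, 1.2), "tail"),
            "water": _spec(f, np.zeros(64), np.full(64, 5.0), "water"),
        }
        rep = waveguide_bands(regions, BandThresholds(min_width_thz=1.0))
        assert rep.windows == []

    def test_degenerate_thresholds_pass_whole_grid(self):
        f = np.linspace(1, 50, 64)
        regions = {
            "head": _spec(f, np.ones(64), np.full(64, 2.0), "head"),
            "tail": _spec(f, np.zeros(64), np.full(64, 1.0), "tail"),
            "water": _spec(f, np.zeros(64), np.full(64, 1.0), "water"),
        }
        thresholds = BandThresholds(margin_real=-100.0, max_imag=np.inf,
                                    min_width_thz=0.0)
        rep = waveguide_bands(regions, thresholds)
        assert len(rep.windows) == 1
        w = rep.windows[0]
        assert (w.f_lo_thz, w.f_hi_thz) == (f[0], f[-1])

    def test_analytic_window_recovered_within_one_grid_step(self, toy_system):
        step = 0.004
        f = np.arange(1, 5001) * step
        regions = _toy_regions(f, toy_system)
        margin, max_imag = 0.05, 0.3

        def eps(label, fq, part):
            st = toy_system.stratum(label)
            V = st.span_volume_nm3(toy_system.area_nm2) * 1e-27
            er, ei = analytic_dielectric(st, V, np.array([fq]))
            return er[0] if part == "real" else ei[0]

        f_lo = brentq(lambda x: eps("head", x, "real") - eps("water", x, "real") - margin,
                      0.1, 3.0)
        f_hi = brentq(lambda x: eps("head", x, "imag") - max_imag, 2.0, 7.9)
        rep = waveguide_bands(regions, BandThresholds(margin_real=margin,
                                                      max_imag=max_imag,
                                                      min_width_thz=0.5))
        assert len(rep.windows) == 1
        w = rep.windows[0]
        assert abs(w.f_lo_thz - f_lo) <= step
        assert abs(w.f_hi_thz - f_hi) <= step

    @pytest.mark.parametrize(
        "loose",
        [dict(max_imag=0.5), dict(margin_real=-0.1), dict(max_imag=1.0, margin_real=-0.2)],
    )
    def test_loosening_thresholds_never_shrinks_windows(self, toy_system, loose):
        f = np.arange(1, 2001) * 0.01
        regions = _toy_regions(f, toy_system)
        base = BandThresholds(margin_real=0.05, max_imag=0.3, min_width_thz=0.0)
        loosened = BandThresholds(
            margin_real=loose.get("margin_real", base.margin_real),
            max_imag=loose.get("max_imag", base.max_imag), min_width_thz=0.0)
        w0 = waveguide_bands(regions, base).windows
        w1 = waveguide_bands(regions, loosened).windows
        for win in w0:   # every original window lies inside some loosened window
            assert any(o.f_lo_thz <= win.f_lo_thz and o.f_hi_thz >= win.f_hi_thz
                       for o in w1)

    def test_missing_region_rejected(self):
        f = np.linspace(1, 10, 8)
        with pytest.raises(ValueError, match="water"):
            waveguide_bands({"head": _spec(f, np.zeros(8), np.ones(8), "head"),
                             "tail": _spec(f, np.zeros(8), np.ones(8), "tail")})


class TestReport:
    def test_roundtrip_json_and_determinism(self, tmp_path, toy_system):
        f = np.arange(1, 201) * 0.05
        regions = _toy_regions(f, toy_system)
        rep = waveguide_bands(regions, BandThresholds(margin_real=0.05, max_imag=0.3,
                                                      min_width_thz=0.5))
        specs = [regions["head"], regions["tail"]]
        scape = build_landscape(specs, np.array([1.6, 0.6]))
        prefix = str(tmp_path / "run")
        doc1 = report(scape, rep, calibration={"eps_inf_head": 1.0},
                      out_prefix=prefix, metadata={"seed": 0})
        parsed = json.loads(open(prefix + "_bands.json").read())
        assert parsed["bands"] == doc1["bands"]
        doc2 = report(scape, rep, calibration={"eps_inf_head": 1.0},
                      metadata={"seed": 0})
        assert doc1 == doc2

    def test_empty_band_list_is_valid(self, tmp_path):
        f = np.linspace(1, 10, 32)
        regions = {
            "head": _spec(f, np.zeros(32), np.ones(32), "head"),
            "tail": _spec(f, np.zeros(32), np.ones(32), "tail"),
            "water": _spec(f, np.zeros(32), np.full(32, 9.0), "water"),
        }
        rep = waveguide_bands(regions)
        scape = build_landscape([regions["head"], regions["tail"]], np.array([1.0, 0.0]))
        doc = report(scape, rep, out_prefix=str(tmp_path / "empty"))
        assert doc["bands"]["windows"] == []
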