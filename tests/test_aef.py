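"""Electropherogram molarity analysis and peak calling."""

import math

import numpy as np
import pandas as pd
import pytest

from cfdna_fragscore import synthgen
from cfdna_fragscore.aef import (
    NO_HMW_SENTINEL,
    Electropherogram,
    find_nucleosomal_peaks,
    molar_density,
    molarity_ratio,
    read_trace_tsv,
    write_trace_tsv,
)
from cfdna_fragscore.amplicon import DEFAULT_ASSAYS
from cfdna_fragscore.qpcr import LONG_ASSAY, SHORT_ASSAY, contamination_score
from cfdna_fragscore.stats import pearson_with_ci


class TestMolarDensity:
    def test_flat_mass_gives_reciprocal_length(self):
        grid = np.arange(100.0, 1001.0)
        eg = Electropherogram(grid, np.ones_like(grid))
        md = molar_density(eg, mass_per_bp=1.0)
        assert np.allclose(md, 1.0 / grid)
        assert np.all(np.diff(md) < 0)

    def test_equal_mass_double_molarity_at_half_length(self):
        grid = np.array([100.0, 200.0])
        eg = Electropherogram(grid, np.array([5.0, 5.0]))
        md = molar_density(eg, mass_per_bp=1.0)
        assert md[0] == pytest.approx(2 * md[1])

    def test_generator_roundtrip_total_moles_equals_count(self, healthy_pop):
        """Integrated molar density (mass_per_bp=1) recovers fragment count."""
        grid = np.arange(1.0, 1001.0)
        eg = synthgen.render_electropherogram(healthy_pop, grid, bandwidth=5.0)
        moles = np.trapezoid(molar_density(eg, mass_per_bp=1.0), grid)
        assert moles == pytest.approx(healthy_pop.n, rel=0.01)


class TestMolarityRatio:
    def test_single_hmw_peak_ratio_is_one(self, hmw_pop):
        grid = np.arange(50.0, 60_001.0, 10.0)
        eg = synthgen.render_electropherogram(hmw_pop, grid, bandwidth=50.0)
        assert molarity_ratio(eg) == pytest.approx(1.0, abs=1e-6)

    def test_pure_mononucleosome_returns_no_hmw_sentinel(self, mono170_pop):
        grid = np.arange(50.0, 2001.0)
        eg = synthgen.render_electropherogram(mono170_pop, grid, bandwidth=10.0)
        assert molarity_ratio(eg) == NO_HMW_SENTINEL

    def test_scale_invariance(self, hmw_pop):
        grid = np.arange(50.0, 60_001.0, 10.0)
        eg = synthgen.render_electropherogram(hmw_pop, grid, bandwidth=50.0)
        mixed = Electropherogram(grid, eg.mass_density + 1e-4)
        scaled = Electropherogram(grid, 7.5 * (eg.mass_density + 1e-4))
        assert molarity_ratio(mixed) == pytest.approx(molarity_ratio(scaled), rel=1e-12)

    def test_monotone_decreasing_in_hmw_fraction(self):
        """More HMW mass pulls the >106/>612 molarity ratio toward 1."""
        panel = synthgen.build_standard_panel(seed=31)
        grid = np.arange(50.0, 60_001.0, 25.0)
        ratios = [
            molarity_ratio(synthgen.render_electropherogram(pop, grid, bandwidth=10.0))
            for _, pop in sorted(panel.items())
        ]
        assert np.all(np.diff(ratios) < 0)
        assert all(r > 1 for r in ratios)

    def test_qpcr_score_agrees_with_aef_ratio_on_16_samples(self):
        """log qPCR score vs log AEF ratio, Pearson r > 0.9 on a matched
        16-sample batch spanning 1-50% HMW."""
        fractions = np.geomspace(0.01, 0.5, 16)
        base = synthgen.simulate_fragments(
            synthgen.sheared_standard_spec(50_000, seed=41), sample_id="base"
        )
        hmw = synthgen.simulate_fragments(synthgen.hmw_spec(3000, seed=43), sample_id="hmw")
        grid = np.arange(50.0, 60_001.0, 25.0)
        ctrl_pop = synthgen.mix_by_mass(base, hmw, 0.5, seed=45, sample_id="ctrl")
        ctrl_cq = pd.concat(
            [
                synthgen.simulate_cq(ctrl_pop, DEFAULT_ASSAYS[a], 1.0, noise_sd=0.1,
                                     seed=47, sample_id="ctrl")
                for a in (SHORT_ASSAY, LONG_ASSAY)
            ],
            ignore_index=True,
        )
        scores, ratios = [], []
        for i, f in enumerate(fractions):
            pop = synthgen.mix_by_mass(base, hmw, f, seed=100 + i, sample_id=f"s{i}")
            cq = pd.concat(
                [
                    synthgen.simulate_cq(pop, DEFAULT_ASSAYS[a], 1.0, noise_sd=0.1,
                                         seed=200 + 2 * i + (a == LONG_ASSAY),
                                         sample_id=f"s{i}")
                    for a in (SHORT_ASSAY, LONG_ASSAY)
                ],
                ignore_index=True,
            )
            scores.append(contamination_score(cq, ctrl_cq).percent_hmw)
            ratios.append(
                molarity_ratio(synthgen.render_electropherogram(pop, grid, bandwidth=10.0))
            )
        res = pearson_with_ci(np.log(scores), np.log(ratios))
        assert abs(res.r) > 0.9
        assert res.r_squared > 0.81

    def test_bad_cut_order_raises(self, hmw_pop):
        grid = np.arange(50.0, 60_001.0, 10.0)
        eg = synthgen.render_electropherogram(hmw_pop, grid, bandwidth=50.0)
        with pytest.raises(ValueError):
            molarity_ratio(eg, 612, 106)


class TestPeakFinding:
    def test_mono_only_trace_no_di_tri_peaks(self, mono170_pop):
        grid = np.arange(50.0, 1001.0)
        eg = synthgen.render_electropherogram(mono170_pop, grid, bandwidth=10.0)
        peaks = find_nucleosomal_peaks(eg, [(360, 400), (540, 600)])
        assert peaks[(360, 400)] == []
        assert peaks[(540, 600)] == []

    def test_storage_trace_one_peak_per_window(self):
        pop = synthgen.simulate_fragments(synthgen.degraded_storage_spec(20_000, seed=51))
        grid = np.arange(50.0, 1001.0)
        eg = synthgen.render_electropherogram(pop, grid, bandwidth=10.0)
        peaks = find_nucleosomal_peaks(eg, [(360, 400), (540, 600)])
        assert len(peaks[(360, 400)]) == 1
        assert len(peaks[(540, 600)]) == 1

    def test_peak_positions_scale_invariant(self):
        pop = synthgen.simulate_fragments(synthgen.degraded_storage_spec(20_000, seed=53))
        grid = np.arange(50.0, 1001.0)
        eg = synthgen.render_electropherogram(pop, grid, bandwidth=10.0)
        scaled = Electropherogram(grid, 1e3 * eg.mass_density)
        assert find_nucleosomal_peaks(eg) == find_nucleosomal_peaks(scaled)


class TestValidationAndIO:
    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            Electropherogram(np.array([100.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            Electropherogram(np.array([200.0, 100.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            Electropherogram(np.array([100.0, 200.0]), np.array([-1.0, 1.0]))

    def test_tsv_roundtrip(self, tmp_path, mono170_pop):
        grid = np.arange(50.0, 501.0)
        eg = synthgen.render_electropherogram(mono170_pop, grid, bandwidth=10.0)
        path = tmp_path / "trace.tsv"
        write_trace_tsv(eg, path)
        back = read_trace_tsv(path, sample_id="x")
        assert np.allclose(back.size_bp, eg.size_bp)
        assert np.allclose(back.mass_density, eg.mass_density)
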