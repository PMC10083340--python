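"""Synthetic generator: mixtures, mass mixing, instrument forward models."""

import numpy as np
import pandas as pd
import pytest

from cfdna_fragscore import synthgen
from cfdna_fragscore.amplicon import AmpliconAssay
from cfdna_fragscore.synthgen import (
    FragmentPopulation,
    MixtureComponent,
    MixtureSpec,
    PanelSpec,
    build_standard_panel,
    mix_by_mass,
    render_electropherogram,
    simulate_cq,
    simulate_droplets,
    simulate_fragments,
)


class TestSimulateFragments:
    def test_zero_variance_component_is_point_mass(self):
        spec = MixtureSpec((MixtureComponent(1.0, "gaussian", 170.0, 0.0),), 5, seed=1)
        pop = simulate_fragments(spec)
        assert list(pop.lengths) == [170] * 5

    def test_healthy_default_median_is_170(self):
        pop = simulate_fragments(synthgen.healthy_spec(10_000, seed=3))
        assert abs(np.median(pop.lengths) - 170) <= 2

    def test_sheared_standard_mean_is_170(self):
        pop = simulate_fragments(synthgen.sheared_standard_spec(10_000, seed=5))
        assert abs(np.mean(pop.lengths) - 170) <= 3

    def test_two_point_mixture_weights_binomial(self):
        """Empirical weight of the 100 bp component ~ Binomial(n, 0.5)."""
        n = 10_000
        spec = MixtureSpec(
            (
                MixtureComponent(0.5, "gaussian", 100.0, 0.0),
                MixtureComponent(0.5, "gaussian", 300.0, 0.0),
            ),
            n,
            seed=11,
        )
        pop = simulate_fragments(spec)
        frac100 = np.mean(pop.lengths == 100)
        sd = np.sqrt(0.5 * 0.5 / n)
        assert abs(frac100 - 0.5) <= 3 * sd

    def test_exact_count_and_determinism(self):
        spec = synthgen.degraded_storage_spec(4321, seed=9)
        a = simulate_fragments(spec)
        b = simulate_fragments(spec)
        assert a.n == 4321
        assert np.array_equal(a.lengths, b.lengths)
        c = simulate_fragments(synthgen.degraded_storage_spec(4321, seed=10))
        assert not np.array_equal(a.lengths, c.lengths)

    def test_invalid_weights_name_offending_component(self):
        with pytest.raises(ValueError, match="component 1"):
            MixtureSpec(
                (
                    MixtureComponent(1.2, "gaussian", 170, 20),
                    MixtureComponent(-0.2, "gaussian", 300, 20),
                ),
                10,
            )

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureSpec((MixtureComponent(0.6, "gaussian", 170, 20),), 10)

    def test_lognormal_median(self):
        pop = simulate_fragments(synthgen.hmw_spec(20_000, seed=2))
        assert np.median(pop.lengths) == pytest.approx(15_000, rel=0.05)


class TestMixByMass:
    def test_zero_fraction_returns_popA_only(self, mono170_pop, hmw_pop):
        out = mix_by_mass(mono170_pop, hmw_pop, 0.0)
        assert np.array_equal(out.lengths, mono170_pop.lengths)

    def test_unit_fraction_returns_popB_only(self, mono170_pop, hmw_pop):
        out = mix_by_mass(mono170_pop, hmw_pop, 1.0)
        assert np.array_equal(out.lengths, hmw_pop.lengths)

    def test_count_ratio_follows_length_ratio(self):
        """Equal masses of 170 bp vs 17 kb DNA: 100x fewer B fragments."""
        a = FragmentPopulation(np.full(10_000, 170))
        b = FragmentPopulation(np.full(100, 17_000))
        out = mix_by_mass(a, b, 0.5, seed=3)
        n_b = np.sum(out.lengths == 17_000)
        assert n_b / 10_000 == pytest.approx(1 / 100, rel=0.05)

    def test_panel_mass_fractions_within_2_percent(self):
        """1/5/25/50% standards carry the requested HMW mass share."""
        panel = build_standard_panel(PanelSpec(), seed=8)
        for frac, pop in panel.items():
            hmw_bp = pop.lengths[pop.lengths > 1000].sum()
            share = hmw_bp / pop.lengths.sum()
            assert abs(share - frac) <= 0.02

    def test_mass_conservation(self, mono170_pop, hmw_pop):
        """A's bp content is preserved; B adds the right expected share."""
        out = mix_by_mass(mono170_pop, hmw_pop, 0.25, seed=4)
        a_bp = mono170_pop.total_bp
        b_bp = out.total_bp - a_bp
        assert b_bp / out.total_bp == pytest.approx(0.25, abs=0.02)

    def test_rejects_bad_fraction(self, mono170_pop, hmw_pop):
        with pytest.raises(ValueError):
            mix_by_mass(mono170_pop, hmw_pop, 1.5)


class TestSimulateDroplets:
    def test_zero_copies_zero_positives(self, mono170_pop):
        assay = AmpliconAssay("long", 612, 1)  # no 170 bp fragment contains it
        plate = simulate_droplets(mono170_pop, assay, 1.0, 20_000, seed=1)
        assert plate["n_positive"].iloc[0] == 0

    def test_zero_mass_zero_positives(self, mono170_pop):
        assay = AmpliconAssay("short", 106, 1)
        plate = simulate_droplets(mono170_pop, assay, 0.0, 20_000, seed=1)
        assert plate["n_positive"].iloc[0] == 0

    @pytest.mark.parametrize("lam", [0.1, 1.0, 3.0])
    def test_poisson_occupancy_law(self, lam):
        """Positive fraction ~ 1 - exp(-lambda) at fixed mean droplet load."""
        n_droplets = 20_000
        # choose mass so expected copies in droplets = lam * n_droplets;
        # infinite-length DNA makes containment 1 and copies = mass/0.0033
        target_copies = lam * n_droplets
        droplet_fraction = n_droplets * 0.85e-3 / 20.0
        mass = target_copies / droplet_fraction * 0.0033
        pop = FragmentPopulation(np.full(100, 10**9))
        assay = AmpliconAssay("sc", 106, 1)
        plate = simulate_droplets(pop, assay, mass, n_droplets, seed=int(lam * 10))
        p_hat = plate["n_positive"].iloc[0] / n_droplets
        p = 1 - np.exp(-lam)
        assert abs(p_hat - p) <= 4 * np.sqrt(p * (1 - p) / n_droplets)

    def test_determinism(self, healthy_pop):
        assay = AmpliconAssay("short", 106, 1)
        a = simulate_droplets(healthy_pop, assay, 1.0, 20_000, seed=5)
        b = simulate_droplets(healthy_pop, assay, 1.0, 20_000, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_zero_droplets(self, healthy_pop):
        with pytest.raises(ValueError):
            simulate_droplets(healthy_pop, AmpliconAssay("a", 106, 1), 1.0, 0)


class TestSimulateCq:
    def test_doubling_copies_drops_cq_by_one_cycle(self, mono170_pop):
        assay = AmpliconAssay("short", 106, 25)
        cq1 = simulate_cq(mono170_pop, assay, 1.0, efficiency=2.0)["cq"].iloc[0]
        cq2 = simulate_cq(mono170_pop, assay, 2.0, efficiency=2.0)["cq"].iloc[0]
        assert cq1 - cq2 == pytest.approx(1.0, abs=1e-9)

    def test_tenfold_copies_is_log2_10_cycles(self, mono170_pop):
        assay = AmpliconAssay("short", 106, 25)
        cq1 = simulate_cq(mono170_pop, assay, 1.0)["cq"].iloc[0]
        cq10 = simulate_cq(mono170_pop, assay, 10.0)["cq"].iloc[0]
        assert cq1 - cq10 == pytest.approx(np.log2(10), abs=1e-9)
        assert cq1 - cq10 == pytest.approx(3.3219, abs=1e-4)

    def test_zero_copies_is_non_detect(self, mono170_pop):
        assay = AmpliconAssay("long", 612, 25)
        cq = simulate_cq(mono170_pop, assay, 1.0)["cq"].iloc[0]
        assert np.isnan(cq)

    def test_rejects_efficiency_at_or_below_one(self, mono170_pop):
        with pytest.raises(ValueError):
            simulate_cq(mono170_pop, AmpliconAssay("a", 106, 1), 1.0, efficiency=1.0)


class TestRenderElectropherogram:
    def test_mono_peak_mode_at_170(self, mono170_pop):
        grid = np.arange(50.0, 1001.0)
        eg = render_electropherogram(mono170_pop, grid, bandwidth=10.0)
        assert grid[np.argmax(eg.mass_density)] == pytest.approx(170, abs=1)

    def test_storage_trace_has_di_tri_peaks(self):
        from cfdna_fragscore.aef import find_nucleosomal_peaks

        pop = simulate_fragments(synthgen.degraded_storage_spec(20_000, seed=13))
        grid = np.arange(50.0, 1001.0)
        eg = render_electropherogram(pop, grid, bandwidth=10.0)
        peaks = find_nucleosomal_peaks(eg, [(360, 400), (540, 600)])
        assert len(peaks[(360, 400)]) >= 1
        assert len(peaks[(540, 600)]) >= 1

    def test_integral_equals_total_mass(self, healthy_pop):
        grid = np.arange(1.0, 1001.0)
        eg = render_electropherogram(healthy_pop, grid, bandwidth=5.0)
        assert eg.total_mass == pytest.approx(healthy_pop.total_bp, rel=1e-3)

    def test_mass_linearity(self, mono170_pop):
        grid = np.arange(50.0, 501.0)
        single = render_electropherogram(mono170_pop, grid, bandwidth=10.0)
        doubled_pop = FragmentPopulation(np.concatenate([mono170_pop.lengths] * 2))
        doubled = render_electropherogram(doubled_pop, grid, bandwidth=10.0)
        assert doubled.total_mass == pytest.approx(2 * single.total_mass, rel=1e-9)

    def test_rejects_tiny_grid(self, mono170_pop):
        with pytest.raises(ValueError):
            render_electropherogram(mono170_pop, np.array([100.0]))


def test_population_io_roundtrip(tmp_path, mono170_pop):
    tsv = tmp_path / "pop.tsv"
    mono170_pop.to_tsv(tsv)
    df = pd.read_csv(tsv, sep="\t")
    assert df["count"].sum() == mono170_pop.n
    bed = tmp_path / "pop.bed"
    mono170_pop.to_bed(bed)
    lines = bed.read_text().strip().split("\n")
    assert len(lines) == mono170_pop.n
    chrom, start, end, name = lines[0].split("\t")
    assert int(end) - int(start) == 170
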