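"""Synthetic cfDNA sample and instrument-data generator.

Plasma cfDNA is dominated by mononucleosomal fragments (~170 bp median in
healthy donors), with di-/tri-nucleosome degradation peaks near 360-400 and
540-600 bp appearing when blood cells lyse during storage, and a high
molecular weight (HMW) genomic-DNA component when lysis contaminates the
sample outright.  This module draws fragment-length populations from
explicit mixture specs, mixes populations by DNA *mass* (so a 15 kb genomic
fragment counts ~90x a mononucleosome), and pushes populations through
forward models of the three instruments used downstream:

* droplet digital PCR — Poisson partitioning of amplifiable copies into
  droplets;
* real-time qPCR — Cq as an intercept minus log-efficiency of the
  amplifiable copy number, plus replicate noise;
* automated electrophoresis — a kernel-smoothed mass density over a size
  grid, each fragment contributing mass proportional to its length.

All randomness is seeded explicitly; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .aef import Electropherogram
from .amplicon import AmpliconAssay, expected_amplifiable_copies
from .constants import DROPLET_VOLUME_NL, MAX_QPCR_CYCLES, REACTION_VOLUME_UL

__all__ = [
    "MixtureComponent",
    "MixtureSpec",
    "FragmentPopulation",
    "PanelSpec",
    "simulate_fragments",
    "mix_by_mass",
    "simulate_droplets",
    "simulate_cq",
    "render_electropherogram",
    "build_standard_panel",
    "healthy_spec",
    "crc_spec",
    "degraded_storage_spec",
    "sheared_standard_spec",
    "hmw_spec",
]


@dataclass(frozen=True)
class MixtureComponent:
    """One component of a fragment-length mixture.

    ``family`` is ``"gaussian"`` (normal truncated at 1 bp; ``location`` =
    mean bp, ``scale`` = SD bp, 0 allowed for a point mass) or
    ``"lognormal"`` (``location`` = median bp, ``scale`` = SD of the
    underlying log, dimensionless — appropriate for the orders-of-magnitude
    spread of HMW genomic DNA).
    """

    weight: float
    family: str
    location: float
    scale: float

    def validate(self, index: int) -> None:
        if self.weight < 0:
            raise ValueError(f"component {index}: weight must be non-negative, got {self.weight}")
        if self.family not in ("gaussian", "lognormal"):
            raise ValueError(f"component {index}: unknown family {self.family!r}")
        if self.location <= 0:
            raise ValueError(f"component {index}: location must be > 0, got {self.location}")
        if self.scale < 0:
            raise ValueError(f"component {index}: scale must be >= 0, got {self.scale}")


@dataclass(frozen=True)
class MixtureSpec:
    """A weighted mixture of length distributions plus a sample size and seed."""

    components: tuple[MixtureComponent, ...]
    total_fragments: int
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("mixture needs at least one component")
        for i, c in enumerate(self.components):
            c.validate(i)
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {w}")
        if self.total_fragments < 1:
            raise ValueError("total_fragments must be >= 1")


@dataclass
class FragmentPopulation:
    """Fragment lengths (bp, positive integers) of one cfDNA sample."""

    lengths: np.ndarray
    sample_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if self.lengths.size == 0:
            raise ValueError("population must be non-empty")
        if np.any(self.lengths < 1):
            raise ValueError("all fragment lengths must be >= 1 bp")

    @property
    def n(self) -> int:
        return int(self.lengths.size)

    @property
    def total_bp(self) -> int:
        """Total base-pair content — the mass of the sample up to a constant."""
        return int(self.lengths.sum())

    def to_tsv(self, path) -> None:
        """Write as two-column TSV (length_bp, count)."""
        lengths, counts = np.unique(self.lengths, return_counts=True)
        pd.DataFrame({"length_bp": lengths, "count": counts}).to_csv(path, sep="\t", index=False)

    def to_bed(self, path, chrom: str = "chr1", start: int = 0, gap: int = 100) -> None:
        """Write fragments as a BED file (0-based half-open), laid end to end."""
        starts = start + np.concatenate(([0], np.cumsum(self.lengths[:-1] + gap)))
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + self.lengths,
                "name": self.sample_id or "fragment",
            }
        )
        df.to_csv(path, sep="\t", index=False, header=False)


@dataclass(frozen=True)
class PanelSpec:
    """Calibration-panel layout: sheared standard spiked with HMW DNA mass.

    ``hmw_mass_fractions`` must be strictly increasing fractions in [0, 1];
    the defaults are the 1 / 5 / 25 / 50 % unfragmented-mass standards.
    """

    hmw_mass_fractions: tuple[float, ...] = (0.01, 0.05, 0.25, 0.50)
    fragmented_length_mean: float = 170.0
    hmw_length_location: float = 15_000.0
    total_mass_ng: float = 1.0

    def __post_init__(self) -> None:
        fr = self.hmw_mass_fractions
        if any(not (0.0 <= f <= 1.0) for f in fr):
            raise ValueError("mass fractions must lie in [0, 1]")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("mass fractions must be strictly increasing")


# ---------------------------------------------------------------------------
# Default mixture specs.  Locations/weights follow the nucleosome ladder:
# mono ~170 bp, di ~380 bp, tri ~570 bp; HMW genomic DNA is modeled as
# lognormal with 15 kb median (must exceed the 612 bp amplicon by orders of
# magnitude).  Scales are assumptions, stated in the methods note.
# ---------------------------------------------------------------------------

def healthy_spec(total_fragments: int = 10_000, seed: int = 0) -> MixtureSpec:
    """Healthy-donor cfDNA: a single mononucleosomal component, median 170 bp."""
    return MixtureSpec(
        (MixtureComponent(1.0, "gaussian", 170.0, 20.0),), total_fragments, seed
    )


def crc_spec(
    total_fragments: int = 10_000, seed: int = 0, short_weight: float = 0.3
) -> MixtureSpec:
    """Colorectal-cancer-like cfDNA: adds a shorter tumor-derived component.

    Cancer plasma carries an increased abundance of sub-mononucleosomal
    fragments; the default places ``short_weight`` of fragments at 145 bp.
    """
    return MixtureSpec(
        (
            MixtureComponent(short_weight, "gaussian", 145.0, 15.0),
            MixtureComponent(1.0 - short_weight, "gaussian", 170.0, 20.0),
        ),
        total_fragments,
        seed,
    )


def degraded_storage_spec(total_fragments: int = 10_000, seed: int = 0) -> MixtureSpec:
    """Week-stored blood cfDNA: mono/di/tri-nucleosome ladder 0.5/0.3/0.2."""
    return MixtureSpec(
        (
            MixtureComponent(0.5, "gaussian", 170.0, 20.0),
            MixtureComponent(0.3, "gaussian", 380.0, 12.0),
            MixtureComponent(0.2, "gaussian", 570.0, 18.0),
        ),
        total_fragments,
        seed,
    )


def sheared_standard_spec(total_fragments: int = 10_000, seed: int = 0) -> MixtureSpec:
    """Ultrasonically sheared calibration standard, mean length ~170 bp."""
    return MixtureSpec(
        (MixtureComponent(1.0, "gaussian", 170.0, 35.0),), total_fragments, seed
    )


def hmw_spec(total_fragments: int = 1_000, seed: int = 0) -> MixtureSpec:
    """Unfragmented (high molecular weight) genomic DNA, median 15 kb."""
    return MixtureSpec(
        (MixtureComponent(1.0, "lognormal", 15_000.0, 0.5),), total_fragments, seed
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _draw_component(c: MixtureComponent, n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if c.family == "gaussian":
        if c.scale == 0:
            x = np.full(n, c.location)
        else:
            # Normal truncated at 1 bp.
            a = (1.0 - c.location) / c.scale
            x = stats.truncnorm.rvs(a, np.inf, loc=c.location, scale=c.scale,
                                    size=n, random_state=rng)
    else:  # lognormal, location = median
        x = np.exp(rng.normal(np.log(c.location), c.scale, size=n))
    return np.maximum(1, np.rint(x)).astype(np.int64)


def simulate_fragments(
    spec: MixtureSpec, sample_id: str = "", group_label: str = ""
) -> FragmentPopulation:
    """Draw exactly ``spec.total_fragments`` lengths i.i.d. from the mixture.

    Deterministic given ``spec.seed``: the same spec always yields the same
    fragments, bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components])
    counts = rng.multinomial(spec.total_fragments, weights)
    parts = [_draw_component(c, int(k), rng) for c, k in zip(spec.components, counts)]
    lengths = np.concatenate(parts)
    rng.shuffle(lengths)
    return FragmentPopulation(lengths, sample_id=sample_id, group_label=group_label)


def mix_by_mass(
    popA: FragmentPopulation,
    popB: FragmentPopulation,
    mass_fraction_B: float,
    total_mass_ng: float | None = None,
    seed: int = 0,
    sample_id: str = "",
) -> FragmentPopulation:
    """Mix two populations so B contributes ``mass_fraction_B`` of the DNA mass.

    Mass is proportional to total base-pair content.  All of ``popA`` is
    kept and B fragments are resampled (with replacement, seeded) until the
    expected bp contributed by B equals ``mass_fraction_B`` of the mixture
    total; each source length distribution is preserved.  ``total_mass_ng``
    is carried only as bookkeeping — absolute reaction mass is always given
    separately to the instrument models.
    """
    if not 0.0 <= mass_fraction_B <= 1.0:
        raise ValueError("mass_fraction_B must lie in [0, 1]")
    if mass_fraction_B == 0.0:
        return FragmentPopulation(popA.lengths.copy(), sample_id=sample_id or popA.sample_id,
                                  group_label=popA.group_label)
    if mass_fraction_B == 1.0:
        return FragmentPopulation(popB.lengths.copy(), sample_id=sample_id or popB.sample_id,
                                  group_label=popB.group_label)
    rng = np.random.default_rng(seed)
    bp_A = popA.total_bp
    mean_len_B = float(np.mean(popB.lengths))
    # target: bp_B / (bp_A + bp_B) = f  =>  bp_B = bp_A * f / (1 - f)
    target_bp_B = bp_A * mass_fraction_B / (1.0 - mass_fraction_B)
    # resample B until the cumulative bp is as close to the target as a
    # whole fragment allows (low-variance even when B fragments are huge)
    n_max = int(np.ceil(target_bp_B / mean_len_B * 4)) + 16
    drawn = rng.choice(popB.lengths, size=n_max, replace=True)
    cum = np.concatenate(([0], np.cumsum(drawn)))
    n_B = int(np.argmin(np.abs(cum - target_bp_B)))
    lengths = np.concatenate([popA.lengths, drawn[:n_B]])
    return FragmentPopulation(lengths, sample_id=sample_id, group_label="mixture")


def build_standard_panel(
    panel: PanelSpec = PanelSpec(),
    n_fragmented: int = 20_000,
    n_hmw_pool: int = 4_000,
    seed: int = 0,
) -> dict[float, FragmentPopulation]:
    """Construct the HMW calibration panel as {mass_fraction: population}.

    Each standard mixes the sheared ~170 bp pool with the HMW pool at the
    requested unfragmented-DNA mass fraction.
    """
    base = simulate_fragments(
        MixtureSpec(
            (MixtureComponent(1.0, "gaussian", panel.fragmented_length_mean, 35.0),),
            n_fragmented,
            seed,
        ),
        sample_id="sheared_standard",
        group_label="standard",
    )
    hmw = simulate_fragments(
        MixtureSpec(
            (MixtureComponent(1.0, "lognormal", panel.hmw_length_location, 0.5),),
            n_hmw_pool,
            seed + 1,
        ),
        sample_id="hmw_pool",
        group_label="standard",
    )
    out: dict[float, FragmentPopulation] = {}
    for i, f in enumerate(panel.hmw_mass_fractions):
        out[f] = mix_by_mass(
            base, hmw, f, panel.total_mass_ng, seed=seed + 100 + i,
            sample_id=f"standard_{100 * f:g}pct",
        )
    return out


# ---------------------------------------------------------------------------
# Instrument forward models
# ---------------------------------------------------------------------------

def simulate_droplets(
    pop: FragmentPopulation,
    assay: AmpliconAssay,
    input_mass_ng: float,
    n_droplets: int = 20_000,
    seed: int = 0,
    sample_id: str | None = None,
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
    reaction_volume_ul: float = REACTION_VOLUME_UL,
) -> pd.DataFrame:
    """Forward-simulate one ddPCR well; returns a single DropletPlate row.

    The expected amplifiable copy number in the reaction is computed from
    the fragment-size distribution via the containment model, thinned to
    the fraction of the reaction volume actually partitioned into droplets
    (n_droplets x 0.85 nL out of 20 uL); the realized copy count is
    Poisson, and each copy lands in a uniformly chosen droplet.  A droplet
    is positive when it holds at least one copy.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    rng = np.random.default_rng(seed)
    droplet_fraction = min(1.0, n_droplets * droplet_volume_nl * 1e-3 / reaction_volume_ul)
    expected = expected_amplifiable_copies(pop, assay, input_mass_ng) * droplet_fraction
    n_copies = int(rng.poisson(expected))
    if n_copies == 0:
        n_positive = 0
    else:
        occupancy = rng.multinomial(n_copies, np.full(n_droplets, 1.0 / n_droplets))
        n_positive = int(np.count_nonzero(occupancy))
    return pd.DataFrame(
        [
            {
                "sample_id": sample_id or pop.sample_id,
                "assay": assay.name,
                "n_total": n_droplets,
                "n_positive": n_positive,
                "input_mass_ng": input_mass_ng,
            }
        ]
    )


def simulate_cq(
    pop: FragmentPopulation,
    assay: AmpliconAssay,
    input_mass_ng: float,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
    intercept: float = 37.0,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Forward-simulate qPCR Cq rows for one sample/assay.

    ``Cq = intercept - log_efficiency(amplifiable copies) + noise``; the
    intercept is the cycle at which a single starting copy crosses
    threshold.  Zero amplifiable copies, or a Cq at/after the last cycle
    (40), is reported as a non-detect (NaN Cq).
    """
    if efficiency <= 1.0:
        raise ValueError("efficiency must be > 1 fold per cycle")
    rng = np.random.default_rng(seed)
    copies = expected_amplifiable_copies(pop, assay, input_mass_ng)
    rows = []
    for rep in range(n_replicates):
        if copies <= 0:
            cq = np.nan
        else:
            cq = intercept - np.log(copies) / np.log(efficiency)
            if noise_sd > 0:
                cq += rng.normal(0.0, noise_sd)
            if cq >= MAX_QPCR_CYCLES:
                cq = np.nan
        rows.append(
            {
                "sample_id": sample_id or pop.sample_id,
                "assay": assay.name,
                "replicate": rep + 1,
                "cq": cq,
                "efficiency": efficiency,
            }
        )
    return pd.DataFrame(rows)


def render_electropherogram(
    pop: FragmentPopulation,
    size_grid: np.ndarray,
    bandwidth: float = 10.0,
    total_mass: float | None = None,
) -> Electropherogram:
    """Render a population as a kernel-smoothed mass-density trace.

    Each fragment contributes mass proportional to its length, spread over
    the grid by a Gaussian kernel of SD ``bandwidth`` bp.  When the grid
    covers the population's support, the trapezoidal integral of the trace
    equals the total mass (``total_mass`` if given, else total bp).
    """
    grid = np.asarray(size_grid, dtype=float)
    if grid.size < 2:
        raise ValueError("size grid needs at least 2 points")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    lengths, counts = np.unique(pop.lengths, return_counts=True)
    mass = counts * lengths.astype(float)  # bp-mass per unique length
    density = np.zeros_like(grid)
    norm = 1.0 / (bandwidth * np.sqrt(2.0 * np.pi))
    # chunk over unique lengths to bound memory
    for i in range(0, lengths.size, 512):
        ls = lengths[i : i + 512, None].astype(float)
        ms = mass[i : i + 512, None]
        z = (grid[None, :] - ls) / bandwidth
        density += (ms * norm * np.exp(-0.5 * z * z)).sum(axis=0)
    if total_mass is not None:
        density *= total_mass / pop.total_bp
    return Electropherogram(grid, density, sample_id=pop.sample_id)
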