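"""Droplet digital PCR absolute quantification and fragmentation statistics.

Droplet digital PCR partitions a reaction into ~20,000 droplets; the
fraction of positive droplets ``p`` yields the mean copies per droplet
through the Poisson occupancy law ``lambda = -ln(1 - p)``, and hence an
absolute concentration with no standard curve.  Comparing copies per
nanogram between a short amplicon (detects nearly all fragments) and a long
amplicon (detects only fragments of at least mononucleosomal length) in the
same region summarizes how fragmented the sample is there: the
short-minus-long difference and short-over-long ratio both grow as DNA
integrity decreases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .constants import DROPLET_VOLUME_NL, REACTION_VOLUME_UL

__all__ = [
    "CopiesEstimate",
    "FragmentationSummary",
    "poisson_quantify",
    "fragmentation_summary",
    "quantify_plate",
    "read_droplet_csv",
    "LOW_QUALITY_DROPLET_THRESHOLD",
]

#: Wells with fewer accepted droplets than this are flagged low-quality
#: (vendor convention), but still quantified.
LOW_QUALITY_DROPLET_THRESHOLD: int = 8000


@dataclass(frozen=True)
class CopiesEstimate:
    """Absolute copy-number estimate for one well."""

    sample_id: str
    assay: str
    copies_per_ul: float
    copies_per_ng: float
    ci_low: float
    ci_high: float
    saturated: bool = False
    low_quality: bool = False

    def __post_init__(self) -> None:
        if not self.saturated:
            if not (self.ci_low <= self.copies_per_ng <= self.ci_high):
                raise ValueError("confidence bounds must bracket the estimate")


@dataclass(frozen=True)
class FragmentationSummary:
    """Short/long copy-number contrast for one sample in one region."""

    sample_id: str
    region_label: str
    short_copies_per_ng: float
    long_copies_per_ng: float
    difference: float  # short - long
    ratio: float  # short / long; NaN when long == 0


def poisson_quantify(
    row,
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
    reaction_volume_ul: float = REACTION_VOLUME_UL,
    ci_level: float = 0.95,
) -> CopiesEstimate:
    """Poisson quantification of one droplet-plate row.

    ``row`` is a mapping (or pandas row) with ``sample_id``, ``assay``,
    ``n_total``, ``n_positive``, ``input_mass_ng``.  The 95% CI comes from
    a Wilson interval on the positive fraction propagated through the
    monotone map ``p -> -ln(1-p)`` — well-behaved at p near 0 and 1.  An
    all-positive well is reported with ``saturated=True`` and infinite
    point estimate/upper bound, never a silent finite number.
    """
    n_total = int(row["n_total"])
    n_pos = int(row["n_positive"])
    mass = float(row["input_mass_ng"])
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_pos <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    if mass <= 0:
        raise ValueError("input_mass_ng must be positive")

    droplet_volume_ul = droplet_volume_nl * 1e-3
    per_ul_factor = 1.0 / droplet_volume_ul
    per_ng_factor = per_ul_factor * reaction_volume_ul / mass
    p_low, p_high = proportion_confint(n_pos, n_total, alpha=1 - ci_level, method="wilson")
    lam_low = -math.log1p(-min(p_low, 1.0 - 1e-15))
    lam_high = math.inf if p_high >= 1.0 else -math.log1p(-p_high)

    low_quality = n_total < LOW_QUALITY_DROPLET_THRESHOLD
    if n_pos == n_total:
        return CopiesEstimate(
            sample_id=str(row["sample_id"]),
            assay=str(row["assay"]),
            copies_per_ul=math.inf,
            copies_per_ng=math.inf,
            ci_low=lam_low * per_ng_factor,
            ci_high=math.inf,
            saturated=True,
            low_quality=low_quality,
        )
    lam = -math.log1p(-n_pos / n_total)
    return CopiesEstimate(
        sample_id=str(row["sample_id"]),
        assay=str(row["assay"]),
        copies_per_ul=lam * per_ul_factor,
        copies_per_ng=lam * per_ng_factor,
        ci_low=lam_low * per_ng_factor,
        ci_high=lam_high * per_ng_factor,
        saturated=False,
        low_quality=low_quality,
    )


def fragmentation_summary(
    short: CopiesEstimate,
    long: CopiesEstimate,
    region_label: str = "",
) -> FragmentationSummary:
    """Combine short- and long-amplicon estimates of one sample/region."""
    if short.sample_id != long.sample_id:
        raise ValueError(
            f"estimates come from different samples: {short.sample_id!r} vs {long.sample_id!r}"
        )
    s, l = short.copies_per_ng, long.copies_per_ng
    return FragmentationSummary(
        sample_id=short.sample_id,
        region_label=region_label,
        short_copies_per_ng=s,
        long_copies_per_ng=l,
        difference=s - l,
        ratio=s / l if l > 0 else math.nan,
    )


def read_droplet_csv(path) -> pd.DataFrame:
    """Read a droplet-count CSV (sample_id, assay, n_total, n_positive, input_mass_ng)."""
    df = pd.read_csv(path)
    required = {"sample_id", "assay", "n_total", "n_positive", "input_mass_ng"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[(df["n_positive"] < 0) | (df["n_positive"] > df["n_total"])]
    if len(bad):
        raise ValueError(f"{path}: n_positive out of range at rows {list(bad)}")
    return df


def quantify_plate(plate: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Quantify every row of a droplet plate; returns a tidy estimate table."""
    recs = []
    for _, row in plate.iterrows():
        est = poisson_quantify(row, **kwargs)
        recs.append(
            {
                "sample_id": est.sample_id,
                "assay": est.assay,
                "copies_per_ul": est.copies_per_ul,
                "copies_per_ng": est.copies_per_ng,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "saturated": est.saturated,
                "low_quality": est.low_quality,
            }
        )
    return pd.DataFrame(recs)
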