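"""qPCR high-molecular-weight (HMW) contamination scoring.

The screen runs two multicopy amplicons on 1 ng of sample: a 106 bp product
that amplifies from essentially all cfDNA, and a 612 bp product that only
intact (unfragmented) DNA can template.  Relative quantification by the
delta-delta-Ct method — long amplicon as target, the 106 bp amplicon as the
reference, and the 50% unfragmented-mass calibration standard as the
control sample — turns the Cq difference into a relative normalized
expression (RNE), and the contamination percentage is ``RNE x 50%`` (the
control's known HMW content).  Scoring the control against itself therefore
yields exactly 50% by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import MAX_QPCR_CYCLES

__all__ = [
    "ContaminationResult",
    "contamination_score",
    "score_batch",
    "screen_batch",
    "idealized_panel_cq",
    "read_cq_csv",
    "SHORT_ASSAY",
    "LONG_ASSAY",
    "CONTROL_PERCENT",
]

SHORT_ASSAY = "short_106"
LONG_ASSAY = "long_612"

#: Known HMW mass percentage of the calibration control standard.
CONTROL_PERCENT = 50.0


@dataclass(frozen=True)
class ContaminationResult:
    """Delta-delta-Ct contamination score for one sample.

    ``percent_hmw = rne * CONTROL_PERCENT`` exactly.  ``below_loq`` marks a
    sample whose long amplicon never amplified: ``percent_hmw`` is then the
    upper bound obtained by placing the long Cq at the last cycle, not a
    measurement (and never silently 0).
    """

    sample_id: str
    delta_ct: float
    delta_delta_ct: float
    rne: float
    percent_hmw: float
    below_loq: bool = False


def _mean_cq(rows: pd.DataFrame, assay: str, what: str) -> tuple[float, float, bool]:
    """(mean detected Cq, efficiency, all_nondetect) for one assay's replicates."""
    sub = rows[rows["assay"] == assay]
    if sub.empty:
        raise ValueError(f"{what}: no rows for assay {assay!r}")
    eff = float(sub["efficiency"].iloc[0])
    if not 1.0 < eff <= 2.2:
        raise ValueError(f"{what}: efficiency for {assay!r} must be in (1, 2.2], got {eff}")
    cq = sub["cq"].to_numpy(dtype=float)
    detected = cq[np.isfinite(cq) & (cq < MAX_QPCR_CYCLES)]
    if detected.size == 0:
        return math.nan, eff, True
    return float(detected.mean()), eff, False


def contamination_score(
    sample_rows: pd.DataFrame,
    control_rows: pd.DataFrame,
    control_percent: float = CONTROL_PERCENT,
) -> ContaminationResult:
    """Score one sample against the calibration control standard.

    Per sample, ``dCt = mean Cq(long) - mean Cq(short)`` over detected
    replicates; ``ddCt = dCt_sample - dCt_control``.  With equal
    amplification efficiencies ``E`` the relative normalized expression is
    ``E**(-ddCt)``; with per-assay efficiencies the Pfaffl form is used::

        rne = E_long**(Cq_long_ctrl - Cq_long_smp)
              / E_short**(Cq_short_ctrl - Cq_short_smp)

    and ``percent_hmw = rne * control_percent``.  A sample whose long
    amplicon is non-detect in every replicate is scored at the last cycle
    and flagged ``below_loq`` (an upper bound on contamination).
    """
    sid = str(sample_rows["sample_id"].iloc[0])
    s_cq, s_eff, s_nd = _mean_cq(sample_rows, SHORT_ASSAY, f"sample {sid}")
    l_cq, l_eff, l_nd = _mean_cq(sample_rows, LONG_ASSAY, f"sample {sid}")
    c_s_cq, c_s_eff, c_s_nd = _mean_cq(control_rows, SHORT_ASSAY, "control")
    c_l_cq, c_l_eff, c_l_nd = _mean_cq(control_rows, LONG_ASSAY, "control")
    if s_nd:
        raise ValueError(f"sample {sid}: short (reference) amplicon never detected")
    if c_s_nd or c_l_nd:
        raise ValueError("control standard must amplify in both assays")
    below_loq = False
    if l_nd:
        l_cq = MAX_QPCR_CYCLES
        below_loq = True

    delta_ct = l_cq - s_cq
    delta_delta_ct = delta_ct - (c_l_cq - c_s_cq)
    # Pfaffl-style: ratio of per-assay fold changes vs control.  Collapses
    # to eff**(-ddCt) when both assays share one efficiency.
    rne = (l_eff ** (c_l_cq - l_cq)) / (s_eff ** (c_s_cq - s_cq))
    return ContaminationResult(
        sample_id=sid,
        delta_ct=delta_ct,
        delta_delta_ct=delta_delta_ct,
        rne=rne,
        percent_hmw=rne * control_percent,
        below_loq=below_loq,
    )


def score_batch(
    table: pd.DataFrame, control_id: str, control_percent: float = CONTROL_PERCENT
) -> pd.DataFrame:
    """Score every non-control sample in a Cq table; rows sorted by sample_id."""
    control_rows = table[table["sample_id"] == control_id]
    if control_rows.empty:
        raise ValueError(f"control sample {control_id!r} not found in table")
    recs = []
    for sid in sorted(set(table["sample_id"]) - {control_id}):
        res = contamination_score(table[table["sample_id"] == sid], control_rows, control_percent)
        recs.append(
            {
                "sample_id": res.sample_id,
                "delta_ct": res.delta_ct,
                "delta_delta_ct": res.delta_delta_ct,
                "rne": res.rne,
                "percent_hmw": res.percent_hmw,
                "below_loq": res.below_loq,
            }
        )
    return pd.DataFrame(
        recs,
        columns=["sample_id", "delta_ct", "delta_delta_ct", "rne", "percent_hmw", "below_loq"],
    )


def screen_batch(
    table: pd.DataFrame,
    control_id: str,
    threshold_percent: float = 10.0,
    control_percent: float = CONTROL_PERCENT,
) -> pd.DataFrame:
    """Flag samples whose contamination percentage exceeds a threshold.

    Returns the scored rows (stable sample_id order) for every flagged
    sample; an empty frame when the table has no non-control samples or
    none exceed the threshold.
    """
    if table.empty:
        return pd.DataFrame(
            columns=["sample_id", "delta_ct", "delta_delta_ct", "rne", "percent_hmw", "below_loq"]
        )
    scored = score_batch(table, control_id, control_percent)
    return scored[scored["percent_hmw"] > threshold_percent].reset_index(drop=True)


def idealized_panel_cq(
    fractions=(0.01, 0.05, 0.25, 0.50),
    efficiency: float = 2.0,
    cq_short: float = 25.0,
    n_replicates: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noiseless (by default) Cq rows for the calibration panel under
    idealized detectability: the short amplicon amplifies from *all* DNA
    mass (so its Cq is the same for every standard), the long amplicon only
    from the HMW mass fraction ``f`` (Cq rising as f shrinks):

        Cq_long(f) = cq_short - log_efficiency(f)

    Under this model the delta-delta-Ct score recovers each standard's HMW
    percentage exactly.  Sample ids are ``std_<percent>pct``.
    """
    if efficiency <= 1.0:
        raise ValueError("efficiency must be > 1")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"mass fraction must be in (0, 1], got {f}")
        sid = f"std_{100 * f:g}pct"
        cq_long = cq_short - math.log(f) / math.log(efficiency)
        for rep in range(1, n_replicates + 1):
            eps_s = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
            eps_l = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((sid, SHORT_ASSAY, rep, cq_short + eps_s, efficiency))
            rows.append((sid, LONG_ASSAY, rep, cq_long + eps_l, efficiency))
    return pd.DataFrame(rows, columns=["sample_id", "assay", "replicate", "cq", "efficiency"])


def read_cq_csv(path) -> pd.DataFrame:
    """Read a Cq CSV (sample_id, assay, replicate, cq, efficiency)."""
    df = pd.read_csv(path)
    required = {"sample_id", "assay", "replicate", "cq", "efficiency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
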