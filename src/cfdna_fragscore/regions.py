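"""Per-region cfDNA fragment-length summarization from interval data.

Given cfDNA fragments as BED intervals and a set of labeled target regions
(e.g. two open-chromatin loci and a pericentromeric closed-chromatin
locus), assign each fragment to the region containing its midpoint and
summarize the fragment-length distribution per region as median and
interquartile range.  Midpoint assignment guarantees a partition on
disjoint regions: no fragment is double counted.  Coordinates follow the
BED convention throughout — 0-based, half-open; strand is ignored because
cfDNA fragments are double-stranded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionSet",
    "RegionLengthSummary",
    "read_bed",
    "assign_fragments",
    "summarize_regions",
    "example_region_set",
]


@dataclass
class RegionSet:
    """Labeled target regions; labels must be unique, intervals non-empty."""

    intervals: pd.DataFrame  # columns: chrom, start, end, label

    def __post_init__(self) -> None:
        df = self.intervals
        required = {"chrom", "start", "end", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"region table missing columns {sorted(missing)}")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"region {bad['label']!r}: start must be < end")
        if df["label"].duplicated().any():
            dup = df["label"][df["label"].duplicated()].iloc[0]
            raise ValueError(f"duplicate region label {dup!r}")
        # disjointness within chromosome (required for searchsorted lookup
        # and the partition guarantee)
        for chrom, sub in df.groupby("chrom"):
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping regions on {chrom}")

    @property
    def labels(self) -> list[str]:
        return list(self.intervals["label"])


@dataclass(frozen=True)
class RegionLengthSummary:
    label: str
    n_fragments: int
    median_bp: float | None
    iqr_low_bp: float | None
    iqr_high_bp: float | None


def read_bed(path, labeled: bool = False) -> pd.DataFrame:
    """Read a BED file; errors cite the offending line number.

    With ``labeled=True`` the 4th column is required and returned as
    ``label`` (region files); otherwise it is optional ``name``.
    """
    with open(path) as fh:
        return _read_bed_handle(fh, str(path), labeled)


def assign_fragments(fragments: pd.DataFrame, regions: RegionSet) -> dict[str, np.ndarray]:
    """Assign fragments to regions by midpoint containment.

    A fragment belongs to a region when its midpoint ``(start + end) / 2``
    lies in the half-open region interval; its recorded length is
    ``end - start``.  Returns ``{label: array of lengths}`` with an entry
    for every region label (possibly empty).
    """
    required = {"chrom", "start", "end"}
    missing = required - set(fragments.columns)
    if missing:
        raise ValueError(f"fragment table missing columns {sorted(missing)}")
    out: dict[str, list] = {label: [] for label in regions.labels}
    by_chrom = {
        chrom: sub.sort_values("start").reset_index(drop=True)
        for chrom, sub in regions.intervals.groupby("chrom")
    }
    for chrom, frag in fragments.groupby("chrom"):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy(dtype=float)
        ends = sub["end"].to_numpy(dtype=float)
        labels = sub["label"].to_numpy()
        f_start = frag["start"].to_numpy(dtype=float)
        f_end = frag["end"].to_numpy(dtype=float)
        mid = (f_start + f_end) / 2.0
        idx = np.searchsorted(starts, mid, side="right") - 1
        ok = (idx >= 0) & (mid < ends[np.clip(idx, 0, len(ends) - 1)])
        lengths = (f_end - f_start).astype(np.int64)
        for i, label in enumerate(labels):
            out[label].extend(lengths[ok & (idx == i)])
    return {label: np.asarray(v, dtype=np.int64) for label, v in out.items()}


def summarize_regions(assignments: dict[str, np.ndarray]) -> list[RegionLengthSummary]:
    """Median and interquartile range (linear interpolation) per region.

    Empty regions are reported with ``n_fragments=0`` and null summaries
    rather than dropped.
    """
    out = []
    for label, lengths in assignments.items():
        lengths = np.asarray(lengths, dtype=float)
        if lengths.size == 0:
            out.append(RegionLengthSummary(label, 0, None, None, None))
            continue
        q1, med, q3 = np.percentile(lengths, [25, 50, 75])
        out.append(RegionLengthSummary(label, int(lengths.size), float(med), float(q1), float(q3)))
    return out


def example_region_set() -> RegionSet:
    """Synthetic placeholder OCR1/OCR2/CCR intervals shipped with the package.

    The true assay coordinates are not published; these exist only so the
    interval machinery can be exercised end to end.
    """
    from importlib.resources import files

    path = files("cfdna_fragscore.data").joinpath("example_regions.bed")
    with path.open() as fh:
        return RegionSet(_read_bed_handle(fh, "example_regions.bed", labeled=True))


def _read_bed_handle(fh, name: str, labeled: bool) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3 or (labeled and len(parts) < 4):
            raise ValueError(f"{name}:{lineno}: expected at least "
                             f"{4 if labeled else 3} BED columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{name}:{lineno}: non-integer coordinates") from exc
        if start < 0 or start >= end:
            raise ValueError(f"{name}:{lineno}: require 0 <= start < end")
        rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else ""))
    cols = ["chrom", "start", "end", "label" if labeled else "name"]
    return pd.DataFrame(rows, columns=cols)


def summary_frame(summaries: list[RegionLengthSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": s.label,
                "n_fragments": s.n_fragments,
                "median_bp": s.median_bp,
                "iqr_low_bp": s.iqr_low_bp,
                "iqr_high_bp": s.iqr_high_bp,
            }
            for s in summaries
        ]
    )
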