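"""Morphological outputs: line counts, lengths, and length-bin percentages.

The elongation phenotype is summarized per image by the number of
detected piecewise lines (a proxy for cell count), their lengths in
pixels, and the percentage of lines in four length bins: 20-25, 25-30,
30-40 and >40 pixels.  Bins are half-open, [lo, hi), with the final bin
[40, inf), so every length >= 20 falls in exactly one bin.  Reported SD
is the sample standard deviation (ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .postprocess import PolylineCell, polyline_length

#: Half-open bin edges over reported lengths; the last bin is unbounded.
BIN_EDGES = (20.0, 25.0, 30.0, 40.0, np.inf)
BIN_LABELS = ("20-25", "25-30", "30-40", ">40")


@dataclass
class MorphologyReport:
    """Per-image quantitative product of the pipeline."""

    image_id: str
    group: str | None = None
    day: int | None = None
    lengths: list[float] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return len(self.lengths)

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.lengths)) if self.lengths else float("nan")

    @property
    def sd_length(self) -> float:
        if len(self.lengths) < 2:
            return float("nan")
        return float(np.std(self.lengths, ddof=1))

    @property
    def bin_percentages(self) -> dict[str, float]:
        """Percentage of lines per length bin; all zero when empty."""
        if not self.lengths:
            return {label: 0.0 for label in BIN_LABELS}
        counts, _ = np.histogram(self.lengths, bins=BIN_EDGES)
        pct = 100.0 * counts / len(self.lengths)
        return dict(zip(BIN_LABELS, pct.tolist()))

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "group": self.group,
            "day": self.day,
            "n_lines": self.n_lines,
            "lengths": list(self.lengths),
            "mean_length": self.mean_length,
            "sd_length": self.sd_length,
            "bin_percentages": self.bin_percentages,
            "bin_convention": "half-open [lo, hi); last bin [40, inf)",
        }


def summarize(
    cells: list[PolylineCell],
    image_id: str,
    group: str | None = None,
    day: int | None = None,
) -> MorphologyReport:
    """Summarize one image's piecewise lines into a report.

    Permutation-invariant over input cells.  An empty input yields a
    report with ``n_lines == 0`` and NaN mean (flagged, not an error).
    """
    lengths = sorted(polyline_length(c) for c in cells)
    return MorphologyReport(image_id=image_id, group=group, day=day,
                            lengths=lengths)


def assemble_timecourse(reports: list[MorphologyReport]) -> pd.DataFrame:
    """Assemble per-image reports into one long-format table.

    Each report contributes one ``summary`` row (with ``n_lines``,
    ``mean_length``) and one ``length`` row per detected line, keyed by
    (group, day, image_id) — a tidy layout ready for plotting or
    external group statistics.  Duplicate keys raise a ValueError.
    """
    columns = ["group", "day", "image_id", "row_type",
               "n_lines", "mean_length", "length"]
    keys = [(r.group, r.day, r.image_id) for r in reports]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (group, day, image_id) keys: {dupes}")
    rows = []
    for r in reports:
        rows.append({"group": r.group, "day": r.day, "image_id": r.image_id,
                     "row_type": "summary", "n_lines": r.n_lines,
                     "mean_length": r.mean_length, "length": np.nan})
        for length in r.lengths:
            rows.append({"group": r.group, "day": r.day,
                         "image_id": r.image_id, "row_type": "length",
                         "n_lines": np.nan, "mean_length": np.nan,
                         "length": length})
    return pd.DataFrame(rows, columns=columns)
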