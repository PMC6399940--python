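"""Near-zero-variance feature filtering and feature-type reporting.

A feature is dropped when it carries (almost) no information across the
sample: either one unique value (zero variance), or very few unique
values relative to the number of samples combined with a dominant modal
value. The two thresholds mirror the defaults of the classic
near-zero-variance filter: frequency-ratio cut 95/5 = 19 and unique-value
percentage cut 10.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REASON_ZERO_VARIANCE = "zero variance"
REASON_NEAR_ZERO_VARIANCE = "near zero variance"

_BLOCK_RE = re.compile(r"^(pse|rk\d+|k\d+|pc|at)_")

_BLOCK_LABELS = {
    "pse": "PseAAC",
    "pc": "physico-chemical profile",
    "at": "atomic profile",
}


@dataclass(frozen=True)
class NZVConfig:
    """Thresholds for the near-zero-variance filter.

    ``freq_cut``: minimum ratio of the most common value's frequency to
    the second most common value's frequency for a feature to count as
    imbalanced. ``unique_cut``: maximum percentage of unique values
    (relative to sample count) for a feature to count as low-cardinality.
    Both conditions must hold for a non-constant feature to be dropped.
    """

    freq_cut: float = 95.0 / 5.0
    unique_cut: float = 10.0

    def __post_init__(self) -> None:
        if self.freq_cut <= 1:
            raise ValueError("freq_cut must be > 1")
        if not 0 < self.unique_cut <= 100:
            raise ValueError("unique_cut must be in (0, 100]")


@dataclass
class SelectionReport:
    """Outcome of a filtering pass: kept names and dropped names with reasons."""

    kept: list[str]
    dropped: dict[str, str]
    n_samples: int

    def __post_init__(self) -> None:
        overlap = set(self.kept) & set(self.dropped)
        if overlap:
            raise ValueError(f"features both kept and dropped: {sorted(overlap)[:5]}")

    @property
    def all_features(self) -> list[str]:
        return self.kept + list(self.dropped)


def near_zero_variance(matrix: pd.DataFrame, cfg: NZVConfig = NZVConfig()) -> SelectionReport:
    """Classify every feature of ``matrix`` as kept or dropped.

    Dropped iff (a) the column has exactly one unique value, or (b) the
    percentage of unique values is <= ``unique_cut`` AND the
    most-common / second-most-common frequency ratio is >= ``freq_cut``.
    Floating-point values are treated as exact keys (no tolerance
    binning). Requires at least two rows; the criteria are undefined on
    a single sample.
    """
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("near-zero-variance filtering needs >= 2 samples")
    arr = matrix.to_numpy()
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for j, name in enumerate(matrix.columns):
        _, counts = np.unique(arr[:, j], return_counts=True)
        if counts.size == 1:
            dropped[str(name)] = REASON_ZERO_VARIANCE
            continue
        pct_unique = 100.0 * counts.size / n
        top2 = np.partition(counts, -2)[-2:]
        ratio = top2[1] / top2[0]
        if pct_unique <= cfg.unique_cut and ratio >= cfg.freq_cut:
            dropped[str(name)] = REASON_NEAR_ZERO_VARIANCE
        else:
            kept.append(str(name))
    return SelectionReport(kept=kept, dropped=dropped, n_samples=n)


def apply_selection(matrix: pd.DataFrame, report: SelectionReport) -> pd.DataFrame:
    """Project a matrix onto the kept features of a report."""
    missing = [f for f in report.kept if f not in matrix.columns]
    if missing:
        raise KeyError(f"matrix lacks kept feature(s): {missing[:10]}")
    return matrix[report.kept]


def _block_key(feature: str) -> str:
    m = _BLOCK_RE.match(feature)
    if m is None:
        raise ValueError(f"feature {feature!r} does not follow the frozen prefix scheme")
    return m.group(1)


def _block_label(key: str) -> str:
    if key in _BLOCK_LABELS:
        return _BLOCK_LABELS[key]
    if key.startswith("rk"):
        return f"k-mer, reduced alphabet (k={key[2:]})"
    return f"k-mer (k={key[1:]})"


def _block_sort_key(key: str) -> tuple:
    order = {"pse": 0, "k": 1, "rk": 2, "pc": 3, "at": 4}
    m = re.match(r"(rk|k)(\d+)", key)
    if m:
        return (order[m.group(1)], int(m.group(2)))
    return (order[key], 0)


def summarize_selected_by_type(report: SelectionReport) -> pd.DataFrame:
    """Tally kept/dropped features per encoder block.

    Returns one row per block present in the report with the number of
    extracted and kept features, the percentage of the block that was
    kept, and the block's share of the total kept set (these shares sum
    to 100 when any feature was kept).
    """
    extracted: dict[str, int] = {}
    kept_counts: dict[str, int] = {}
    for f in report.kept:
        key = _block_key(f)
        extracted[key] = extracted.get(key, 0) + 1
        kept_counts[key] = kept_counts.get(key, 0) + 1
    for f in report.dropped:
        key = _block_key(f)
        extracted[key] = extracted.get(key, 0) + 1
        kept_counts.setdefault(key, 0)

    n_kept_total = sum(kept_counts.values())
    rows = []
    for key in sorted(extracted, key=_block_sort_key):
        n_ext, n_kept = extracted[key], kept_counts[key]
        rows.append(
            {
                "feature_type": _block_label(key),
                "n_extracted": n_ext,
                "n_kept": n_kept,
                "pct_kept": 100.0 * n_kept / n_ext,
                "pct_of_kept_total": (100.0 * n_kept / n_kept_total) if n_kept_total else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["feature_type", "n_extracted", "n_kept", "pct_kept", "pct_of_kept_total"])
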