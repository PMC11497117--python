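"""Marker-intensity quantization and 8-way CD8/NOS2/COX2 phenotype assignment.

Each cell carries continuous intensities for the three core markers.  These
are quantized into ordinal levels (negative < weak < moderate < strong) by
per-marker thresholds, and the levels are collapsed to a +/- call per marker
via a configurable positivity set.  The three binary calls are packed into a
single integer phenotype code::

    code = 4*CD8 + 2*NOS2 + COX2        (0..7; 7 = CD8+NOS2+COX2+)

NOS2 strength is retained alongside the code because downstream analyses
distinguish strong-NOS2 ("NOS2s") cells from merely moderate ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEVELS = ("negative", "weak", "moderate", "strong")
LEVEL_ORDER = {lvl: i for i, lvl in enumerate(LEVELS)}

CORE_MARKERS = ("cd8", "nos2", "cox2")

#: bit position of each marker in the phenotype code
MARKER_BITS = {"cd8": 4, "nos2": 2, "cox2": 1}

#: human-readable name for each of the 8 codes, e.g. 3 -> "CD8-NOS2+COX2+"
PHENOTYPE_NAMES = {
    code: "CD8{}NOS2{}COX2{}".format(
        "+" if code & 4 else "-",
        "+" if code & 2 else "-",
        "+" if code & 1 else "-",
    )
    for code in range(8)
}


def _default_positivity() -> dict:
    # CD8 is a lineage marker: any detectable signal counts as positive.
    # NOS2/COX2 are graded functional markers: moderate-or-above counts.
    return {
        "cd8": frozenset({"weak", "moderate", "strong"}),
        "nos2": frozenset({"moderate", "strong"}),
        "cox2": frozenset({"moderate", "strong"}),
    }


@dataclass(frozen=True)
class QuantizationRule:
    """Per-marker intensity thresholds and positivity sets.

    Parameters
    ----------
    thresholds
        ``{marker: (t_weak, t_moderate, t_strong)}``.  Intensity ``v`` maps to
        negative if ``v < t_weak``, weak if ``t_weak <= v < t_moderate``,
        moderate if ``t_moderate <= v < t_strong``, else strong.  Boundaries
        are lower-inclusive.
    positivity
        ``{marker: set of levels counted as "+"}``.  Each set must be
        upward-closed in level order (if weak is positive, so are moderate
        and strong).
    """

    thresholds: dict
    positivity: dict = field(default_factory=_default_positivity)

    def __post_init__(self):
        for marker, (tw, tm, ts) in self.thresholds.items():
            if not (0 <= tw <= tm <= ts):
                raise ValueError(
                    f"{marker}: thresholds must satisfy 0 <= t_weak <= "
                    f"t_moderate <= t_strong, got ({tw}, {tm}, {ts})"
                )
        for marker, pos in self.positivity.items():
            ranks = sorted(LEVEL_ORDER[lvl] for lvl in pos)
            if ranks and ranks != list(range(ranks[0], 4)):
                raise ValueError(
                    f"{marker}: positivity set {set(pos)} is not upward-closed"
                )

    @classmethod
    def from_quantiles(
        cls,
        cells: pd.DataFrame,
        markers=CORE_MARKERS,
        quantiles=(0.5, 0.75, 0.9),
        positivity: dict | None = None,
    ) -> "QuantizationRule":
        """Derive thresholds as per-marker intensity quantiles of a cohort.

        The default (0.5, 0.75, 0.9) makes the top half of a marker's
        distribution at least weak, the top quarter at least moderate and the
        top decile strong.
        """
        thresholds = {
            m: tuple(np.quantile(cells[m].to_numpy(float), quantiles))
            for m in markers
        }
        kwargs = {} if positivity is None else {"positivity": positivity}
        return cls(thresholds=thresholds, **kwargs)

    def to_json(self, path) -> None:
        payload = {
            "thresholds": {m: list(t) for m, t in self.thresholds.items()},
            "positivity": {m: sorted(p) for m, p in self.positivity.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QuantizationRule":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            thresholds={m: tuple(t) for m, t in payload["thresholds"].items()},
            positivity={
                m: frozenset(p) for m, p in payload["positivity"].items()
            },
        )


def quantize_intensity(value, rule: QuantizationRule, marker: str):
    """Map intensity value(s) to a level in {negative, weak, moderate, strong}.

    Accepts a scalar or array; returns a string or array of strings.
    Boundaries are lower-inclusive: a value exactly at ``t_moderate`` is
    moderate.  NaN intensities raise.
    """
    arr = np.asarray(value, dtype=float)
    if np.isnan(arr).any():
        bad = np.nonzero(np.atleast_1d(np.isnan(arr)))[0]
        raise ValueError(
            f"NaN intensity for marker {marker!r} at row(s) {bad.tolist()}"
        )
    edges = np.asarray(rule.thresholds[marker], dtype=float)
    idx = np.searchsorted(edges, arr, side="right")
    out = np.take(np.asarray(LEVELS), idx)
    return out if arr.ndim else out.item()


def level_to_positive(level, rule: QuantizationRule, marker: str):
    """Collapse quantized level(s) to a boolean +/- call for a marker."""
    pos = rule.positivity[marker]
    arr = np.atleast_1d(np.asarray(level))
    out = np.isin(arr, sorted(pos))
    return out if np.asarray(level).ndim else bool(out[0])


def assign_phenotype(cd8_level, nos2_level, cox2_level, rule: QuantizationRule):
    """Combine per-marker levels into an integer phenotype code 0..7."""
    code = (
        4 * np.asarray(level_to_positive(cd8_level, rule, "cd8"), dtype=int)
        + 2 * np.asarray(level_to_positive(nos2_level, rule, "nos2"), dtype=int)
        + np.asarray(level_to_positive(cox2_level, rule, "cox2"), dtype=int)
    )
    return code if np.asarray(cd8_level).ndim else int(code)


def phenotype_cells(
    cells: pd.DataFrame, rule: QuantizationRule, markers=CORE_MARKERS
) -> pd.DataFrame:
    """Append ``level_<marker>`` columns and a ``phenotype`` code column.

    Returns a copy; the input table is not modified.
    """
    out = cells.copy()
    for m in markers:
        out[f"level_{m}"] = quantize_intensity(
            out[m].to_numpy(float), rule, m
        )
    out["phenotype"] = assign_phenotype(
        out["level_cd8"].to_numpy(),
        out["level_nos2"].to_numpy(),
        out["level_cox2"].to_numpy(),
        rule,
    )
    return out


def phenotype_counts(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-phenotype cell counts and percentages for a phenotyped table.

    Returns a frame indexed by code 0..7 with columns ``name``, ``count``,
    ``percent``.  Percentages sum to 100 (all-zero for an empty table, with
    a warning).
    """
    counts = np.zeros(8, dtype=int)
    if len(cells) == 0:
        warnings.warn("phenotype_counts: empty sample, all counts zero")
    else:
        vc = cells["phenotype"].value_counts()
        counts[vc.index.to_numpy(int)] = vc.to_numpy()
    total = counts.sum()
    percent = 100.0 * counts / total if total else np.zeros(8)
    return pd.DataFrame(
        {
            "name": [PHENOTYPE_NAMES[c] for c in range(8)],
            "count": counts,
            "percent": percent,
        },
        index=pd.RangeIndex(8, name="phenotype"),
    )
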