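"""Canonical 68-variable feature manifest.

Each specimen is described by 34 variables per view (dorsal, ventral):
13 size/shape descriptors plus 7 intensity statistics for each of the three
RGB channels.  Every table produced or consumed by the pipeline uses these
column names in this order.
"""

from __future__ import annotations

VIEWS: tuple[str, ...] = ("dorsal", "ventral")

SHAPE_VARS: tuple[str, ...] = (
    "area",
    "perimeter",
    "width",
    "height",
    "feret",
    "min_feret",
    "major",
    "minor",
    "angle",
    "circularity",
    "aspect_ratio",
    "roundness",
    "solidity",
)

CHANNELS: tuple[str, ...] = ("R", "G", "B")

COLOR_STATS: tuple[str, ...] = (
    "mean",
    "sd",
    "integrated_density",
    "skewness",
    "kurtosis",
    "min",
    "max",
)


def view_variables() -> list[str]:
    """The 34 per-view variable names (shape first, then channel-major color)."""
    out = list(SHAPE_VARS)
    for ch in CHANNELS:
        out.extend(f"{ch}_{stat}" for stat in COLOR_STATS)
    return out


def feature_names() -> list[str]:
    """The canonical 68 feature column names."""
    return [f"{view}_{var}" for view in VIEWS for var in view_variables()]


N_FEATURES: int = len(feature_names())
assert N_FEATURES == 68
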