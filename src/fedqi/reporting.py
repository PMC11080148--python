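"""Cross-center comparison plots in the national-audit dashboard style.

Two figures, mirroring how the registry feeds results back to hospitals:

* Waiting-time indicator: per-center percentage of short-wait patients
  against cohort size, with a green horizontal line at the cross-center
  mean percentage.
* Complication indicator: each center's rate expressed relative to the
  cross-center mean (rate-of-mean) against its expected number of events
  (mean rate x cohort size), with a blue reference line at the mean level
  (rate-of-mean = 1).

No funnel control limits are drawn — only mean lines.  Output is
regenerable byte-stably: SVG metadata dates are stripped and the SVG hash
salt is pinned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .federated import GlobalResult
from .indicators import format_percentage, format_rate

logger = logging.getLogger(__name__)

plt.rcParams["svg.hashsalt"] = "fedqi"


@dataclass(frozen=True)
class PlotSpec:
    indicator_id: str
    output_path: Union[str, Path]
    image_format: str = "png"  # png | svg
    labels: Optional[dict[str, str]] = None  # center_id -> display name

    def __post_init__(self) -> None:
        if self.image_format not in ("png", "svg"):
            raise ValueError(f"unknown image format {self.image_format!r}")

    def label(self, center_id: str) -> str:
        return (self.labels or {}).get(center_id, center_id)


def _save(fig, spec: PlotSpec) -> Path:
    path = Path(spec.output_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # metadata pinned so identical inputs give identical bytes
    metadata = {"Date": None} if spec.image_format == "svg" else {"Software": "fedqi"}
    fig.savefig(path, format=spec.image_format, metadata=metadata)
    plt.close(fig)
    return path


def _defined_locals(result: GlobalResult):
    defined = [lr for lr in result.local_results if lr.ratio is not None]
    omitted = [lr.center_id for lr in result.local_results if lr.ratio is None]
    if omitted:
        logger.info("centers omitted from plot (undefined ratio): %s", omitted)
    if not defined:
        raise ValueError("no plottable centers: every ratio is undefined")
    return defined


def plot_qi2b(result: GlobalResult, spec: PlotSpec) -> Path:
    """Percentage of short-wait patients vs cohort size, mean line in green."""
    defined = _defined_locals(result)
    fig, ax = plt.subplots(figsize=(7, 5))
    xs = [lr.denominator for lr in defined]
    ys = [lr.ratio * 100 for lr in defined]
    ax.scatter(xs, ys, color="tab:orange", zorder=3)
    for lr, x, y in zip(defined, xs, ys):
        ax.annotate(
            f"{spec.label(lr.center_id)} ({format_percentage(lr.ratio)}%)",
            (x, y),
            textcoords="offset points",
            xytext=(6, 6),
            fontsize=9,
        )
    mean_pct = result.mean_ratio * 100
    ax.axhline(mean_pct, color="green", label=f"mean {format_percentage(result.mean_ratio)}%")
    ax.set_xlabel("number of patients")
    ax.set_ylabel("patients with waiting time < 5 weeks (%)")
    ax.set_title("Waiting time between diagnosis and start of therapy")
    ax.set_ylim(-5, 105)
    ax.legend(loc="lower right")
    return _save(fig, spec)


def plot_qi8(result: GlobalResult, spec: PlotSpec) -> Path:
    """Rate-of-mean vs expected events, mean reference line in blue."""
    defined = _defined_locals(result)
    fig, ax = plt.subplots(figsize=(7, 5))
    xs = [result.per_center_expected_events[lr.center_id] for lr in defined]
    ys = [result.per_center_rate_of_mean[lr.center_id] for lr in defined]
    ax.scatter(xs, ys, color="tab:red", zorder=3)
    for lr, x, y in zip(defined, xs, ys):
        ax.annotate(
            f"{spec.label(lr.center_id)} ({format_rate(lr.ratio)})",
            (x, y),
            textcoords="offset points",
            xytext=(6, 6),
            fontsize=9,
        )
    ax.axhline(1.0, color="tab:blue", label=f"mean rate {format_rate(result.mean_ratio)}")
    ax.set_xlabel("expected events (mean rate x cohort size)")
    ax.set_ylabel("complication rate / mean rate")
    ax.set_title("Postoperative complications after resection")
    ax.legend(loc="lower right")
    return _save(fig, spec)


def plot_indicator(result: GlobalResult, spec: PlotSpec) -> Path:
    if result.indicator_id == "qi2b":
        return plot_qi2b(result, spec)
    return plot_qi8(result, spec)
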