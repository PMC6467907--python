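"""Iso-mortality structures and quadrant plots of the investment plane.

The classification figure is a scatter of relative offspring quality ``S``
against offspring quantity ``N`` per species, with the axes "moved" to the
set points so the four selection categories appear as quadrants, and optional
iso-predation-mortality gridlines superimposed.  Because ``P = 1 - w/N``,
the clutch size at which predation mortality reaches a level ``p`` is
``N = w/(1 - p)``; scarcity mortality equals ``S`` itself, so its iso-lines
are horizontal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")  # file output only; no interactive backend assumed
import matplotlib.pyplot as plt
import pandas as pd

from .model_core import (
    Category,
    ClassificationResult,
    DomainError,
    InvalidInputError,
    ModelParams,
)

__all__ = ["MortalitySurface", "iso_mortality_n", "mortality_surface", "quadrant_plot"]

_CATEGORY_CORNERS = {
    # (x, y) in axes-fraction coordinates for the region labels
    Category.WEAK: (0.02, 0.02),
    Category.PREDATION: (0.98, 0.02),
    Category.SCARCITY: (0.02, 0.98),
    Category.CONVERGENT: (0.98, 0.98),
}


@dataclass(frozen=True)
class MortalitySurface:
    """Iso-mortality levels superimposed on the investment plane.

    ``n_at_level[i]`` is the offspring count at which predation mortality
    equals ``p_levels[i]`` for the given ``w``; ``s_levels`` are the scarcity
    mortality probabilities, numerically identical to the ``S`` axis values.
    """

    p_levels: tuple[float, ...]
    n_at_level: tuple[float, ...]
    s_levels: tuple[float, ...]


def iso_mortality_n(p_level: float, w: float = 2.0) -> float:
    """Offspring count at which predation mortality equals ``p_level``.

    Inverts ``P = 1 - w/N`` to ``N = w/(1 - P)``; a mutual inverse of
    :func:`breederinvest.model_core.predation_mortality`.
    """
    if not w > 0:
        raise InvalidInputError(f"w must be > 0, got {w}")
    if p_level < 0:
        raise InvalidInputError(f"p_level must be >= 0, got {p_level}")
    if p_level >= 1:
        raise DomainError(f"p_level must be < 1 (no finite N reaches P = {p_level})")
    return w / (1.0 - p_level)


def mortality_surface(p_levels: Sequence[float], w: float = 2.0) -> MortalitySurface:
    """Build the iso-mortality structure for a sorted set of P levels."""
    levels = tuple(sorted(set(float(p) for p in p_levels)))
    n_at = tuple(iso_mortality_n(p, w) for p in levels)
    return MortalitySurface(p_levels=levels, n_at_level=n_at, s_levels=levels)


def _results_frame(
    results: Union[Sequence[ClassificationResult], pd.DataFrame]
) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        required = {"effective_n", "S", "taxon_group", "category"}
        missing = required - set(results.columns)
        if missing:
            raise InvalidInputError(f"classified table missing columns {sorted(missing)}")
        df = results.copy()
        df["effective_n"] = df["effective_n"].astype(float)
        df["S"] = df["S"].astype(float)
        return df
    return pd.DataFrame(
        {
            "species": [r.species for r in results],
            "taxon_group": [r.taxon_group for r in results],
            "effective_n": [r.effective_n for r in results],
            "S": [r.s_value for r in results],
            "category": [r.category.value for r in results],
        }
    )


def quadrant_plot(
    results: Union[Sequence[ClassificationResult], pd.DataFrame],
    params: ModelParams = ModelParams(),
    path: Union[str, Path] = "quadrants.png",
    *,
    log_x: bool = True,
    iso_p: Sequence[float] = (),
    color_by: str = "taxon_group",
    title: Optional[str] = None,
) -> Path:
    """Scatter species on the (N, S) plane with set-point axes.

    One point per species at ``(effective_n, S)``, coloured by
    ``color_by`` (taxon group by default); solid lines mark the set points,
    dashed vertical lines mark optional iso-P levels, and each quadrant is
    labelled with its category name.  ``N`` spans singleton broods to
    pelagic-spawner clutches, so the x axis is log-scaled unless ``log_x``
    is false.  Output format follows the file suffix (png, svg, pdf).
    """
    df = _results_frame(results)
    if len(df) == 0:
        raise InvalidInputError("no classified species to plot")
    path = Path(path)

    fig, ax = plt.subplots(figsize=(7.5, 5.5))
    for key, group in df.groupby(color_by, sort=True):
        ax.scatter(group["effective_n"], group["S"], s=36, alpha=0.8, label=str(key))
    if log_x:
        ax.set_xscale("log")

    ax.axvline(params.n_setpoint, color="black", lw=1.2)
    ax.axhline(params.s_setpoint, color="black", lw=1.2)
    for p in iso_p:
        n = iso_mortality_n(p, params.w)
        ax.axvline(n, color="grey", lw=0.8, ls="--")
        ax.annotate(
            f"P={p:g}", (n, ax.get_ylim()[1]), ha="center", va="top", fontsize=8, color="grey"
        )

    for cat, (x, y) in _CATEGORY_CORNERS.items():
        ax.text(
            x, y, f"{cat.value} selection",
            transform=ax.transAxes,
            ha="left" if x < 0.5 else "right",
            va="bottom" if y < 0.5 else "top",
            fontsize=9, style="italic", color="dimgrey",
        )

    ax.set_xlabel("offspring quantity per breeding event, N")
    ax.set_ylabel("relative offspring quality, S = m/M")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, loc="center left", bbox_to_anchor=(1.01, 0.5), frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
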