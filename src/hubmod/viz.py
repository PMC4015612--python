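"""Colour-coded module visualisation and Cytoscape export.

Hub-partner co-expression is rendered as edge colour on a red → yellow
→ green ramp (strong negative → none → strong positive correlation).
For a global view the module topology and per-condition edge attributes
are written as Cytoscape-importable files: a SIF edge list, one
edge-attribute table per condition, and a Vizmap visual-style properties
file.  A two-condition side-by-side hub-and-spokes plot is available for
single modules; for three or more conditions use the Cytoscape export.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .data_model import (ConditionLabels, ExpressionMatrix, HubTestResult,
                         Network, NetworkModule)
from .stats import DegenerateModuleError, module_profile

logger = logging.getLogger(__name__)

UNDEFINED_COLOR = "#BEBEBE"

#: colour ramps as (r=-1, r=0, r=+1) RGB anchors; "cb" is a
#: colour-blind-safe blue/grey/orange alternative
PALETTES = {
    "ryg": ((255, 0, 0), (255, 255, 0), (0, 255, 0)),
    "cb": ((0, 114, 178), (153, 153, 153), (230, 159, 0)),
}

_PROPS_ASSET = "example_visual_style_synthetic.props"


@dataclass(frozen=True)
class EdgeVisual:
    hub: str
    partner: str
    condition: str
    correlation: float
    color: str


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def correlation_color(r: float, palette: str = "ryg") -> str:
    """Hex colour for a correlation coefficient.

    Piecewise-linear in each RGB channel between the palette anchors at
    r = -1, 0, +1 (default red/yellow/green); NaN maps to neutral grey.
    """
    try:
        lo, mid, hi = PALETTES[palette]
    except KeyError:
        raise ValueError(f"unknown palette {palette!r}") from None
    if r is None or (isinstance(r, float) and math.isnan(r)):
        return UNDEFINED_COLOR
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if r <= 0:
        frac = r + 1.0
        a, b = lo, mid
    else:
        frac = r
        a, b = mid, hi
    channels = [_round_half_up(a[i] + (b[i] - a[i]) * frac) for i in range(3)]
    return "#{:02X}{:02X}{:02X}".format(*channels)


def obtain_pair_subset(expr: ExpressionMatrix, labels: ConditionLabels,
                       results: list[HubTestResult], network: Network,
                       hubs_of_interest: list[str] | None = None,
                       alpha: float = 0.05, method: str = "pearson",
                       palette: str = "ryg") -> list[EdgeVisual]:
    """Per-condition coloured edges for the selected hub modules.

    Defaults to every hub significant at ``alpha``; explicitly requested
    hubs must be present in the results.  Correlations are recomputed
    from the unpermuted data with the same partner-drop rule as the
    test, so a partner undefined in any condition is absent from every
    condition's edge set.
    """
    by_hub = {r.hub: r for r in results}
    if hubs_of_interest is None:
        selected = [r.hub for r in results if r.p_value < alpha]
    else:
        unknown = [h for h in hubs_of_interest if h not in by_hub]
        if unknown:
            raise ValueError(
                f"unknown hubs {unknown}; valid hubs: {sorted(by_hub)}")
        selected = list(hubs_of_interest)

    adjacency: dict[str, set] = {}
    for a, b in network.edges:
        adjacency.setdefault(a, set()).add(b)
        if not network.directed:
            adjacency.setdefault(b, set()).add(a)
    genes = set(expr.gene_ids)

    visuals: list[EdgeVisual] = []
    for hub in selected:
        partners = sorted((adjacency.get(hub, set()) - {hub}) & genes)
        module = NetworkModule(hub=hub, partners=tuple(partners))
        try:
            profile = module_profile(expr, labels, module, method=method)
        except DegenerateModuleError as exc:
            logger.warning("skipping hub %s in visualisation: %s", hub, exc)
            continue
        for j, partner in enumerate(profile.partner_ids):
            for ci, cond in enumerate(profile.conditions):
                r = float(profile.corr[j, ci])
                visuals.append(EdgeVisual(
                    hub=hub, partner=partner, condition=cond,
                    correlation=r, color=correlation_color(r, palette)))
    return visuals


def export_cytoscape(edge_visuals: list[EdgeVisual], out_dir) -> list[Path]:
    """Write a Cytoscape-importable file set; returns the paths written.

    Files: ``modules.sif`` (one "hub pp partner" line per unique pair,
    condition-independent), one ``edge_attributes_<condition>.tsv`` per
    condition (edge key "hub (pp) partner", correlation, colour), and
    the packaged visual-style properties file.  Output is deterministic:
    re-export of identical input is byte-identical.
    """
    if not edge_visuals:
        raise ValueError("no edges to export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pairs = sorted({(v.hub, v.partner) for v in edge_visuals})
    sif = out / "modules.sif"
    with open(sif, "w", encoding="utf-8") as fh:
        for hub, partner in pairs:
            fh.write(f"{hub}\tpp\t{partner}\n")
    written.append(sif)

    conditions = list(dict.fromkeys(v.condition for v in edge_visuals))
    for cond in conditions:
        path = out / f"edge_attributes_{cond}.tsv"
        rows = sorted((v.hub, v.partner, v) for v in edge_visuals
                      if v.condition == cond)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("edge\tcorrelation\tcolor\n")
            for hub, partner, v in rows:
                fh.write(f"{hub} (pp) {partner}\t{v.correlation:.6f}\t"
                         f"{v.color}\n")
        written.append(path)

    props = out / "ExampleVisualStyle.props"
    asset = resources.files("hubmod.assets").joinpath(_PROPS_ASSET)
    props.write_text(asset.read_text(encoding="utf-8"), encoding="utf-8")
    written.append(props)
    logger.info("export_cytoscape: wrote %d files to %s", len(written), out)
    return written


def plot_module(edge_visuals: list[EdgeVisual], path,
                figsize: tuple[float, float] = (10.0, 5.0)) -> Path:
    """Side-by-side hub-and-spokes plot of one module in two conditions.

    The hub (dark grey) sits at the centre with partners (light grey) on
    a circle in sorted-ID order; edge colours follow the correlation
    ramp.  Deterministic layout.  Raises for anything but exactly two
    conditions (use :func:`export_cytoscape` for more).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    hubs = {v.hub for v in edge_visuals}
    if len(hubs) != 1:
        raise ValueError("plot_module draws exactly one hub module")
    hub = hubs.pop()
    conditions = list(dict.fromkeys(v.condition for v in edge_visuals))
    if len(conditions) != 2:
        raise ValueError("plot_module requires exactly 2 conditions; "
                         "use export_cytoscape for more")
    partners = sorted({v.partner for v in edge_visuals})
    angles = np.linspace(0, 2 * np.pi, len(partners), endpoint=False)
    pos = {p: (math.cos(a), math.sin(a)) for p, a in zip(partners, angles)}

    fig, axes = plt.subplots(1, 2, figsize=figsize)
    for ax, cond in zip(axes, conditions):
        colors = {v.partner: v.color for v in edge_visuals
                  if v.condition == cond}
        for p in partners:
            x, y = pos[p]
            ax.plot([0, x], [0, y], color=colors.get(p, UNDEFINED_COLOR),
                    linewidth=2.5, zorder=1)
            ax.scatter([x], [y], s=300, color="#D3D3D3", zorder=2,
                       edgecolors="black", linewidths=0.5)
            ax.annotate(p, (x, y), ha="center", va="center", fontsize=7,
                        zorder=3)
        ax.scatter([0], [0], s=600, color="#555555", zorder=2,
                   edgecolors="black", linewidths=0.5)
        ax.annotate(hub, (0, 0), ha="center", va="center", fontsize=8,
                    color="white", zorder=3)
        ax.set_title(cond)
        ax.set_xlim(-1.4, 1.4)
        ax.set_ylim(-1.4, 1.4)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.suptitle(f"Module {hub}: hub-partner co-expression by condition")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
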