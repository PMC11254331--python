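"""Sankey flow graphs over severity trajectories.

The Sankey model has three parts: **Stages** (the assessment cycles),
**Nodes** (one per severity state within a stage, height proportional to
the number of patients in that state at that cycle) and **Flows** (bands
between consecutive stages, width proportional to the number of patients
making that state-to-state transition).

:func:`build_flow_graph` tallies a :class:`FlowGraph` from a trajectory
matrix; by construction the graph satisfies three conservation
identities, which :meth:`FlowGraph.check_conservation` re-verifies:

* node counts at every stage sum to the cohort size;
* outflow of every non-terminal node equals its count;
* inflow of every non-initial node equals its count.

:func:`render_sankey` draws the graph with matplotlib. SVG is the
canonical target: output is byte-deterministic (fixed hash salt, no
timestamp metadata, text kept as text), so figures are diffable and two
renders of the same graph are identical files. Node and band elements
carry SVG ``id`` attributes (``node-<stage>-<state>``,
``link-<i>-<from>-<to>``) so tests and downstream tools can inspect the
geometry without image parsing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Rectangle

from .data_model import SeverityScale, TrajectoryMatrix

__all__ = ["FlowGraph", "build_flow_graph", "render_sankey"]

RENDER_FORMATS = ("svg", "png", "html")

# colour for the missing/off-treatment node; ordinary levels get a
# deterministic viridis ramp by level index.
_MISSING_COLOR = (0.62, 0.62, 0.62, 1.0)


@dataclass(frozen=True)
class FlowGraph:
    """Stage-indexed node counts and between-stage transition counts.

    ``node_counts`` covers the full state vocabulary at every stage
    (zero-count states are retained so consumers see the whole scale);
    ``link_counts`` holds only observed (non-zero) transitions, keyed by
    (stage index of the source stage, from-state, to-state).
    """

    stages: tuple[str, ...]
    states: tuple[str, ...]
    node_counts: Mapping[tuple[str, str], int]
    link_counts: Mapping[tuple[int, str, str], int]
    total: int

    def node(self, stage: str, state: str) -> int:
        return int(self.node_counts.get((stage, state), 0))

    def link(self, stage_index: int, a: str, b: str) -> int:
        return int(self.link_counts.get((stage_index, a, b), 0))

    def check_conservation(self) -> None:
        """Raise :class:`ValueError` if any conservation identity fails."""
        for st in self.stages:
            tot = sum(self.node(st, s) for s in self.states)
            if tot != self.total:
                raise ValueError(f"stage {st!r}: node counts sum to {tot}, not {self.total}")
        for i, st in enumerate(self.stages[:-1]):
            nxt = self.stages[i + 1]
            for a in self.states:
                out = sum(self.link(i, a, b) for b in self.states)
                if out != self.node(st, a):
                    raise ValueError(f"outflow of ({st!r}, {a!r}) is {out}")
            for b in self.states:
                inn = sum(self.link(i, a, b) for a in self.states)
                if inn != self.node(nxt, b):
                    raise ValueError(f"inflow of ({nxt!r}, {b!r}) is {inn}")

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "nodes": [
                {"stage": st, "state": s, "count": self.node(st, s)}
                for st in self.stages
                for s in self.states
            ],
            "links": [
                {"stage_index": i, "from": a, "to": b, "count": c}
                for (i, a, b), c in sorted(self.link_counts.items())
            ],
            "total": self.total,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FlowGraph":
        stages = tuple(d["stages"])
        states = tuple(dict.fromkeys(n["state"] for n in d["nodes"]))
        nodes = {(n["stage"], n["state"]): int(n["count"]) for n in d["nodes"]}
        links = {
            (int(l["stage_index"]), l["from"], l["to"]): int(l["count"])
            for l in d["links"]
            if int(l["count"]) != 0
        }
        return cls(stages=stages, states=states, node_counts=nodes,
                   link_counts=links, total=int(d["total"]))


def build_flow_graph(trajectories: TrajectoryMatrix) -> FlowGraph:
    """Tally marginal node counts and consecutive-stage transition counts.

    Requires at least one patient and at least two stages (a single stage
    defines no flows).
    """
    if trajectories.n_patients < 1:
        raise ValueError("flow graph needs at least one patient")
    if len(trajectories.stages) < 2:
        raise ValueError("flow graph needs at least two stages (no flows otherwise)")
    scale = trajectories.scale
    states = scale.all_states
    nodes = {(st, s): 0 for st in trajectories.stages for s in states}
    links: dict[tuple[int, str, str], int] = {}
    for row in trajectories.states:
        for st, s in zip(trajectories.stages, row):
            nodes[(st, s)] += 1
        for i, (a, b) in enumerate(zip(row, row[1:])):
            links[(i, a, b)] = links.get((i, a, b), 0) + 1
    return FlowGraph(
        stages=trajectories.stages,
        states=states,
        node_counts=nodes,
        link_counts=links,
        total=trajectories.n_patients,
    )


def _palette(scale: SeverityScale) -> dict[str, tuple]:
    cmap = plt.get_cmap("viridis")
    n = max(len(scale.levels) - 1, 1)
    colors = {lv: cmap(i / n) for i, lv in enumerate(scale.levels)}
    colors[scale.missing_level] = _MISSING_COLOR
    return colors


def _sigmoid_band(x0, x1, ytop0, ytop1, ybot0, ybot1, npts=40):
    """Vertices of a smooth band between two node edges (smoothstep blend)."""
    t = np.linspace(0.0, 1.0, npts)
    s = t * t * (3.0 - 2.0 * t)
    x = x0 + (x1 - x0) * t
    top = ytop0 + (ytop1 - ytop0) * s
    bot = ybot0 + (ybot1 - ybot0) * s
    xs = np.concatenate([x, x[::-1]])
    ys = np.concatenate([top, bot[::-1]])
    return np.column_stack([xs, ys])


def render_sankey(
    graph: FlowGraph,
    scale: SeverityScale,
    title: str = "",
    out=None,
    format: str = "svg",
) -> Path:
    """Render a flow graph as an alluvial/Sankey figure.

    Within each stage, nodes are stacked most-severe at the top down to
    least severe, with the missing/off-treatment category pinned last;
    zero-count nodes are omitted entirely (no zero-height artifacts).
    Band colour follows the source node. Colours are assigned
    deterministically by level index.

    ``format`` is one of ``svg`` (canonical, byte-deterministic), ``png``
    or ``html`` (the SVG wrapped in a standalone page).
    """
    if format not in RENDER_FORMATS:
        raise ValueError(f"unsupported format {format!r}; expected one of {RENDER_FORMATS}")
    if graph.total <= 0:
        raise ValueError("cannot render a zero-count graph")
    if out is None:
        raise ValueError("an output path is required")
    out = Path(out)

    order = [s for s in scale.display_order if s in graph.states]
    colors = _palette(scale)
    nstage = len(graph.stages)
    node_w = 0.22
    gap = 0.02

    # node layout: (stage_index, state) -> (ytop, ybot); heights are
    # fractions of the cohort, stacked from y=1 downwards
    geom: dict[tuple[int, str], tuple[float, float]] = {}
    for i, st in enumerate(graph.stages):
        y = 1.0
        for s in order:
            c = graph.node(st, s)
            if c == 0:
                continue
            h = c / graph.total
            geom[(i, s)] = (y, y - h)
            y -= h + gap

    with plt.rc_context(
        {"svg.hashsalt": "toxflow", "svg.fonttype": "none", "font.family": "DejaVu Sans"}
    ):
        fig, ax = plt.subplots(figsize=(max(1.6 * nstage, 6.0), 5.0))
        # bands first so nodes overprint their edges
        for i in range(nstage - 1):
            # running offsets measured from each node's top edge
            out_off = {s: 0.0 for s in order}
            in_off = {s: 0.0 for s in order}
            for a in order:
                if (i, a) not in geom:
                    continue
                for b in order:
                    c = graph.link(i, a, b)
                    if c == 0 or (i + 1, b) not in geom:
                        continue
                    h = c / graph.total
                    atop = geom[(i, a)][0] - out_off[a]
                    btop = geom[(i + 1, b)][0] - in_off[b]
                    out_off[a] += h
                    in_off[b] += h
                    verts = _sigmoid_band(
                        i + node_w, i + 1.0, atop, btop, atop - h, btop - h
                    )
                    poly = plt.Polygon(
                        verts, closed=True, facecolor=colors[a], edgecolor="none", alpha=0.45
                    )
                    poly.set_gid(f"link-{i}-{a}-{b}")
                    ax.add_patch(poly)
        for (i, s), (ytop, ybot) in sorted(geom.items()):
            rect = Rectangle(
                (i, ybot), node_w, ytop - ybot, facecolor=colors[s], edgecolor="white",
                linewidth=0.5,
            )
            rect.set_gid(f"node-{graph.stages[i]}-{s}")
            ax.add_patch(rect)
        ax.set_xlim(-0.3, nstage - 1 + node_w + 0.3)
        ax.set_ylim(-0.25, 1.05)
        ax.set_xticks([i + node_w / 2 for i in range(nstage)])
        ax.set_xticklabels(graph.stages)
        ax.set_yticks([])
        for side in ("top", "right", "left", "bottom"):
            ax.spines[side].set_visible(False)
        present = [s for s in order if any(graph.node(st, s) for st in graph.stages)]
        handles = [
            Rectangle((0, 0), 1, 1, facecolor=colors[s], edgecolor="none") for s in present
        ]
        ax.legend(
            handles, present, loc="upper center", bbox_to_anchor=(0.5, -0.08),
            ncol=min(len(present), 7), frameon=False, fontsize=8,
        )
        if title:
            ax.set_title(title)
        fig.tight_layout()
        try:
            if format == "png":
                fig.savefig(out, format="png", dpi=150)
            else:
                svg_target = out if format == "svg" else None
                import io

                buf = io.StringIO()
                fig.savefig(buf, format="svg", metadata={"Date": None})
                svg = buf.getvalue()
                if format == "svg":
                    out.write_text(svg, encoding="utf-8")
                else:  # html
                    out.write_text(
                        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
                        f"<title>{title or 'Sankey'}</title></head>\n<body>\n"
                        + svg
                        + "\n</body></html>\n",
                        encoding="utf-8",
                    )
        finally:
            plt.close(fig)
    return out
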