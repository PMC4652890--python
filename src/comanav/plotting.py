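"""Static top-view figures of arenas and trajectories."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .environments import Environment
from .simulate import Trajectory

_OUTCOME_COLORS = {"goal": "tab:green", "crash": "black",
                   "timeout": "tab:gray"}


def plot_top_view(
    env: Environment,
    trajectories: list[Trajectory] | None = None,
    path: str | None = None,
    color_by: str = "outcome",
):
    """Arena seen from above, with obstacles, goal and trajectories.

    ``color_by`` is ``"outcome"`` (goal/crash/timeout) or ``"index"`` (one
    color per trajectory, e.g. to show route membership).  Saves a PNG when
    ``path`` is given; returns the matplotlib figure either way.
    """
    fig, ax = plt.subplots(figsize=(6, 6 * env.depth / env.width))
    if env.walls:
        ax.add_patch(Rectangle((0, 0), env.width, env.depth, fill=False,
                               linewidth=2, edgecolor="black"))
    for ob in env.obstacles:
        h = ob.base_edge / 2.0
        ax.add_patch(Rectangle((ob.center[0] - h, ob.center[1] - h),
                               ob.base_edge, ob.base_edge, color="black"))
    if env.goal is not None:
        ax.plot(*env.goal, "o", color="tab:green", markersize=10, zorder=5)

    for i, tr in enumerate(trajectories or []):
        if color_by == "index":
            color = plt.cm.tab20(i % 20)
        else:
            color = _OUTCOME_COLORS.get(tr.outcome, "tab:blue")
        ax.plot(tr.x, tr.y, color=color, linewidth=0.8)
        ax.plot(tr.x[0], tr.y[0], ".", color=color, markersize=6)

    ax.set_xlim(-0.05 * env.width, 1.05 * env.width)
    ax.set_ylim(-0.05 * env.depth, 1.05 * env.depth)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
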