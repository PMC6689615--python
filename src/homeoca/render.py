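"""Snapshot rendering: proliferative red, quiescent grey, vacant white."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.colors import BoundaryNorm, ListedColormap

#: colour order corresponds to states -1 (quiescent), 0 (vacant), 1 (proliferative)
STATE_CMAP = ListedColormap(["#9e9e9e", "#ffffff", "#d62728"])
STATE_NORM = BoundaryNorm([-1.5, -0.5, 0.5, 1.5], STATE_CMAP.N)


def render_frame(grid, ax=None):
    """Draw one lattice with the standard colour convention."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(grid, cmap=STATE_CMAP, norm=STATE_NORM, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def render_animation(snapshots, out: str | Path, fps: int = 10) -> list[Path]:
    """Render snapshots to an animated GIF, or to per-frame PNG stills.

    ``snapshots`` is a sequence of ``(t, grid)`` pairs.  If ``out`` ends
    in ``.gif`` an animation is attempted; on failure (or for any other
    suffix) the function degrades to one PNG per frame next to ``out``.
    Returns the list of files written.
    """
    snapshots = list(snapshots)
    if not snapshots:
        raise ValueError("no snapshots to render")
    out = Path(out)
    if out.suffix == ".gif":
        try:
            from matplotlib.animation import FuncAnimation, PillowWriter

            fig, ax = plt.subplots(figsize=(4, 4))
            im = ax.imshow(snapshots[0][1], cmap=STATE_CMAP, norm=STATE_NORM,
                           interpolation="nearest")
            ax.set_xticks([])
            ax.set_yticks([])
            title = ax.set_title(f"t = {snapshots[0][0]}")

            def update(k):
                im.set_data(snapshots[k][1])
                title.set_text(f"t = {snapshots[k][0]}")
                return [im, title]

            anim = FuncAnimation(fig, update, frames=len(snapshots))
            anim.save(out, writer=PillowWriter(fps=fps))
            plt.close(fig)
            return [out]
        except Exception:
            pass  # fall through to stills
    out.parent.mkdir(parents=True, exist_ok=True)
    written = []
    stem = out.stem if out.suffix else out.name
    for t, grid in snapshots:
        fig, ax = plt.subplots(figsize=(4, 4))
        render_frame(grid, ax)
        ax.set_title(f"t = {t}")
        frame_path = out.parent / f"{stem}_t{t:06d}.png"
        fig.savefig(frame_path, dpi=120)
        plt.close(fig)
        written.append(frame_path)
    return written
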