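"""Optional PNG export of trajectories and Lyapunov traces.

Matplotlib is imported lazily; nothing else in the package depends on this
module, and no test does either.
"""

from __future__ import annotations

from .ffsolver import Trajectory
from .lyapunov import LyapunovTrace

__all__ = ["plot_trajectory", "plot_lyapunov_trace"]


def plot_trajectory(traj: Trajectory, path, *, title: str | None = None) -> None:
    """Healthy and malignant proportions over time, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(traj.times, traj.x1, label="healthy cells $x_1$")
    ax.plot(traj.times, traj.x2, label="malignant cells $x_2$")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cell proportion")
    if title is None:
        title = str(traj.meta.get("patient", traj.meta.get("scheme", "")))
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lyapunov_trace(trace: LyapunovTrace, path) -> None:
    """L and the Upsilon dissipation balance over time, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    ax1.plot(trace.times, trace.L)
    ax1.set_ylabel("L")
    ax2.plot(trace.times, trace.upsilon1, label=r"$\Upsilon_1$")
    ax2.plot(trace.times, trace.upsilon2, label=r"$\Upsilon_2$")
    ax2.set_yscale("log")
    ax2.set_xlabel("time (h)")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
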