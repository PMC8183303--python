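"""Report figures: recognition rates, reaction times, amplitudes, profiles."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .stimulus import CHANGE_TYPES


def _ordered(rows: list[dict]) -> list[dict]:
    by_type = {r["change_type"]: r for r in rows}
    return [by_type[t] for t in CHANGE_TYPES if t in by_type]


def plot_recognition_rates(report: dict, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rows = _ordered(report["cohort_summary"])
    ax.bar([r["change_type"] for r in rows], [r["detection_rate"] for r in rows], color="C0")
    ax.set_ylabel("recognition rate")
    ax.set_ylim(0, 1)
    return ax


def plot_reaction_times(report: dict, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rows = _ordered(report["cohort_summary"])
    x = np.arange(len(rows))
    ax.bar(x - 0.2, [r["mean_key_rt_s"] for r in rows], width=0.4, label="keypress")
    ax.bar(x + 0.2, [r["mean_gaze_rt_s"] for r in rows], width=0.4, label="gaze")
    ax.set_xticks(x, [r["change_type"] for r in rows])
    ax.set_ylabel("mean reaction time (s)")
    ax.legend()
    return ax


def plot_amplitudes(report: dict, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rows = _ordered(report["cohort_summary"])
    x = np.arange(len(rows))
    ax.bar(x - 0.2, [r["mean_amp_deg"] for r in rows], width=0.4, label="mean")
    ax.bar(x + 0.2, [r["max_amp_deg"] for r in rows], width=0.4, label="max")
    ax.set_xticks(x, [r["change_type"] for r in rows])
    ax.set_ylabel("saccade amplitude toward feature (deg)")
    ax.legend()
    return ax


def plot_profiles(report: dict, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    e = np.linspace(0, 75, 300)
    for k, ctype in enumerate(CHANGE_TYPES):
        fit = report["profile_fits"].get(ctype, {})
        if "amplitude" not in fit:
            continue
        p = fit["amplitude"] * np.exp(-(e**2) / (2 * fit["sigma_deg"] ** 2))
        ax.plot(e, p, color=f"C{k}", label=f"{ctype} (A={fit['amplitude']:.2f}, "
                                           f"s={fit['sigma_deg']:.0f} deg)")
    ax.set_xlabel("eccentricity (deg)")
    ax.set_ylabel("perception probability")
    ax.legend()
    return ax


def render_report_plots(report: dict, out_dir) -> list[Path]:
    """Render all four report figures as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, fn in [
        ("recognition_rates", plot_recognition_rates),
        ("reaction_times", plot_reaction_times),
        ("amplitudes", plot_amplitudes),
        ("profiles", plot_profiles),
    ]:
        fig, ax = plt.subplots(figsize=(5, 4))
        fn(report, ax)
        fig.tight_layout()
        path = out / f"{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
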