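"""Matplotlib figures: KM step curves and WI group strip plots."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .survival import KmCurve, SurvivalRecord, km_estimate


def _ensure_agg():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_km(groups: Mapping[str, Sequence[SurvivalRecord]], path,
            title: str = "Distant disease-free survival") -> None:
    """Kaplan-Meier step curves, one per group, with events/n in the legend."""
    plt = _ensure_agg()
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, recs in groups.items():
        curve: KmCurve = km_estimate(recs)
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        events = sum(r.event for r in recs)
        ax.step(t, s, where="post", label=f"{label} ({events}/{len(recs)})")
    ax.set_xlabel("years from start of chemotherapy")
    ax.set_ylabel("DDFS probability")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_wi_groups(values_by_group: Mapping[str, Sequence[float]], path,
                   title: str = "Washout index by response group") -> None:
    """Jittered strip plot of WI per group with mean +/- SD bars."""
    plt = _ensure_agg()
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, (label, vals) in enumerate(values_by_group.items()):
        vals = np.asarray(list(vals), dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            continue
        x = i + rng.uniform(-0.12, 0.12, size=len(vals))
        ax.plot(x, vals, "o", ms=3, alpha=0.5)
        ax.errorbar(
            [i], [vals.mean()],
            yerr=[vals.std(ddof=1)] if len(vals) > 1 else None,
            fmt="_", color="black", capsize=6, ms=20,
        )
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(range(len(values_by_group)), list(values_by_group))
    ax.set_ylabel("washout index (%)")
    ax.set_title(title)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
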