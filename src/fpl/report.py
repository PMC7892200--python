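"""Static figures and a summary document for a completed results bundle."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

log = logging.getLogger("fpl")

_CONDITION_STYLE = {-200.0: "-", 200.0: ":", -50.0: "--", 50.0: "-."}


def make_report(bundle, out: Path) -> list[Path]:
    out = Path(out)
    figdir = out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    if bundle.group_tc is not None:
        files.append(_fig_timecourses(bundle.group_tc,
                                      figdir / "timecourses.png"))
        files.append(_fig_violins(bundle.comp, figdir / "violins.png"))
    if bundle.comp is not None:
        files.append(_fig_mid_whole(bundle.comp, figdir / "mid_whole.png"))
    if bundle.adaptation_records is not None:
        files.append(_fig_adaptation(bundle.adaptation_records,
                                     figdir / "adaptation.png"))
        if bundle.comp is not None:
            files.append(_fig_comp_adapt(bundle, figdir / "comp_adapt.png"))
    if bundle.dynamics_timecourses is not None:
        files.append(_fig_dynamics(bundle, figdir / "dynamics.png"))
    else:
        log.info("report: dynamics figure skipped (no responder data)")
    files.append(_summary(bundle, out / "summary.md"))
    return files


def _fig_timecourses(group_tc: pd.DataFrame, path: Path) -> Path:
    kinds = sorted(group_tc.pert_kind.unique())
    fig, axes = plt.subplots(1, len(kinds), figsize=(5 * len(kinds), 3.5),
                             squeeze=False)
    for ax, kind in zip(axes[0], kinds):
        for p, g in group_tc[group_tc.pert_kind == kind].groupby("pert_hz"):
            g = g.sort_values("bin_start_ms")
            style = _CONDITION_STYLE.get(p, "-")
            ax.plot(g.bin_start_ms, g.mean_hz, style, label=f"{p:+g} Hz")
            ax.fill_between(g.bin_start_ms, g.mean_hz - g.sem_hz,
                            g.mean_hz + g.sem_hz, alpha=0.25)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("time from perturbation onset (ms)")
        ax.set_ylabel("normalized F1 (Hz)")
        ax.set_title(kind.replace("_", " "))
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _fig_violins(comp: pd.DataFrame, path: Path) -> Path:
    kinds = sorted(comp.pert_kind.unique())
    fig, axes = plt.subplots(1, len(kinds), figsize=(5 * len(kinds), 3.5),
                             squeeze=False)
    for ax, kind in zip(axes[0], kinds):
        sub = comp[comp.pert_kind == kind]
        mags = sorted(sub.pert_hz.unique())
        data = [sub.loc[sub.pert_hz == m, "peak_pct"].to_numpy()
                for m in mags]
        if len(data):
            ax.violinplot(data, showmedians=True)
            ax.set_xticks(range(1, len(mags) + 1),
                          [f"{m:+g}" for m in mags])
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("perturbation (Hz)")
        ax.set_ylabel("peak compensation (%)")
        ax.set_title(kind.replace("_", " "))
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _scatter_fit(ax, x, y):
    ax.scatter(x, y, s=18, alpha=0.7)
    if len(x) > 2 and np.ptp(x) > 0:
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(min(x), max(x), 20)
        ax.plot(xs, a + b * xs, "k-")
    ax.axhline(0, ls="--", color="gray", lw=0.5)
    ax.axvline(0, ls="--", color="gray", lw=0.5)


def _fig_mid_whole(comp: pd.DataFrame, path: Path) -> Path:
    wide = comp.pivot_table(index=["participant_id", "pert_hz"],
                            columns="pert_kind",
                            values="peak_pct").reset_index()
    fig, ax = plt.subplots(figsize=(4, 4))
    if {"mid_utterance", "whole_utterance"} <= set(wide.columns):
        _scatter_fit(ax, wide["mid_utterance"].to_numpy(),
                     wide["whole_utterance"].to_numpy())
    ax.set_xlabel("mid-utterance compensation (%)")
    ax.set_ylabel("whole-utterance compensation (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _fig_adaptation(records, path: Path) -> Path:
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5),
                                   gridspec_kw={"width_ratios": [2, 1]})
    rows = pd.concat([
        pd.DataFrame({"direction": r.direction,
                      "window_index": np.arange(1, len(r.smoothed_hz) + 1),
                      "normalized_hz": r.smoothed_hz})
        for r in records], ignore_index=True)
    for d, g in rows.groupby("direction"):
        agg = g.groupby("window_index")["normalized_hz"].agg(["mean", "sem"])
        ax1.plot(agg.index, agg["mean"], marker="o" if d < 0 else "D",
                 ms=3, label=f"{d:+g} Hz")
        ax1.fill_between(agg.index, agg["mean"] - agg["sem"],
                         agg["mean"] + agg["sem"], alpha=0.25)
    ax1.axhline(0, color="k", lw=0.5)
    ax1.set_xlabel("five-trial window")
    ax1.set_ylabel("normalized early F1 (Hz)")
    ax1.legend(fontsize=8)
    pct = pd.DataFrame([{"direction": r.direction, "pct": r.adaptation_pct}
                        for r in records])
    dirs = sorted(pct.direction.unique())
    ax2.violinplot([pct.loc[pct.direction == d, "pct"] for d in dirs],
                   showmedians=True)
    ax2.set_xticks(range(1, len(dirs) + 1), [f"{d:+g}" for d in dirs])
    ax2.axhline(0, color="k", lw=0.5)
    ax2.set_ylabel("adaptation (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _fig_comp_adapt(bundle, path: Path) -> Path:
    from .adaptation import records_frame
    adapt = records_frame(bundle.adaptation_records)
    merged = adapt.merge(bundle.comp, left_on=["participant_id", "direction"],
                         right_on=["participant_id", "pert_hz"])
    kinds = sorted(merged.pert_kind.unique())
    fig, axes = plt.subplots(1, max(len(kinds), 1), figsize=(4 * len(kinds), 4),
                             squeeze=False)
    for ax, kind in zip(axes[0], kinds):
        sub = merged[merged.pert_kind == kind]
        _scatter_fit(ax, sub.peak_pct.to_numpy(),
                     sub.adaptation_pct.to_numpy())
        ax.set_xlabel(f"{kind.replace('_', ' ')} compensation (%)")
        ax.set_ylabel("adaptation (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _fig_dynamics(bundle, path: Path) -> Path:
    tc = bundle.dynamics_timecourses
    wm = bundle.dynamics_window_means
    dirs = sorted(tc.direction.unique())
    fig, axes = plt.subplots(2, len(dirs), figsize=(5 * len(dirs), 6),
                             squeeze=False)
    for j, d in enumerate(dirs):
        ax = axes[0][j]
        sub = tc[tc.direction == d]
        for phase, g in sub.groupby("phase"):
            agg = g.groupby("time_ms")["value_hz"].agg(["mean", "sem"])
            ax.plot(agg.index, agg["mean"], label=phase, lw=1)
            ax.fill_between(agg.index, agg["mean"] - agg["sem"],
                            agg["mean"] + agg["sem"], alpha=0.2)
        ax.set_title(f"{d:+g} Hz")
        ax.set_xlabel("time from voice onset (ms)")
        ax.set_ylabel("normalized F1 (Hz)")
        ax.legend(fontsize=7)
        ax = axes[1][j]
        sub = wm[wm.direction == d]
        phases = [p for p in ("late_baseline", "early_adapt", "late_adapt",
                              "late_washout") if p in set(sub.phase)]
        for k, window in enumerate(("O", "M")):
            data = [sub[(sub.phase == p) & (sub.window == window)].pct
                    for p in phases]
            pos = np.arange(len(phases)) + (k - 0.5) * 0.3
            ax.boxplot(data, positions=pos, widths=0.25)
        ax.set_xticks(range(len(phases)), phases, rotation=20, fontsize=7)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("compensation (%) [O left, M right]")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _summary(bundle, path: Path) -> Path:
    lines = ["# Run summary", ""]
    if bundle.screening_report is not None:
        pct = bundle.screening_report.pct_excluded.mean()
        lines += [f"Mean head-trial exclusion rate: {pct:.2f}%", ""]
    if bundle.comp_summary is not None:
        lines += ["## Peak compensation by condition", "",
                  bundle.comp_summary.to_markdown(index=False), ""]
    if bundle.latencies is not None:
        lines += ["## Group latencies", "",
                  bundle.latencies.to_markdown(index=False), ""]
    if bundle.adaptation_summary is not None:
        lines += ["## Sensorimotor adaptation", "",
                  bundle.adaptation_summary.to_markdown(index=False), ""]
    if bundle.responders:
        for d, pids in bundle.responders.items():
            lines.append(f"Positive responders {d:+g} Hz: {len(pids)}")
        lines.append("")
    for name, res in bundle.models.items():
        lines.append(f"- model `{name}` written to models/{name}.json")
    path.write_text("\n".join(lines))
    return path
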