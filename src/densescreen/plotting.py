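"""Minimal plots: tornado diagram, CEAC, cost-effectiveness plane."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def tornado_plot(tornado: pd.DataFrame, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(tornado) + 1))
    base = tornado.attrs.get("base_icer")
    df = tornado.sort_values("width")
    y = range(len(df))
    lo = df[["icer_low", "icer_high"]].min(axis=1)
    hi = df[["icer_low", "icer_high"]].max(axis=1)
    ax.barh(y, hi - lo, left=lo, color="#4878a8")
    ax.set_yticks(list(y), df["parameter"])
    if base is not None:
        ax.axvline(base, color="k", lw=1, ls="--")
    ax.set_xlabel("ICER (k€/LYG)")
    return ax


def ceac_plot(ceac: pd.DataFrame, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(ceac["lambda"], ceac["probability"], marker="o", ms=3)
    ax.set_xlabel("Willingness to pay (€/LYG)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    return ax


def ce_plane(psa: pd.DataFrame, threshold: float = 20_000.0, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    nmb = threshold * psa["delta_effect"] - psa["delta_cost"]
    colors = ["#2b6cb0" if v > 0 else "#a8c4e0" for v in nmb]
    ax.scatter(psa["delta_effect"], psa["delta_cost"] / 1000.0, s=8, c=colors)
    ax.axline((0, 0), slope=threshold / 1000.0, color="r", ls="--", lw=1)
    ax.set_xlabel("Incremental life-years (per 10,000)")
    ax.set_ylabel("Incremental cost (k€ per 10,000)")
    return ax
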