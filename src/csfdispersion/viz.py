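"""Plot helpers: spatial-temporal heatmaps, SD maps, Bland-Altman, AUC."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .quantify import AUCProfile, SpatioTemporalMap  # noqa: E402
from .stats import BlandAltman  # noqa: E402

#: isoconcentration contour levels drawn on spatial-temporal maps, uM
CONTOUR_LEVELS_UM = (1.0, 5.0, 10.0, 30.0, 40.0)


def plot_spatiotemporal(stmap: SpatioTemporalMap, path, title: str = "",
                        contours: bool = True) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    t_h = stmap.t_frames / 3600.0
    mesh = ax.pcolormesh(t_h, stmap.z_centers, stmap.c, cmap="viridis", shading="auto")
    if contours and stmap.c.max() > min(CONTOUR_LEVELS_UM):
        levels = [lv for lv in CONTOUR_LEVELS_UM if lv < stmap.c.max()]
        ax.contour(t_h, stmap.z_centers, stmap.c, levels=levels,
                   colors="w", linewidths=0.6, linestyles="--")
    ax.axhline(0.0, color="r", lw=0.8)  # foramen magnum
    ax.set_xlabel("time post injection (h)")
    ax.set_ylabel("z (mm, 0 = foramen magnum)")
    ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="concentration (uM)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sd_map(z, t_s, sd_map, path, title: str = "repetition SD") -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    mesh = ax.pcolormesh(np.asarray(t_s) / 3600.0, z, sd_map, cmap="magma",
                         shading="auto")
    ax.set_xlabel("time post injection (h)")
    ax.set_ylabel("z (mm)")
    ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="SD (uM)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bland_altman(ba: BlandAltman, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for rep in range(ba.differences.shape[0]):
        ax.plot(ba.mean_values, ba.differences[rep], ".", ms=2, alpha=0.4,
                label=f"rep {rep + 1}")
    ax.axhline(ba.mean_difference, color="k", lw=1)
    for lim in ba.limits:
        ax.axhline(lim, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of repetitions (uM)")
    ax.set_ylabel("difference from mean (uM)")
    ax.set_title(title)
    ax.legend(markerscale=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_auc_profiles(profiles: dict[str, AUCProfile], path,
                      title: str = "AUC profiles") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        ax.plot(prof.z_centers, prof.auc, lw=1, label=label)
    ax.axvline(0.0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("z (mm, 0 = foramen magnum)")
    ax.set_ylabel("AUC (uM*hr)")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
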