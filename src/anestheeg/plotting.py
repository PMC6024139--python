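"""Figure helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohortspec import AgeVaryingSpectrogram


def plot_age_varying_spectrograms(
    specs: dict[str, AgeVaryingSpectrogram],
    path: str | Path,
    f_max: float = 40.0,
    vmin: float = -10.0,
    vmax: float = 25.0,
) -> None:
    """Two-panel (NT, ASD) age-by-frequency power image in dB."""
    fig, axes = plt.subplots(1, len(specs), figsize=(6 * len(specs), 4),
                             sharey=True, constrained_layout=True)
    axes = np.atleast_1d(axes)
    for ax, (label, spec) in zip(axes, specs.items()):
        fmask = spec.freqs <= f_max
        im = ax.pcolormesh(spec.age_grid, spec.freqs[fmask],
                           spec.power_db[:, fmask].T,
                           vmin=vmin, vmax=vmax, shading="nearest",
                           cmap="jet")
        ax.set_xlabel("age (years)")
        ax.set_title(f"{label} (n per bin: median "
                     f"{int(np.median(spec.n_subjects_per_bin))})")
    axes[0].set_ylabel("frequency (Hz)")
    fig.colorbar(im, ax=axes, label="power (dB)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
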