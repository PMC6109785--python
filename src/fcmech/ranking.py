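"""Global FC (gFC) index and network-alteration ranking.

For each network and contrast the gFC score sums |t| over the
FWE-significant voxels inside the network's spatial extent, so both the
extent of significant clusters (through the voxel count) and the magnitude
of the FC change (through |t|) enter the score.  The exact functional form
is this package's interpretation of that extent-and-magnitude property and
is exposed as a pluggable scoring hook.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .containers import StatMap

__all__ = ["compute_gfc", "rank_networks", "plot_gfc"]


def _gfc_abs_t_sum(t: np.ndarray, sig: np.ndarray) -> float:
    return float(np.abs(t[sig]).sum())


def compute_gfc(
    stat: StatMap,
    rsn_mask: np.ndarray,
    alpha: float = 0.05,
    score: Callable = _gfc_abs_t_sum,
) -> tuple[float, int]:
    """gFC score and significant-voxel count of one network/contrast."""
    rsn_mask = np.asarray(rsn_mask, dtype=bool)
    if (rsn_mask & ~stat.mask).any():
        raise ValueError("rsn_mask must lie within the analysis mask")
    sig = stat.sig_mask(alpha) & rsn_mask
    n = int(sig.sum())
    return (score(stat.t, sig) if n else 0.0), n


def rank_networks(
    stats: list[StatMap],
    atlas: dict,
    alpha: float = 0.05,
    score: Callable = _gfc_abs_t_sum,
) -> pd.DataFrame:
    """Ranked gFC table over (network, contrast) pairs.

    ``atlas`` maps component/network name to its 3D boolean extent.  The
    table is sorted by descending gFC within each contrast, ties broken
    alphabetically by network name.
    """
    seen = set()
    rows = []
    for stat in stats:
        key = (stat.component, stat.contrast_name)
        if key in seen:
            raise ValueError(f"duplicate (component, contrast) pair {key}")
        seen.add(key)
        gfc, n_sig = compute_gfc(stat, atlas[stat.component], alpha, score)
        rows.append(
            {
                "network": stat.component,
                "contrast": stat.contrast_name,
                "gfc": gfc,
                "n_sig_voxels": n_sig,
            }
        )
    table = pd.DataFrame(rows)
    return (
        table.sort_values(
            ["contrast", "gfc", "network"], ascending=[True, False, True]
        ).reset_index(drop=True)
    )


def plot_gfc(table: pd.DataFrame, path: str) -> None:
    """Horizontal bar chart of gFC per network, one panel per contrast."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    contrasts = list(table["contrast"].unique())
    fig, axes = plt.subplots(
        1, max(len(contrasts), 1), figsize=(5 * max(len(contrasts), 1), 4), squeeze=False
    )
    for ax, con in zip(axes[0], contrasts):
        sub = table[table["contrast"] == con].iloc[::-1]
        ax.barh(sub["network"], sub["gfc"])
        ax.set_title(con)
        ax.set_xlabel("gFC")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
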