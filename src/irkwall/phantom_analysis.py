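"""Displacement-sensitivity ratios for the cavity phantom.

Post-processes dose profiles from three source placements (central
axis, and the two cavity-surface points A/B on the monitoring diameter)
into the ratio table quantifying how far the delivered dose departs
from the plan when the source drifts inside the cavity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transport import DoseProfile


@dataclass(frozen=True)
class RatioTable:
    distances: np.ndarray  # cm
    ratio_A_over_central: np.ndarray
    ratio_B_over_central: np.ndarray
    ratio_A_over_B: np.ndarray
    rel_std_err_A_over_central: np.ndarray
    rel_std_err_B_over_central: np.ndarray
    rel_std_err_A_over_B: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_cm": self.distances,
                "A_over_central": self.ratio_A_over_central,
                "B_over_central": self.ratio_B_over_central,
                "A_over_B": self.ratio_A_over_B,
                "rel_std_err_A_over_central": self.rel_std_err_A_over_central,
                "rel_std_err_B_over_central": self.rel_std_err_B_over_central,
                "rel_std_err_A_over_B": self.rel_std_err_A_over_B,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def dose_ratio_table(
    central: DoseProfile, at_A: DoseProfile, at_B: DoseProfile
) -> RatioTable:
    """Elementwise dose ratios with uncorrelated error propagation.

    The A/B column is the exact quotient of the other two at every
    distance (the profiles share the central denominator)."""
    if (
        central.distances.shape != at_A.distances.shape
        or central.distances.shape != at_B.distances.shape
        or not np.allclose(central.distances, at_A.distances)
        or not np.allclose(central.distances, at_B.distances)
    ):
        raise ValueError("profiles are on different distance grids")
    if np.any(central.dose_per_history <= 0) or np.any(at_B.dose_per_history <= 0):
        raise ValueError("zero dose in a ratio denominator")
    a_c = at_A.dose_per_history / central.dose_per_history
    b_c = at_B.dose_per_history / central.dose_per_history
    se_ac = np.sqrt(at_A.rel_std_err**2 + central.rel_std_err**2)
    se_bc = np.sqrt(at_B.rel_std_err**2 + central.rel_std_err**2)
    se_ab = np.sqrt(at_A.rel_std_err**2 + at_B.rel_std_err**2)
    return RatioTable(
        distances=central.distances.copy(),
        ratio_A_over_central=a_c,
        ratio_B_over_central=b_c,
        ratio_A_over_B=a_c / b_c,
        rel_std_err_A_over_central=se_ac,
        rel_std_err_B_over_central=se_bc,
        rel_std_err_A_over_B=se_ab,
    )


def surface_to_center_ratio(
    profile: DoseProfile, center_cm: float = 1.25, surface_cm: float = 9.75
) -> float:
    """dose(surface cube)/dose(innermost cube).

    'Phantom centre' is read as the innermost monitoring cube — no
    scoring volume exists inside the air cavity itself."""
    return profile.dose_at(surface_cm) / profile.dose_at(center_cm)


def plot_profiles(profiles, path=None, ax=None):
    """Relative dose vs distance on a log scale, one curve per source
    position (the companion figure to the ratio table)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for profile in profiles:
        ref = profile.dose_per_history.max()
        ax.semilogy(
            profile.distances,
            profile.dose_per_history / ref,
            marker="o",
            label=profile.source_position,
        )
    ax.set_xlabel("distance from cavity axis (cm)")
    ax.set_ylabel("relative dose")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
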