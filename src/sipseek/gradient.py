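"""Buoyant-density gradient analysis.

After isopycnic CsCl centrifugation a DNA extract is collected as an ordered
series of fractions, densest first.  DNA from cells that assimilated a
``13C`` substrate equilibrates at a higher buoyant density than unlabelled
DNA, so comparing the per-fraction gene abundance profile of a ``13C``
incubation against its ``12C`` control reveals whether labeling occurred and
which fractions carry the labelled ("heavy") DNA.

Fractions are numbered from 1 (densest).  The default 14-fraction gradient
places the heavy window (1.740-1.748 g/mL) on fractions 4-6 and the light
window (1.719-1.728 g/mL) on fractions 8-10.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Buoyant density (g/mL) of each of the 14 default gradient fractions,
#: densest first.  Piecewise-linear, anchored so that fractions 4-6 cover the
#: heavy window 1.740-1.748 g/mL and fractions 8-10 the light window
#: 1.719-1.728 g/mL.
DEFAULT_DENSITIES: tuple[float, ...] = (
    1.7600, 1.7560, 1.7520,          # 1-3: above the heavy window
    1.7480, 1.7440, 1.7400,          # 4-6: heavy (13C-labelled) window
    1.7340,                          # 7: between windows
    1.7280, 1.7235, 1.7190,          # 8-10: light (unlabelled) window
    1.7145, 1.7100, 1.7055, 1.7010,  # 11-14: tail of the gradient
)

#: Default heavy / light density windows (g/mL).
HEAVY_WINDOW: tuple[float, float] = (1.740, 1.748)
LIGHT_WINDOW: tuple[float, float] = (1.719, 1.728)

#: Minimum abundance-weighted mean-density shift (g/mL) accepted as evidence
#: of isotope incorporation: about half the separation between the fully
#: labelled (1.744) and unlabelled (1.7235) density centres.
DEFAULT_MIN_SHIFT: float = 0.008


@dataclass
class FractionSet:
    """An ordered set of density-gradient fractions for one treatment.

    Parameters
    ----------
    densities : array of float
        Buoyant density (g/mL) per fraction, strictly decreasing.
    abundance : pandas.DataFrame
        Per-fraction gene abundance; one column per measured series (a qPCR
        gene target, or one column per genotype in simulated gradients).
        The index holds 1-based fraction numbers.
    treatment : str
        ``"13C"`` or ``"12C"``.
    """

    densities: np.ndarray
    abundance: pd.DataFrame
    treatment: str = "13C"

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if np.any(np.diff(self.densities) >= 0):
            raise ValueError("densities must strictly decrease with fraction index")
        if len(self.densities) != len(self.abundance):
            raise ValueError("densities and abundance must have equal length")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.treatment not in ("13C", "12C"):
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def fraction_index(self) -> np.ndarray:
        """1-based fraction numbers."""
        return np.asarray(self.abundance.index, dtype=int)

    def total(self) -> np.ndarray:
        """Total abundance per fraction, summed over series."""
        return self.abundance.to_numpy().sum(axis=1)

    def weighted_mean_density(self) -> float:
        """Abundance-weighted mean buoyant density (g/mL)."""
        w = self.total()
        if w.sum() <= 0:
            raise ValueError("cannot average an all-zero profile")
        return float(np.average(self.densities, weights=w))

    def modal_density(self) -> float:
        """Density of the fraction with the highest total abundance."""
        return float(self.densities[int(np.argmax(self.total()))])

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (fraction_index, density_g_per_ml, series, abundance)."""
        out = self.abundance.copy()
        out.insert(0, "density_g_per_ml", self.densities)
        out.index.name = "fraction_index"
        out["treatment"] = self.treatment
        return out.reset_index()


@dataclass
class HeavyCall:
    """Outcome of labeling detection on a 13C/12C profile pair."""

    heavy_fractions: tuple[int, ...]
    light_fractions: tuple[int, ...]
    labelled: bool
    shift: float  # weighted-mean density difference, g/mL
    min_shift: float = DEFAULT_MIN_SHIFT

    def __post_init__(self) -> None:
        if set(self.heavy_fractions) & set(self.light_fractions):
            raise ValueError("heavy and light fraction sets must be disjoint")


def normalize_profile(abundances) -> np.ndarray:
    """Scale a non-negative abundance series to its maximum.

    This is the standard presentation of gradient qPCR profiles: each
    treatment's series is divided by its own maximum so the peak is 1.

    Raises
    ------
    ValueError
        If the input has no positive value.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    m = a.max() if a.size else 0.0
    if m <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return a / m


def select_fraction_window(fractions: FractionSet, lo: float, hi: float) -> tuple[int, ...]:
    """Return the 1-based indices of fractions with density in [lo, hi].

    The interval is closed: a fraction whose density equals a bound is
    included.  An empty result is legal (a window outside the gradient) and
    only logs a warning.
    """
    if not lo < hi:
        raise ValueError("window requires lo < hi")
    mask = (fractions.densities >= lo) & (fractions.densities <= hi)
    idx = tuple(int(i) for i in fractions.fraction_index[mask])
    if not idx:
        logger.warning("density window [%g, %g] selects no fraction", lo, hi)
    return idx


def detect_labeling(
    profile_13c: FractionSet,
    profile_12c: FractionSet,
    min_shift: float = DEFAULT_MIN_SHIFT,
    heavy_window: tuple[float, float] = HEAVY_WINDOW,
    light_window: tuple[float, float] = LIGHT_WINDOW,
) -> HeavyCall:
    """Decide whether the 13C profile shows isotope incorporation.

    The shift statistic is the difference in abundance-weighted mean buoyant
    density between the 13C profile and the 12C control; it depends only on
    the shapes of the two profiles, not on their absolute scale.  Labeling is
    called when the shift reaches ``min_shift``, in which case the heavy
    fractions are those inside ``heavy_window``.
    """
    if not np.allclose(profile_13c.densities, profile_12c.densities):
        raise ValueError("13C and 12C profiles must share the same density grid")
    shift = profile_13c.weighted_mean_density() - profile_12c.weighted_mean_density()
    labelled = bool(shift >= min_shift)
    heavy = select_fraction_window(profile_13c, *heavy_window) if labelled else ()
    light = select_fraction_window(profile_12c, *light_window)
    return HeavyCall(
        heavy_fractions=heavy,
        light_fractions=light,
        labelled=labelled,
        shift=float(shift),
        min_shift=min_shift,
    )


def read_fraction_table(path, treatment: str | None = None) -> FractionSet:
    """Load a fraction table written by :meth:`FractionSet.to_frame` (TSV)."""
    df = pd.read_csv(path, sep="\t")
    if treatment is None:
        treatment = str(df["treatment"].iloc[0]) if "treatment" in df else "13C"
    df = df.set_index("fraction_index")
    dens = df.pop("density_g_per_ml").to_numpy()
    df = df.drop(columns=["treatment"], errors="ignore")
    return FractionSet(densities=dens, abundance=df, treatment=treatment)


def write_fraction_table(fractions: FractionSet, path) -> None:
    fractions.to_frame().to_csv(path, sep="\t", index=False)
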