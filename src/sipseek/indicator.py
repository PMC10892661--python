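"""Active methanotrophs, gas-indicator genotypes and the biotic index (BI).

The prospecting logic: genotypes abundant in the 13C-labelled heavy DNA
fractions of a soil are its *active* methanotrophs; genotypes active above
the gas reservoir but not in background soils are *gas indicators*; a
site's biotic index is the summed relative abundance of the indicator
genotypes in its in-situ pmoA profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sipseek.community import GenotypeProfile

logger = logging.getLogger(__name__)

#: Mean heavy-fraction relative abundance (percent of the methanotroph
#: community) above which a genotype counts as active.
DEFAULT_ACTIVITY_THRESHOLD = 5.0


@dataclass
class ActiveSet:
    """Genotypes called active in one scenario's heavy fractions."""

    scenario: str
    mean_abundance: dict[str, float]  # mean over heavy fractions, percent
    threshold: float

    @property
    def active(self) -> frozenset:
        return frozenset(g for g, v in self.mean_abundance.items()
                         if v >= self.threshold)


@dataclass
class BIResult:
    """Biotic index of one sample: summed indicator-genotype abundance."""

    sample_id: str
    bi: float                         # percent, 0-100
    indicators: frozenset

    def __post_init__(self) -> None:
        if not 0 <= self.bi <= 100 + 1e-9:
            raise ValueError("BI must lie in [0, 100]")


def _as_mapping(profile) -> dict[str, float]:
    return dict(getattr(profile, "abundances", profile))


def labeling_contrast(
    heavy_13c,
    heavy_12c_control,
    fold_threshold: float = 10.0,
    abs_threshold: float = 1.0,
) -> dict[str, bool]:
    """Flag genotypes whose heavy-fraction share demonstrates labeling.

    A genotype is labelled when its mean share across the 13C heavy
    fractions is at least ``fold_threshold`` times its share in the 12C
    control heavy fractions and at least ``abs_threshold`` percent in
    absolute terms — an operational version of the observation that control
    heavy fractions carry under 1% methanotrophs.

    Both arguments are sequences of profiles covering the same heavy
    fractions (or single profiles).
    """
    if heavy_12c_control is None:
        raise ValueError("a 12C control is required to call labeling")
    p13 = _mean_profiles(heavy_13c)
    p12 = _mean_profiles(heavy_12c_control)
    out = {}
    for g in set(p13) | set(p12):
        share13 = p13.get(g, 0.0)
        share12 = p12.get(g, 0.0)
        enriched = share13 >= fold_threshold * share12 if share12 > 0 else share13 > 0
        out[g] = bool(enriched and share13 >= abs_threshold)
    return out


def _mean_profiles(profiles) -> dict[str, float]:
    if isinstance(profiles, (GenotypeProfile, dict)):
        profiles = [profiles]
    profiles = [_as_mapping(p) for p in profiles]
    if not profiles:
        raise ValueError("no profiles given")
    keys = sorted({g for p in profiles for g in p})
    return {g: float(np.mean([p.get(g, 0.0) for p in profiles])) for g in keys}


def active_set(
    heavy_profiles,
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    scenario: str = "",
) -> ActiveSet:
    """Call active genotypes from per-fraction heavy profiles.

    The per-genotype abundance is the unweighted mean over the heavy
    fractions; a genotype is active when that mean reaches ``threshold``
    percent.
    """
    means = _mean_profiles(heavy_profiles)
    return ActiveSet(scenario=scenario, mean_abundance=means, threshold=threshold)


def select_indicators(gas: ActiveSet, background: ActiveSet) -> frozenset:
    """Gas-indicator genotypes: active above gas, not active in background."""
    if gas.threshold != background.threshold:
        raise ValueError("active sets must be computed at the same threshold")
    if not gas.active:
        raise ValueError("gas scenario has no active genotype; no indicator derivable")
    indicators = gas.active - background.active
    if not indicators:
        logger.warning("no discriminating taxa: gas and background active sets coincide")
    return indicators


def biotic_index(profile, indicators, sample_id: str = "") -> BIResult:
    """BI = summed relative abundance (percent) of the indicator genotypes.

    Genotypes absent from the profile contribute zero.  An empty indicator
    set yields BI 0 with a warning.
    """
    mapping = _as_mapping(profile)
    indicators = frozenset(indicators)
    if not indicators:
        logger.warning("empty indicator set: BI is 0 by definition")
    sid = sample_id or getattr(profile, "sample_id", "")
    bi = float(sum(mapping.get(g, 0.0) for g in indicators))
    return BIResult(sample_id=sid, bi=bi, indicators=indicators)


@dataclass
class ZoneContrast:
    """Per-zone BI summary and the gas/background fold difference."""

    summary: pd.DataFrame             # index: zone; columns: mean, min, max, n
    fold: float                       # mean(gas) / mean(background)
    infinite_fold: bool = False


def zone_contrast(bi_results, zones: dict[str, str],
                  gas_zone: str = "gas_field",
                  background_zone: str = "background") -> ZoneContrast:
    """Summarize site BI values per zone and their fold difference of means."""
    rows = []
    for r in bi_results:
        if r.sample_id not in zones:
            raise ValueError(f"no zone label for site {r.sample_id!r}")
        rows.append({"site_id": r.sample_id, "bi": r.bi, "zone": zones[r.sample_id]})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no BI results given")
    for z in (gas_zone, background_zone):
        if (df["zone"] == z).sum() < 1:
            raise ValueError(f"zone {z!r} has no site")
    summary = df.groupby("zone")["bi"].agg(["mean", "min", "max", "count"]).rename(
        columns={"count": "n"})
    bg_mean = float(summary.loc[background_zone, "mean"])
    gas_mean = float(summary.loc[gas_zone, "mean"])
    if bg_mean == 0:
        return ZoneContrast(summary=summary, fold=float("inf"), infinite_fold=True)
    return ZoneContrast(summary=summary, fold=gas_mean / bg_mean)
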