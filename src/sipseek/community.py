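"""Community profiles, diversity indices, qPCR quantification and group tests.

Relative abundances are kept on a 0-100 percent scale throughout.  Diversity
follows the Shannon-Wiener index in bits, H = -sum(p_i * log2 p_i) over the
methanotroph groups with p_i > 0 (proportions renormalized over the groups
present), evenness E = H / log2(S), and richness S the number of groups with
non-zero abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypeProfile:
    """Per-genotype relative abundance (percent) for one sample or fraction."""

    abundances: dict[str, float]
    sample_id: str = ""
    source: str = "in_situ"           # in_situ | heavy_fraction_k | light_fraction_k

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        if sum(self.abundances.values()) > 100 + 1e-6:
            raise ValueError("abundances must sum to at most 100")

    def __getitem__(self, genotype: str) -> float:
        return self.abundances.get(genotype, 0.0)

    def proportions(self, exclude: set[str] | None = None) -> dict[str, float]:
        """Abundances renormalized to proportions over the retained groups."""
        items = {g: v for g, v in self.abundances.items()
                 if v > 0 and (exclude is None or g not in exclude)}
        total = sum(items.values())
        if total <= 0:
            raise ValueError("profile has no positive abundance")
        return {g: v / total for g, v in items.items()}


@dataclass
class DiversityResult:
    """Shannon-Wiener diversity (bits), evenness, richness."""

    H: float
    E: float
    S: int

    @property
    def H_max(self) -> float:
        return float(np.log2(self.S))


def relative_abundance(counts: dict[str, int], sample_id: str = "",
                       source: str = "in_situ") -> GenotypeProfile:
    """Convert read counts to percent relative abundances (sum to 100)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must contain at least one read")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    return GenotypeProfile(
        abundances={g: 100.0 * c / total for g, c in counts.items()},
        sample_id=sample_id, source=source,
    )


def shannon(profile, exclude: set[str] | None = None) -> float:
    """Shannon-Wiener index H in bits over the groups with p_i > 0.

    Proportions are renormalized over the retained groups, so a profile given
    on the percent scale and one given as proportions yield the same H.
    Zero-abundance groups contribute nothing.
    """
    if isinstance(profile, GenotypeProfile):
        p = np.array(list(profile.proportions(exclude=exclude).values()))
    else:
        p = np.asarray([v for v in dict(profile).values() if v > 0], dtype=float)
        if p.size == 0:
            raise ValueError("profile has no positive abundance")
        p = p / p.sum()
    return float(-(p * np.log2(p)).sum())


def richness(profile) -> int:
    """Number of groups with non-zero abundance."""
    values = profile.abundances.values() if isinstance(profile, GenotypeProfile) \
        else dict(profile).values()
    return int(sum(1 for v in values if v > 0))


def evenness(H: float, S: int) -> float:
    """Evenness E = H / log2(S); requires at least two groups."""
    if S < 2:
        raise ValueError("evenness is undefined for fewer than 2 groups")
    e = H / float(np.log2(S))
    return float(min(max(e, 0.0), 1.0))


def diversity(profile, exclude: set[str] | None = None) -> DiversityResult:
    """H, E and S for one profile in a single call."""
    h = shannon(profile, exclude=exclude)
    s = richness(profile)
    return DiversityResult(H=h, E=evenness(h, s) if s >= 2 else float("nan"), S=s)


# --------------------------------------------------------------------------
# qPCR
# --------------------------------------------------------------------------

@dataclass
class QPCRResult:
    """Copy-number estimates with their standard curve."""

    gene_target: str
    copies: np.ndarray                # per unknown, copies per g dry soil
    slope: float
    intercept: float
    efficiency: float                 # 1.0 == 100%
    r_squared: float


def qpcr_quantify(
    standard_cq,
    standard_copies,
    unknown_cq,
    gene_target: str = "pmoA",
) -> QPCRResult:
    """Fit a standard curve and quantify unknowns.

    The curve is the least-squares line of Cq against log10(copies) over the
    dilution series; unknown copies are 10**((Cq - intercept) / slope) and
    the amplification efficiency is 10**(-1/slope) - 1.  A slope outside
    [-3.9, -3.0] (efficiency outside roughly 80-120%) or R^2 < 0.98 raises a
    warning, not an error.
    """
    copies = np.asarray(standard_copies, dtype=float)
    cq = np.asarray(standard_cq, dtype=float)
    if copies.size < 3:
        raise ValueError("need at least 3 standard points")
    if (copies <= 0).any():
        raise ValueError("standard copies must be positive")
    logc = np.log10(copies)
    if logc.max() - logc.min() < 3:
        raise ValueError("standards must span at least 3 orders of magnitude")
    fit = stats.linregress(logc, cq)
    r2 = float(fit.rvalue**2)
    if r2 < 0.98:
        warnings.warn(f"standard curve R^2 = {r2:.4f} < 0.98", stacklevel=2)
    if not -3.9 <= fit.slope <= -3.0:
        warnings.warn(f"standard-curve slope {fit.slope:.3f} outside [-3.9, -3.0]",
                      stacklevel=2)
    unknowns = np.atleast_1d(np.asarray(unknown_cq, dtype=float))
    est = 10 ** ((unknowns - fit.intercept) / fit.slope)
    efficiency = 10 ** (-1.0 / fit.slope) - 1.0
    return QPCRResult(gene_target=gene_target, copies=est, slope=float(fit.slope),
                      intercept=float(fit.intercept), efficiency=float(efficiency),
                      r_squared=r2)


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Two-sample t-test (or one-way ANOVA) summary."""

    statistic: float
    p_value: float
    significant: bool
    test: str = "t"
    posthoc: object | None = None     # Tukey HSD result for >2 groups


def compare_groups(*groups, alpha: float = 0.05) -> GroupComparison:
    """Compare group means: Student's t-test for 2 groups, one-way ANOVA with
    Tukey's HSD post hoc for more.

    Typical use is contrasting pmoA/16S copy-number ratios between gas-field
    and background soils.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError("all groups have zero variance; the test is undefined")
    if len(arrays) == 2:
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return GroupComparison(statistic=float(res.statistic),
                               p_value=float(res.pvalue),
                               significant=bool(res.pvalue < alpha), test="t")
    f = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    return GroupComparison(statistic=float(f.statistic), p_value=float(f.pvalue),
                           significant=bool(f.pvalue < alpha), test="anova",
                           posthoc=tukey)
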