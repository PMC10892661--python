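"""Synthetic data generators for the DNA-SIP gas-prospecting pipeline.

This module produces every input the analysis consumes: pmoA-like reference
databases, microcosm methane-consumption kinetics, isopycnic-gradient
observations, amplicon read sets with known truth, qPCR readouts and survey
lines with a gas-field anomaly.  Each generator is a pure function of its
configuration and seed.

The statistical structure mirrors a two-scenario field design: soils above a
producing gas reservoir (``gas_well``) host a methanotroph community with
abundant RPC-2 and *Methylosarcina*, while background soils (``dry_well``)
are dominated by *Methylocystis* in SIP incubations and show far less
incorporation of the labelled substrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from shapely.geometry import LineString, Point, Polygon

from sipseek import _seq
from sipseek.gradient import DEFAULT_DENSITIES, FractionSet

#: pmoA genotype roster used throughout: cultured genera plus the uncultured
#: rice-paddy (RPC) and upland-soil (USC) clusters.
GENOTYPES: tuple[str, ...] = (
    "Methylocystis",
    "RPC-2",
    "USC-gamma",
    "Methylosarcina",
    "RPCs",
    "pmoA-2",
    "USC-alpha",
    "Methylobacter",
    "Methylocaldum",
    "Methylosinus",
)

#: Name used for the pooled non-methanotroph background in community-level
#: (16S-style) simulations.
OTHER_BACTERIA = "other_bacteria"

#: Amplicon length (nt), the scale of a pmoA amplicon.
AMPLICON_LENGTH = 471

#: Buoyant-density model defaults (g/mL): centre of unlabelled DNA, centre of
#: fully 13C-labelled DNA, and the spread of one genotype's DNA across the
#: gradient.
UNLABELLED_CENTER = 1.7235
LABELLED_CENTER = 1.744
DENSITY_SD = 0.004

#: Microcosm defaults (ppmv).
INITIAL_CH4 = 25_000.0
TERMINATION_CH4 = 5_000.0


# --------------------------------------------------------------------------
# reference database
# --------------------------------------------------------------------------

@dataclass
class ReferenceDB:
    """Synthetic reference sequences grouped by genotype.

    All sequences share one length.  ``within_divergence`` and
    ``between_divergence`` are the substitution fractions the generator was
    asked for (expected pairwise p-distances within and between genotypes).
    """

    sequences: dict[str, list[str]]
    within_divergence: float
    between_divergence: float

    def __post_init__(self) -> None:
        lengths = {len(s) for seqs in self.sequences.values() for s in seqs}
        if len(lengths) > 1:
            raise ValueError("all reference sequences must share one length")

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))[0])

    def to_fasta(self, path) -> None:
        """Write references as FASTA with ``genotype|refN`` headers."""
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(s), id=f"{g}|ref{i}", description="")
            for g, seqs in self.sequences.items()
            for i, s in enumerate(seqs)
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceDB":
        from Bio import SeqIO

        seqs: dict[str, list[str]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            genotype = rec.id.rsplit("|", 1)[0]
            seqs.setdefault(genotype, []).append(str(rec.seq).upper())
        if not seqs:
            raise ValueError(f"no sequences found in {path}")
        return cls(sequences=seqs, within_divergence=math.nan, between_divergence=math.nan)


def _rate_for_distance(d: float) -> float:
    """Per-lineage substitution rate q so that two sequences independently
    mutated from a common template at rate q differ at a fraction d of sites.

    A site differs when exactly one lineage mutated, or both mutated and
    picked different bases (probability 2/3 under uniform choice):
    d = 2q(1-q) + (2/3)q^2.
    """
    if d <= 0:
        return 0.0
    # solve (4/3) q^2 - 2 q + d = 0, smaller root
    return float((2.0 - math.sqrt(4.0 - (16.0 / 3.0) * d)) / (8.0 / 3.0))


def make_reference_db(
    genotypes=GENOTYPES,
    n_refs_per_genotype: int = 8,
    divergence: tuple[float, float] = (0.02, 0.15),
    length: int = AMPLICON_LENGTH,
    seed: int | None = 20240211,
) -> ReferenceDB:
    """Generate a reference database with controlled sequence divergence.

    Each genotype gets a consensus derived from a shared random root, and
    ``n_refs_per_genotype`` references derived from that consensus, so that
    mean pairwise p-distances approximate ``divergence = (within, between)``.
    """
    genotypes = tuple(genotypes)
    if not genotypes:
        raise ValueError("genotype list must not be empty")
    within, between = divergence
    if not (0 <= within < between <= 0.5):
        raise ValueError("require 0 <= within-divergence < between-divergence <= 0.5")
    rng = np.random.default_rng(seed)

    root = rng.integers(0, 4, size=length).astype(np.uint8)
    q_between = _rate_for_distance(between)
    q_within = _rate_for_distance(within)

    sequences: dict[str, list[str]] = {}
    for g in genotypes:
        consensus = _seq.mutate(root[None, :], q_between, rng)
        refs = _seq.mutate(np.repeat(consensus, n_refs_per_genotype, axis=0), q_within, rng)
        sequences[g] = _seq.decode(refs)
    return ReferenceDB(sequences=sequences, within_divergence=within, between_divergence=between)


# --------------------------------------------------------------------------
# microcosm kinetics
# --------------------------------------------------------------------------

@dataclass
class ConsumptionCurve:
    """Headspace CH4 (ppmv) against time (days) for one SIP microcosm."""

    times: np.ndarray                 # days, daily sampling
    ch4_ppmv: np.ndarray
    initial_ppmv: float = INITIAL_CH4
    threshold_ppmv: float = TERMINATION_CH4
    termination_day: float | None = None
    terminated_by_threshold: bool = False

    @property
    def threshold_consumed_fraction(self) -> float:
        """Fraction of CH4 consumed at the exact termination threshold."""
        return (self.initial_ppmv - self.threshold_ppmv) / self.initial_ppmv

    def consumed_fraction(self, day: float) -> float:
        c = float(np.interp(day, self.times, self.ch4_ppmv))
        return (self.initial_ppmv - c) / self.initial_ppmv

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.times, "ch4_ppmv": self.ch4_ppmv})


@dataclass
class ScenarioConfig:
    """Study conditions for one microcosm/survey scenario.

    ``activities`` give per-genotype methane-assimilation activity in [0, 1];
    they drive the buoyant-density shift under a 13C substrate.
    ``heavy_mob_composition`` holds the methanotroph community of each heavy
    fraction (percent over methanotrophs) and ``mob_share_heavy`` the share
    of methanotrophs in the whole community per heavy fraction (percent).
    """

    label: str
    in_situ_profile: dict[str, float]
    activities: dict[str, float]
    heavy_mob_composition: dict[int, dict[str, float]]
    mob_share_heavy: dict[int, float]
    # pmoA community at the end of the SIP incubation (active genotypes have
    # grown on the labelled substrate); defaults to the in-situ profile
    incubated_profile: dict[str, float] | None = None
    lag_days: float = 13.0
    max_rate_ppmv_per_day: float = 1200.0
    max_consumed_fraction: float = 0.995
    max_days: int = 44
    initial_ppmv: float = INITIAL_CH4
    depth: int = 50_000
    qpcr_noise_sd: float = 0.1       # log10 units
    seed: int = 20240211

    def __post_init__(self) -> None:
        if any(not 0 <= a <= 1 for a in self.activities.values()):
            raise ValueError("activities must lie in [0, 1]")
        if any(v < 0 for v in self.in_situ_profile.values()):
            raise ValueError("profile means must be non-negative")

    @classmethod
    def gas_well(cls, **overrides) -> "ScenarioConfig":
        """Soil above a producing gas reservoir (forward-model site P-type).

        In-situ community led by Methylocystis and RPC-2; rapid methane
        oxidation after a short lag; heavy fractions carry a mixed active
        community of Methylocystis, RPC-2 and Methylosarcina.
        """
        cfg = cls(
            label="gas_well",
            in_situ_profile={
                "Methylocystis": 40.0, "RPC-2": 25.6, "Methylosarcina": 14.6,
                "RPCs": 11.0, "USC-gamma": 3.0, "pmoA-2": 2.0, "USC-alpha": 1.0,
                "Methylobacter": 1.3, "Methylocaldum": 0.5, "Methylosinus": 1.0,
            },
            activities={
                "Methylocystis": 0.95, "RPC-2": 0.95, "Methylosarcina": 0.90,
                "RPCs": 0.50, "pmoA-2": 0.50, "USC-gamma": 0.05, "USC-alpha": 0.05,
                "Methylobacter": 0.05, "Methylocaldum": 0.05, "Methylosinus": 0.05,
            },
            heavy_mob_composition={
                4: {"Methylocystis": 89.49, "RPC-2": 2.34, "USC-gamma": 0.89,
                    "Methylosarcina": 0.84, "RPCs": 1.76, "pmoA-2": 1.97,
                    "USC-alpha": 0.04, "Methylobacter": 0.59, "Methylocaldum": 0.01,
                    "Methylosinus": 0.05},
                5: {"Methylocystis": 45.01, "RPC-2": 41.15, "USC-gamma": 0.67,
                    "Methylosarcina": 5.21, "RPCs": 1.95, "pmoA-2": 3.64,
                    "USC-alpha": 0.15, "Methylobacter": 0.06, "Methylocaldum": 0.01,
                    "Methylosinus": 0.02},
                6: {"Methylocystis": 26.93, "RPC-2": 50.4, "USC-gamma": 0.61,
                    "Methylosarcina": 19.43, "RPCs": 0.47, "pmoA-2": 1.51,
                    "USC-alpha": 0.04, "Methylobacter": 0.01, "Methylocaldum": 0.0,
                    "Methylosinus": 0.01},
            },
            mob_share_heavy={4: 38.73, 5: 32.41, 6: 20.26},
            incubated_profile={
                "Methylocystis": 45.0, "RPC-2": 30.0, "Methylosarcina": 10.0,
                "RPCs": 4.0, "pmoA-2": 3.0, "USC-gamma": 5.0, "USC-alpha": 1.0,
                "Methylobacter": 1.0, "Methylocaldum": 0.5, "Methylosinus": 0.5,
            },
            lag_days=13.0,
            max_rate_ppmv_per_day=1200.0,
            max_consumed_fraction=0.995,
            max_days=44,
        )
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def dry_well(cls, **overrides) -> "ScenarioConfig":
        """Background soil away from the reservoir (J-type site).

        USC-gamma dominates in situ; methane oxidation starts late and stays
        slow; the little labelled DNA is almost entirely Methylocystis.
        """
        cfg = cls(
            label="dry_well",
            in_situ_profile={
                "USC-gamma": 89.0, "Methylocystis": 3.0, "USC-alpha": 3.0,
                "RPCs": 1.5, "RPC-2": 1.0, "Methylosarcina": 0.5, "pmoA-2": 0.5,
                "Methylobacter": 0.5, "Methylocaldum": 0.5, "Methylosinus": 0.5,
            },
            activities={
                "Methylocystis": 0.95, "RPC-2": 0.10, "Methylosarcina": 0.10,
                "RPCs": 0.10, "pmoA-2": 0.10, "USC-gamma": 0.05, "USC-alpha": 0.05,
                "Methylobacter": 0.05, "Methylocaldum": 0.05, "Methylosinus": 0.05,
            },
            heavy_mob_composition={
                4: {"Methylocystis": 91.69, "RPC-2": 1.4, "USC-gamma": 1.94,
                    "Methylosarcina": 0.85, "RPCs": 0.65, "pmoA-2": 0.27,
                    "USC-alpha": 0.58, "Methylobacter": 0.0, "Methylocaldum": 0.1,
                    "Methylosinus": 0.78},
                5: {"Methylocystis": 97.44, "RPC-2": 0.0, "USC-gamma": 0.0,
                    "Methylosarcina": 2.56, "RPCs": 0.0, "pmoA-2": 0.0,
                    "USC-alpha": 0.0, "Methylobacter": 0.0, "Methylocaldum": 0.0,
                    "Methylosinus": 0.0},
                6: {"Methylocystis": 88.72, "RPC-2": 5.93, "USC-gamma": 1.48,
                    "Methylosarcina": 0.0, "RPCs": 2.08, "pmoA-2": 0.59,
                    "USC-alpha": 0.0, "Methylobacter": 0.3, "Methylocaldum": 0.0,
                    "Methylosinus": 0.3},
            },
            mob_share_heavy={4: 13.31, 5: 8.75, 6: 5.49},
            incubated_profile={
                "Methylocystis": 60.0, "USC-gamma": 30.0, "USC-alpha": 4.0,
                "RPCs": 2.0, "RPC-2": 1.0, "Methylosarcina": 1.0, "pmoA-2": 1.0,
                "Methylobacter": 0.5, "Methylocaldum": 0.25, "Methylosinus": 0.25,
            },
            lag_days=26.0,
            max_rate_ppmv_per_day=900.0,
            max_consumed_fraction=0.90,
            max_days=57,
        )
        return replace(cfg, **overrides) if overrides else cfg


def simulate_microcosm(config: ScenarioConfig, noise_sd: float = 0.0,
                       seed: int | None = None) -> ConsumptionCurve:
    """Simulate headspace CH4 consumption with lagged logistic kinetics.

    The consumed fraction follows a logistic curve that stays near zero until
    the end of the lag phase and saturates at ``max_consumed_fraction``; the
    peak consumption rate equals ``max_rate_ppmv_per_day``.  The incubation
    terminates on the first day the headspace concentration drops below the
    threshold (5,000 ppmv by default, i.e. 80% of the initial 25,000 ppmv
    consumed), or at ``max_days`` otherwise.
    """
    c0 = config.initial_ppmv
    if c0 <= 0:
        raise ValueError("initial concentration must be positive")
    f_max = config.max_consumed_fraction
    times = np.arange(0, config.max_days + 1, dtype=float)
    if config.max_rate_ppmv_per_day <= 0:
        if f_max > 0:
            raise ValueError("rate must be positive unless consumption is disabled")
        ch4 = np.full_like(times, c0)
    else:
        r = 4.0 * config.max_rate_ppmv_per_day / (c0 * max(f_max, 1e-12))
        # logistic midpoint placed so only 5% of the final consumption has
        # happened by the end of the lag phase
        t_mid = config.lag_days + math.log(19.0) / r
        consumed = f_max / (1.0 + np.exp(-r * (times - t_mid)))
        ch4 = c0 * (1.0 - consumed)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ch4 = ch4 * 10 ** rng.normal(0.0, noise_sd, size=ch4.shape)
    ch4 = np.clip(ch4, 0.0, None)

    below = np.nonzero(ch4 < TERMINATION_CH4)[0]
    crossed = below.size > 0
    term = float(times[below[0]]) if crossed else float(config.max_days)
    return ConsumptionCurve(
        times=times, ch4_ppmv=ch4, initial_ppmv=c0,
        threshold_ppmv=TERMINATION_CH4, termination_day=term,
        terminated_by_threshold=crossed,
    )


# --------------------------------------------------------------------------
# density gradient
# --------------------------------------------------------------------------

def simulate_gradient(
    profile,
    activities: dict[str, float],
    treatment: str = "13C",
    n_fractions: int = 14,
    seed: int | None = 20240211,
    noise_sd: float = 0.1,
    unlabelled_center: float = UNLABELLED_CENTER,
    labelled_center: float = LABELLED_CENTER,
    density_sd: float = DENSITY_SD,
) -> FractionSet:
    """Distribute each genotype's DNA over buoyant-density fractions.

    A genotype's DNA mass spreads as a Gaussian in density.  Its centre sits
    at the unlabelled position and moves linearly toward the fully labelled
    position with (activity x treatment-is-13C); buoyant density grows about
    linearly with the 13C content of DNA.  Multiplicative log-normal noise
    perturbs each fraction, after which the genotype's mass is renormalized,
    so per-genotype mass is conserved exactly.
    """
    profile = dict(getattr(profile, "abundances", profile))
    if not profile:
        raise ValueError("profile must not be empty")
    if n_fractions < 5:
        raise ValueError("need at least 5 fractions")
    bad = [g for g, a in activities.items() if not 0 <= a <= 1]
    if bad:
        raise ValueError(f"activities outside [0, 1] for {bad}")

    if n_fractions == 14:
        densities = np.asarray(DEFAULT_DENSITIES)
    else:
        densities = np.linspace(1.760, 1.701, n_fractions)
    rng = np.random.default_rng(seed)
    genotypes = list(profile)
    # one noise draw per (genotype, fraction), independent of activities so
    # that the density shift is monotone in activity for a fixed seed
    noise = np.exp(rng.normal(0.0, noise_sd, size=(len(genotypes), n_fractions)))

    table = {}
    labelled = treatment == "13C"
    for row, g in enumerate(genotypes):
        a = activities.get(g, 0.0) if labelled else 0.0
        center = unlabelled_center + a * (labelled_center - unlabelled_center)
        w = np.exp(-0.5 * ((densities - center) / density_sd) ** 2)
        w = w * noise[row]
        table[g] = profile[g] * w / w.sum()
    abundance = pd.DataFrame(table, index=pd.RangeIndex(1, n_fractions + 1))
    return FractionSet(densities=densities, abundance=abundance, treatment=treatment)


# --------------------------------------------------------------------------
# amplicon reads
# --------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Simulated amplicon reads with their true genotype labels.

    Sequences are stored as a uint8 code matrix (see :mod:`sipseek._seq`);
    ``sequences`` decodes them on demand.
    """

    codes: np.ndarray                 # (n_reads, length) uint8
    ids: list[str]
    true_genotypes: np.ndarray        # (n_reads,) object / str

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def sequences(self) -> list[str]:
        return _seq.decode(self.codes)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame({"read_id": self.ids, "genotype": self.true_genotypes})

    def to_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(s), id=i, description="")
            for i, s in zip(self.ids, self.sequences)
        ]
        SeqIO.write(records, path, "fasta")


def simulate_amplicon_reads(
    fraction_composition,
    db: ReferenceDB,
    depth: int = 50_000,
    error_rate: float = 0.01,
    seed: int | None = 20240211,
    id_prefix: str = "read",
) -> ReadSet:
    """Draw amplicon reads multinomially from a genotype composition.

    Each read copies a uniformly chosen reference of its genotype and picks
    up i.i.d. substitutions at ``error_rate``.  True labels are recorded so
    recovery can be checked downstream.
    """
    composition = dict(getattr(fraction_composition, "abundances", fraction_composition))
    composition = {g: v for g, v in composition.items() if v > 0}
    if not composition:
        raise ValueError("composition must contain a positive abundance")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= error_rate < 0.1:
        raise ValueError("error_rate must lie in [0, 0.1)")
    unknown = set(composition) - set(db.genotypes)
    if unknown:
        raise ValueError(f"composition genotypes missing from the database: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    genotypes = list(composition)
    p = np.array([composition[g] for g in genotypes], dtype=float)
    counts = rng.multinomial(depth, p / p.sum())

    blocks, labels = [], []
    for g, n in zip(genotypes, counts):
        if n == 0:
            continue
        refs = _seq.encode(db.sequences[g])
        picks = rng.integers(0, len(refs), size=n)
        blocks.append(refs[picks])
        labels.extend([g] * n)
    codes = _seq.mutate(np.concatenate(blocks, axis=0), error_rate, rng)
    # shuffle so read order carries no genotype signal
    order = rng.permutation(len(labels))
    codes = codes[order]
    labels = np.array(labels, dtype=object)[order]
    ids = [f"{id_prefix}{i:06d}" for i in range(len(labels))]
    return ReadSet(codes=codes, ids=ids, true_genotypes=labels)


# --------------------------------------------------------------------------
# qPCR
# --------------------------------------------------------------------------

def simulate_qpcr(
    true_copies,
    standard: tuple[float, float] = (-3.3219, 38.0),
    noise_sd: float = 0.1,
    seed: int | None = 20240211,
):
    """Simulate quantification-cycle values for given template copy numbers.

    Cq = intercept + slope * log10(copies) + Normal(0, noise_sd).  The
    default slope of -3.3219 corresponds to 100% amplification efficiency
    (a perfect doubling per cycle).
    """
    copies = np.asarray(true_copies, dtype=float)
    scalar = copies.ndim == 0
    copies = np.atleast_1d(copies)
    if (copies <= 0).any():
        raise ValueError("copy numbers must be positive")
    slope, intercept = standard
    cq = intercept + slope * np.log10(copies)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cq = cq + rng.normal(0.0, noise_sd, size=cq.shape)
    return float(cq[0]) if scalar else cq


# --------------------------------------------------------------------------
# survey
# --------------------------------------------------------------------------

#: Expected biotic index (percent) per survey zone; the gas-field mean and
#: the background level implied by the reported 8.9-fold contrast.
DEFAULT_BI_MEANS = {"gas_field": 24.9, "background": 2.8}

#: Split of the biotic index between the two indicator genotypes, matching
#: their in-situ ratio above the reservoir (RPC-2 25.6 : Methylosarcina 14.6).
INDICATOR_SPLIT = {"RPC-2": 25.6 / 40.2, "Methylosarcina": 14.6 / 40.2}

#: Non-indicator community used to fill the remainder of a survey profile.
_FILL_PROFILE = {
    "USC-gamma": 50.0, "Methylocystis": 30.0, "RPCs": 6.0, "pmoA-2": 5.0,
    "USC-alpha": 5.0, "Methylobacter": 2.0, "Methylocaldum": 1.0,
    "Methylosinus": 1.0,
}


def default_survey_geometry() -> tuple[LineString, Polygon]:
    """A 10 km NW-SE survey line crossing an irregular ~3 km gas enclosure."""
    line = LineString([(0.0, 0.0), (10_000.0, 0.0)])
    polygon = Polygon([
        (3_500, -1_200), (4_200, -1_500), (5_800, -1_400), (6_500, -900),
        (6_400, 800), (5_500, 1_500), (4_100, 1_300), (3_600, 300),
    ])
    return line, polygon


@dataclass
class SurveyTable:
    """Simulated survey sites with their true compositions and geometry."""

    sites: pd.DataFrame               # site_id, easting_m, northing_m, bi_percent, zone
    profiles: dict[str, dict[str, float]]
    polygon: Polygon
    line: LineString

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)


def _logit_normal_mu(mean_fraction: float, sigma: float) -> float:
    """Location parameter so that E[expit(Normal(mu, sigma))] = mean_fraction."""
    if sigma == 0:
        return float(logit(mean_fraction))
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def expected(mu):
        return float(weights @ expit(mu + sigma * nodes)) - mean_fraction

    return float(brentq(expected, -30.0, 30.0))


def simulate_survey(
    n_sites: int = 40,
    polygon: Polygon | None = None,
    line: LineString | None = None,
    bi_means: dict[str, float] | None = None,
    bi_dispersion: float = 0.65,
    lateral_jitter_m: float = 100.0,
    seed: int | None = 20240211,
) -> SurveyTable:
    """Place survey sites along a line and draw their true compositions.

    Sites are evenly spaced along the survey line with lateral jitter (field
    sites cannot follow a perfect line in mountainous terrain).  A site's
    zone comes from polygon containment.  The site's biotic index is drawn
    logit-normal with dispersion ``bi_dispersion`` on the logit scale,
    calibrated so its expectation equals the zone mean; the two indicator
    genotypes share the BI and the non-indicator community fills the rest.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if line is None or polygon is None:
        default_line, default_poly = default_survey_geometry()
        line = line if line is not None else default_line
        polygon = polygon if polygon is not None else default_poly
    if polygon.area <= 0:
        raise ValueError("polygon must be non-degenerate")
    bi_means = dict(DEFAULT_BI_MEANS if bi_means is None else bi_means)
    for zone, m in bi_means.items():
        if not 0 <= m <= 100:
            raise ValueError(f"zone mean for {zone!r} outside [0, 100]")

    rng = np.random.default_rng(seed)
    stations = np.linspace(0.0, line.length, n_sites)
    pts = [line.interpolate(s) for s in stations]
    # lateral offset perpendicular to the local line direction
    offsets = rng.normal(0.0, lateral_jitter_m, size=(n_sites, 2)) if lateral_jitter_m > 0 \
        else np.zeros((n_sites, 2))
    coords = np.array([(p.x, p.y) for p in pts]) + offsets
    zones = np.array([
        "gas_field" if polygon.covers(Point(x, y)) else "background"
        for x, y in coords
    ])

    mus = {z: _logit_normal_mu(m / 100.0, bi_dispersion) for z, m in bi_means.items()}
    z_draw = rng.normal(0.0, 1.0, size=n_sites)
    bi = np.array([
        100.0 * expit(mus[z] + bi_dispersion * e) for z, e in zip(zones, z_draw)
    ])

    profiles: dict[str, dict[str, float]] = {}
    records = []
    for i, ((x, y), zone, b) in enumerate(zip(coords, zones, bi)):
        site_id = f"S{i + 1:03d}"
        prof = {g: b * share for g, share in INDICATOR_SPLIT.items()}
        fill_total = sum(_FILL_PROFILE.values())
        for g, v in _FILL_PROFILE.items():
            prof[g] = (100.0 - b) * v / fill_total
        profiles[site_id] = prof
        records.append({
            "site_id": site_id, "easting_m": float(x), "northing_m": float(y),
            "bi_percent": float(b), "zone": zone,
        })
    sites = pd.DataFrame.from_records(records)
    return SurveyTable(sites=sites, profiles=profiles, polygon=polygon, line=line)


def simulate_site_reads(
    table: SurveyTable,
    db: ReferenceDB,
    depth: int = 5_000,
    error_rate: float = 0.01,
    seed: int | None = 20240211,
):
    """Yield ``(site_id, ReadSet)`` for every survey site, one site at a time."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(table.profiles))
    for (site_id, profile), child in zip(table.profiles.items(), children):
        site_seed = int(child.generate_state(1)[0] % 2**31)
        yield site_id, simulate_amplicon_reads(
            profile, db, depth=depth, error_rate=error_rate,
            seed=site_seed, id_prefix=f"{site_id}_",
        )
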