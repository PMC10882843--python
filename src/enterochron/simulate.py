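"""Synthetic cohort generator.

Emulates the longitudinal design of the study population: 18 female pigs in
two cohorts (6 and 12 animals) sampled at nine ages from 3 to 53 weeks, with
an 8-pig microbiome subset (72 sequenced samples), a four-enterotype
community trajectory E1 -> E2 -> E3 -> E4 with two of the eight profiled
pigs reverting to E3 after estrus, age-increasing alpha diversity, a
low-diversity high-variance fungal community with a parturition bump in
Candida-like taxa, drug-class-specific nonlinear resistant-count
trajectories with continuous-time AR(1) within-pig correlation, and qPCR
copy numbers for tet(A), bla_CTX-M and the 16S rRNA gene.

Bacterial counts are drawn from the Dirichlet-multinomial model that the
enterotyping stage fits, with the trajectory-mapped component's
concentration vector scaled by an age-dependent factor so that community
evenness (and hence Shannon diversity) rises with age. Every generator is a
pure function of the configuration seed: a fixed seed reproduces all tables
byte for byte regardless of call order, because each generator derives its
own random stream from the seed plus a stage tag.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from enterochron.io import CountTable, SampleRecord, AnalysisDataset, assemble_dataset

__all__ = [
    "CohortConfig",
    "TruthLabels",
    "SimulationResult",
    "generate_design",
    "generate_bacterial_counts",
    "generate_fungal_counts",
    "generate_amr_observations",
    "generate_qpcr_observations",
    "simulate_cohort",
    "write_simulation",
]

AGE_GRID = (3, 6, 10, 12, 22, 32, 49, 50, 53)

# Named anchor genera per enterotype, echoing the dominant taxa of each
# community type: E1 early-life (Rikenellaceae RC9 / Prevotella / UCG-002),
# E2 growing (Megasphaera / Streptococcus / Prevotella_9), E3 late-growing
# (Streptococcus / Clostridium s.s. 1 / Treponema), E4 adult
# (Treponema / Clostridium s.s. 1).
ENTEROTYPE_ANCHORS: tuple[dict[str, float], ...] = (
    {
        "Rikenellaceae_RC9_gut_group": 0.13,
        "Prevotella": 0.11,
        "Lachnospiraceae_UCG-002": 0.08,
    },
    {
        "Megasphaera": 0.13,
        "Streptococcus": 0.08,
        "Prevotella_9": 0.09,
    },
    {
        "Streptococcus": 0.11,
        "Clostridium_sensu_stricto_1": 0.08,
        "Treponema": 0.06,
    },
    {
        "Treponema": 0.14,
        "Clostridium_sensu_stricto_1": 0.10,
    },
)

#: Default mapping from sampling age to the active enterotype component
#: (0-based): E1 through week 10, E2 at 12, E3 at 22, E4 from estrus on.
DEFAULT_TRAJECTORY: dict[int, int] = {
    3: 0, 6: 0, 10: 0, 12: 1, 22: 2, 32: 3, 49: 3, 50: 3, 53: 3,
}

#: Evenness scale per age: multiplies the active component's concentration
#: vector, so early samples are spikier (lower Shannon diversity). Monotone
#: in age, with only a mild gradient across the ages a single enterotype
#: spans: most of the diversity rise comes from the enterotype transitions,
#: and strong within-enterotype concentration gradients would constitute
#: community substructure beyond the four types.
DEFAULT_ALPHA_GROWTH: dict[int, float] = {
    3: 0.32, 6: 0.35, 10: 0.38, 12: 0.65, 22: 0.85,
    32: 1.08, 49: 1.13, 50: 1.18, 53: 1.23,
}

#: Per-age log10 library-size model (mean, sd): week-3 samples sequence
#: shallower, later samples around 160 K reads (cohort average ~150 K).
DEFAULT_LIBRARY_MODEL: dict[int, tuple[float, float]] = {
    3: (4.70, 0.20),
    **{a: (5.20, 0.10) for a in (6, 10, 12, 22, 32, 49, 50, 53)},
}

# Antimicrobial panels used for plate counts: (drug, drug_class) per
# bacterium; "none" is growth without antimicrobial (total count).
AMR_PANEL: dict[str, tuple[tuple[str, str], ...]] = {
    "coliform": (
        ("none", "total"),
        ("ampicillin", "aminopenicillins"),
        ("gentamicin", "aminoglycosides"),
        ("streptomycin", "aminoglycosides"),
        ("ceftriaxone", "cephalosporins_3rd"),
        ("ciprofloxacin", "fluoroquinolones"),
        ("enrofloxacin", "fluoroquinolones"),
        ("azithromycin", "macrolides"),
        ("chloramphenicol", "phenicols"),
        ("nalidixic_acid", "quinolones"),
        ("sulfamethoxazole", "sulfonamides"),
        ("tetracycline", "tetracyclines"),
    ),
    "enterococcus": (
        ("none", "total"),
        ("gentamicin", "aminoglycosides"),
        ("streptomycin", "aminoglycosides"),
        ("ciprofloxacin", "fluoroquinolones"),
        ("enrofloxacin", "fluoroquinolones"),
        ("lincomycin", "lincosamides"),
        ("erythromycin", "macrolides"),
        ("tylosin", "macrolides"),
        ("nitrofurantoin", "nitrofurans"),
        ("penicillin", "penicillins"),
        ("nalidixic_acid", "quinolones"),
        ("tetracycline", "tetracyclines"),
    ),
}

#: Combinations on which no resistant growth occurs (plates stay blank):
#: fluoroquinolones for both bacteria, quinolones for coliforms only.
NO_GROWTH: frozenset[tuple[str, str]] = frozenset(
    {
        ("coliform", "fluoroquinolones"),
        ("coliform", "quinolones"),
        ("enterococcus", "fluoroquinolones"),
    }
)


def _curve(values: Sequence[float]) -> dict[int, float]:
    return dict(zip(AGE_GRID, [float(v) for v in values]))


# Mean log10 CFU/g trajectories per (bacterium, drug_class): high at week 3,
# decline to week 10, then class-specific rises between 12 and 32 weeks and
# late-gestation behavior.
DEFAULT_AMR_SHAPES: dict[tuple[str, str], dict[int, float]] = {
    ("coliform", "total"): _curve([7.8, 7.9, 8.0, 8.0, 8.0, 8.0, 7.9, 7.9, 7.9]),
    ("coliform", "aminopenicillins"): _curve([6.0, 5.0, 3.8, 3.9, 5.0, 5.6, 5.3, 5.2, 5.1]),
    ("coliform", "aminoglycosides"): _curve([6.2, 5.2, 4.0, 4.1, 5.1, 5.7, 5.0, 4.8, 4.2]),
    ("coliform", "cephalosporins_3rd"): _curve([4.8, 4.0, 3.2, 2.9, 2.4, 2.6, 3.2, 3.4, 3.4]),
    ("coliform", "macrolides"): _curve([5.9, 5.0, 3.9, 4.0, 4.9, 5.5, 5.3, 5.2, 5.2]),
    ("coliform", "phenicols"): _curve([5.0, 4.2, 3.5, 3.5, 3.8, 3.9, 4.3, 4.5, 4.5]),
    ("coliform", "sulfonamides"): _curve([6.1, 5.1, 4.0, 4.1, 5.0, 5.6, 5.0, 4.8, 4.7]),
    ("coliform", "tetracyclines"): _curve([6.5, 5.6, 4.4, 4.5, 5.4, 6.0, 5.4, 5.2, 5.1]),
    ("enterococcus", "total"): _curve([6.8, 7.0, 7.2, 7.3, 7.6, 7.8, 7.6, 7.2, 6.9]),
    ("enterococcus", "aminoglycosides"): _curve([6.5, 6.2, 5.8, 5.6, 4.9, 4.2, 3.0, 2.9, 2.7]),
    ("enterococcus", "lincosamides"): _curve([5.8, 4.6, 3.9, 3.9, 4.3, 5.2, 5.3, 5.2, 5.0]),
    ("enterococcus", "macrolides"): _curve([5.9, 4.7, 4.0, 4.0, 4.4, 5.3, 5.3, 5.1, 4.6]),
    ("enterococcus", "nitrofurans"): _curve([4.5, 4.2, 3.9, 3.9, 3.4, 3.4, 3.4, 3.4, 3.4]),
    ("enterococcus", "penicillins"): _curve([6.6, 6.3, 5.9, 5.7, 5.0, 4.3, 3.2, 3.1, 2.9]),
    ("enterococcus", "quinolones"): _curve([5.7, 4.5, 3.8, 3.8, 4.2, 5.1, 5.5, 5.4, 5.3]),
    ("enterococcus", "tetracyclines"): _curve([6.4, 5.5, 4.3, 4.4, 5.3, 5.9, 5.5, 5.4, 5.3]),
}

# Week-3 anchored log10 copies/g trajectories for the qPCR targets. tet(A)
# starts at 7.10 and bla_CTX-M at 5.35, both falling rapidly to week 10 and
# partially rebounding by week 22; the 16S curve starts at 10.70 so the
# standardized tet(A) value opens at -3.6.
DEFAULT_QPCR_CURVES: dict[str, dict[int, float]] = {
    "tetA": _curve([7.10, 6.20, 5.40, 5.50, 6.00, 6.10, 6.10, 6.15, 6.30]),
    "blaCTXM": _curve([5.35, 4.60, 3.90, 4.00, 4.60, 4.70, 4.70, 4.70, 4.75]),
    "16S": _curve([10.70, 10.80, 10.90, 10.95, 11.00, 11.10, 11.10, 11.10, 11.10]),
}


def _default_profiles(n_taxa: int) -> tuple[list[str], np.ndarray]:
    """Build the four enterotype concentration profiles (relative weights).

    Each component gets its named anchor genera at high weight plus a
    ten-genus companion block at moderate weight (~2% relative abundance,
    safely above the 0.5% first-appearance threshold of the maturation
    score); all other genera share a small baseline (~0.07% relative
    abundance) kept low enough that sampling overdispersion rarely pushes
    them over that threshold.
    """
    anchor_names: list[str] = []
    for anchors in ENTEROTYPE_ANCHORS:
        for name in anchors:
            if name not in anchor_names:
                anchor_names.append(name)
    n_filler = n_taxa - len(anchor_names)
    if n_filler < 44:
        raise ValueError("n_bacterial_taxa too small for the default profiles")
    taxa = anchor_names + [f"Genus_{i:03d}" for i in range(1, n_filler + 1)]
    idx = {t: i for i, t in enumerate(taxa)}
    K = len(ENTEROTYPE_ANCHORS)
    profiles = np.full((K, n_taxa), 0.0005)
    offset = len(anchor_names)
    for k, anchors in enumerate(ENTEROTYPE_ANCHORS):
        for name, w in anchors.items():
            profiles[k, idx[name]] = w
        block = slice(offset + 10 * k, offset + 10 * (k + 1))
        profiles[k, block] = 0.02
    profiles /= profiles.sum(axis=1, keepdims=True)
    return taxa, profiles


@dataclasses.dataclass
class CohortConfig:
    """Study-design and generative parameters for the synthetic cohort.

    Defaults reproduce the real design: 18 pigs in cohorts of 6 and 12,
    nine sampling ages, an 8-pig (4 + 4 per cohort) microbiome subset, 100
    bacterial genera in four enterotype profiles, 291 fungal taxa in two
    phyla, and week-3 qPCR baselines of 7.10 (tetA) and 5.35 (blaCTXM)
    log10 copies/g.
    """

    n_pigs: int = 18
    cohort_sizes: tuple[int, int] = (6, 12)
    age_grid: tuple[int, ...] = AGE_GRID
    microbiome_subset_size: int = 8
    n_bacterial_taxa: int = 100
    n_fungal_taxa: int = 291
    base_concentration: float = 60.0
    alpha_growth: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ALPHA_GROWTH)
    )
    trajectory_map: Mapping[int, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORY)
    )
    n_reverting_pigs: int = 2
    reversion_component: int = 2
    reversion_from_age: int = 49
    library_size_model: Mapping[int, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LIBRARY_MODEL)
    )
    enterotype_profiles: np.ndarray | None = None
    taxon_names: list[str] | None = None
    fungal_concentration: float = 8.0
    candida_bump: float = 6.0
    amr_trend_shapes: Mapping[tuple[str, str], Mapping[int, float]] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AMR_SHAPES.items()}
    )
    ar1_phi: float = 0.8
    noise_sd: float = 0.5
    amr_cohort_effect: float = 0.0
    detection_limit_log10: float = 1.7
    qpcr_curves: Mapping[str, Mapping[int, float]] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_QPCR_CURVES.items()}
    )
    qpcr_pig_sd: float = 0.30
    qpcr_noise_sd: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.cohort_sizes) != self.n_pigs:
            raise ValueError(
                f"cohort_sizes {self.cohort_sizes} must sum to n_pigs={self.n_pigs}"
            )
        if self.microbiome_subset_size > self.n_pigs:
            raise ValueError("microbiome_subset_size exceeds n_pigs")
        if self.enterotype_profiles is None:
            self.taxon_names, self.enterotype_profiles = _default_profiles(
                self.n_bacterial_taxa
            )
        else:
            self.enterotype_profiles = np.asarray(self.enterotype_profiles, float)
            if self.taxon_names is None:
                self.taxon_names = [
                    f"Genus_{i:03d}"
                    for i in range(1, self.enterotype_profiles.shape[1] + 1)
                ]
            self.n_bacterial_taxa = self.enterotype_profiles.shape[1]
        if (self.enterotype_profiles <= 0).any():
            raise ValueError("enterotype profiles must be strictly positive")
        K = self.enterotype_profiles.shape[0]
        for age, comp in self.trajectory_map.items():
            if not 0 <= comp < K:
                raise ValueError(
                    f"trajectory_map[{age}]={comp} does not index a profile (K={K})"
                )
        for age in self.age_grid:
            if age not in self.trajectory_map:
                raise ValueError(f"trajectory_map missing age {age}")
            if age not in self.alpha_growth:
                raise ValueError(f"alpha_growth missing age {age}")
            if age not in self.library_size_model:
                raise ValueError(f"library_size_model missing age {age}")

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclasses.dataclass
class TruthLabels:
    """Ground truth recorded at generation time, the oracle for
    parameter-recovery tests."""

    sample_component: dict[str, int] = dataclasses.field(default_factory=dict)
    reverting_pigs: list[str] = dataclasses.field(default_factory=list)
    amr_true_curves: dict[tuple[str, str], dict[int, float]] = dataclasses.field(
        default_factory=dict
    )
    ar1_phi: float = float("nan")

    def to_json(self) -> str:
        payload = {
            "sample_component": self.sample_component,
            "reverting_pigs": self.reverting_pigs,
            "amr_true_curves": {
                f"{b}|{c}": curve for (b, c), curve in self.amr_true_curves.items()
            },
            "ar1_phi": self.ar1_phi,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _pig_ids(config: CohortConfig) -> list[tuple[str, int]]:
    """(pig_id, cohort) pairs; cohort 1 then cohort 2."""
    out = []
    n1 = config.cohort_sizes[0]
    for i in range(config.n_pigs):
        out.append((f"P{i + 1:02d}", 1 if i < n1 else 2))
    return out


def _subset_pigs(config: CohortConfig) -> list[str]:
    """Microbiome-subset pigs, balanced across cohorts (first animals of
    each cohort, deterministic)."""
    pigs = _pig_ids(config)
    per_cohort = config.microbiome_subset_size // 2
    rem = config.microbiome_subset_size - 2 * per_cohort
    c1 = [p for p, c in pigs if c == 1][: per_cohort + rem]
    c2 = [p for p, c in pigs if c == 2][:per_cohort]
    chosen = c1 + c2
    if len(chosen) != config.microbiome_subset_size:
        raise ValueError("cohorts too small for the requested balanced subset")
    return chosen


def _reverting_pigs(config: CohortConfig) -> list[str]:
    """Pigs whose enterotype reverts after estrus: the last n_reverting
    microbiome-subset pigs (deterministic)."""
    subset = _subset_pigs(config)
    if config.n_reverting_pigs > len(subset):
        raise ValueError("n_reverting_pigs exceeds the microbiome subset")
    return subset[len(subset) - config.n_reverting_pigs:]


def sample_id_for(pig_id: str, age: int) -> str:
    return f"{pig_id}_w{age:02d}"


def generate_design(config: CohortConfig) -> list[SampleRecord]:
    """One record per pig per age point; microbiome_subset flags exactly
    ``microbiome_subset_size`` pigs at every age."""
    subset = set(_subset_pigs(config))
    records = []
    for pig, cohort in _pig_ids(config):
        for age in config.age_grid:
            records.append(
                SampleRecord(
                    sample_id=sample_id_for(pig, age),
                    pig_id=pig,
                    cohort=cohort,
                    age_weeks=float(age),
                    microbiome_subset=pig in subset,
                )
            )
    return records


def _true_component(config: CohortConfig, pig: str, age: int,
                    reverting: set[str]) -> int:
    comp = config.trajectory_map[age]
    if pig in reverting and age >= config.reversion_from_age:
        # late reversion only applies once the pig has reached the terminal
        # component of the trajectory
        terminal = config.trajectory_map[max(config.age_grid)]
        if comp == terminal:
            comp = config.reversion_component
    return comp


def generate_bacterial_counts(
    design: Sequence[SampleRecord], config: CohortConfig
) -> tuple[CountTable, TruthLabels]:
    """Dirichlet-multinomial draws for every microbiome-subset sample.

    The sample's true component is the trajectory-mapped enterotype (with
    the configured late reversion); its concentration vector is the
    component profile times ``base_concentration`` times the age's
    evenness scale. Library sizes follow the per-age log10-normal model
    and are written back onto the design records as raw read counts.
    """
    rng = config._rng(1)
    reverting = set(_reverting_pigs(config))
    profiles = config.enterotype_profiles
    truth = TruthLabels(reverting_pigs=sorted(reverting), ar1_phi=config.ar1_phi)
    rows, ids = [], []
    for rec in design:
        if not rec.microbiome_subset:
            continue
        age = int(rec.age_weeks)
        comp = _true_component(config, rec.pig_id, age, reverting)
        truth.sample_component[rec.sample_id] = comp
        mu, sd = config.library_size_model[age]
        size = int(round(10.0 ** (mu + sd * rng.standard_normal())))
        size = max(size, 1)
        alpha = profiles[comp] * config.base_concentration * config.alpha_growth[age]
        p = rng.dirichlet(alpha)
        counts = rng.multinomial(size, p)
        rec.raw_read_count = int(counts.sum())
        rows.append(counts)
        ids.append(rec.sample_id)
    table = CountTable(
        sample_ids=ids,
        taxon_ids=list(config.taxon_names),
        counts=np.asarray(rows, dtype=np.int64),
    )
    return table, truth


# Candida-like fungal taxa that bloom at parturition, plus early-life yeasts.
CANDIDA_LIKE = ("Candida", "Issatchenkia", "Kazachstania", "Clavispora")


def _fungal_profile(config: CohortConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Single-component fungal profile: two phyla with Ascomycota dominant.

    Returns taxon names, baseline relative weights, and a boolean mask of
    the Candida-like taxa.
    """
    n = config.n_fungal_taxa
    n_asco = max(int(round(n * 0.69)), len(CANDIDA_LIKE))
    names = list(CANDIDA_LIKE)
    names += [f"Ascomycota_sp_{i:03d}" for i in range(1, n_asco - len(CANDIDA_LIKE) + 1)]
    names += [f"Basidiomycota_sp_{i:03d}" for i in range(1, n - n_asco + 1)]
    w = np.empty(n)
    w[:n_asco] = 3.0  # dominant phylum
    w[n_asco:] = 0.5
    w[: len(CANDIDA_LIKE)] = 6.0
    w /= w.sum()
    mask = np.zeros(n, bool)
    mask[: len(CANDIDA_LIKE)] = True
    return names, w, mask


def generate_fungal_counts(
    design: Sequence[SampleRecord], config: CohortConfig
) -> CountTable:
    """Fungal (ITS) counts for the microbiome subset: one overdispersed
    Dirichlet-multinomial component (small concentration total) with a
    parturition-age bloom in the Candida-like taxa."""
    rng = config._rng(2)
    names, weights, candida = _fungal_profile(config)
    rows, ids = [], []
    for rec in design:
        if not rec.microbiome_subset:
            continue
        age = int(rec.age_weeks)
        w = weights.copy()
        if rec.stage == "parturition":
            w[candida] *= config.candida_bump
            w /= w.sum()
        mu, sd = config.library_size_model[age]
        size = max(int(round(10.0 ** (mu + sd * rng.standard_normal()) / 3.0)), 1)
        p = rng.dirichlet(w * config.fungal_concentration)
        rows.append(rng.multinomial(size, p))
        ids.append(rec.sample_id)
    return CountTable(
        sample_ids=ids, taxon_ids=names, counts=np.asarray(rows, dtype=np.int64)
    )


def _ar1_path(rng: np.random.Generator, ages: np.ndarray, phi: float,
              sd: float) -> np.ndarray:
    """Stationary continuous-time AR(1) path over an age sequence:
    corr(e_s, e_t) = phi ** |t - s| (weeks), marginal sd ``sd``."""
    e = np.empty(len(ages))
    if sd == 0:
        return np.zeros(len(ages))
    e[0] = sd * rng.standard_normal()
    for i in range(1, len(ages)):
        dt = ages[i] - ages[i - 1]
        rho = np.sign(phi) ** dt * abs(phi) ** dt if phi != 0 else 0.0
        e[i] = rho * e[i - 1] + sd * np.sqrt(max(1 - rho**2, 0.0)) * rng.standard_normal()
    return e


def generate_amr_observations(
    design: Sequence[SampleRecord], config: CohortConfig
) -> tuple[pd.DataFrame, TruthLabels]:
    """Plate-count observations for every pig x age x drug.

    log10 CFU/g = class mean curve(age) + cohort effect + stationary
    continuous-time AR(1) error over the pig's age sequence. Plates on the
    configured no-growth combinations, and values falling below the
    detection limit, are recorded as missing (no growth).
    """
    rng = config._rng(3)
    ages = np.array(sorted({int(r.age_weeks) for r in design}))
    by_pig: dict[str, dict[int, SampleRecord]] = {}
    for rec in design:
        by_pig.setdefault(rec.pig_id, {})[int(rec.age_weeks)] = rec
    truth = TruthLabels(ar1_phi=config.ar1_phi)
    for key, curve in config.amr_trend_shapes.items():
        truth.amr_true_curves[key] = {int(a): float(v) for a, v in curve.items()}
    rows = []
    for pig in sorted(by_pig):
        pig_ages = np.array(sorted(by_pig[pig]))
        cohort = by_pig[pig][int(pig_ages[0])].cohort
        for bacterium, panel in AMR_PANEL.items():
            for drug, drug_class in panel:
                if (bacterium, drug_class) in NO_GROWTH:
                    for age in pig_ages:
                        rows.append(
                            (by_pig[pig][int(age)].sample_id, bacterium, drug,
                             drug_class, np.nan)
                        )
                    continue
                curve = config.amr_trend_shapes[(bacterium, drug_class)]
                e = _ar1_path(rng, pig_ages, config.ar1_phi, config.noise_sd)
                for i, age in enumerate(pig_ages):
                    mu = curve[int(age)] + config.amr_cohort_effect * (cohort - 1)
                    val = mu + e[i]
                    if val < config.detection_limit_log10:
                        val = np.nan
                    rows.append(
                        (by_pig[pig][int(age)].sample_id, bacterium, drug,
                         drug_class, val)
                    )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "bacterium", "drug", "drug_class", "log10_cfu_per_g"],
    )
    return df, truth


def generate_qpcr_observations(
    design: Sequence[SampleRecord], config: CohortConfig
) -> pd.DataFrame:
    """qPCR copies/g for tet(A), bla_CTX-M and 16S on the microbiome subset.

    log10 copies = gene age curve + pig random intercept + noise; the table
    stores linear copies per gram. With all noise terms at zero the week-3
    tet(A) value is exactly its configured baseline (default 7.10).
    """
    rng = config._rng(4)
    rows = []
    subset = [r for r in design if r.microbiome_subset]
    pigs = sorted({r.pig_id for r in subset})
    genes = list(config.qpcr_curves)
    intercepts = {
        (p, g): config.qpcr_pig_sd * rng.standard_normal()
        for p in pigs
        for g in genes
    }
    for rec in subset:
        age = int(rec.age_weeks)
        for gene in genes:
            log10 = (
                config.qpcr_curves[gene][age]
                + intercepts[(rec.pig_id, gene)]
                + config.qpcr_noise_sd * rng.standard_normal()
            )
            rows.append((rec.sample_id, gene, 10.0 ** log10))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "copies_per_g"])


@dataclasses.dataclass
class SimulationResult:
    design: list[SampleRecord]
    bacterial_counts: CountTable
    fungal_counts: CountTable
    amr: pd.DataFrame
    qpcr: pd.DataFrame
    truth: TruthLabels

    def dataset(self) -> AnalysisDataset:
        return assemble_dataset(
            self.bacterial_counts, self.design, amr=self.amr, qpcr=self.qpcr
        )


def simulate_cohort(config: CohortConfig | None = None) -> SimulationResult:
    """Run every generator under one configuration and join the outputs."""
    config = config if config is not None else CohortConfig()
    design = generate_design(config)
    counts, truth = generate_bacterial_counts(design, config)
    fungal = generate_fungal_counts(design, config)
    amr, amr_truth = generate_amr_observations(design, config)
    truth.amr_true_curves = amr_truth.amr_true_curves
    qpcr = generate_qpcr_observations(design, config)
    return SimulationResult(
        design=design,
        bacterial_counts=counts,
        fungal_counts=fungal,
        amr=amr,
        qpcr=qpcr,
        truth=truth,
    )


def write_simulation(sim: SimulationResult, outdir: str | Path) -> dict[str, str]:
    """Write all simulation tables as TSV plus the truth record as JSON."""
    from enterochron.io import write_count_table, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "fungal_counts": outdir / "fungal_counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "amr": outdir / "amr.tsv",
        "qpcr": outdir / "qpcr.tsv",
        "truth": outdir / "truth.json",
    }
    write_count_table(sim.bacterial_counts, paths["counts"])
    write_count_table(sim.fungal_counts, paths["fungal_counts"])
    write_metadata(sim.design, paths["metadata"])
    sim.amr.to_csv(paths["amr"], sep="\t", index=False)
    sim.qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    paths["truth"].write_text(sim.truth.to_json())
    return {k: str(v) for k, v in paths.items()}
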