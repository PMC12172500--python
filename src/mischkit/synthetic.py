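"""Synthetic scalp-microbiome cohort generator.

Emulates the statistical structure the downstream analyses assume: a
cohort of male subjects sampled at two scalp regions (T = frontal, H =
occipital), with genus-level bacterial and fungal communities whose mean
composition shifts with clinical stage, an age signal carried by a handful
of genera in healthy subjects only, and within-subject correlation between
the two regions.

The noise model is Dirichlet-multinomial: each subject draws a composition
from a Dirichlet centered on their stage template, the two region profiles
are mixtures of the subject draw and a fresh draw (mixing weight rho), and
sequencing is a multinomial at a fixed depth.

Stage templates encode the qualitative dysbiosis gradient of the study
system: Propionibacterium enriched with severity, Corynebacterium
depleted, Malassezia depleted, Alternaria exploding past 50% in AGA7,
Aspergillus peaking at AGA5.  Age trends (healthy subjects only) act on
the logit scale so they can never drive an abundance negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._seeds import child_rng
from .data_model import (
    AGE_MAX,
    AGE_MIN,
    KINGDOMS,
    STAGES,
    AbundanceTable,
    CohortMetadata,
    stage_index,
)

__all__ = [
    "StageTemplate",
    "AgeTrend",
    "SyntheticConfig",
    "default_config",
    "planted_feature_config",
    "default_lineages",
    "simulate_cohort",
    "inject_high_risk",
]

#: study cohort: 51 healthy + 18 AGA3 + 10 AGA5 + 10 AGA7 subjects
DEFAULT_N_SUBJECTS = {"Healthy": 51, "AGA3": 18, "AGA5": 10, "AGA7": 10}


@dataclass
class StageTemplate:
    """Mean genus composition (per kingdom) for one clinical stage."""

    stage: str
    composition: dict[str, pd.Series]  # kingdom -> probability vector

    def __post_init__(self):
        for kingdom, comp in self.composition.items():
            if kingdom not in KINGDOMS:
                raise ValueError(f"unknown kingdom {kingdom!r}")
            vals = comp.to_numpy(dtype=float)
            if (vals < 0).any() or vals.sum() <= 0:
                raise ValueError(f"degenerate {kingdom} template for {self.stage}")
            self.composition[kingdom] = comp / vals.sum()


@dataclass(frozen=True)
class AgeTrend:
    """Per-year logit-abundance slope of one genus, healthy subjects only."""

    taxon: str
    kingdom: str
    slope: float  # logit units per year

    def __post_init__(self):
        if not math.isfinite(self.slope):
            raise ValueError("age-trend slope must be finite")


@dataclass
class SyntheticConfig:
    n_subjects: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_SUBJECTS)
    )
    age_range: tuple[int, int] = (AGE_MIN, AGE_MAX)
    templates: dict[str, StageTemplate] = field(default_factory=dict)
    age_trends: tuple[AgeTrend, ...] = ()
    rho: float = 0.7  # within-subject region correlation
    concentration: float = 500.0  # Dirichlet precision
    depth: int = 100_000  # multinomial reads per sample per kingdom
    region_effect: float = 0.20  # healthy-only T/H logit perturbation

    def __post_init__(self):
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        for stage, n in self.n_subjects.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            if n < 1:
                raise ValueError("n_subjects must be >= 1 per stage")


# ---------------------------------------------------------------------------
# default templates
# ---------------------------------------------------------------------------

# Named genera with stage-dependent means (Healthy, AGA3, AGA5, AGA7).
# The stage-to-stage spacing is not arbitrary: under the MiSCH score
# formula the published category boundaries (75/25/15) are only mutually
# consistent when the healthy-to-stage JSD profile gives normalized
# weights w_AGA3 in roughly [0.25, 0.75) and w_AGA5 in [0.75, 0.85).
# These means realize that profile (measured w ~ (0, 0.33, 0.80, 1))
# while preserving the qualitative taxon dynamics of the study system.
_BACTERIA_MEANS = {
    "Propionibacterium": (0.30, 0.41, 0.47, 0.52),  # enriched with severity
    "Corynebacterium": (0.20, 0.115, 0.065, 0.040),  # strictly decreasing
    "Staphylococcus": (0.10, 0.090, 0.082, 0.080),
    "Macrococcus": (0.010, 0.050, 0.072, 0.085),  # strong stage discriminator
    "Micrococcus": (0.050, 0.038, 0.032, 0.028),
    "Paracoccus": (0.040, 0.034, 0.031, 0.028),
    "Rothia": (0.030, 0.024, 0.021, 0.018),
    "Acinetobacter": (0.030, 0.024, 0.021, 0.018),
    "Streptococcus": (0.040, 0.028, 0.022, 0.018),
    "Pseudomonas": (0.020, 0.020, 0.020, 0.020),
    "Lawsonella": (0.020, 0.020, 0.020, 0.020),
    "Enhydrobacter": (0.015, 0.015, 0.015, 0.015),
    "Kocuria": (0.015, 0.015, 0.015, 0.015),
    "Brevibacterium": (0.010, 0.010, 0.010, 0.010),
    "Dermacoccus": (0.010, 0.010, 0.010, 0.010),
    "Moraxella": (0.010, 0.010, 0.010, 0.010),
}

_FUNGI_MEANS = {
    "Malassezia": (0.60, 0.38, 0.21, 0.15),  # depleted with severity
    "Alternaria": (0.030, 0.110, 0.400, 0.580),  # >50% by AGA7
    "Aspergillus": (0.060, 0.130, 0.200, 0.080),  # peaks at AGA5
    "Cladosporium": (0.080, 0.068, 0.055, 0.048),
    "Candida": (0.050, 0.044, 0.033, 0.028),
    "Penicillium": (0.050, 0.040, 0.032, 0.028),
    "Fusarium": (0.030, 0.026, 0.021, 0.018),
    "Trichophyton": (0.020, 0.016, 0.011, 0.009),
}

_N_BACKGROUND = {"bacteria": 24, "fungi": 7}

#: age-correlated taxa in healthy subjects (logit units / year)
_DEFAULT_TRENDS = (
    AgeTrend("Paracoccus", "bacteria", 0.045),
    AgeTrend("Micrococcus", "bacteria", 0.035),
    AgeTrend("Rothia", "bacteria", -0.035),
    AgeTrend("Propionibacterium", "bacteria", -0.015),
    AgeTrend("Acinetobacter", "bacteria", 0.030),
    AgeTrend("Cladosporium", "fungi", 0.040),
)


def _broken_stick(n: int) -> np.ndarray:
    """Expected broken-stick proportions for n background taxa."""
    w = np.array([sum(1.0 / k for k in range(i + 1, n + 1)) for i in range(n)])
    return w / w.sum()


def _build_templates() -> dict[str, StageTemplate]:
    templates = {}
    for s_idx, stage in enumerate(STAGES):
        comp = {}
        for kingdom, means in (("bacteria", _BACTERIA_MEANS), ("fungi", _FUNGI_MEANS)):
            named = pd.Series({g: v[s_idx] for g, v in means.items()})
            residual = 1.0 - named.sum()
            if residual <= 0:
                raise ValueError("named genera exceed total mass")
            n_bg = _N_BACKGROUND[kingdom]
            prefix = "Bact" if kingdom == "bacteria" else "Fungi"
            bg = pd.Series(
                residual * _broken_stick(n_bg),
                index=[f"{prefix}_bg{i:02d}" for i in range(1, n_bg + 1)],
            )
            comp[kingdom] = pd.concat([named, bg])
        templates[stage] = StageTemplate(stage, comp)
    return templates


def default_config() -> SyntheticConfig:
    """The default study-like cohort: 89 subjects x 2 regions.

    Encodes the qualitative stage dynamics (Propionibacterium up,
    Corynebacterium/Malassezia down, Alternaria > 0.5 in AGA7, Aspergillus
    peaking at AGA5), healthy-only age trends in six genera, mild
    T/H distinction for healthy subjects and none for AGA stages.
    """
    return SyntheticConfig(templates=_build_templates(), age_trends=_DEFAULT_TRENDS)


def planted_feature_config(
    n_bacteria: int = 75,
    n_fungi: int = 25,
    n_informative_bacteria: int = 22,
    n_informative_fungi: int = 5,
    effects: tuple[float, float, float] = (0.9, 0.55, 0.38),
    concentration: float = 80.0,
) -> tuple[SyntheticConfig, list[str]]:
    """A cohort where only a known subset of genera carries stage signal.

    Returns the config and the list of informative genus names, for
    feature-selection recovery experiments.  The informative genera are
    organized in three tiers of decreasing effect size that resolve
    complementary contrasts — disease severity ({Healthy, AGA3} vs
    {AGA5, AGA7}), onset (Healthy vs AGA3), and late progression (AGA5 vs
    AGA7) — on the logit scale; all other genera are flat across stages.
    Because the weakest tier alone separates the two advanced stages,
    cross-validated kappa keeps improving until essentially the whole
    panel is included, which is the regime where prefix selection is a
    meaningful benchmark.  The benchmark cohort doubles the study design
    (200 subjects in the same stage proportions): resolving the marginal
    contribution of ~27 weak markers by cross-validation needs more
    statistical power than the 89-subject cohort provides.
    """
    contrasts = (
        np.array([-1.0, -1.0, 1.0, 1.0]),  # severity split
        np.array([-1.0, 1.0, 0.0, 0.0]),  # onset split
        np.array([0.0, 0.0, -1.0, 1.0]),  # late-progression split
    )
    base = {
        "bacteria": pd.Series(
            _broken_stick(n_bacteria),
            index=[f"PlantB_{i:03d}" for i in range(n_bacteria)],
        ),
        "fungi": pd.Series(
            _broken_stick(n_fungi),
            index=[f"PlantF_{i:03d}" for i in range(n_fungi)],
        ),
    }
    info_idx = {
        "bacteria": list(range(n_informative_bacteria)),
        "fungi": list(range(n_informative_fungi)),
    }
    informative: list[str] = []
    tier_of: dict[str, int] = {}
    for kingdom in KINGDOMS:
        names = [base[kingdom].index[i] for i in info_idx[kingdom]]
        informative.extend(names)
        # split each kingdom's panel roughly in thirds across the tiers
        n = len(names)
        cuts = (int(round(n * 0.36)), int(round(n * 0.68)))
        for i, name in enumerate(names):
            tier_of[name] = 0 if i < cuts[0] else (1 if i < cuts[1] else 2)
    sign_rng = np.random.default_rng(99)  # fixed: signs are part of the design
    signs = {n: (1.0 if sign_rng.random() < 0.5 else -1.0) for n in informative}
    templates = {}
    for s_idx, stage in enumerate(STAGES):
        comp = {}
        for kingdom in KINGDOMS:
            vec = base[kingdom].copy()
            for i in info_idx[kingdom]:
                name = vec.index[i]
                tier = tier_of[name]
                shift = signs[name] * effects[tier] * contrasts[tier][s_idx]
                vec.iloc[i] = expit(logit(min(vec.iloc[i], 0.999)) + shift)
            comp[kingdom] = vec / vec.sum()
        templates[stage] = StageTemplate(stage, comp)
    cfg = SyntheticConfig(
        templates=templates,
        age_trends=(),
        concentration=concentration,
        n_subjects={"Healthy": 100, "AGA3": 36, "AGA5": 20, "AGA7": 20},
    )
    return cfg, informative


# ---------------------------------------------------------------------------
# synthetic lineages (for taxonomic aggregation of generator output)
# ---------------------------------------------------------------------------


def default_lineages(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """A synthetic lineage table for the generator's genera.

    Every genus gets a made-up but internally consistent higher taxonomy:
    consecutive genera (per kingdom) share families in groups of three,
    families share orders in groups of two, and so on.  This is synthetic
    scaffolding for level-aggregation experiments, not a real taxonomy.
    """
    config = config or default_config()
    rows = []
    for kingdom in KINGDOMS:
        genera = list(config.templates[STAGES[0]].composition[kingdom].index)
        for i, genus in enumerate(genera):
            fam, order, cls, phyl = i // 3, i // 6, i // 12, i // 24
            tag = "B" if kingdom == "bacteria" else "F"
            rows.append(
                {
                    "taxon_id": genus,
                    "kingdom": kingdom,
                    "phylum": f"{tag}_phylum{phyl:02d}",
                    "class": f"{tag}_class{cls:02d}",
                    "order": f"{tag}_order{order:02d}",
                    "family": f"{tag}_family{fam:02d}",
                    "genus": genus,
                    "species": f"{genus}_sp",
                }
            )
    return pd.DataFrame(rows).set_index("taxon_id")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _apply_age_trends(
    comp: pd.Series, trends: list[AgeTrend], age: float, age_mid: float
) -> pd.Series:
    if not trends:
        return comp
    vec = comp.copy()
    for trend in trends:
        p = min(max(vec[trend.taxon], 1e-9), 1 - 1e-9)
        vec[trend.taxon] = expit(logit(p) + trend.slope * (age - age_mid))
    return vec / vec.sum()


def _region_template(
    comp: pd.Series, stage: str, region: str, effect: float
) -> pd.Series:
    """Mild fixed T/H perturbation for healthy subjects; AGA regions identical."""
    if stage != "Healthy" or region == "T" or effect == 0.0:
        return comp
    signs = np.where(np.arange(len(comp)) % 2 == 0, 1.0, -1.0)
    p = np.clip(comp.to_numpy(), 1e-9, 1 - 1e-9)
    vec = pd.Series(expit(logit(p) + effect * signs), index=comp.index)
    return vec / vec.sum()


def _sample_composition(
    rng: np.random.Generator, template: pd.Series, concentration: float
) -> np.ndarray:
    alpha = np.maximum(concentration * template.to_numpy(), 1e-9)
    return rng.dirichlet(alpha)


def simulate_cohort(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[AbundanceTable, AbundanceTable, CohortMetadata]:
    """Simulate a paired two-region cohort; deterministic under ``seed``.

    Per subject: an integer age is drawn uniformly from the configured
    range; the stage template (age-shifted for healthy subjects) seeds a
    subject-level Dirichlet draw; each region's composition is the mixture
    ``rho * subject + (1 - rho) * fresh`` with a fresh Dirichlet draw from
    the region template; counts are multinomial at the configured depth
    and renormalized.
    """
    config = config or default_config()
    if not config.templates:
        raise ValueError("config has no stage templates")
    rng = child_rng(seed, "simulate")
    age_lo, age_hi = config.age_range
    age_mid = (age_lo + age_hi) / 2.0

    meta_rows = []
    rel = {k: [] for k in KINGDOMS}
    sample_index = []
    subj_no = 0
    for stage in STAGES:
        n = config.n_subjects.get(stage, 0)
        template = config.templates[stage]
        trends = [t for t in config.age_trends] if stage == "Healthy" else []
        for _ in range(n):
            subj_no += 1
            subject_id = f"S{subj_no:03d}"
            age = int(rng.integers(age_lo, age_hi + 1))
            subject_comp = {}
            for kingdom in KINGDOMS:
                comp = template.composition[kingdom]
                comp = _apply_age_trends(comp, [t for t in trends if t.kingdom == kingdom], age, age_mid)
                subject_comp[kingdom] = (comp, _sample_composition(rng, comp, config.concentration))
            for region in ("T", "H"):
                sample_id = f"{subject_id}_{region}"
                sample_index.append(sample_id)
                meta_rows.append(
                    {"sample_id": sample_id, "subject_id": subject_id,
                     "region": region, "age": age, "stage": stage}
                )
                for kingdom in KINGDOMS:
                    base_comp, subj_draw = subject_comp[kingdom]
                    reg_comp = _region_template(
                        base_comp, stage, region, config.region_effect
                    )
                    fresh = _sample_composition(rng, reg_comp, config.concentration)
                    mix = config.rho * subj_draw + (1.0 - config.rho) * fresh
                    mix = mix / mix.sum()
                    counts = rng.multinomial(config.depth, mix)
                    rel[kingdom].append(counts / counts.sum())

    tables = {}
    for kingdom in KINGDOMS:
        taxa = config.templates[STAGES[0]].composition[kingdom].index
        df = pd.DataFrame(rel[kingdom], index=sample_index, columns=taxa)
        tables[kingdom] = AbundanceTable(df, kingdom, "genus").normalize()
    metadata = CohortMetadata(pd.DataFrame(meta_rows))
    return tables["bacteria"], tables["fungi"], metadata


def inject_high_risk(
    bacterial: AbundanceTable,
    fungal: AbundanceTable,
    metadata: CohortMetadata,
    n: int = 10,
    from_stage: str = "AGA5",
    to_stage: str = "AGA7",
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> tuple[AbundanceTable, AbundanceTable, CohortMetadata, list[str]]:
    """Append ``n`` samples drawn from ``to_stage`` but labeled ``from_stage``.

    These mimic high-risk subjects whose microbiome has already progressed
    past their clinical presentation.  New subjects carry both regions
    (last subject gets a single T sample when ``n`` is odd).  Returns the
    augmented tables/metadata plus the ground-truth list of injected
    sample ids.
    """
    if stage_index(from_stage) >= stage_index(to_stage):
        raise ValueError(
            f"from_stage {from_stage!r} must be less severe than to_stage {to_stage!r}"
        )
    if n == 0:
        return bacterial, fungal, metadata, []
    if n < 0:
        raise ValueError("n must be >= 0")
    config = config or default_config()
    rng = child_rng(seed, "inject_high_risk")
    template = config.templates[to_stage]
    age_lo, age_hi = config.age_range

    rows_b, rows_f, meta_rows, truth = [], [], [], []
    n_subjects = (n + 1) // 2
    for i in range(n_subjects):
        subject_id = f"INJ{i + 1:03d}"
        age = int(rng.integers(age_lo, age_hi + 1))
        draws = {
            k: _sample_composition(rng, template.composition[k], config.concentration)
            for k in KINGDOMS
        }
        regions = ("T", "H") if (2 * i + 2) <= n else ("T",)
        for region in regions:
            sample_id = f"{subject_id}_{region}"
            truth.append(sample_id)
            meta_rows.append(
                {"sample_id": sample_id, "subject_id": subject_id,
                 "region": region, "age": age, "stage": from_stage}
            )
            for kingdom, rows in (("bacteria", rows_b), ("fungi", rows_f)):
                fresh = _sample_composition(
                    rng, template.composition[kingdom], config.concentration
                )
                mix = config.rho * draws[kingdom] + (1.0 - config.rho) * fresh
                counts = rng.multinomial(config.depth, mix / mix.sum())
                rows.append(counts / counts.sum())

    def _extend(table: AbundanceTable, rows: list[np.ndarray], kingdom: str):
        extra = pd.DataFrame(rows, index=truth, columns=table.taxon_ids)
        data = pd.concat([table.data, extra])
        return AbundanceTable(data, kingdom, table.level).normalize()

    new_b = _extend(bacterial, rows_b, "bacteria")
    new_f = _extend(fungal, rows_f, "fungi")
    new_meta = CohortMetadata(
        pd.concat([metadata.df.reset_index(), pd.DataFrame(meta_rows)]).set_index(
            "sample_id"
        )
    )
    return new_b, new_f, new_meta, truth
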