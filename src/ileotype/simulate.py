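"""Synthetic ileal-microbiome cohorts with known enterotype structure.

Generates genus-level count tables, growth/carcass phenotypes and true
component labels that mirror the statistical structure the downstream
analysis assumes: a 200-duck cohort split into three communities of 76,
67 and 57 samples whose dominant genera are Streptococcus (17.40%, with
Vibrio at 12.20%), Candidatus Arthromitus (33.39%) and Bacteroides
(30.94%); sequencing depths uniform on [21,243, 59,481]; the
Bacteroides community carrying extra rare genera (higher richness) and a
higher leg-muscle weight; and genus-trait couplings (Lactococcus,
Bradyrhizobium) expressed on the Spearman scale through a Gaussian
copula.

Counts follow a Dirichlet-multinomial: within a component, each sample's
genus proportions are Dirichlet(theta * mean) draws, then counts are
multinomial at the sample's depth.  theta is the Dirichlet precision -
large theta pins samples to the component mean, small theta makes the
community noisy.  The default theta=60 gives separable but realistically
overlapping clusters.

All randomness flows from one integer seed; sub-streams for the count
and phenotype stages are derived with fixed offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .abundance import AbundanceTable, PhenotypeTable, derive_carcass_traits

__all__ = [
    "CommunityTemplate",
    "EffectConfig",
    "SyntheticCohort",
    "build_default_template",
    "simulate_counts",
    "simulate_phenotypes",
    "simulate_correlated_pair",
    "simulate_cohort",
    "spearman_to_pearson",
]

#: Genera named as dominants of the three ileal enterotypes and the
#: cohort-wide abundant genera they co-occur with.
NAMED_GENERA = (
    "Streptococcus",
    "Vibrio",
    "Candidatus Arthromitus",
    "Bacteroides",
    "Romboutsia",
    "Cetobacterium",
    "Clostridium sensu stricto 1",
    "Terrisporobacter",
    "Escherichia-Shigella",
    "Lactobacillus",
    "Enterococcus",
    "Turicibacter",
    "Lactococcus",
    "Bradyrhizobium",
)

#: Planted dominant means per component (fraction of community).
COMPONENT_DOMINANTS = (
    {"Streptococcus": 0.1740, "Vibrio": 0.1220},
    {"Candidatus Arthromitus": 0.3339},
    {"Bacteroides": 0.3094},
)

DEFAULT_COMPONENT_SIZES = (76, 67, 57)
DEFAULT_DEPTH_RANGE = (21243, 59481)
DEFAULT_THETA = 60.0
DEFAULT_N_FILLER = 100
DEFAULT_RICHNESS_BOOST = 30
BOOST_MEAN_ABUNDANCE = 1e-4

# deterministic evenness profile of the non-dominant mass: geometric decay
# over the other named genera (shared ratio) and over the filler tail.
# the Bacteroides community gets a flatter filler tail - it is the
# high-diversity enterotype - so its Shannon/Chao1 exceed the other two.
NAMED_DECAY = 0.55
NAMED_SHARE = 0.45
FILLER_DECAY = (0.85, 0.85, 0.98)


@dataclass
class CommunityTemplate:
    """Mixture template: per-component genus means, sizes and depths."""

    genus_names: list[str]
    component_means: np.ndarray          # n_components x n_genera
    component_sizes: tuple[int, ...] = DEFAULT_COMPONENT_SIZES
    concentration: tuple[float, ...] = (DEFAULT_THETA,) * 3
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE
    richness_boost: int = DEFAULT_RICHNESS_BOOST

    def __post_init__(self) -> None:
        self.component_means = np.asarray(self.component_means, dtype=float)
        k, g = self.component_means.shape
        if g != len(self.genus_names):
            raise ValueError("component_means width does not match genus list")
        if len(self.component_sizes) != k or len(self.concentration) != k:
            raise ValueError("sizes/concentration do not match component count")
        if (self.component_means < 0).any():
            raise ValueError("component means must be non-negative")
        if not np.allclose(self.component_means.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every component mean vector must sum to 1")
        if any(s <= 0 for s in self.component_sizes):
            raise ValueError("component sizes must be positive")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] <= 0:
            raise ValueError("invalid depth range")

    @property
    def n_components(self) -> int:
        return self.component_means.shape[0]

    @property
    def cohort_size(self) -> int:
        return int(sum(self.component_sizes))

    def dominant_genus(self, component: int) -> str:
        """Genus with the largest mean in ``component`` (0-based)."""
        return self.genus_names[int(np.argmax(self.component_means[component]))]


@dataclass
class EffectConfig:
    """Phenotype effect sizes.

    ``leg_muscle_shift_g`` is the additive leg-muscle-weight advantage of
    the third (Bacteroides) community in grams; the ``rho_*`` fields are
    target Spearman correlations injected through the Gaussian copula
    (realised correlations are mildly attenuated by body-weight noise and
    abundance ties; see docs).
    """

    leg_muscle_shift_g: float = 30.0
    rho_lactococcus_leg: float = 0.35
    rho_lactococcus_dressed: float = 0.30
    rho_lactococcus_eviscerated_yield: float = 0.25
    rho_bradyrhizobium_eviscerated_yield: float = 0.40

    # cohort-level trait scale (grams / fractions), shared by all components
    body_weight_mean: float = 2400.0
    body_weight_sd: float = 180.0
    dressed_fraction: float = 0.88
    dressed_fraction_sd: float = 0.012
    eviscerated_fraction: float = 0.74
    eviscerated_fraction_sd: float = 0.012
    leg_fraction: float = 0.11
    leg_fraction_sd: float = 0.008
    breast_fraction: float = 0.15
    breast_fraction_sd: float = 0.010

    @classmethod
    def null(cls) -> "EffectConfig":
        """No enterotype effect and no genus-trait coupling."""
        return cls(leg_muscle_shift_g=0.0, rho_lactococcus_leg=0.0,
                   rho_lactococcus_dressed=0.0,
                   rho_lactococcus_eviscerated_yield=0.0,
                   rho_bradyrhizobium_eviscerated_yield=0.0)


@dataclass
class SyntheticCohort:
    """Bundle of generated abundance, phenotypes and ground truth."""

    abundance: AbundanceTable
    true_labels: np.ndarray
    seed: int
    template: CommunityTemplate
    phenotypes: PhenotypeTable | None = None
    meta: dict = field(default_factory=dict)


def build_default_template(
    component_sizes: tuple[int, ...] = DEFAULT_COMPONENT_SIZES,
    theta: float | tuple[float, ...] = DEFAULT_THETA,
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE,
    n_filler: int = DEFAULT_N_FILLER,
    richness_boost: int = DEFAULT_RICHNESS_BOOST,
) -> CommunityTemplate:
    """Three-component template with the planted dominant-genus means.

    Component 1 carries Streptococcus 17.40% and Vibrio 12.20%,
    component 2 Candidatus Arthromitus 33.39%, component 3 Bacteroides
    30.94%.  The remaining mass is split deterministically: 60% over the
    other named genera with geometric decay 0.8 (the genus order rotated
    per component so each community has its own co-dominants) and 40%
    over ``n_filler`` filler genera with a geometric tail.  Component 3
    additionally carries ``richness_boost`` rare genera at mean relative
    abundance 1e-4 each.
    """
    if isinstance(theta, (int, float)):
        theta = (float(theta),) * len(component_sizes)
    fillers = [f"SimGenus_{i+1:03d}" for i in range(n_filler)]
    rares = [f"RareGenus_{i+1:03d}" for i in range(richness_boost)]
    genera = list(NAMED_GENERA) + fillers + rares
    gi = {g: i for i, g in enumerate(genera)}
    k = len(component_sizes)
    means = np.zeros((k, len(genera)))
    for c in range(k):
        dom = COMPONENT_DOMINANTS[c] if c < len(COMPONENT_DOMINANTS) else {}
        for g, m in dom.items():
            means[c, gi[g]] = m
        boost_mass = richness_boost * BOOST_MEAN_ABUNDANCE if c == 2 else 0.0
        if c == 2 and richness_boost:
            means[c, [gi[r] for r in rares]] = BOOST_MEAN_ABUNDANCE
        remaining = 1.0 - sum(dom.values()) - boost_mass
        others = [g for g in NAMED_GENERA if g not in dom]
        others = others[5 * c % len(others):] + others[:5 * c % len(others)]
        w_named = NAMED_DECAY ** np.arange(len(others))
        w_named = w_named / w_named.sum() * (NAMED_SHARE * remaining)
        for g, w in zip(others, w_named):
            means[c, gi[g]] = w
        if n_filler:
            rot = (31 * c) % n_filler
            order = fillers[rot:] + fillers[:rot]
            decay = FILLER_DECAY[c % len(FILLER_DECAY)]
            w_fill = decay ** np.arange(n_filler)
            w_fill = w_fill / w_fill.sum() * ((1.0 - NAMED_SHARE) * remaining)
            for g, w in zip(order, w_fill):
                means[c, gi[g]] = w
    means = means / means.sum(axis=1, keepdims=True)
    return CommunityTemplate(genera, means, tuple(component_sizes),
                             tuple(theta), tuple(depth_range), richness_boost)


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, offset])


def simulate_counts(template: CommunityTemplate, seed: int) -> SyntheticCohort:
    """Draw a Dirichlet-multinomial count table from the template.

    Per sample of component c: proportions ~ Dirichlet(theta_c * mean_c)
    (taxa with zero mean stay exactly zero), depth ~ uniform integer on
    the depth range, counts ~ Multinomial(depth, proportions).  For the
    third component the rare richness-boost genera enter the proportion
    vector as a fixed 1e-4 admixture rather than through the Dirichlet,
    so they reliably seed nonzero counts.
    """
    if any(t <= 0 for t in template.concentration):
        raise ValueError("Dirichlet precision theta must be > 0")
    rng = _rng(seed, 10)
    g = len(template.genus_names)
    n = template.cohort_size
    counts = np.zeros((g, n), dtype=np.int64)
    labels = np.zeros(n, dtype=int)
    rare_mask = np.array([t.startswith("RareGenus_") for t in template.genus_names])
    col = 0
    for c, size in enumerate(template.component_sizes):
        mean = template.component_means[c].copy()
        theta = template.concentration[c]
        boost = np.zeros(g)
        if c == 2 and template.richness_boost:
            boost[rare_mask] = mean[rare_mask]
            mean = np.where(rare_mask, 0.0, mean)
            mean = mean / mean.sum()
        nz = mean > 0
        alpha = theta * mean[nz]
        depths = rng.integers(template.depth_range[0],
                              template.depth_range[1] + 1, size=size)
        for s in range(size):
            p = np.zeros(g)
            p[nz] = rng.dirichlet(alpha)
            p = p * (1.0 - boost.sum()) + boost
            counts[:, col] = rng.multinomial(depths[s], p / p.sum())
            labels[col] = c + 1
            col += 1
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    table = AbundanceTable(counts, list(template.genus_names), sample_ids,
                           mode="counts", level="genus")
    return SyntheticCohort(table, labels, int(seed), template)


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula relation r = 2*sin(pi*rho_s/6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _normal_scores(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Copula normal scores of a vector; exact-zero ties are broken by a
    reproducible jitter so the scores stay continuous."""
    v = np.asarray(v, dtype=float)
    jitter = rng.uniform(0, 1e-12, size=v.shape) * (np.ptp(v) + 1.0)
    r = pd.Series(v + jitter).rank(method="average").to_numpy()
    return ndtri(r / (len(v) + 1.0))


def simulate_phenotypes(labels, abundance: AbundanceTable,
                        effects: EffectConfig | None = None,
                        seed: int = 0) -> PhenotypeTable:
    """Generate growth and carcass traits coupled to the community.

    Body weight is one shared normal with no enterotype effect.  Dressed,
    eviscerated, leg- and breast-muscle weights are body weight times
    noisy fractions; the third component receives an additive leg-muscle
    shift.  Lactococcus couples positively to leg-muscle weight, dressed
    weight and eviscerated yield, Bradyrhizobium to eviscerated yield,
    each at its configured target Spearman rho through a Gaussian copula
    on abundance ranks.  Derived percentages come from
    :func:`derive_carcass_traits`, so they are exactly consistent with
    the weights.
    """
    effects = effects or EffectConfig()
    labels = np.asarray(labels)
    if len(labels) != abundance.n_samples:
        raise ValueError("labels are not aligned with the abundance samples")
    rng = _rng(seed, 20)
    n = abundance.n_samples

    def genus_scores(name: str) -> np.ndarray:
        if name in abundance.taxon_ids:
            return _normal_scores(abundance.values[abundance.taxon_ids.index(name)], rng)
        return rng.standard_normal(n)

    z_lac = genus_scores("Lactococcus")
    z_brady = genus_scores("Bradyrhizobium")

    def mix(loadings: list[tuple[np.ndarray, float]]) -> np.ndarray:
        total = sum(spearman_to_pearson(r) ** 2 for _, r in loadings)
        if total >= 1.0:
            raise ValueError("copula loadings exceed unit variance")
        z = rng.standard_normal(n) * math.sqrt(1.0 - total)
        for score, r in loadings:
            z = z + spearman_to_pearson(r) * score
        return np.clip(z, -4.0, 4.0)

    body = effects.body_weight_mean + effects.body_weight_sd * np.clip(
        rng.standard_normal(n), -4.0, 4.0)
    dressed_frac = effects.dressed_fraction + effects.dressed_fraction_sd * mix(
        [(z_lac, effects.rho_lactococcus_dressed)])
    evisc_frac = effects.eviscerated_fraction + effects.eviscerated_fraction_sd * mix(
        [(z_brady, effects.rho_bradyrhizobium_eviscerated_yield),
         (z_lac, effects.rho_lactococcus_eviscerated_yield)])
    leg_frac = effects.leg_fraction + effects.leg_fraction_sd * mix(
        [(z_lac, effects.rho_lactococcus_leg)])
    breast_frac = effects.breast_fraction + effects.breast_fraction_sd * np.clip(
        rng.standard_normal(n), -4.0, 4.0)

    dressed = body * dressed_frac
    evisc = body * evisc_frac
    leg = evisc * leg_frac + effects.leg_muscle_shift_g * (labels == 3)
    breast = evisc * breast_frac
    raw = pd.DataFrame({
        "body_weight": body,
        "dressed_weight": dressed,
        "eviscerated_weight": evisc,
        "breast_muscle_weight": breast,
        "leg_muscle_weight": leg,
    }, index=list(abundance.sample_ids))
    return derive_carcass_traits(raw)


def simulate_correlated_pair(n: int, rho_s: float, seed: int = 0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate normal pair whose population Spearman correlation is
    ``rho_s`` (Pearson r = 2 sin(pi rho_s / 6))."""
    if n < 10:
        raise ValueError("need n >= 10")
    if not -1.0 < rho_s < 1.0:
        raise ValueError("rho_s must lie strictly inside (-1, 1)")
    r = spearman_to_pearson(rho_s)
    rng = _rng(seed, 30)
    x = rng.standard_normal(n)
    y = r * x + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return x, y


def simulate_cohort(template: CommunityTemplate | None = None,
                    effects: EffectConfig | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Counts + labels + phenotypes in one call (the default study cohort)."""
    template = template or build_default_template()
    cohort = simulate_counts(template, seed)
    cohort.phenotypes = simulate_phenotypes(cohort.true_labels,
                                            cohort.abundance, effects, seed)
    cohort.meta["effects"] = asdict(effects or EffectConfig())
    return cohort
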