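"""Synthetic plasma, fractionation and omics generators.

This module provides a ground-truth test bed for the downstream analytics:

* a particle-level plasma model (EV, HDL, APOB-carrying lipoproteins and a
  soluble-protein background) with realistic concentrations — roughly 1e10
  EV per ml against a lipoprotein pool about six orders of magnitude more
  concentrated, and >90 % of protein mass in a few abundant soluble species;
* size-exclusion chromatography (SEC) simulated as a discretized Gaussian
  elution kernel whose peak fraction decreases log-linearly with particle
  size, calibrated so that the EV marker CD9 peaks in fractions 5–6 (~73 %
  recovered there) while APOA1-carrying HDL elutes from fraction 7 onwards
  (~1.4 % in 5–6);
* density-gradient banding (ODG) as a Gaussian over the fraction densities,
  placing lipoproteins in the 1.04–1.07 g/ml window and EV at
  1.09–1.10 g/ml;
* grouped log2 LFQ intensity matrices with planted group shifts and
  intensity-dependent (missing-not-at-random) dropout;
* negative-binomial small-RNA count matrices with a biotype/tRNA-isotype
  composition per group — the plasma tRNA pool dominated by the Gly isotype —
  planted HDL/platelet miRNA signatures and an optional decaying time-course
  miRNA.

Everything is deterministic given the seed passed to each generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fracmetrics import FractionationRun

__all__ = [
    "ParticleClass",
    "PlasmaModel",
    "SECColumnModel",
    "DensityGradientModel",
    "OmicsDesign",
    "Extract",
    "StageSimulation",
    "make_default_plasma",
    "simulate_sec",
    "pool_extract",
    "simulate_odg",
    "simulate_lfq",
    "simulate_smallrna",
    "default_smallrna_composition",
    "default_gene_sets",
    "default_proteomics_design",
    "TRNA_ISOTYPES",
    "ESSENTIAL_AA",
]

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_CATEGORIES = {"EV", "HDL", "APOB_LPP", "soluble_protein", "spike_in"}


@dataclass(frozen=True)
class ParticleClass:
    """One particle population in plasma.

    ``payload`` maps marker names to the amount carried per particle
    (arbitrary mass units); ``size_median_nm``/``size_gsd`` parameterize a
    log-normal size distribution and ``density_mean``/``density_sd`` a normal
    buoyant-density distribution in g/ml.
    """

    name: str
    category: str
    concentration: float  # particles per ml plasma
    size_median_nm: float
    size_gsd: float
    density_mean: float
    density_sd: float
    payload: Mapping[str, float] = field(default_factory=dict)
    nta_visible: bool = True  # counted by nanoparticle tracking

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.size_median_nm <= 0:
            raise ValueError("median size must be > 0")
        if not (0.95 <= self.density_mean <= 1.35):
            raise ValueError("density mean outside [0.95, 1.35] g/ml")
        if any(v < 0 for v in self.payload.values()):
            raise ValueError("payload amounts must be >= 0")


@dataclass(frozen=True)
class PlasmaModel:
    """A plasma sample: particle classes plus a soluble-protein background."""

    volume_ml: float
    classes: tuple[ParticleClass, ...]
    background_protein_per_ml: float = 70_000.0  # µg/ml; dominated by albumin etc.
    albumin_fraction: float = 0.55
    background_size_nm: float = 5.0
    background_density_mean: float = 1.015
    background_density_sd: float = 0.012

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("plasma volume must be > 0")
        names = [c.name for c in self.classes]
        if len(names) != len(set(names)):
            raise ValueError("particle class names must be unique")

    def class_by_name(self, name: str) -> ParticleClass:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def markers(self) -> list[str]:
        # the "protein" payload key contributes to bulk protein mass, not to
        # the marker columns
        seen: dict[str, None] = {}
        for c in self.classes:
            for m in c.payload:
                if m != "protein":
                    seen.setdefault(m, None)
        seen.setdefault("ALB", None)
        return list(seen)


@dataclass(frozen=True)
class SECColumnModel:
    """Size-exclusion column with a size-dependent Gaussian elution kernel.

    The peak fraction of a particle class decreases log-linearly with its
    median size: ``mean = peak_intercept - peak_slope * log10(size_nm)``;
    the kernel spread widens for small species the same way.  Weights are
    the Gaussian mass in each unit fraction window, renormalized over the
    available fractions to sum to ``1 - loss_fraction``.
    """

    n_fractions: int = 16
    fraction_volume_ml: float = 1.0
    capacity_ml: float = 2.0
    loss_fraction: float = 0.0
    peak_intercept: float = 13.2065
    peak_slope: float = 3.7065
    spread_intercept: float = 1.6706
    spread_slope: float = 0.3706
    min_spread: float = 0.35
    noise_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("need at least 2 fractions")
        if not (0 <= self.loss_fraction < 1):
            raise ValueError("loss_fraction must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def elution_weights(self, size_nm: float) -> np.ndarray:
        """Per-fraction weights for a species of the given size."""
        log_size = math.log10(size_nm)
        mean = self.peak_intercept - self.peak_slope * log_size
        sd = max(self.spread_intercept - self.spread_slope * log_size, self.min_spread)
        edges = np.arange(0.5, self.n_fractions + 1.5)
        cdf = stats.norm.cdf(edges, loc=mean, scale=sd)
        weights = np.diff(cdf)
        total = weights.sum()
        if total <= 0:
            raise ValueError("elution kernel has no mass inside the column")
        return weights / total * (1.0 - self.loss_fraction)


@dataclass(frozen=True)
class DensityGradientModel:
    """Density gradient with fixed per-fraction densities and Gaussian banding."""

    n_fractions: int = 16
    fraction_densities: tuple[float, ...] = (
        1.01, 1.02, 1.03, 1.04, 1.05, 1.06, 1.07, 1.08,
        1.09, 1.10, 1.11, 1.13, 1.15, 1.18, 1.22, 1.27,
    )
    fraction_volume_ml: float = 1.0
    loss_fraction: float = 0.0
    noise_cv: float = 0.10

    def __post_init__(self) -> None:
        dens = np.asarray(self.fraction_densities, dtype=float)
        if len(dens) != self.n_fractions:
            raise ValueError("fraction_densities length must equal n_fractions")
        if np.any(np.diff(dens) < 0):
            raise ValueError("fraction densities must be monotone non-decreasing")
        if np.any(dens < 1.00) or np.any(dens > 1.30):
            raise ValueError("fraction densities must lie in [1.00, 1.30] g/ml")
        if not (0 <= self.loss_fraction < 1):
            raise ValueError("loss_fraction must be in [0, 1)")

    def banding_weights(self, density_mean: float, density_sd: float) -> np.ndarray:
        """Gaussian banding weights over the fraction densities, renormalized."""
        dens = np.asarray(self.fraction_densities, dtype=float)
        pdf = stats.norm.pdf(dens, loc=density_mean, scale=max(density_sd, 1e-6))
        total = pdf.sum()
        if total <= 0:
            raise ValueError("banding kernel has no mass on the gradient")
        return pdf / total * (1.0 - self.loss_fraction)


@dataclass(frozen=True)
class OmicsDesign:
    """Design of a grouped omics matrix with planted effects.

    ``planted_effects`` maps feature id -> {group label -> log2 shift} (LFQ)
    or -> {group label -> fold multiplier} (counts).  ``dropout_scale = None``
    disables dropout.  For counts, ``dispersion`` is the NB dispersion alpha
    in var = mu + alpha * mu^2; zero falls back to Poisson.
    """

    groups: Mapping[str, int]
    n_features: int = 500
    baseline_mean: float = 26.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    planted_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    dropout_location: float = 22.0
    dropout_scale: float | None = 0.8
    dispersion: float = 0.1
    library_size: float = 5e5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ValueError("at least one group required")
        if any(n < 2 for n in self.groups.values()):
            raise ValueError("replicate counts must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def sample_ids(self) -> list[str]:
        return [f"{g}_{i + 1}" for g, n in self.groups.items() for i in range(n)]

    def sample_groups(self) -> pd.Series:
        labels = [g for g, n in self.groups.items() for _ in range(n)]
        return pd.Series(labels, index=self.sample_ids(), name="group")


@dataclass
class Extract:
    """Pooled material from selected fractions, resolved per particle class."""

    name: str
    class_particles: dict[str, float]  # particles per class in the pool
    background_protein: float  # µg soluble background in the pool
    plasma: PlasmaModel  # carries payload/density definitions

    def marker_total(self, marker: str) -> float:
        total = 0.0
        for cname, particles in self.class_particles.items():
            payload = self.plasma.class_by_name(cname).payload
            total += particles * payload.get(marker, 0.0)
        if marker == "ALB":
            total += self.background_protein * self.plasma.albumin_fraction
        return total

    def totals(self) -> dict[str, float]:
        out = {
            "particles": sum(
                p
                for c, p in self.class_particles.items()
                if self.plasma.class_by_name(c).nta_visible
            ),
            "protein": self.background_protein
            + sum(
                p * self.plasma.class_by_name(c).payload.get("protein", 0.0)
                for c, p in self.class_particles.items()
            ),
        }
        for m in self.plasma.markers:
            out[m] = self.marker_total(m)
        return out


@dataclass
class StageSimulation:
    """A simulated separation stage: the measured run plus noise-free truth."""

    run: FractionationRun
    class_profiles: pd.DataFrame  # classes x fractions, true particle counts
    background_profile: np.ndarray  # true soluble protein µg per fraction
    plasma: PlasmaModel


# ---------------------------------------------------------------------------
# default plasma
# ---------------------------------------------------------------------------

def make_default_plasma(seed: int = 0, volume_ml: float = 2.0) -> PlasmaModel:
    """Default plasma composition used throughout the test bed.

    EV at 1e10 particles/ml; HDL plus APOB-carrying lipoproteins about six
    orders of magnitude more concentrated in total; EV buoyant density
    centred in the 1.09–1.10 g/ml window, lipoproteins in 1.04–1.07 g/ml.
    The model is deterministic — the seed is accepted for interface symmetry
    with the stochastic generators and reserved for future randomized
    compositions.
    """
    del seed  # composition defaults are fixed
    ev = ParticleClass(
        name="EV",
        category="EV",
        concentration=1e10,
        size_median_nm=120.0,
        size_gsd=1.5,
        density_mean=1.095,
        density_sd=0.007,
        payload={"CD9": 1.0, "FLOT1": 0.6, "protein": 1e-11},
        nta_visible=True,
    )
    hdl = ParticleClass(
        name="HDL",
        category="HDL",
        concentration=1.5e16,
        size_median_nm=10.0,
        size_gsd=1.2,
        density_mean=1.055,
        density_sd=0.010,
        payload={"APOA1": 8.7e-14, "protein": 1.5e-13},
        nta_visible=False,  # below the NTA detection range
    )
    apob = ParticleClass(
        name="APOB_LPP",
        category="APOB_LPP",
        concentration=1.0e15,
        size_median_nm=25.0,
        size_gsd=1.4,
        density_mean=1.052,
        density_sd=0.007,
        payload={"APOB": 5.5e-13, "protein": 6.0e-13},
        nta_visible=True,
    )
    return PlasmaModel(volume_ml=volume_ml, classes=(ev, hdl, apob))


# ---------------------------------------------------------------------------
# fractionation simulators
# ---------------------------------------------------------------------------

def _measure(true_amounts: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal measurement noise with the given CV."""
    if cv <= 0:
        return true_amounts.copy()
    sigma = math.sqrt(math.log(1.0 + cv**2))
    mu = -0.5 * sigma**2  # unit-mean log-normal
    return true_amounts * rng.lognormal(mean=mu, sigma=sigma, size=true_amounts.shape)


def _assemble_run(
    stage: str,
    plasma: PlasmaModel,
    class_profiles: pd.DataFrame,
    background_profile: np.ndarray,
    reference: dict[str, float],
    volumes: np.ndarray,
    densities: np.ndarray | None,
    noise_cv: float,
    rng: np.random.Generator,
) -> FractionationRun:
    n = class_profiles.shape[1]
    particle_true = np.zeros(n)
    protein_true = background_profile.astype(float).copy()
    marker_true = {m: np.zeros(n) for m in plasma.markers}
    marker_true["ALB"] += background_profile * plasma.albumin_fraction
    for cname, row in class_profiles.iterrows():
        cls = plasma.class_by_name(str(cname))
        counts = row.to_numpy(dtype=float)
        if cls.nta_visible:
            particle_true += counts
        protein_true += counts * cls.payload.get("protein", 0.0)
        for m, per_particle in cls.payload.items():
            if m == "protein":
                continue
            marker_true[m] += counts * per_particle
    table = pd.DataFrame(
        {
            "fraction_id": np.arange(1, n + 1),
            "volume_ml": volumes,
            "density_g_ml": densities if densities is not None else np.nan,
            "particle_count": _measure(particle_true, noise_cv, rng),
            "protein_mass": _measure(protein_true, noise_cv, rng),
        }
    )
    for m in plasma.markers:
        table[m] = _measure(marker_true[m], noise_cv, rng)
    return FractionationRun(stage=stage, reference=reference, fractions=table)


def simulate_sec(
    plasma: PlasmaModel, column: SECColumnModel | None = None, seed: int = 0
) -> StageSimulation:
    """Simulate SEC elution of a plasma sample into sequential fractions.

    Each particle class and the soluble background distribute over fractions
    according to the column's size-dependent elution kernel.  The measured
    table carries multiplicative log-normal noise (``column.noise_cv``);
    the noise-free per-class truth is kept alongside for calibration checks.
    """
    column = column or SECColumnModel()
    if plasma.volume_ml > column.capacity_ml:
        raise ValueError(
            f"plasma volume {plasma.volume_ml} ml exceeds column capacity "
            f"{column.capacity_ml} ml"
        )
    rng = np.random.default_rng(seed)
    profiles = {}
    for cls in plasma.classes:
        total = cls.concentration * plasma.volume_ml
        profiles[cls.name] = total * column.elution_weights(cls.size_median_nm)
    class_profiles = pd.DataFrame.from_dict(profiles, orient="index")
    class_profiles.columns = np.arange(1, column.n_fractions + 1)
    background_total = plasma.background_protein_per_ml * plasma.volume_ml
    background_profile = background_total * column.elution_weights(plasma.background_size_nm)

    reference = {
        "particles": sum(
            c.concentration * plasma.volume_ml for c in plasma.classes if c.nta_visible
        ),
        "protein": background_total
        + sum(
            c.concentration * plasma.volume_ml * c.payload.get("protein", 0.0)
            for c in plasma.classes
        ),
    }
    for m in plasma.markers:
        total = sum(
            c.concentration * plasma.volume_ml * c.payload.get(m, 0.0) for c in plasma.classes
        )
        if m == "ALB":
            total += background_total * plasma.albumin_fraction
        reference[m] = total

    volumes = np.full(column.n_fractions, column.fraction_volume_ml)
    run = _assemble_run(
        "SEC", plasma, class_profiles, background_profile, reference, volumes, None,
        column.noise_cv, rng,
    )
    return StageSimulation(
        run=run,
        class_profiles=class_profiles,
        background_profile=background_profile,
        plasma=plasma,
    )


def pool_extract(
    sim: StageSimulation, fraction_ids: Sequence[int], name: str = "crude"
) -> Extract:
    """Pool selected fractions of a simulated stage into an extract."""
    ids = [int(f) for f in fraction_ids]
    missing = [f for f in ids if f not in sim.class_profiles.columns]
    if missing:
        raise ValueError(f"fraction ids {missing} not present")
    class_particles = {
        str(c): float(sim.class_profiles.loc[c, ids].sum()) for c in sim.class_profiles.index
    }
    background = float(sim.background_profile[[f - 1 for f in ids]].sum())
    return Extract(
        name=name,
        class_particles=class_particles,
        background_protein=background,
        plasma=sim.plasma,
    )


def simulate_odg(
    extract: Extract, gradient: DensityGradientModel | None = None, seed: int = 0
) -> StageSimulation:
    """Simulate density-gradient banding of a pooled extract.

    Each particle class bands around its buoyant-density mean with its
    density sd; the soluble background remains in the light top fractions.
    """
    gradient = gradient or DensityGradientModel()
    totals = extract.totals()
    if all(v == 0 for v in totals.values()):
        raise ValueError("extract carries no analyte mass")
    rng = np.random.default_rng(seed)
    profiles = {}
    for cname, particles in extract.class_particles.items():
        cls = extract.plasma.class_by_name(cname)
        profiles[cname] = particles * gradient.banding_weights(cls.density_mean, cls.density_sd)
    class_profiles = pd.DataFrame.from_dict(profiles, orient="index")
    class_profiles.columns = np.arange(1, gradient.n_fractions + 1)
    background_profile = extract.background_protein * gradient.banding_weights(
        extract.plasma.background_density_mean, extract.plasma.background_density_sd
    )
    volumes = np.full(gradient.n_fractions, gradient.fraction_volume_ml)
    densities = np.asarray(gradient.fraction_densities, dtype=float)
    run = _assemble_run(
        "ODG", extract.plasma, class_profiles, background_profile, totals, volumes,
        densities, gradient.noise_cv, rng,
    )
    return StageSimulation(
        run=run,
        class_profiles=class_profiles,
        background_profile=background_profile,
        plasma=extract.plasma,
    )


# ---------------------------------------------------------------------------
# LFQ matrix generator
# ---------------------------------------------------------------------------

def simulate_lfq(design: OmicsDesign) -> tuple["pd.DataFrame", pd.Series, pd.DataFrame]:
    """Generate a grouped log2 LFQ intensity matrix with MNAR dropout.

    Returns ``(matrix, groups, truth)`` where *matrix* is features x samples
    with NaN for missing values, *groups* maps sample id -> group label and
    *truth* records each feature's baseline and planted per-group shifts.

    Intensities are ``baseline + shift + N(0, noise_sd)``; the probability
    that a value is missing increases as the (pre-dropout) intensity
    decreases, following a logistic curve centred at ``dropout_location``.
    """
    rng = np.random.default_rng(design.seed)
    features = [f"P{i:04d}" for i in range(design.n_features)]
    groups = design.sample_groups()
    samples = list(groups.index)
    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=design.n_features)

    shift = np.zeros((design.n_features, len(samples)))
    feat_index = {f: i for i, f in enumerate(features)}
    for feat, per_group in design.planted_effects.items():
        if feat not in feat_index:
            raise KeyError(f"planted effect for unknown feature {feat!r}")
        for g, delta in per_group.items():
            cols = np.where(groups.to_numpy() == g)[0]
            if cols.size == 0:
                raise KeyError(f"planted effect references unknown group {g!r}")
            shift[feat_index[feat], cols] = delta

    values = (
        baseline[:, None]
        + shift
        + rng.normal(0.0, design.noise_sd, size=(design.n_features, len(samples)))
    )
    if design.dropout_scale is not None:
        # logistic MNAR: low intensities drop out preferentially
        p_missing = 1.0 / (
            1.0 + np.exp((values - design.dropout_location) / design.dropout_scale)
        )
        values = np.where(rng.random(values.shape) < p_missing, np.nan, values)

    matrix = pd.DataFrame(values, index=pd.Index(features, name="feature"), columns=samples)
    truth = pd.DataFrame({"baseline": baseline}, index=matrix.index)
    for g in design.groups:
        truth[f"shift_{g}"] = [
            design.planted_effects.get(f, {}).get(g, 0.0) for f in features
        ]
    return matrix, groups, truth


def default_proteomics_design(
    seed: int = 0,
    n_features: int = 600,
    n_contaminants: int = 83,
    n_corona: int = 20,
    n_ev_markers: int = 30,
    effect: float = 3.0,
) -> tuple[OmicsDesign, pd.DataFrame]:
    """Three-extract LFQ design with planted lipoprotein, corona and EV features.

    Groups crude/LPP/EV with six replicates each.  Contaminant proteins are
    shifted up in crude and LPP extracts (different density than EV), corona
    proteins and EV markers up in EV extracts; corona proteins are flagged
    secreted and get a plasma concentration that scales with their planted
    abundance.  Returns the design plus an annotation table
    (protein_id, role, secreted, plasma_concentration).
    """
    if n_contaminants + n_corona + n_ev_markers > n_features:
        raise ValueError("planted feature classes exceed n_features")
    rng = np.random.default_rng(seed)
    features = [f"P{i:04d}" for i in range(n_features)]
    contaminants = features[:n_contaminants]
    corona = features[n_contaminants : n_contaminants + n_corona]
    ev_markers = features[n_contaminants + n_corona : n_contaminants + n_corona + n_ev_markers]

    planted: dict[str, dict[str, float]] = {}
    for f in contaminants:
        planted[f] = {"crude": effect, "LPP": effect}
    corona_level = {}
    for f in corona:
        level = effect + float(rng.uniform(-0.5, 1.5))
        corona_level[f] = level
        planted[f] = {"EV": level, "crude": effect / 2}
    for f in ev_markers:
        planted[f] = {"EV": effect, "crude": effect / 2}

    design = OmicsDesign(
        groups={"crude": 6, "LPP": 6, "EV": 6},
        n_features=n_features,
        planted_effects=planted,
        seed=seed,
    )
    roles = []
    for f in features:
        if f in planted and f in set(contaminants):
            roles.append("contaminant")
        elif f in set(corona):
            roles.append("corona")
        elif f in set(ev_markers):
            roles.append("ev_marker")
        else:
            roles.append("background")
    secreted = [r == "corona" or (r == "background" and rng.random() < 0.3) for r in roles]
    conc = np.full(n_features, np.nan)
    for i, f in enumerate(features):
        if roles[i] == "corona":
            # abundance tracks plasma concentration with noise (power-law-ish)
            conc[i] = 10 ** (corona_level[f] / 2 + rng.normal(0, 0.15))
        elif secreted[i]:
            conc[i] = 10 ** rng.uniform(0.0, 3.0)
    annotations = pd.DataFrame(
        {
            "protein_id": features,
            "role": roles,
            "secreted": np.asarray(secreted, dtype=int),
            "plasma_concentration": conc,
        }
    ).set_index("protein_id")
    return design, annotations


# ---------------------------------------------------------------------------
# small-RNA generator
# ---------------------------------------------------------------------------

#: 19 tRNA isotypes observed in the plasma pool (Trp fragments are too rare)
TRNA_ISOTYPES = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Tyr", "Val",
)

#: amino acids the human body cannot synthesize
ESSENTIAL_AA = frozenset({"His", "Ile", "Leu", "Lys", "Met", "Phe", "Thr", "Trp", "Val"})

_BIOTYPES = ("miRNA", "tRNA", "piRNA", "lncRNA", "other")


def default_smallrna_composition() -> dict[str, dict]:
    """Default per-group biotype and tRNA-isotype proportions.

    EV extracts: miRNA 7.18 %, tRNA 7.79 %, piRNA 0.358 %, lncRNA 16.1 % of
    non-ribosomal reads, remainder "other", with a fairly flat tRNA isotype
    pool.  Total plasma: a Gly-dominated tRNA pool (with Glu and Val the
    next-largest shares) and elevated HDL- and platelet-signature miRNAs.
    """
    flat = 1.0 / len(TRNA_ISOTYPES)
    ev_isotypes = {aa: flat for aa in TRNA_ISOTYPES}
    plasma_isotypes = {aa: 0.31 / 16 for aa in TRNA_ISOTYPES}
    plasma_isotypes["Gly"] = 0.45
    plasma_isotypes["Glu"] = 0.15
    plasma_isotypes["Val"] = 0.09
    return {
        "EV": {
            "biotypes": {
                "miRNA": 0.0718,
                "tRNA": 0.0779,
                "piRNA": 0.00358,
                "lncRNA": 0.161,
                "other": 1.0 - (0.0718 + 0.0779 + 0.00358 + 0.161),
            },
            "trna_isotypes": ev_isotypes,
        },
        "plasma": {
            "biotypes": {
                "miRNA": 0.12,
                "tRNA": 0.10,
                "piRNA": 0.004,
                "lncRNA": 0.12,
                "other": 1.0 - (0.12 + 0.10 + 0.004 + 0.12),
            },
            "trna_isotypes": plasma_isotypes,
        },
    }


#: miRNAs carried by HDL particles and platelets, enriched in total plasma
HDL_MIRNAS = tuple(f"hsa-miR-45{i}" for i in range(1, 11))
PLATELET_MIRNAS = tuple(f"hsa-miR-2{i}" for i in range(5, 15))
EV_MIRNAS = ("hsa-let-7e-5p", "hsa-miR-125a-5p", "hsa-miR-99b-5p",
             "hsa-miR-150-5p", "hsa-miR-378a-3p")


def default_gene_sets() -> dict[str, tuple[str, ...]]:
    """Bundled miRNA signature sets (HDL-associated, platelet-associated)."""
    return {"HDL_TOP": HDL_MIRNAS, "PLATELET_TOP": PLATELET_MIRNAS}


def _feature_catalog(rng: np.random.Generator) -> pd.DataFrame:
    """Fixed feature catalogue: ids, biotypes, tRNA isotypes, within-biotype weights."""
    rows = []
    mirna_names = list(HDL_MIRNAS + PLATELET_MIRNAS + EV_MIRNAS)
    mirna_names += [f"hsa-miR-{1000 + i}" for i in range(35)]
    for name in mirna_names:
        rows.append((name, "miRNA", "", ""))
    for aa in TRNA_ISOTYPES:
        for j in (1, 2):
            rows.append((f"tRNA-{aa}-frag{j}", "tRNA", aa, int(aa in ESSENTIAL_AA)))
    for i in range(10):
        rows.append((f"piR-{i + 1:03d}", "piRNA", "", ""))
    for i in range(25):
        rows.append((f"lnc-{i + 1:03d}", "lncRNA", "", ""))
    for i in range(40):
        rows.append((f"smallRNA-{i + 1:03d}", "other", "", ""))
    catalog = pd.DataFrame(rows, columns=["feature", "biotype", "isotype", "essential"])
    catalog = catalog.set_index("feature")
    # skewed within-biotype weights: a few features take most of the reads
    weights = np.empty(len(catalog))
    for bt in _BIOTYPES:
        mask = (catalog["biotype"] == bt).to_numpy()
        w = rng.dirichlet(np.full(mask.sum(), 0.8))
        weights[mask] = w
    catalog["weight"] = weights
    return catalog


def simulate_smallrna(
    design: OmicsDesign,
    composition: Mapping[str, Mapping] | None = None,
    decay_feature: str | None = None,
    decay_factor: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate a grouped NB small-RNA count matrix.

    Counts are NB with mean ``library_size * biotype share * within-biotype
    weight`` (tRNA means are further split by the group's isotype
    proportions) and dispersion ``design.dispersion`` (var = mu + alpha
    mu^2); dispersion 0 falls back to Poisson.  ``planted_effects`` entries
    are fold multipliers per group.  If ``decay_feature`` is set, its mean is
    multiplied by ``decay_factor ** t`` for the t-th sample (0-based) within
    each group, emulating a time course over ordered samples.

    Returns ``(counts, groups, annotation)``; *annotation* has columns
    biotype, isotype, essential.
    """
    composition = composition or default_smallrna_composition()
    for g in design.groups:
        if g not in composition:
            raise KeyError(f"no composition for group {g!r}")
        bio = composition[g]["biotypes"]
        if any(v < 0 for v in bio.values()):
            raise ValueError("negative biotype proportions")
        if abs(sum(bio.values()) - 1.0) > 1e-9:
            raise ValueError(f"biotype proportions for {g!r} do not sum to 1")
        iso = composition[g]["trna_isotypes"]
        if any(v < 0 for v in iso.values()):
            raise ValueError("negative isotype proportions")
        if abs(sum(iso.values()) - 1.0) > 1e-9:
            raise ValueError(f"tRNA isotype proportions for {g!r} do not sum to 1")

    rng = np.random.default_rng(design.seed)
    catalog = _feature_catalog(np.random.default_rng(design.seed + 104729))
    groups = design.sample_groups()
    n_feat = len(catalog)

    means = np.zeros((n_feat, len(groups)))
    biotypes = catalog["biotype"].to_numpy()
    isotypes = catalog["isotype"].to_numpy()
    weights = catalog["weight"].to_numpy()
    for col, (sample, g) in enumerate(groups.items()):
        bio = composition[g]["biotypes"]
        iso = composition[g]["trna_isotypes"]
        mu = np.zeros(n_feat)
        for bt in _BIOTYPES:
            mask = biotypes == bt
            if bt == "tRNA":
                # split the tRNA share by isotype, then by within-isotype weight
                for aa, share in iso.items():
                    amask = mask & (isotypes == aa)
                    if amask.any():
                        w = weights[amask]
                        mu[amask] = bio[bt] * share * w / w.sum()
            else:
                w = weights[mask]
                mu[mask] = bio[bt] * w / w.sum()
        means[:, col] = design.library_size * mu

    feat_pos = {f: i for i, f in enumerate(catalog.index)}
    for feat, per_group in design.planted_effects.items():
        if feat not in feat_pos:
            raise KeyError(f"planted effect for unknown feature {feat!r}")
        for g, fold in per_group.items():
            cols = np.where(groups.to_numpy() == g)[0]
            means[feat_pos[feat], cols] *= fold
    if decay_feature is not None:
        if decay_feature not in feat_pos:
            raise KeyError(f"unknown decay feature {decay_feature!r}")
        for g in design.groups:
            cols = np.where(groups.to_numpy() == g)[0]
            means[feat_pos[decay_feature], cols] *= decay_factor ** np.arange(len(cols))

    if design.dispersion == 0:
        counts = rng.poisson(means)
    else:
        n_param = 1.0 / design.dispersion
        p_param = n_param / (n_param + np.maximum(means, 1e-12))
        counts = rng.negative_binomial(n_param, p_param)
        counts = np.where(means == 0, 0, counts)

    matrix = pd.DataFrame(counts, index=catalog.index.copy(), columns=list(groups.index))
    annotation = catalog[["biotype", "isotype", "essential"]].copy()
    return matrix, groups, annotation


def default_rna_design(seed: int = 0, n_reps: int = 4) -> OmicsDesign:
    """EV-extract vs total-plasma small-RNA design with planted signatures.

    HDL- and platelet-signature miRNAs are planted at higher abundance in
    total plasma, the EV-enriched miRNAs at higher abundance in EV extracts.
    """
    planted: dict[str, dict[str, float]] = {}
    for f in HDL_MIRNAS + PLATELET_MIRNAS:
        planted[f] = {"plasma": 4.0}
    for f in EV_MIRNAS:
        planted[f] = {"EV": 4.0}
    return OmicsDesign(
        groups={"EV": n_reps, "plasma": n_reps},
        planted_effects=planted,
        dispersion=0.1,
        library_size=5e5,
        seed=seed,
    )
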