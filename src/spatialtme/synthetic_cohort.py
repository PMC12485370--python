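"""Synthetic multi-sample cohorts with known ground truth.

Emulates a tissue-microarray cohort of 1-mm cores: each patient contributes
2–3 circular cores, each core holds a few thousand cells with planar
coordinates, per-marker intensities, a planted phenotype, and (optionally)
planted spatial structure — pairwise attraction/avoidance between phenotypes
and/or region-wise neighborhood motifs.  Patient survival is drawn from a
proportional-hazards model on a planted feature, so every downstream stage
(phenotyping, interaction testing, neighborhood discovery, survival
statistics) can be checked against known truth.

Spatial mechanisms are deliberately simple enough to have closed-form
expectations: attraction is a Thomas-type parent–offspring process, avoidance
a hard-core rejection (thinning), and "neutral" is complete spatial
randomness on the core disc.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cell_data import DEFAULT_MARKERS, MarkerPanel, DEFAULT_PANEL

__all__ = [
    "MAIN_TYPES",
    "PHENOTYPES",
    "MAIN_OF_PHENOTYPE",
    "CHECKPOINT_OF_PHENOTYPE",
    "MAIN_SIGNATURE",
    "IntensityModel",
    "InteractionPlan",
    "MotifMap",
    "SurvivalModel",
    "SyntheticConfig",
    "GroundTruth",
    "default_phenotype_mixture",
    "default_motif_map",
    "place_uniform_disc",
    "plant_interaction",
    "plant_rcn_regions",
    "simulate_survival",
    "generate_cohort",
]

# ---------------------------------------------------------------------------
# Phenotype taxonomy
# ---------------------------------------------------------------------------

#: The eight main cell types of the lineage-level grouping.
MAIN_TYPES = (
    "B cell",
    "CD4 T cell",
    "CD8 T cell",
    "Treg",
    "M1 macrophage",
    "M2 macrophage",
    "other immune",
    "nonimmune",
)

#: Lineage markers expected positive per main type (CD45 marks all immune
#: cells; nonimmune cells are negative for everything).
MAIN_SIGNATURE: dict[str, tuple[str, ...]] = {
    "B cell": ("CD20", "CD45"),
    "CD4 T cell": ("CD3", "CD4", "CD45"),
    "CD8 T cell": ("CD3", "CD8", "CD45"),
    "Treg": ("CD3", "CD4", "Foxp3", "CD45"),
    "M1 macrophage": ("CD68", "CD45"),
    "M2 macrophage": ("CD68", "CD163", "CD45"),
    "other immune": ("CD45",),
    "nonimmune": (),
}

# The 17-label phenotype set: checkpoint-positive subsets split off the main
# types (PD-1 on T cells, PD-L1 on B cells and macrophages, CD96 on B and
# conventional T cells), plus the two residual classes.
_CHECKPOINT_SPLITS: tuple[tuple[str, str], ...] = (
    ("B cell", "PD-L1"),
    ("B cell", "CD96"),
    ("CD4 T cell", "PD-1"),
    ("CD4 T cell", "CD96"),
    ("CD8 T cell", "PD-1"),
    ("CD8 T cell", "CD96"),
    ("Treg", "PD-1"),
    ("M1 macrophage", "PD-L1"),
    ("M2 macrophage", "PD-L1"),
)


def _build_phenotypes() -> tuple[tuple[str, ...], dict[str, str], dict[str, str | None]]:
    labels: list[str] = []
    main_of: dict[str, str] = {}
    cp_of: dict[str, str | None] = {}
    for main in MAIN_TYPES:
        labels.append(main)
        main_of[main] = main
        cp_of[main] = None
        for m, marker in _CHECKPOINT_SPLITS:
            if m == main:
                lab = f"{marker}+ {main}"
                labels.append(lab)
                main_of[lab] = main
                cp_of[lab] = marker
    return tuple(labels), main_of, cp_of


PHENOTYPES, MAIN_OF_PHENOTYPE, CHECKPOINT_OF_PHENOTYPE = _build_phenotypes()
assert len(PHENOTYPES) == 17


def default_phenotype_mixture() -> pd.Series:
    """Cohort-mean phenotype frequencies.

    Lineage-level fractions reflect a B-cell lymphoma microenvironment
    (B cells most abundant, then CD4 T, CD8 T, macrophage subsets, Tregs);
    checkpoint-positive fractions within each lineage follow the same
    magnitudes (about a fifth of CD4 T cells PD-1+, a ninth of CD8 T cells,
    PD-L1 common on M2-like and rare on M1-like macrophages and B cells).
    CD96-positive fractions are set to 5% as a generator choice.
    """
    main_frac = {
        "B cell": 0.55,
        "CD4 T cell": 0.14,
        "CD8 T cell": 0.099,
        "Treg": 0.036,
        "M1 macrophage": 0.054,
        "M2 macrophage": 0.079,
        "other immune": 0.0026,
        "nonimmune": 0.040,
    }
    cp_frac = {
        ("B cell", "PD-L1"): 0.0401,
        ("B cell", "CD96"): 0.05,
        ("CD4 T cell", "PD-1"): 0.209,
        ("CD4 T cell", "CD96"): 0.05,
        ("CD8 T cell", "PD-1"): 0.114,
        ("CD8 T cell", "CD96"): 0.05,
        ("Treg", "PD-1"): 0.10,
        ("M1 macrophage", "PD-L1"): 0.122,
        ("M2 macrophage", "PD-L1"): 0.365,
    }
    probs = {}
    for lab in PHENOTYPES:
        main = MAIN_OF_PHENOTYPE[lab]
        cp = CHECKPOINT_OF_PHENOTYPE[lab]
        if cp is None:
            rest = sum(v for (m, _), v in cp_frac.items() if m == main)
            probs[lab] = main_frac[main] * (1.0 - rest)
        else:
            probs[lab] = main_frac[main] * cp_frac[(main, cp)]
    s = pd.Series(probs, dtype=float)
    return s / s.sum()


# ---------------------------------------------------------------------------
# Model components
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntensityModel:
    """Log-normal marker intensities conditional on phenotype.

    A marker that belongs to the phenotype's signature (lineage markers of
    its main type, plus its checkpoint marker if any) is drawn from
    ``LogNormal(log(separation), sigma)``; all other markers from
    ``LogNormal(0, sigma)``.  The default separation of 8-fold with
    sigma = 0.3 puts positive and negative populations ~6.9 log-sd apart,
    i.e. near-perfect Bayes separability, so downstream phenotyping failures
    indicate pipeline bugs rather than irreducible noise.  Lower
    ``separation`` for stress tests ("hard mode").
    """

    separation: float = 8.0
    sigma: float = 0.3
    markers: tuple[str, ...] = DEFAULT_MARKERS

    def positive_markers(self, phenotype: str) -> tuple[str, ...]:
        pos = list(MAIN_SIGNATURE[MAIN_OF_PHENOTYPE[phenotype]])
        cp = CHECKPOINT_OF_PHENOTYPE[phenotype]
        if cp is not None:
            pos.append(cp)
        return tuple(pos)

    def sample(self, phenotypes: Sequence[str], rng: np.random.Generator) -> np.ndarray:
        """Draw an (n_cells, n_markers) intensity matrix."""
        n = len(phenotypes)
        loc = np.zeros((n, len(self.markers)))
        midx = {m: j for j, m in enumerate(self.markers)}
        for lab in set(phenotypes):
            rows = np.fromiter((p == lab for p in phenotypes), bool, count=n)
            for m in self.positive_markers(lab):
                if m in midx:
                    loc[rows, midx[m]] = log(self.separation)
        return np.exp(rng.normal(loc, self.sigma))


@dataclass(frozen=True)
class InteractionPlan:
    """Planted pairwise spatial dependence between two phenotypes.

    ``strength`` is a radius in pixels: the offspring dispersion s.d. for
    ``attract`` (Thomas process) and the hard-core exclusion radius for
    ``avoid``.  ``neutral`` ignores it.
    """

    type_a: str
    type_b: str
    mode: Literal["attract", "avoid", "neutral"] = "neutral"
    strength: float = 60.0

    def __post_init__(self) -> None:
        if self.mode not in {"attract", "avoid", "neutral"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


@dataclass(frozen=True)
class MotifMap:
    """A partition of the core disc into regions with distinct mixtures.

    Regions are the Voronoi cells of ``seeds`` (coordinates relative to the
    core centre, pixels), which tile the disc by construction; ``mixtures``
    holds one phenotype probability vector per region (rows sum to 1).
    A cell is assigned the region of its nearest seed.
    """

    seeds: np.ndarray  # (n_regions, 2)
    mixtures: np.ndarray  # (n_regions, n_phenotypes)
    phenotypes: tuple[str, ...] = PHENOTYPES

    def __post_init__(self) -> None:
        seeds = np.asarray(self.seeds, float)
        mix = np.asarray(self.mixtures, float)
        object.__setattr__(self, "seeds", seeds)
        object.__setattr__(self, "mixtures", mix)
        if seeds.ndim != 2 or seeds.shape[1] != 2:
            raise ValueError("seeds must be (n_regions, 2)")
        if len({tuple(s) for s in seeds.round(9).tolist()}) != len(seeds):
            raise ValueError("coincident seeds would make regions ambiguous")
        if mix.shape != (len(seeds), len(self.phenotypes)):
            raise ValueError("mixtures must be (n_regions, n_phenotypes)")
        if (mix < 0).any() or np.abs(mix.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("each mixture row must be a probability vector")

    @property
    def n_regions(self) -> int:
        return len(self.seeds)


def default_motif_map(n_regions: int = 10, dominant_weight: float = 0.7) -> MotifMap:
    """Ten-region default map with one dominant phenotype per region.

    Seeds follow a sunflower (golden-angle) layout at 72% of the core
    radius expressed in relative units and scaled at generation time; the
    dominant phenotypes echo the recurring neighborhood themes seen in
    lymphoma tissue (tumor-B-cell-rich/immune-poor, CD8-rich, CD4-rich,
    PD-1+ cell-rich, nonimmune, macrophage-subset-rich, PD-L1+ rich).
    """
    dominants = (
        "B cell",
        "CD8 T cell",
        "CD4 T cell",
        "PD-1+ CD4 T cell",
        "nonimmune",
        "M2 macrophage",
        "PD-L1+ B cell",
        "M1 macrophage",
        "PD-1+ CD8 T cell",
        "PD-L1+ M2 macrophage",
    )[:n_regions]
    golden = np.pi * (3 - np.sqrt(5.0))
    i = np.arange(n_regions)
    r = 0.72 * np.sqrt((i + 0.5) / n_regions)  # relative to core radius
    seeds = np.c_[r * np.cos(i * golden), r * np.sin(i * golden)]
    mixtures = np.full((n_regions, len(PHENOTYPES)),
                       (1 - dominant_weight) / (len(PHENOTYPES) - 1))
    for j, dom in enumerate(dominants):
        mixtures[j, PHENOTYPES.index(dom)] = dominant_weight
    return MotifMap(seeds=seeds, mixtures=mixtures)


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential-baseline proportional-hazards survival generator.

    ``hazard(x) = baseline_hazard * exp(sum_f coefficients[f] * x[f])`` with
    administrative censoring at ``censoring_time`` months.  Defaults: a
    baseline of 0.008 events/month (median ~7 years) and a log-hazard of
    log(3) on the planted binary ``group`` feature, censored at 120 months.
    """

    baseline_hazard: float = 0.008
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"group": log(3.0)}
    )
    censoring_time: float = 120.0

    def __post_init__(self) -> None:
        if not self.baseline_hazard > 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_time < 0:
            raise ValueError("censoring_time must be >= 0")


def simulate_survival(
    features: pd.DataFrame, model: SurvivalModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (times, events) for each row of ``features``.

    Event times are exponential with rate ``baseline * exp(linear
    predictor)``; observations past the administrative censoring time are
    censored there.  A censoring time of 0 censors everything at 0.
    """
    lp = np.zeros(len(features))
    for name, coef in model.coefficients.items():
        lp += coef * features[name].to_numpy(dtype=float)
    rate = model.baseline_hazard * np.exp(lp)
    t = rng.exponential(1.0 / rate)
    event = (t <= model.censoring_time).astype(int)
    time = np.minimum(t, model.censoring_time)
    if model.censoring_time == 0:
        event[:] = 0
    return time, event


# ---------------------------------------------------------------------------
# Point placement
# ---------------------------------------------------------------------------


def place_uniform_disc(
    n: int, radius: float, rng: np.random.Generator,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Complete spatial randomness on a disc: n points, uniform."""
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.c_[center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]


def plant_interaction(
    points_a: np.ndarray,
    n_b: int,
    mode: str,
    strength: float,
    radius: float,
    rng: np.random.Generator,
    center: tuple[float, float] = (0.0, 0.0),
    max_tries: int = 200,
) -> np.ndarray:
    """Place ``n_b`` points relative to ``points_a`` on the core disc.

    attract
        Thomas-type parent–offspring placement: each b point picks a uniform
        a parent and lands at a Gaussian offset with s.d. ``strength`` px
        (redrawn until inside the disc).
    avoid
        Hard-core thinning: uniform proposals are rejected while within
        ``strength`` px of any a point; raises after ``max_tries`` rounds if
        the exclusion constraint is infeasible at this density.
    neutral
        Uniform on the disc, independent of a.
    """
    from scipy.spatial import cKDTree

    if mode == "neutral" or len(points_a) == 0 or n_b == 0:
        return place_uniform_disc(n_b, radius, rng, center)
    c = np.asarray(center, float)
    if mode == "attract":
        out = np.empty((n_b, 2))
        todo = np.arange(n_b)
        for _ in range(max_tries):
            parents = points_a[rng.integers(0, len(points_a), size=len(todo))]
            prop = parents + rng.normal(0.0, strength, size=(len(todo), 2))
            ok = ((prop - c) ** 2).sum(axis=1) <= radius**2
            out[todo[ok]] = prop[ok]
            todo = todo[~ok]
            if not len(todo):
                return out
        raise RuntimeError("attract placement failed: dispersion incompatible with core")
    if mode == "avoid":
        tree = cKDTree(points_a)
        out = np.empty((n_b, 2))
        filled = 0
        for _ in range(max_tries):
            prop = place_uniform_disc(2 * (n_b - filled) + 16, radius, rng, center)
            d, _ = tree.query(prop, k=1)
            prop = prop[d > strength]
            take = min(len(prop), n_b - filled)
            out[filled : filled + take] = prop[:take]
            filled += take
            if filled == n_b:
                return out
        raise RuntimeError(
            "avoid placement failed: exclusion radius incompatible with density"
        )
    raise ValueError(f"unknown mode {mode!r}")


def plant_rcn_regions(
    xy: np.ndarray, motif_map: MotifMap, center: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Region id per cell: index of the nearest motif seed (Voronoi)."""
    rel = np.asarray(xy, float) - np.asarray(center, float)
    d2 = ((rel[:, None, :] - motif_map.seeds[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


# ---------------------------------------------------------------------------
# Cohort configuration and generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything that defines a synthetic cohort (besides the seed).

    The defaults describe the study conditions the package is tested under:
    40 patients x 2 cores, 1-mm cores (radius 1540 px at 0.325 µm/px),
    2,000 cells per core, lymphoma-like phenotype frequencies with mild
    per-sample Dirichlet heterogeneity, and survival tied to a planted
    binary patient group with hazard ratio 3.  Patient groups 0/1 carry the
    ``interaction_plans`` for their group (default: in group 0 B cells avoid
    PD-1+ CD4 T cells; in group 1 they attract them), which is what the
    interaction-profile clustering stage is expected to recover.
    """

    n_patients: int = 40
    cores_per_patient: int = 2
    core_radius: float = 1540.0
    cells_per_core: int | tuple[int, int] = 2000
    phenotype_mixture: pd.Series | None = None  # default: default_phenotype_mixture()
    mixture_concentration: float | None = 150.0  # Dirichlet alpha scale; None = exact
    interaction_plans: Mapping[int, Sequence[InteractionPlan]] | None = None
    group_fraction: float = 0.5  # fraction of patients in group 1
    motif_map: MotifMap | None = None
    intensity: IntensityModel = field(default_factory=IntensityModel)
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_radius <= 0:
            raise ValueError("core_radius must be > 0")
        if self.n_patients < 0 or not (2 <= self.cores_per_patient <= 3):
            raise ValueError("need n_patients >= 0 and 2-3 cores per patient")
        mix = self.phenotype_mixture
        if mix is not None and abs(float(np.sum(mix)) - 1) > 1e-9:
            raise ValueError("phenotype_mixture must sum to 1")


def default_interaction_plans() -> dict[int, tuple[InteractionPlan, ...]]:
    return {
        0: (InteractionPlan("B cell", "PD-1+ CD4 T cell", "avoid", 60.0),),
        1: (InteractionPlan("B cell", "PD-1+ CD4 T cell", "attract", 30.0),),
    }


@dataclass
class GroundTruth:
    """Planted truth aligned to the emitted tables by key."""

    cells: pd.DataFrame  # cell_id, sample_id, phenotype, region
    patients: pd.DataFrame  # patient_id, group, linear_predictor


def _core_rng(seed: int, patient_i: int, core_j: int) -> np.random.Generator:
    # One stream per (patient, core): reproducible under partial regeneration.
    return np.random.default_rng(np.random.SeedSequence([seed, patient_i, core_j]))


def generate_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (cell table, clinical table, ground truth) for one cohort.

    Deterministic given the seed.  Cells are confined to the core disc
    (centred at ``(core_radius, core_radius)`` per sample so coordinates are
    nonnegative); intensities come from the phenotype's intensity model;
    survival from the configured proportional-hazards model on the planted
    patient group.
    """
    master = config.seed if seed is None else seed
    mixture = (
        default_phenotype_mixture()
        if config.phenotype_mixture is None
        else pd.Series(config.phenotype_mixture, dtype=float)
    )
    phen_labels = list(mixture.index)
    plans = (
        default_interaction_plans()
        if config.interaction_plans is None and config.motif_map is None
        else (config.interaction_plans or {})
    )
    R = config.core_radius
    center = (R, R)

    cohort_rng = np.random.default_rng(np.random.SeedSequence([master, 2**20]))
    n_group1 = int(round(config.group_fraction * config.n_patients))
    groups = np.zeros(config.n_patients, int)
    if config.n_patients:
        groups[cohort_rng.choice(config.n_patients, size=n_group1, replace=False)] = 1

    cell_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    clin_rows: list[dict] = []
    for pi in range(config.n_patients):
        patient_id = f"P{pi:03d}"
        prng = _core_rng(master, pi, 10**6)
        clin_rows.append(
            {
                "patient_id": patient_id,
                "age": int(prng.integers(25, 86)),
                "sex": prng.choice(["M", "F"]),
                "ipi": int(prng.integers(0, 6)),
                "coo": prng.choice(
                    ["GCB", "ABC", "Unclassified", "nd"], p=[0.31, 0.37, 0.10, 0.22]
                ),
                "stage": prng.choice(["I-II", "III-IV"]),
            }
        )
        for cj in range(config.cores_per_patient):
            rng = _core_rng(master, pi, cj)
            sample_id = f"{patient_id}c{cj}"
            if isinstance(config.cells_per_core, tuple):
                lo, hi = config.cells_per_core
                n = int(rng.integers(lo, hi + 1))
            else:
                n = int(config.cells_per_core)
            if n == 0:
                continue
            samp_mix = mixture.to_numpy()
            if config.mixture_concentration is not None:
                alpha = np.maximum(samp_mix * config.mixture_concentration, 1e-3)
                samp_mix = rng.dirichlet(alpha)
            if config.motif_map is not None:
                mm = config.motif_map
                seeds_px = mm.seeds * R  # seeds are in relative units
                mm_px = MotifMap(seeds=seeds_px, mixtures=mm.mixtures,
                                 phenotypes=mm.phenotypes)
                xy = place_uniform_disc(n, R, rng, center)
                region = plant_rcn_regions(xy, mm_px, center)
                phen_idx = np.empty(n, int)
                for g in np.unique(region):
                    rows = region == g
                    phen_idx[rows] = rng.choice(
                        len(mm.phenotypes), size=int(rows.sum()), p=mm.mixtures[g]
                    )
                phen = np.asarray(mm.phenotypes, object)[phen_idx]
            else:
                counts = rng.multinomial(n, samp_mix)
                placed: dict[str, np.ndarray] = {}
                group_plans = list(plans.get(groups[pi], ()))
                for plan in group_plans:
                    if plan.type_a not in placed:
                        ia = phen_labels.index(plan.type_a)
                        placed[plan.type_a] = place_uniform_disc(
                            counts[ia], R, rng, center
                        )
                    if plan.type_b not in placed:
                        ib = phen_labels.index(plan.type_b)
                        placed[plan.type_b] = plant_interaction(
                            placed[plan.type_a], counts[ib], plan.mode,
                            plan.strength, R, rng, center,
                        )
                for lab, cnt in zip(phen_labels, counts):
                    if lab not in placed:
                        placed[lab] = place_uniform_disc(cnt, R, rng, center)
                phen = np.concatenate(
                    [np.repeat(lab, len(placed[lab])) for lab in phen_labels]
                )
                xy = np.concatenate([placed[lab] for lab in phen_labels])
                region = np.zeros(len(phen), int)
            order = rng.permutation(len(phen))  # decouple row order from phenotype
            phen, xy, region = phen[order], xy[order], region[order]
            intens = config.intensity.sample(list(phen), rng)
            area = rng.lognormal(np.log(280.0), 0.35, size=len(phen))
            cells = pd.DataFrame(
                {
                    "cell_id": [f"{sample_id}_{i}" for i in range(len(phen))],
                    "sample_id": sample_id,
                    "patient_id": patient_id,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "area": area,
                }
            )
            for j, m in enumerate(config.intensity.markers):
                cells[m] = intens[:, j]
            cell_frames.append(cells)
            truth_frames.append(
                pd.DataFrame(
                    {
                        "cell_id": cells["cell_id"],
                        "sample_id": sample_id,
                        "phenotype": phen,
                        "region": region,
                    }
                )
            )

    clinical = pd.DataFrame(
        clin_rows,
        columns=["patient_id", "age", "sex", "ipi", "coo", "stage"],
    )
    truth_patients = pd.DataFrame(
        {"patient_id": clinical["patient_id"], "group": groups[: len(clinical)]}
    )
    lp = np.zeros(len(clinical))
    feats = truth_patients.copy()
    for name, coef in config.survival.coefficients.items():
        if name in feats.columns:
            lp += coef * feats[name].to_numpy(dtype=float)
    truth_patients["linear_predictor"] = lp
    surv_rng = np.random.default_rng(np.random.SeedSequence([master, 2**21]))
    if len(clinical):
        pfs_t, pfs_e = simulate_survival(truth_patients, config.survival, surv_rng)
        os_model = replace(
            config.survival, baseline_hazard=config.survival.baseline_hazard * 0.7
        )
        os_t, os_e = simulate_survival(truth_patients, os_model, surv_rng)
        clinical["pfs_time"], clinical["pfs_event"] = pfs_t, pfs_e
        clinical["os_time"], clinical["os_event"] = os_t, os_e
    else:
        for c in ("pfs_time", "pfs_event", "os_time", "os_event"):
            clinical[c] = pd.Series(dtype=float)

    if cell_frames:
        cells_all = pd.concat(cell_frames, ignore_index=True)
        truth_cells = pd.concat(truth_frames, ignore_index=True)
    else:
        cols = list(
            ("cell_id", "sample_id", "patient_id", "x", "y", "area")
        ) + list(config.intensity.markers)
        cells_all = pd.DataFrame(columns=cols)
        truth_cells = pd.DataFrame(columns=["cell_id", "sample_id", "phenotype", "region"])
    return cells_all, clinical, GroundTruth(cells=truth_cells, patients=truth_patients)
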