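"""Synthetic patient cohorts for the bag-of-embeddings pipeline.

Each synthetic patient is a "bag" of single-cell embedding vectors plus a
manifest row (diagnosis at three hierarchy levels, measured hemoglobin,
cell-type counts, derived ratios).  Cells are drawn from a small set of
cell-type profiles — isotropic Gaussian clusters in embedding space that
stand in for the latent clusters a single-cell image encoder produces.
Disease classes differ in their cell-type composition, drawn from a
class-specific Dirichlet; for the myeloid malignancies the myeloblast
fraction is an explicit latent severity drawn uniformly from a
class-specific range and substituted into the composition, so that the
relation between predicted acute-leukemia probability and blast ratio has
a controllable ground truth (acute leukemia at blast fraction 0.20-0.90,
MDS below the classical 20% blast criterion, healthy/reactive near zero).

The ``separation`` knob scales the distance between cell-type centroids:
``separation=0`` produces embeddings with no class signal (negative
control), large values an easily recoverable signal (positive control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import LabelHierarchy, default_hierarchy

__all__ = [
    "CellTypeProfile",
    "ClassRecipe",
    "CellBag",
    "CELL_TYPE_NAMES",
    "RELEASED_TEST_SET_COUNTS",
    "released_test_set_priors",
    "default_recipes",
    "generate_bag",
    "generate_cohort",
    "MANIFEST_COLUMNS",
]

# Canonical cell-type order; index 0 is the blast coordinate that the
# latent severity overrides.
CELL_TYPE_NAMES = (
    "myeloblast",
    "promyelocyte",
    "neutrophil",
    "lymphocyte",
    "monocyte",
    "giant platelet",
)

#: Per-class patient counts of the released internal test set
#: (coarse-class order of the default hierarchy); used as default priors.
RELEASED_TEST_SET_COUNTS = {
    "acute leukemia": 46,
    "MDS": 38,
    "MDS/MPN": 22,
    "MPN": 48,
    "lymphoma": 57,
    "plasma cell neoplasm": 57,
    "reactive changes": 42,
    "healthy": 99,
}

# Mean cell-type composition per coarse class (columns follow
# CELL_TYPE_NAMES).  For blast-driven classes the myeloblast entry is a
# placeholder: the latent blast fraction overrides it at sampling time.
_COMPOSITION_MEANS = {
    "acute leukemia":       (0.50, 0.06, 0.18, 0.16, 0.07, 0.03),
    "MDS":                  (0.10, 0.18, 0.45, 0.14, 0.09, 0.04),
    "MDS/MPN":              (0.08, 0.05, 0.28, 0.14, 0.41, 0.04),
    "MPN":                  (0.01, 0.25, 0.40, 0.10, 0.04, 0.20),
    "lymphoma":             (0.01, 0.02, 0.15, 0.75, 0.05, 0.02),
    "plasma cell neoplasm": (0.01, 0.02, 0.70, 0.15, 0.10, 0.02),
    "reactive changes":     (0.02, 0.05, 0.25, 0.45, 0.20, 0.03),
    "healthy":              (0.01, 0.03, 0.50, 0.33, 0.10, 0.03),
}

_BLAST_RANGES = {
    "acute leukemia": (0.20, 0.90),
    "MDS": (0.02, 0.19),
    "MDS/MPN": (0.02, 0.15),
    "MPN": (0.00, 0.05),
    "lymphoma": (0.00, 0.02),
    "plasma cell neoplasm": (0.00, 0.02),
    "reactive changes": (0.00, 0.02),
    "healthy": (0.00, 0.02),
}

# Hemoglobin (mean g/dL, sd g/dL): cytopenic classes low, MPN high.
# Placeholders with plausible ordering, not clinical claims.
_HEMOGLOBIN = {
    "acute leukemia": (9.0, 1.2),
    "MDS": (9.5, 1.2),
    "MDS/MPN": (10.5, 1.2),
    "MPN": (15.0, 1.5),
    "lymphoma": (12.0, 1.3),
    "plasma cell neoplasm": (10.0, 1.2),
    "reactive changes": (12.5, 1.3),
    "healthy": (14.0, 1.0),
}

_CONCENTRATION_SCALE = 200.0  # total Dirichlet concentration per class

HB_BOUNDS = (3.0, 20.0)  # physiological plausibility truncation, g/dL

MANIFEST_COLUMNS = (
    "patient_id",
    "detailed_class",
    "coarse_class",
    "malignant",
    "hemoglobin",
    "blast_ratio",
    "lymphocyte_ratio",
    "fold_id",
)


@dataclass(frozen=True)
class CellTypeProfile:
    """Isotropic Gaussian cluster standing in for one cell type."""

    name: str
    mean_vector: np.ndarray
    spread: float

    def __post_init__(self) -> None:
        mv = np.asarray(self.mean_vector, dtype=float)
        object.__setattr__(self, "mean_vector", mv)
        if mv.ndim != 1:
            raise ValueError("mean_vector must be one-dimensional")
        if self.spread < 0:
            raise ValueError("spread must be nonnegative")


@dataclass(frozen=True)
class ClassRecipe:
    """Sampling recipe for one coarse class."""

    coarse_class: str
    composition_concentration: np.ndarray  # Dirichlet parameters, > 0
    blast_fraction_range: tuple[float, float]
    hemoglobin_mean: float
    hemoglobin_sd: float

    def __post_init__(self) -> None:
        conc = np.asarray(self.composition_concentration, dtype=float)
        object.__setattr__(self, "composition_concentration", conc)
        if np.any(conc <= 0):
            raise ValueError("composition_concentration entries must be > 0")
        lo, hi = self.blast_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("blast_fraction_range must satisfy 0 <= low <= high <= 1")
        if self.hemoglobin_sd < 0:
            raise ValueError("hemoglobin_sd must be nonnegative")


@dataclass
class CellBag:
    """One patient's set of single-cell embedding vectors.

    ``cell_types`` and ``latent_blast_fraction`` are populated for
    synthetic bags only (ground-truth tags for attention tests).
    """

    patient_id: str
    embeddings: np.ndarray  # (n_cells, embedding_dim)
    cell_types: np.ndarray | None = None
    latent_blast_fraction: float | None = None

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise ValueError("embeddings must be a (n_cells >= 1, dim) matrix")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("embeddings contain non-finite values")

    @property
    def n_cells(self) -> int:
        return self.embeddings.shape[0]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def released_test_set_priors(
    hierarchy: LabelHierarchy | None = None,
) -> np.ndarray:
    """Class priors mirroring the released internal test-set composition."""
    h = hierarchy or default_hierarchy()
    counts = np.array([RELEASED_TEST_SET_COUNTS[c] for c in h.coarse_classes], float)
    return counts / counts.sum()


def default_recipes(
    n_cell_types: int = 6,
    embedding_dim: int = 768,
    separation: float = 5.0,
    seed: int | np.random.Generator = 0,
    spread: float = 1.0,
    hierarchy: LabelHierarchy | None = None,
) -> tuple[list[CellTypeProfile], dict[str, ClassRecipe]]:
    """Cell-type profiles and recipes for all 8 coarse classes.

    Centroids are drawn reproducibly from a standard normal and scaled by
    ``separation``, so pairwise centroid distance grows linearly with it
    and ``separation=0`` collapses all cell types onto one point (null
    signal).  With fewer or more than the 6 canonical cell types the
    composition table is truncated/extended and renormalized; index 0 is
    always the blast coordinate.
    """
    if n_cell_types < 4:
        raise ValueError("n_cell_types must be >= 4")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = _as_rng(seed)
    names = [
        CELL_TYPE_NAMES[i] if i < len(CELL_TYPE_NAMES) else f"cell-type-{i + 1}"
        for i in range(n_cell_types)
    ]
    profiles = [
        CellTypeProfile(
            name=name,
            mean_vector=separation * rng.normal(size=embedding_dim),
            spread=spread,
        )
        for name in names
    ]
    h = hierarchy or default_hierarchy()
    recipes: dict[str, ClassRecipe] = {}
    for coarse in h.coarse_classes:
        base = np.array(_COMPOSITION_MEANS[coarse], dtype=float)
        if n_cell_types <= len(base):
            comp = base[:n_cell_types]
        else:  # spread a small mass over extra types
            extra = np.full(n_cell_types - len(base), 0.02)
            comp = np.concatenate([base, extra])
        comp = comp / comp.sum()
        hb_mean, hb_sd = _HEMOGLOBIN[coarse]
        recipes[coarse] = ClassRecipe(
            coarse_class=coarse,
            composition_concentration=_CONCENTRATION_SCALE * comp,
            blast_fraction_range=_BLAST_RANGES[coarse],
            hemoglobin_mean=hb_mean,
            hemoglobin_sd=hb_sd,
        )
    return profiles, recipes


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Normal(mean, sd) truncated to [lo, hi] by rejection; sd=0 clips."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))  # pathological parameters


def generate_bag(
    recipe: ClassRecipe,
    profiles: Sequence[CellTypeProfile],
    n_cells: int,
    seed: int | np.random.Generator,
    patient_id: str = "patient-0",
) -> tuple[CellBag, dict[str, int], float]:
    """Draw one synthetic patient bag.

    The cell-type composition is Dirichlet with the recipe's concentration,
    with the blast coordinate replaced by a uniform draw from the recipe's
    blast range (remaining coordinates renormalized to the complement).
    Cell types are drawn multinomially; each cell is its type centroid
    plus isotropic Gaussian noise; hemoglobin is Normal truncated to
    [3, 20] g/dL.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if len(profiles) != len(recipe.composition_concentration):
        raise ValueError("profiles and composition_concentration length mismatch")
    rng = _as_rng(seed)
    comp = rng.dirichlet(recipe.composition_concentration)
    lo, hi = recipe.blast_fraction_range
    blast = rng.uniform(lo, hi)
    rest = comp[1:]
    rest_sum = rest.sum()
    if rest_sum > 0:
        comp = np.concatenate([[blast], (1.0 - blast) * rest / rest_sum])
    else:  # degenerate: everything on the blast coordinate
        comp = np.concatenate([[1.0], np.zeros(len(rest))])
    counts = rng.multinomial(n_cells, comp)
    dim = len(profiles[0].mean_vector)
    embeddings = np.empty((n_cells, dim))
    types = np.empty(n_cells, dtype=object)
    row = 0
    for prof, k in zip(profiles, counts):
        if k == 0:
            continue
        embeddings[row : row + k] = prof.mean_vector + prof.spread * rng.normal(
            size=(k, dim)
        )
        types[row : row + k] = prof.name
        row += k
    # shuffle so cell order carries no type information
    perm = rng.permutation(n_cells)
    bag = CellBag(
        patient_id=patient_id,
        embeddings=embeddings[perm],
        cell_types=types[perm],
        latent_blast_fraction=float(blast),
    )
    hb = _truncated_normal(rng, recipe.hemoglobin_mean, recipe.hemoglobin_sd, *HB_BOUNDS)
    count_map = {prof.name: int(k) for prof, k in zip(profiles, counts)}
    return bag, count_map, hb


def _detailed_classes_of(h: LabelHierarchy, coarse: str) -> list[str]:
    dets = sorted(d for d, c in h.detailed_to_coarse.items() if c == coarse)
    return dets or [coarse]


def generate_cohort(
    n_patients: int,
    class_priors: Sequence[float] | None = None,
    n_cells: int = 500,
    seed: int = 0,
    *,
    profiles: Sequence[CellTypeProfile] | None = None,
    recipes: Mapping[str, ClassRecipe] | None = None,
    hierarchy: LabelHierarchy | None = None,
    embedding_dim: int = 768,
    n_cell_types: int = 6,
    separation: float = 5.0,
    spread: float = 1.0,
) -> tuple[pd.DataFrame, list[CellBag]]:
    """Generate a full cohort: manifest DataFrame plus aligned bags.

    ``class_priors`` follows the hierarchy's coarse-class order and
    defaults to the released test-set composition.  The whole cohort is a
    pure function of the arguments; the same seed reproduces it exactly.
    """
    h = hierarchy or default_hierarchy()
    if n_patients < len(h.coarse_classes):
        raise ValueError("n_patients must be at least the number of classes")
    priors = (
        released_test_set_priors(h)
        if class_priors is None
        else np.asarray(class_priors, dtype=float)
    )
    if priors.shape != (len(h.coarse_classes),):
        raise ValueError("class_priors length must equal the number of coarse classes")
    if abs(priors.sum() - 1.0) > 1e-9 or np.any(priors < 0):
        raise ValueError("class_priors must be a probability vector (sum 1 within 1e-9)")
    rng = np.random.default_rng(seed)
    if profiles is None or recipes is None:
        profiles, recipes = default_recipes(
            n_cell_types=n_cell_types,
            embedding_dim=embedding_dim,
            separation=separation,
            seed=rng,
            spread=spread,
            hierarchy=h,
        )
    classes = rng.choice(len(h.coarse_classes), size=n_patients, p=priors)
    rows = []
    bags: list[CellBag] = []
    profile_names = [p.name for p in profiles]
    for i, ci in enumerate(classes):
        coarse = h.coarse_classes[ci]
        pid = f"P{i:05d}"
        bag, counts, hb = generate_bag(
            recipes[coarse], profiles, n_cells, rng, patient_id=pid
        )
        detailed = rng.choice(_detailed_classes_of(h, coarse))
        total = sum(counts.values())
        row = {
            "patient_id": pid,
            "detailed_class": detailed,
            "coarse_class": coarse,
            "malignant": bool(h.malignant_flags[coarse]),
            "hemoglobin": hb,
            "blast_ratio": counts.get("myeloblast", 0) / total,
            "lymphocyte_ratio": counts.get("lymphocyte", 0) / total,
            "fold_id": -1,
        }
        for name in profile_names:
            row[f"count_{name}"] = counts[name]
        rows.append(row)
        bags.append(bag)
    manifest = pd.DataFrame(rows)
    return manifest, bags
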