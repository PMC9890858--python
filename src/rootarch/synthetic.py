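"""Synthetic root networks and trait tables with known ground truth.

Two generators stand in for the study's raw data:

* a geometric generator that grows 2D root networks (primary axes with
  Poisson-spawned laterals, headings perturbed by a tortuosity-scaled
  random walk) and rasterizes them into white-on-black masks, returning
  the analytic centerline length, depth and lateral count alongside —
  so trait extraction can be validated against exact ground truth;
* an additive trait-table generator that draws genotype, genotype x
  environment, genotype x replication and three-way interaction effects
  at stated variances for a balanced design (by default 200 genotypes x
  {HP, LP} x 2 replications), with three planted rooting-type
  archetypes (small / medium / large) separated along a latent size
  score — so heritability estimation and rooting-type classification
  can be validated against known components and labels.

The trait-table generator bypasses images entirely (statistical tests
stay fast); image generation is reserved for extraction tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import BinaryMask

__all__ = [
    "ArchetypeSpec",
    "GroundTruth",
    "SimulationConfig",
    "TraitParams",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_TRAIT_PARAMS",
    "SIZE_CLASSES",
    "simulate_root_polylines",
    "rasterize_network",
    "generate_trait_dataset",
    "generate_experiment",
]

SIZE_CLASSES = ("small", "medium", "large")

_STEP_CM = 0.1          # straight-segment length of the growth walk
_MAX_HEADING = 1.31     # ~75 deg from vertical; keeps roots growing downward
_LATERAL_ANGLE = math.pi / 3.0   # laterals leave the parent at ~±60 deg


@dataclass
class ArchetypeSpec:
    """Geometry of one rooting-type archetype."""

    n_primary: int = 3
    primary_depth_cm: float = 10.0     # axis length of each primary root
    lateral_rate_per_cm: float = 2.0   # Poisson rate of laterals per cm of primary
    lateral_length_cm: float = 1.5     # mean lateral axis length
    lateral_length_disp: float = 0.5   # s.d. of lateral length
    root_radius_cm: float = 0.018      # fine-root radius (~0.36 mm width)
    tortuosity: float = 0.25           # heading-noise scale, rad per sqrt(cm)
    gravitropism: float = 0.6          # per-cm pull of the heading to its course
    size_class: str = "medium"

    def __post_init__(self) -> None:
        for name in ("primary_depth_cm", "lateral_length_cm", "root_radius_cm"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        for name in ("lateral_rate_per_cm", "tortuosity", "lateral_length_disp",
                     "gravitropism"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative and finite, got {v}")
        if self.n_primary < 1:
            raise ValueError(f"n_primary must be >= 1, got {self.n_primary}")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"size_class must be one of {SIZE_CLASSES}")


@dataclass
class GroundTruth:
    """Analytic truth for one simulated root network."""

    total_centerline_length_cm: float
    n_lateral_roots: int
    max_depth_cm: float
    radius_cm: float


#: Rooting-type archetypes spanning the small/medium/large gradient the
#: classification stage must recover.
DEFAULT_ARCHETYPES: dict[str, ArchetypeSpec] = {
    "small": ArchetypeSpec(n_primary=2, primary_depth_cm=6.0,
                           lateral_rate_per_cm=1.2, lateral_length_cm=1.0,
                           lateral_length_disp=0.3, size_class="small"),
    "medium": ArchetypeSpec(n_primary=3, primary_depth_cm=10.0,
                            lateral_rate_per_cm=2.0, lateral_length_cm=1.5,
                            lateral_length_disp=0.5, size_class="medium"),
    "large": ArchetypeSpec(n_primary=4, primary_depth_cm=14.0,
                           lateral_rate_per_cm=2.8, lateral_length_cm=2.0,
                           lateral_length_disp=0.6, size_class="large"),
}


def _grow_axis(
    rng: np.random.Generator,
    origin: np.ndarray,
    heading: float,
    length_cm: float,
    tortuosity: float,
    bounds: tuple[float, float, float] | None,
    pull: float = 0.0,
    target_heading: float = 0.0,
) -> np.ndarray:
    """Random-walk polyline from ``origin``: straight 0.1 cm segments,
    heading (radians from vertical-down) perturbed by Gaussian noise at
    each step and relaxed toward ``target_heading`` at rate ``pull``
    per cm — the tropic pull that keeps primaries on their fanned
    course and bends laterals toward vertical.  Growth stops at
    ``bounds`` = (x_min, x_max, y_max)."""
    pts = [origin.copy()]
    pos = origin.copy()
    n_full, rem = divmod(length_cm, _STEP_CM)
    steps = [_STEP_CM] * int(n_full) + ([rem] if rem > 1e-9 else [])
    for step in steps:
        heading += tortuosity * rng.normal() * math.sqrt(step)
        heading = target_heading + (heading - target_heading) * math.exp(-pull * step)
        heading = float(np.clip(heading, -_MAX_HEADING, _MAX_HEADING))
        nxt = pos + step * np.array([math.sin(heading), math.cos(heading)])
        if bounds is not None:
            x_min, x_max, y_max = bounds
            if not (x_min <= nxt[0] <= x_max and 0.0 <= nxt[1] <= y_max):
                break
        pts.append(nxt)
        pos = nxt
    return np.array(pts)


def _polyline_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def simulate_root_polylines(
    arch: ArchetypeSpec,
    seed: int | np.random.SeedSequence,
    bounds_cm: tuple[float, float, float] | None = None,
) -> tuple[list[tuple[np.ndarray, float]], GroundTruth]:
    """Grow one root network as centerline polylines with radii.

    All roots start (directly or via their parent) at a common crown
    point at the top edge, (0, 0), with y increasing downward.  Primary
    axes fan out around vertical; laterals spawn along each primary as
    a Poisson process at ``lateral_rate_per_cm`` and leave at ~±60 deg
    from the parent's local heading.

    Returns the polylines as ``(points, radius_cm)`` pairs and a
    :class:`GroundTruth` whose totals are sums over the generated
    segments (so they remain exact when ``bounds_cm`` truncates a
    root at the domain edge).
    """
    rng = np.random.default_rng(seed)
    polylines: list[tuple[np.ndarray, float]] = []
    n_lat = 0

    if arch.n_primary == 1:
        fan = np.array([0.0])
    else:
        fan = np.linspace(-0.5, 0.5, arch.n_primary)
    crown = np.zeros(2)
    for heading0 in fan:
        primary = _grow_axis(rng, crown, float(heading0),
                             arch.primary_depth_cm, arch.tortuosity, bounds_cm,
                             pull=arch.gravitropism, target_heading=float(heading0))
        polylines.append((primary, arch.root_radius_cm))
        seg_len = np.linalg.norm(np.diff(primary, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg_len)])
        total_len = arc[-1]
        n_here = rng.poisson(arch.lateral_rate_per_cm * total_len)
        if total_len <= 0 or n_here == 0:
            continue
        positions = np.sort(rng.uniform(0.0, total_len, n_here))
        for pos_cm in positions:
            i = int(np.searchsorted(arc, pos_cm, side="right") - 1)
            i = min(i, len(primary) - 2)
            frac = (pos_cm - arc[i]) / max(arc[i + 1] - arc[i], 1e-12)
            start = primary[i] + frac * (primary[i + 1] - primary[i])
            d = primary[i + 1] - primary[i]
            parent_heading = math.atan2(d[0], d[1])
            side = rng.choice([-1.0, 1.0])
            heading = parent_heading + side * (_LATERAL_ANGLE + 0.15 * rng.normal())
            length = max(0.1, rng.normal(arch.lateral_length_cm,
                                         arch.lateral_length_disp))
            lat = _grow_axis(rng, start, heading, length,
                             arch.tortuosity, bounds_cm,
                             pull=arch.gravitropism, target_heading=0.0)
            if len(lat) > 1:
                polylines.append((lat, arch.root_radius_cm))
                n_lat += 1

    total = sum(_polyline_length(p) for p, _ in polylines)
    max_depth = max(float(p[:, 1].max()) for p, _ in polylines)
    truth = GroundTruth(
        total_centerline_length_cm=total,
        n_lateral_roots=n_lat,
        max_depth_cm=max_depth,
        radius_cm=arch.root_radius_cm,
    )
    return polylines, truth


def rasterize_network(
    polylines: list[tuple[np.ndarray, float]],
    canvas_px: tuple[int, int],
    px_per_cm: float,
    origin_px: tuple[float, float] | None = None,
) -> BinaryMask:
    """Rasterize centerline polylines into a binary mask.

    The foreground is the union of disks of the local radius swept
    along each centerline: a pixel is set when its center lies within
    the root radius of the (continuous) centerline, computed by exact
    point-to-segment distances, and every digitized centerline pixel
    is set regardless, so roots thinner than a pixel stay connected.
    The crown (0, 0) maps to ``origin_px`` (row, col), by default just
    below the top edge at the geometric center of the pixel grid.
    """
    h, w = canvas_px
    grid = np.zeros((h, w), dtype=bool)
    if not polylines:
        return BinaryMask(grid=grid, px_per_cm=px_per_cm)

    max_r_px = max(r for _, r in polylines) * px_per_cm
    if origin_px is None:
        origin_px = (math.ceil(max_r_px) + 2, (w - 1) / 2.0)
    r0, c0 = origin_px

    for points, radius in polylines:
        px = np.empty_like(points)
        px[:, 0] = r0 + points[:, 1] * px_per_cm   # row from depth
        px[:, 1] = c0 + points[:, 0] * px_per_cm   # col from x
        r_px = radius * px_per_cm
        bad = (
            (px[:, 0] < r_px - 0.5) | (px[:, 0] > h - 1 - r_px + 0.5)
            | (px[:, 1] < r_px - 0.5) | (px[:, 1] > w - 1 - r_px + 0.5)
        )
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"polyline point ({points[i, 0]:.3f}, {points[i, 1]:.3f}) cm "
                f"maps outside the {h}x{w} px canvas at {px_per_cm} px/cm"
            )
        for a, b in zip(px[:-1], px[1:]):
            # disks swept along segment a-b: exact distance in a bounding box
            lo_r = max(0, math.floor(min(a[0], b[0]) - r_px) - 1)
            hi_r = min(h - 1, math.ceil(max(a[0], b[0]) + r_px) + 1)
            lo_c = max(0, math.floor(min(a[1], b[1]) - r_px) - 1)
            hi_c = min(w - 1, math.ceil(max(a[1], b[1]) + r_px) + 1)
            rr = np.arange(lo_r, hi_r + 1)[:, None]
            cc = np.arange(lo_c, hi_c + 1)[None, :]
            d = b - a
            denom = float(d @ d)
            if denom == 0:
                dist2 = (rr - a[0]) ** 2 + (cc - a[1]) ** 2
            else:
                t = ((rr - a[0]) * d[0] + (cc - a[1]) * d[1]) / denom
                t = np.clip(t, 0.0, 1.0)
                dist2 = (rr - (a[0] + t * d[0])) ** 2 + (cc - (a[1] + t * d[1])) ** 2
            grid[lo_r : hi_r + 1, lo_c : hi_c + 1] |= dist2 <= r_px * r_px
            # digitized centerline, so sub-pixel-thin roots stay connected
            n = max(2, int(math.ceil(math.sqrt(denom) / 0.4)) + 1)
            line = np.linspace(a, b, n)
            grid[np.clip(np.rint(line[:, 0]).astype(int), 0, h - 1),
                 np.clip(np.rint(line[:, 1]).astype(int), 0, w - 1)] = True
    return BinaryMask(grid=grid, px_per_cm=px_per_cm)


# ---------------------------------------------------------------------------
# trait-table generator
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Design and variance structure of a simulated trait experiment.

    Variance components are on the latent (standardized) trait scale
    and follow the additive decomposition value = mu + shift_LP + g +
    ge + gr + ger underlying the broad-sense heritability formula.
    Planted rooting types displace each genotype's latent size score by
    (-sep, 0, +sep) genotype standard deviations.
    """

    n_genotypes: int = 200
    environments: tuple[str, ...] = ("HP", "LP")
    n_replications: int = 2
    sigma_g: float = 1.0
    sigma_ge: float = 0.25
    sigma_gr: float = 0.25
    sigma_ger: float = 0.25
    treatment_shift: float = 0.0        # latent-scale LP main effect
    type_proportions: dict = field(
        default_factory=lambda: {"small": 0.255, "medium": 0.46, "large": 0.285}
    )
    type_separation: float = 3.0        # in genotype-s.d. units of the size score
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_g", "sigma_ge", "sigma_gr", "sigma_ger"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replications < 2:
            raise ValueError(
                "n_replications must be >= 2 (heritability denominators are "
                "undefined with a single replication)"
            )
        if self.n_genotypes < 1:
            raise ValueError("n_genotypes must be >= 1")
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"type_proportions must sum to 1, got {total}")
        if set(self.type_proportions) != set(SIZE_CLASSES):
            raise ValueError(f"type_proportions keys must be {SIZE_CLASSES}")

    @property
    def genotype_ids(self) -> list[str]:
        return [f"G{i + 1:03d}" for i in range(self.n_genotypes)]


@dataclass
class TraitParams:
    """Marginal parameters of one trait in the table generator.

    ``h2`` fixes the split of unit latent variance into components via
    the heritability formula (interactions equal); ``None`` means use
    the config's sigma components directly.  ``size_loading`` is the
    correlation of the genotype effect with the shared latent size
    score; negative for traits that run against root-system size.
    """

    hp_mean: float
    lp_shift: float = 0.0
    sd: float = 1.0
    h2: float | None = None
    size_loading: float = 0.0
    nonneg: bool = True


def _components_from_h2(h2: float) -> tuple[float, float]:
    """(sigma_g, c) with sigma_ge = sigma_gr = sigma_ger = c, unit total
    variance sigma_g + 3c = 1, and h2 = sigma_g / (sigma_g + 1.25 c)."""
    if h2 <= 0:
        return 0.0, 1.0 / 3.0
    sigma_g = 1.25 * h2 / (1.25 * h2 + 3.0 * (1.0 - h2))
    return sigma_g, (1.0 - sigma_g) / 3.0


#: Trait magnitudes, LP shifts, s.d. and heritabilities matching the
#: published 200-genotype HP/LP experiment; size loadings follow the
#: reported correlation structure (the ten strongly intercorrelated
#: size/extent/count traits load ~0.95, width- and distribution-type
#: traits load weakly or negatively).
DEFAULT_TRAIT_PARAMS: dict[str, TraitParams] = {
    "SDW":  TraitParams(0.065, -0.003, 0.021, 0.75, 0.90),
    "RDW":  TraitParams(0.026, -0.002, 0.011, 0.70, 0.90),
    "SRR":  TraitParams(2.50, -0.05, 0.64, 0.49, 0.30),
    "ARW":  TraitParams(0.047, 0.000, 0.005, 0.42, -0.50),
    "NeA":  TraitParams(13.60, -1.155, 5.764, 0.67, 0.95),
    "NeL":  TraitParams(360.21, -30.74, 165.21, 0.65, 0.95),
    "NeP":  TraitParams(669.35, -58.79, 311.97, 0.65, 0.95),
    "NeSA": TraitParams(51.975, -4.408, 22.030, 0.66, 0.95),
    "NeV":  TraitParams(0.764, -0.060, 0.308, 0.66, 0.95),
    "MaEA": TraitParams(19.166, 0.301, 3.073, 0.62, 0.85),
    "MiEA": TraitParams(8.301, -0.518, 3.172, 0.31, 0.95),
    "NeCA": TraitParams(163.12, -9.04, 71.746, 0.54, 0.95),
    "NeD":  TraitParams(20.516, 0.141, 3.038, 0.67, 0.85),
    "NeW":  TraitParams(10.365, -0.544, 4.047, 0.43, 0.95),
    "MaNR": TraitParams(13.583, -1.151, 4.464, 0.51, 0.95),
    "MeNR": TraitParams(7.869, -0.773, 3.149, 0.53, 0.95),
    "NeB":  TraitParams(1.817, 0.021, 0.468, 0.06, -0.40),
    "NeLD": TraitParams(0.541, 0.049, 0.258, 0.28, -0.55),
    "NeS":  TraitParams(0.088, -0.002, 0.024, 0.45, -0.60),
    "SRL":  TraitParams(466.1, -4.6, 95.74, 0.44, -0.55),
    "EAR":  TraitParams(0.433, -0.032, 0.154, 0.00, 0.0),
    "NeWDR": TraitParams(0.499, -0.029, 0.173, 0.18, 0.50),
}

_TYPE_OFFSET = {"small": -1.0, "medium": 0.0, "large": 1.0}

#: weight of the shared (size-factor) component in each trait's
#: within-type genotype variation; the rest is trait-idiosyncratic
_WITHIN_SHARED = 0.45


def _assign_types(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    probs = [config.type_proportions[c] for c in SIZE_CLASSES]
    return rng.choice(np.array(SIZE_CLASSES), size=config.n_genotypes, p=probs)


def generate_trait_dataset(
    config: SimulationConfig,
    traits: dict[str, TraitParams] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a balanced long-format trait observation table.

    With ``traits=None`` a single latent trait is generated with the
    config's variance components and treatment shift exactly — the mode
    used to validate variance-component and heritability recovery.
    Passing :data:`DEFAULT_TRAIT_PARAMS` (as the pipeline does) yields
    the full 22-trait table at published magnitudes, with per-trait
    heritabilities and a shared size score carrying the planted
    rooting-type structure.

    Returns ``(table, truth)``: the table has one row per genotype x
    environment x replication x trait; ``truth`` records the planted
    type of every genotype, the latent size scores, and each trait's
    generating components.
    """
    rng = np.random.default_rng(config.seed)
    n_g = config.n_genotypes
    envs = tuple(config.environments)
    n_e, n_r = len(envs), config.n_replications

    types = _assign_types(config, rng)
    offsets = np.array([_TYPE_OFFSET[t] for t in types])
    shared = rng.normal(size=n_g)            # within-type size factor, shared
    size_score = config.type_separation * offsets + shared

    if traits is None:
        traits = {
            "latent": TraitParams(
                hp_mean=0.0, lp_shift=config.treatment_shift, sd=1.0,
                h2=None, size_loading=1.0, nonneg=False,
            )
        }

    frames = []
    truth_components: dict[str, dict] = {}
    for name, tp in traits.items():
        if tp.h2 is None:
            sg, sge, sgr, sger = (config.sigma_g, config.sigma_ge,
                                  config.sigma_gr, config.sigma_ger)
        else:
            sg, c = _components_from_h2(tp.h2)
            sge = sgr = sger = c
        # Genotype effect: between-type offset plus within-type variation.
        # The within-type part mixes the shared size factor (weight
        # _WITHIN_SHARED * loading) with trait-idiosyncratic variation so
        # that Var(g) = sigma_g exactly for any loading when the type
        # separation is zero; adjacent type centroids sit
        # type_separation * loading within-type s.d. apart in each trait.
        lam = tp.size_loading
        a = _WITHIN_SHARED
        ind = rng.normal(size=n_g)
        within = a * lam * shared + math.sqrt(max(0.0, 1.0 - (a * lam) ** 2)) * ind
        g = math.sqrt(sg) * (config.type_separation * lam * offsets + within)
        ge = math.sqrt(sge) * rng.normal(size=(n_g, n_e))
        gr = math.sqrt(sgr) * rng.normal(size=(n_g, n_r))
        ger = math.sqrt(sger) * rng.normal(size=(n_g, n_e, n_r))

        latent = (g[:, None, None] + ge[:, :, None] + gr[:, None, :] + ger)
        shift = np.array([tp.lp_shift if e == "LP" else 0.0 for e in envs])
        values = tp.hp_mean + shift[None, :, None] + tp.sd * latent
        if tp.nonneg:
            values = np.clip(values, 0.0, None)

        idx = pd.MultiIndex.from_product(
            [config.genotype_ids, envs, range(1, n_r + 1)],
            names=["genotype", "environment", "replication"],
        )
        df = pd.DataFrame({"value": values.ravel()}, index=idx).reset_index()
        df.insert(3, "trait", name)
        frames.append(df)
        truth_components[name] = {
            "sigma_g": sg, "sigma_ge": sge, "sigma_gr": sgr, "sigma_ger": sger,
            "h2": (sg / (sg + sge / 2 + sgr / 2 + sger / 4)
                   if sg + sge + sgr + sger > 0 else math.nan),
            "g": g, "size_loading": lam,
        }

    table = pd.concat(frames, ignore_index=True)
    truth = {
        "types": pd.Series(types, index=config.genotype_ids, name="type"),
        "size_score": pd.Series(size_score, index=config.genotype_ids),
        "components": truth_components,
        "config": config,
    }
    return table, truth


# ---------------------------------------------------------------------------
# full experiment writer (images + CSVs + ground truth)
# ---------------------------------------------------------------------------

#: dry tissue density matching published RDW ~0.026 g at NeV ~0.76 cm^3
_TISSUE_DENSITY_G_PER_CM3 = 0.034
_SHOOT_TO_ROOT = 2.5
_LP_SIZE_FACTOR = 0.92     # LP roots ~8% smaller, as in the size traits


def _scaled_archetype(arch: ArchetypeSpec, factor: float) -> ArchetypeSpec:
    """Latent size score scales depth and lateral rate multiplicatively."""
    return ArchetypeSpec(
        n_primary=arch.n_primary,
        primary_depth_cm=arch.primary_depth_cm * factor,
        lateral_rate_per_cm=arch.lateral_rate_per_cm * factor,
        lateral_length_cm=arch.lateral_length_cm,
        lateral_length_disp=arch.lateral_length_disp,
        root_radius_cm=arch.root_radius_cm,
        tortuosity=arch.tortuosity,
        gravitropism=arch.gravitropism,
        size_class=arch.size_class,
    )


def generate_experiment(
    config: SimulationConfig,
    archetype_map: dict[str, ArchetypeSpec] | None = None,
    out_dir: str | Path = ".",
    px_per_cm: float = 50.0,
    canvas_cm: tuple[float, float] = (24.0, 22.0),
) -> dict:
    """Write a complete synthetic experiment to ``out_dir``.

    One white-on-black PNG mask per plant (rhizotron-window canvas,
    default 24 x 22 cm), a metadata CSV (plant_id, genotype,
    environment, replication), a dry-weight CSV (plant_id, SDW_g,
    RDW_g) and a ground-truth JSON.  Re-running with the same config
    reproduces byte-identical CSV/JSON output.

    ``archetype_map`` maps size-class names to archetypes; a genotype
    whose planted class is missing from the map raises an error naming
    the genotype.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    if archetype_map is None:
        archetype_map = DEFAULT_ARCHETYPES

    rng = np.random.default_rng(config.seed)
    types = _assign_types(config, rng)
    h_px = int(round(canvas_cm[0] * px_per_cm))
    w_px = int(round(canvas_cm[1] * px_per_cm))

    meta_rows, weight_rows, truths = [], [], {}
    plant_index = 0
    for gi, genotype in enumerate(config.genotype_ids):
        size_class = str(types[gi])
        if size_class not in archetype_map:
            raise KeyError(
                f"no archetype for genotype {genotype} (size class {size_class!r})"
            )
        base = archetype_map[size_class]
        g_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, 500_000 + gi)))
        g_factor = float(np.exp(0.12 * g_rng.normal()))
        for env in config.environments:
            env_factor = _LP_SIZE_FACTOR if env == "LP" else 1.0
            arch = _scaled_archetype(base, g_factor * env_factor)
            for rep in range(1, config.n_replications + 1):
                plant_id = f"{genotype}_{env}_r{rep}"
                seed_seq = np.random.SeedSequence((config.seed, plant_index))
                margin = 2.0 * arch.root_radius_cm + 0.2
                bounds = (-(canvas_cm[1] / 2 - margin),
                          canvas_cm[1] / 2 - margin,
                          canvas_cm[0] - 2 * margin)
                polylines, truth = simulate_root_polylines(
                    arch, seed_seq, bounds_cm=bounds)
                mask = rasterize_network(polylines, (h_px, w_px), px_per_cm)
                mask.save(img_dir / f"{plant_id}.png")

                wr = np.random.default_rng(seed_seq.spawn(1)[0])
                rdw = (_TISSUE_DENSITY_G_PER_CM3 * math.pi
                       * truth.radius_cm**2 * truth.total_centerline_length_cm
                       * float(np.exp(0.10 * wr.normal())))
                sdw = rdw * _SHOOT_TO_ROOT * float(np.exp(0.15 * wr.normal()))
                meta_rows.append((plant_id, genotype, env, rep))
                weight_rows.append((plant_id, round(sdw, 6), round(rdw, 6)))
                truths[plant_id] = {
                    "total_centerline_length_cm": truth.total_centerline_length_cm,
                    "n_lateral_roots": truth.n_lateral_roots,
                    "max_depth_cm": truth.max_depth_cm,
                    "radius_cm": truth.radius_cm,
                    "size_class": size_class,
                }
                plant_index += 1

    meta = pd.DataFrame(meta_rows,
                        columns=["plant_id", "genotype", "environment", "replication"])
    weights = pd.DataFrame(weight_rows, columns=["plant_id", "SDW_g", "RDW_g"])
    meta.to_csv(out_dir / "metadata.csv", index=False)
    weights.to_csv(out_dir / "weights.csv", index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    return {
        "n_plants": len(meta_rows),
        "images_dir": str(img_dir),
        "metadata_csv": str(out_dir / "metadata.csv"),
        "weights_csv": str(out_dir / "weights.csv"),
        "ground_truth_json": str(out_dir / "ground_truth.json"),
        "px_per_cm": px_per_cm,
    }
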