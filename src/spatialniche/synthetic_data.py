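"""Ground-truthed marked point-pattern tissue simulator.

Generates segmented-cell tables (no pixels) with the spatial organization the
downstream analysis assumes, so every stage can be tested against a recorded
ground truth.  A sample is a rectangular field (μm, origin bottom-left, y-up)
with three regions:

* ``tumor_core``      — a disk of tumor cells;
* ``stroma_margin``   — an annulus of configurable width around the core;
* ``stroma``          — the remainder of the field.

Three tissue archetypes are provided:

``immune_desert``
    COX2+ tumor core devoid of CD8+ T cells, sparse distal CD8+ lymphoid
    aggregates 500-1,000 μm beyond the margin.
``inflamed_margin``
    COX2+ core plus CD8-NOS2+COX2+ satellite clusters (Thomas process,
    Gaussian offspring) seeded on the tumor edge, with stroma-restricted
    CD8+ cells held off the edge by a configurable gap (default 50 μm) and
    distal aggregates.
``fully_inflamed``
    Diffuse CD8+NOS2-COX2- infiltration throughout the core and stroma.

Homogeneous Poisson sampling is used within each region at configured
intensities (cells/mm^2).  Marker intensities are synthesized so that the
canonical quantization rule recovers the intended level exactly at zero
noise: level means sit midway between the canonical thresholds (1, 2, 3)
and Gaussian noise of configurable sd is added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .phenotyping import QuantizationRule

UM2_PER_MM2 = 1e6

REGIONS = ("tumor_core", "stroma_margin", "stroma")

ARCHETYPES = ("immune_desert", "inflamed_margin", "fully_inflamed")

#: canonical intensity thresholds used by the generator (per marker)
CANONICAL_THRESHOLDS = (1.0, 2.0, 3.0)

#: intensity mean for each level: midway between canonical thresholds
LEVEL_MEANS = {"negative": 0.5, "weak": 1.5, "moderate": 2.5, "strong": 3.5}

#: marker levels synthesized for each phenotype code.  Positive NOS2 cells
#: are given *strong* signal so strong-NOS2 ("NOS2s") analyses see them;
#: positive CD8/COX2 cells are given moderate signal.
CODE_LEVELS = {
    code: {
        "cd8": "moderate" if code & 4 else "negative",
        "nos2": "strong" if code & 2 else "negative",
        "cox2": "moderate" if code & 1 else "negative",
    }
    for code in range(8)
}


def canonical_rule() -> QuantizationRule:
    """The quantization rule the generator's intensities are built for."""
    return QuantizationRule(
        thresholds={m: CANONICAL_THRESHOLDS for m in ("cd8", "nos2", "cox2")}
    )


# default per-region Poisson intensities (cells/mm^2) per archetype.
# phenotype codes: 0=triple-negative, 1=CD8-NOS2-COX2+, 3=CD8-NOS2+COX2+,
# 4=CD8+NOS2-COX2-.  The fully_inflamed baseline of code-3 cells provides a
# nonzero reference density against which planted satellite niches are
# ~10x enriched locally (see docs/methods.md).
DEFAULT_INTENSITIES = {
    "immune_desert": {
        "tumor_core": {1: 1000.0},
        "stroma_margin": {0: 300.0, 1: 150.0},
        "stroma": {0: 250.0},
    },
    "inflamed_margin": {
        "tumor_core": {1: 700.0, 0: 200.0},
        "stroma_margin": {0: 200.0},
        "stroma": {0: 250.0},
    },
    "fully_inflamed": {
        "tumor_core": {0: 400.0, 4: 800.0, 3: 320.0},
        "stroma_margin": {0: 250.0, 4: 500.0, 3: 320.0},
        "stroma": {0: 250.0, 4: 400.0, 3: 320.0},
    },
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated tissue sample.

    Distances in μm, intensities in cells/mm^2.
    """

    seed: int = 0
    archetype: str = "fully_inflamed"
    field_size_um: tuple = (2000.0, 2000.0)
    tumor_center_um: tuple = (1000.0, 1000.0)
    tumor_radius_um: float = 600.0
    stroma_margin_um: float = 300.0
    #: region -> {phenotype_code: lambda}; None = archetype default
    intensities: dict | None = None
    #: satellite Thomas clusters on the tumor edge (inflamed_margin only):
    #: (n_parents, mean offspring per parent, offspring sd μm)
    satellite_clusters: tuple = (10, 40.0, 30.0)
    #: offset of stroma-restricted CD8+ cells from the tumor edge
    cd8_gap_um: float = 50.0
    #: width and intensity of the stroma-restricted CD8+ band at the gap
    cd8_band_um: float = 20.0
    cd8_band_intensity: float = 3000.0
    #: distal CD8+ lymphoid aggregates: (n, cells per aggregate, sd μm)
    aggregates: tuple = (2, 60, 40.0)
    #: aggregate centers placed uniformly this far beyond the tumor edge
    aggregate_offset_um: tuple = (500.0, 1000.0)
    #: Gaussian sd of marker intensity noise (0 = exactly invertible)
    noise_sd: float = 0.15

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        w, h = self.field_size_um
        cx, cy = self.tumor_center_um
        r = self.tumor_radius_um
        if not (r > 0 and r <= cx <= w - r and r <= cy <= h - r):
            raise ValueError("tumor core must fit inside the field")
        if self.stroma_margin_um < 0 or self.cd8_gap_um < 0:
            raise ValueError("margin and gap must be >= 0")
        if self.satellite_clusters[2] <= 0 or self.aggregates[2] <= 0:
            raise ValueError("cluster dispersion sd must be > 0")
        if min(self.aggregate_offset_um) < 0:
            raise ValueError("aggregate offsets must be >= 0")
        for region, lam in (self.intensities or {}).items():
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
            if any(v < 0 for v in lam.values()):
                raise ValueError("intensities must be >= 0")

    def region_intensities(self) -> dict:
        base = {
            reg: dict(lam)
            for reg, lam in DEFAULT_INTENSITIES[self.archetype].items()
        }
        for reg, lam in (self.intensities or {}).items():
            base[reg] = dict(lam)
        return base

    def region_areas_mm2(self) -> dict:
        w, h = self.field_size_um
        r, m = self.tumor_radius_um, self.stroma_margin_um
        core = np.pi * r**2
        margin = np.pi * ((r + m) ** 2 - r**2)
        return {
            "tumor_core": core / UM2_PER_MM2,
            "stroma_margin": margin / UM2_PER_MM2,
            "stroma": (w * h - core - margin) / UM2_PER_MM2,
        }


@dataclass
class GroundTruth:
    """Per-cell truth and per-region bookkeeping for one simulated sample."""

    phenotype: np.ndarray  # true code per cell
    region: np.ndarray  # region label per cell
    niche: np.ndarray  # 'background', 'satellite:<i>', 'fence', 'aggregate:<i>'
    levels: pd.DataFrame  # true level per marker per cell
    realized_densities: dict  # region -> {code: cells/mm^2}
    region_areas_mm2: dict


def _sample_disk(rng, n, center, radius):
    theta = rng.uniform(0, 2 * np.pi, n)
    rad = radius * np.sqrt(rng.uniform(0, 1, n))
    return np.column_stack(
        [center[0] + rad * np.cos(theta), center[1] + rad * np.sin(theta)]
    )


def _sample_annulus(rng, n, center, r_in, r_out):
    theta = rng.uniform(0, 2 * np.pi, n)
    rad = np.sqrt(rng.uniform(r_in**2, r_out**2, n))
    return np.column_stack(
        [center[0] + rad * np.cos(theta), center[1] + rad * np.sin(theta)]
    )


def _sample_outer_stroma(rng, n, cfg: SimulationConfig):
    """Uniform points in the field outside the core+margin disk (rejection)."""
    w, h = cfg.field_size_um
    r_excl = cfg.tumor_radius_um + cfg.stroma_margin_um
    cx, cy = cfg.tumor_center_um
    pts = np.empty((0, 2))
    while len(pts) < n:
        cand = rng.uniform([0, 0], [w, h], size=(max(2 * n, 64), 2))
        keep = np.hypot(cand[:, 0] - cx, cand[:, 1] - cy) > r_excl
        pts = np.vstack([pts, cand[keep]])
    return pts[:n]


def _region_sampler(region, cfg):
    c, r, m = cfg.tumor_center_um, cfg.tumor_radius_um, cfg.stroma_margin_um
    if region == "tumor_core":
        return lambda rng, n: _sample_disk(rng, n, c, r)
    if region == "stroma_margin":
        return lambda rng, n: _sample_annulus(rng, n, c, r, r + m)
    return lambda rng, n: _sample_outer_stroma(rng, n, cfg)


def _in_field(xy, cfg):
    w, h = cfg.field_size_um
    return (
        (xy[:, 0] >= 0) & (xy[:, 0] <= w) & (xy[:, 1] >= 0) & (xy[:, 1] <= h)
    )


def _classify_region(xy, cfg):
    d = np.hypot(
        xy[:, 0] - cfg.tumor_center_um[0], xy[:, 1] - cfg.tumor_center_um[1]
    )
    out = np.full(len(xy), "stroma", dtype=object)
    out[d <= cfg.tumor_radius_um + cfg.stroma_margin_um] = "stroma_margin"
    out[d <= cfg.tumor_radius_um] = "tumor_core"
    return out


def simulate_sample(config: SimulationConfig, sample_id: str = "s0"):
    """Generate one tissue sample.

    Returns ``(cells, truth)`` where ``cells`` is a DataFrame with columns
    cell_id, sample_id, x_um, y_um, cd8, nos2, cox2, region, true_phenotype
    and ``truth`` is the matching :class:`GroundTruth`.  Identical config and
    seed give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    areas = config.region_areas_mm2()
    lam_map = config.region_intensities()

    xs, phen, region, niche = [], [], [], []

    # homogeneous Poisson background per region x phenotype
    for reg in REGIONS:
        sampler = _region_sampler(reg, config)
        for code in sorted(lam_map.get(reg, {})):
            lam = lam_map[reg][code]
            n = rng.poisson(lam * areas[reg])
            if lam > 0 and n == 0:
                warnings.warn(
                    f"{sample_id}: region {reg} phenotype {code} realized "
                    "0 cells"
                )
            pts = sampler(rng, n)
            xs.append(pts)
            phen.append(np.full(n, code))
            region.append(np.full(n, reg, dtype=object))
            niche.append(np.full(n, "background", dtype=object))

    cx, cy = config.tumor_center_um
    r = config.tumor_radius_um

    if config.archetype == "inflamed_margin":
        # CD8-NOS2+COX2+ satellite clusters: Thomas process with parents on
        # the tumor edge circle and isotropic Gaussian offspring
        # parents evenly spaced on the edge (jittered) so neighboring
        # satellites do not overlap and the planted local offspring density
        # stays analytically predictable: mu * (1 - exp(-R^2/(4 sigma^2)))
        # / (pi R^2) within radius R of a member cell
        n_parents, mu_off, sigma = config.satellite_clusters
        spacing = 2 * np.pi / int(n_parents)
        theta = (
            np.arange(int(n_parents)) * spacing
            + rng.uniform(0, spacing)
            + rng.normal(0, 0.02 * spacing, int(n_parents))
        )
        parents = np.column_stack(
            [cx + r * np.cos(theta), cy + r * np.sin(theta)]
        )
        for i, p in enumerate(parents):
            n_off = rng.poisson(mu_off)
            pts = p + rng.normal(0, sigma, size=(n_off, 2))
            keep = _in_field(pts, config)
            pts = pts[keep]
            xs.append(pts)
            phen.append(np.full(len(pts), 3))
            region.append(_classify_region(pts, config))
            niche.append(np.full(len(pts), f"satellite:{i}", dtype=object))

        # stroma-restricted CD8+ band held off the tumor edge by cd8_gap_um
        r_in = r + config.cd8_gap_um
        r_out = r_in + config.cd8_band_um
        band_area = np.pi * (r_out**2 - r_in**2) / UM2_PER_MM2
        n_band = rng.poisson(config.cd8_band_intensity * band_area)
        pts = _sample_annulus(rng, n_band, (cx, cy), r_in, r_out)
        pts = pts[_in_field(pts, config)]
        xs.append(pts)
        phen.append(np.full(len(pts), 4))
        region.append(_classify_region(pts, config))
        niche.append(np.full(len(pts), "fence", dtype=object))

    if config.archetype in ("immune_desert", "inflamed_margin"):
        # distal CD8+ lymphoid aggregates, 500-1,000 μm beyond the edge;
        # cells falling outside the field (tissue boundary) are dropped
        n_agg, n_cells, sigma = config.aggregates
        lo, hi = config.aggregate_offset_um
        for i in range(int(n_agg)):
            theta = rng.uniform(0, 2 * np.pi)
            rad = r + rng.uniform(lo, hi)
            center = np.array(
                [cx + rad * np.cos(theta), cy + rad * np.sin(theta)]
            )
            pts = center + rng.normal(0, sigma, size=(int(n_cells), 2))
            keep = _in_field(pts, config)
            # aggregates must respect the CD8 gap even if placed obliquely
            d_edge = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r
            keep &= d_edge >= config.cd8_gap_um
            pts = pts[keep]
            xs.append(pts)
            phen.append(np.full(len(pts), 4))
            region.append(_classify_region(pts, config))
            niche.append(np.full(len(pts), f"aggregate:{i}", dtype=object))

    xy = np.vstack(xs) if xs else np.empty((0, 2))
    phen = np.concatenate(phen).astype(int) if phen else np.empty(0, int)
    region = np.concatenate(region) if region else np.empty(0, object)
    niche = np.concatenate(niche) if niche else np.empty(0, object)

    n = len(xy)
    levels = pd.DataFrame(
        {
            m: np.array([CODE_LEVELS[c][m] for c in phen], dtype=object)
            for m in ("cd8", "nos2", "cox2")
        }
    )
    intensities = {
        m: np.array([LEVEL_MEANS[lvl] for lvl in levels[m]])
        + (rng.normal(0, config.noise_sd, n) if config.noise_sd > 0 else 0.0)
        for m in ("cd8", "nos2", "cox2")
    }

    cells = pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_c{i:06d}" for i in range(n)],
            "sample_id": sample_id,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "cd8": np.clip(intensities["cd8"], 0, None),
            "nos2": np.clip(intensities["nos2"], 0, None),
            "cox2": np.clip(intensities["cox2"], 0, None),
            "region": region,
            "true_phenotype": phen,
        }
    )

    realized = {}
    for reg in REGIONS:
        mask = region == reg
        realized[reg] = {
            int(c): float(np.sum(phen[mask] == c) / areas[reg])
            for c in np.unique(phen[mask])
        }
    truth = GroundTruth(
        phenotype=phen,
        region=region,
        niche=niche,
        levels=levels,
        realized_densities=realized,
        region_areas_mm2=areas,
    )
    return cells, truth


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample seed from a master seed (counter-based)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    n_deceased: int,
    n_alive: int,
    base_config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
):
    """Simulate a two-outcome cohort.

    Deceased samples alternate between the ``immune_desert`` and
    ``inflamed_margin`` archetypes; alive samples are ``fully_inflamed``.
    Per-sample seeds are derived deterministically from the master seed.

    Returns ``(cells, meta, truths)``: the concatenated cell table, a
    per-sample metadata DataFrame (sample_id, group, archetype, seed,
    survival time_years/event), and ``{sample_id: GroundTruth}``.
    """
    if n_deceased < 1 or n_alive < 1:
        raise ValueError("need at least one sample per group")
    rng = np.random.default_rng(derive_seed(seed, 10_000))
    tables, meta, truths = [], [], {}
    plan = [("deceased", i) for i in range(n_deceased)] + [
        ("alive", i) for i in range(n_alive)
    ]
    for idx, (group, i) in enumerate(plan):
        if group == "deceased":
            arch = "immune_desert" if i % 2 == 0 else "inflamed_margin"
            time_years = float(rng.uniform(0.5, 4.5))
            event = 1
        else:
            arch = "fully_inflamed"
            time_years, event = 5.0, 0
        sid = f"{group[0]}{i:02d}"
        cfg = replace(base_config, archetype=arch, seed=derive_seed(seed, idx))
        cells, truth = simulate_sample(cfg, sample_id=sid)
        tables.append(cells)
        truths[sid] = truth
        meta.append(
            {
                "sample_id": sid,
                "group": group,
                "archetype": arch,
                "seed": cfg.seed,
                "time_years": time_years,
                "event": event,
            }
        )
    return (
        pd.concat(tables, ignore_index=True),
        pd.DataFrame(meta),
        truths,
    )


def simulate_survival_cohort(
    n: int,
    true_hr: float,
    censor_rate: float = 0.0,
    horizon_years: float | None = None,
    baseline_hazard: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-stratum exponential survival data with a planted hazard ratio.

    ``n`` subjects split evenly into ``low`` (hazard ``baseline_hazard``
    per year) and ``high`` (hazard ``baseline_hazard * true_hr``) strata.
    With probability ``censor_rate`` a subject is randomly censored at a
    uniform fraction of its event time; if ``horizon_years`` is given,
    administrative censoring is applied there as well.
    """
    if true_hr <= 0:
        raise ValueError("true_hr must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if n < 4:
        raise ValueError("need at least 2 subjects per stratum")
    rng = np.random.default_rng(seed)
    n_low = n // 2
    n_high = n - n_low
    stratum = np.array(["low"] * n_low + ["high"] * n_high)
    rate = np.where(stratum == "high", baseline_hazard * true_hr, baseline_hazard)
    time = rng.exponential(1.0 / rate)
    event = np.ones(n, dtype=int)
    if censor_rate > 0:
        cens = rng.uniform(0, 1, n) < censor_rate
        time = np.where(cens, time * rng.uniform(0, 1, n), time)
        event[cens] = 0
    if horizon_years is not None:
        over = time > horizon_years
        time = np.where(over, horizon_years, time)
        event[over] = 0
    return pd.DataFrame(
        {
            "sample_id": [f"p{i:04d}" for i in range(n)],
            "time_years": time,
            "event": event,
            "stratum": stratum,
        }
    )
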