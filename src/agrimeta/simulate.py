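"""Synthetic meta-analytic datasets and land-cover maps with known truth.

The generator mirrors the structure of the real study sample: ~94
publications contributing 1-6 dependent observations each (~184 in total),
true effects theta = x'beta + b_pub + w_obs with between-effect SD tau
split by phi into a shared publication-level deviation and an
observation-level one, and arm-level richness summaries computed as sample
statistics of simulated replicate draws, so sampling variance arises
organically rather than being stamped on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .effects import effects_from_records
from .io import StudyRecord
from .landscape import HABITAT_CODE, FIELD_CODE, LandCoverMap

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_meta_dataset",
    "simulate_landcover",
    "inject_small_study_bias",
    "threshold_censor_rule",
]

# Level frequencies follow the subgroup counts of the real sample.
_DEFAULT_FUNCTIONAL = {
    "decomposers": 19, "herbivores": 6, "other": 27,
    "pollinators": 21, "predators": 49, "producers": 62,
}
_DEFAULT_TAXON = {"arthropods": 89, "birds": 17, "microbes": 6, "plants": 62}
_DEFAULT_CROP = {
    "cereals": 100, "grassland": 13, "mixed": 40,
    "orchard": 9, "miscellaneous": 6, "vegetables": 16,
}
_DEFAULT_SCALE = {"farm": 10, "field": 6, "plot": 4}
_DEFAULT_COUNTRIES = ("SE", "UK", "DE", "US", "DK", "FI", "NL")


def _normalise(freqs: dict[str, float]) -> dict[str, float]:
    total = float(sum(freqs.values()))
    if total <= 0:
        raise ValueError("level frequencies must have positive total")
    return {k: v / total for k, v in freqs.items()}


@dataclass
class SimulationConfig:
    n_publications: int = 94
    obs_per_pub_probs: Sequence[float] = (0.45, 0.30, 0.12, 0.06, 0.04, 0.03)
    beta0: float = 0.3
    beta: dict = field(default_factory=dict)  # var -> {level: coef} or float
    tau: float = 0.3
    phi: float = 0.5
    n_min: int = 2
    n_max: int = 30
    mu_conv_median: float = 15.0
    mu_conv_sigma: float = 0.5
    cv: float = 0.4
    count_model: str = "lognormal"  # or "poisson"
    functional_freqs: dict = field(default_factory=lambda: dict(_DEFAULT_FUNCTIONAL))
    taxon_freqs: dict = field(default_factory=lambda: dict(_DEFAULT_TAXON))
    crop_freqs: dict = field(default_factory=lambda: dict(_DEFAULT_CROP))
    scale_freqs: dict = field(default_factory=lambda: dict(_DEFAULT_SCALE))
    countries: Sequence[str] = _DEFAULT_COUNTRIES
    seed: int = 0

    def validate(self) -> None:
        probs = np.asarray(self.obs_per_pub_probs, dtype=float)
        if probs.ndim != 1 or probs.size < 1 or np.any(probs < 0):
            raise ValueError("obs_per_pub_probs must be nonnegative")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("obs_per_pub_probs must sum to 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must lie in [0, 1)")
        if self.n_min < 2 or self.n_max < self.n_min:
            raise ValueError("replicate count range must satisfy 2 <= n_min <= n_max")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.count_model not in ("lognormal", "poisson"):
            raise ValueError("count_model must be 'lognormal' or 'poisson'")
        for freqs in (self.functional_freqs, self.taxon_freqs,
                      self.crop_freqs, self.scale_freqs):
            if any(v < 0 for v in freqs.values()):
                raise ValueError("level frequencies must be nonnegative")


@dataclass
class GroundTruth:
    beta0: float
    beta: dict
    tau: float
    phi: float
    theta: dict[str, float]
    pub_effects: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _draw_level(rng: np.random.Generator, freqs: dict[str, float]) -> str:
    levels = sorted(freqs)
    probs = np.array([freqs[lv] for lv in levels], dtype=float)
    return levels[rng.choice(len(levels), p=probs / probs.sum())]


def _replicates(rng, mu: float, sd: float, n: int, model: str) -> np.ndarray:
    if model == "poisson":
        return rng.poisson(mu, size=n).astype(float)
    if sd == 0:
        return np.full(n, mu)
    sigma2 = np.log1p((sd / mu) ** 2)
    return rng.lognormal(np.log(mu) - sigma2 / 2.0, np.sqrt(sigma2), size=n)


def _arm_summary(rng, mu: float, cv: float, n: int, model: str) -> tuple[float, float]:
    # redraw in the rare degenerate cases (all-zero Poisson counts / zero SD)
    for _ in range(100):
        draws = _replicates(rng, mu, cv * mu, n, model)
        m = float(draws.mean())
        s = float(draws.std(ddof=1))
        if m > 0 and s > 0:
            return m, s
    raise RuntimeError("could not draw a non-degenerate arm summary")


def simulate_meta_dataset(
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[StudyRecord], GroundTruth]:
    """Generate a study table plus its ground truth. Deterministic per seed."""
    config = config or SimulationConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    f_freqs = _normalise(config.functional_freqs)
    t_freqs = _normalise(config.taxon_freqs)
    c_freqs = _normalise(config.crop_freqs)
    s_freqs = _normalise(config.scale_freqs)
    obs_probs = np.asarray(config.obs_per_pub_probs, dtype=float)

    tau2 = config.tau**2
    sd_pub = np.sqrt(config.phi * tau2)
    sd_obs = np.sqrt((1.0 - config.phi) * tau2)

    records: list[StudyRecord] = []
    theta_map: dict[str, float] = {}
    pub_effects: dict[str, float] = {}

    for j in range(config.n_publications):
        pub_id = f"pub{j + 1:03d}"
        n_obs = int(rng.choice(len(obs_probs), p=obs_probs)) + 1
        b_j = float(rng.normal(0.0, sd_pub))
        pub_effects[pub_id] = b_j
        year = int(rng.integers(1981, 2012))
        country = str(config.countries[rng.integers(0, len(config.countries))])
        # landscape covariates are shared by all observations of a publication
        pct_arable = float(rng.uniform(0.0, 100.0))
        n_hab = int(rng.integers(1, 9))
        field_size = float(rng.lognormal(np.log(5.0), 0.6))

        for i in range(n_obs):
            obs_id = f"{pub_id}_o{i + 1}"
            covs = {
                "functional_group": _draw_level(rng, f_freqs),
                "taxon_group": _draw_level(rng, t_freqs),
                "crop_type": _draw_level(rng, c_freqs),
                "scale": _draw_level(rng, s_freqs),
            }
            theta = config.beta0 + b_j + float(rng.normal(0.0, sd_obs))
            for var, eff in config.beta.items():
                if isinstance(eff, dict):
                    theta += eff.get(covs[var], 0.0)
                else:  # continuous: pct_arable contributes on the [0, 1] scale
                    value = pct_arable / 100.0 if var == "pct_arable" else n_hab
                    theta += float(eff) * value
            theta_map[obs_id] = theta

            mu_c = float(
                rng.lognormal(np.log(config.mu_conv_median), config.mu_conv_sigma)
            )
            mu_o = mu_c * np.exp(theta)
            n_o = int(rng.integers(config.n_min, config.n_max + 1))
            n_c = int(rng.integers(config.n_min, config.n_max + 1))
            m_o, s_o = _arm_summary(rng, mu_o, config.cv, n_o, config.count_model)
            m_c, s_c = _arm_summary(rng, mu_c, config.cv, n_c, config.count_model)

            records.append(
                StudyRecord(
                    publication_id=pub_id,
                    observation_id=obs_id,
                    pub_year=year,
                    country=country,
                    region="",
                    mean_org=m_o, sd_org=s_o, n_org=n_o,
                    mean_conv=m_c, sd_conv=s_c, n_conv=n_c,
                    pct_arable=pct_arable,
                    n_habitats=float(n_hab),
                    avg_field_size=field_size,
                    **covs,
                )
            )

    truth = GroundTruth(
        beta0=config.beta0,
        beta=dict(config.beta),
        tau=config.tau,
        phi=config.phi,
        theta=theta_map,
        pub_effects=pub_effects,
    )
    return records, truth


def simulate_landcover(
    shape: tuple[int, int] = (200, 200),
    cell_size: float = 10.0,
    mixture: dict[str, float] | None = None,
    mean_parcel_area_ha: float = 8.0,
    seed: int | np.random.Generator = 0,
) -> LandCoverMap:
    """Parcel-tessellated synthetic land cover.

    Seeds a Voronoi tessellation with parcel density matched to the target
    mean parcel area, then assigns parcels to habitats greedily so realised
    habitat fractions track the requested mixture closely.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mixture = mixture or {"field": 0.6, "forest": 0.3, "pasture": 0.1}
    for name in mixture:
        if name not in HABITAT_CODE:
            raise ValueError(f"unknown habitat {name!r}")
    if any(p < 0 for p in mixture.values()) or not np.isclose(
        sum(mixture.values()), 1.0
    ):
        raise ValueError("habitat mixture proportions must be nonnegative and sum to 1")

    h, w = shape
    total_ha = h * w * cell_size**2 / 1e4
    n_parcels = max(1, int(round(total_ha / mean_parcel_area_ha)))
    seeds = rng.uniform(0.0, 1.0, size=(n_parcels, 2)) * [w, h]
    rows, cols = np.mgrid[0:h, 0:w]
    pts = np.column_stack([cols.ravel() + 0.5, rows.ravel() + 0.5])
    _, nearest = cKDTree(seeds).query(pts)
    parcel_of_cell = nearest.reshape(h, w)

    areas = np.bincount(parcel_of_cell.ravel(), minlength=n_parcels).astype(float)
    habitats = sorted(mixture)
    target = np.array([mixture[name] for name in habitats]) * areas.sum()
    assigned = np.zeros(len(habitats))
    parcel_habitat = np.empty(n_parcels, dtype=int)
    for pid in rng.permutation(n_parcels):
        deficit = target - assigned
        k = int(np.argmax(deficit))
        parcel_habitat[pid] = k
        assigned[k] += areas[pid]

    codes = np.array([HABITAT_CODE[name] for name in habitats])
    grid = codes[parcel_habitat][parcel_of_cell]
    parcels = np.where(grid == FIELD_CODE, parcel_of_cell + 1, 0)
    return LandCoverMap(grid=grid, parcels=parcels, cell_size=cell_size)


def threshold_censor_rule(
    y_max: float = 0.0, v_quantile: float = 0.5, p_drop: float = 1.0
) -> Callable:
    """Censor rule factory: drop observations with y < y_max whose sampling
    variance exceeds the given quantile of v, with probability p_drop."""

    def rule(y: np.ndarray, v: np.ndarray) -> np.ndarray:
        thresh = np.quantile(v, v_quantile)
        return np.where((y < y_max) & (v > thresh), p_drop, 0.0)

    return rule


def inject_small_study_bias(
    records: Sequence[StudyRecord],
    censor_rule: Callable | None = None,
    rng: np.random.Generator | int = 0,
) -> list[StudyRecord]:
    """Drop observations per the censor rule to emulate the file drawer.

    The rule receives the y and v arrays and returns per-observation drop
    probabilities; small negative results from noisy studies are the
    intended casualties.
    """
    if not records:
        raise ValueError("table is empty")
    if censor_rule is None:
        censor_rule = threshold_censor_rule()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    effects = effects_from_records(records)
    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])
    p = np.clip(np.asarray(censor_rule(y, v), dtype=float), 0.0, 1.0)
    keep = rng.uniform(size=len(records)) >= p
    out = [rec for rec, k in zip(records, keep) if k]
    if not out:
        raise ValueError("censor rule dropped every observation")
    return out
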