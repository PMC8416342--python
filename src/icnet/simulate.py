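"""Synthetic survey cohorts with the statistical structure the analyses
assume: latent-factor-driven ordinal symptom items, grade-dependent binary
lifestyle prevalences, and optionally planted "bridge" items for testing
intra-individual covariance-network hub detection.

The generative model, per respondent in grade g:

* a general distress factor ``G ~ N(0, 1)``;
* block factors ``B_stress, B_anxiety, B_depression ~ N(0, 1)`` shared by
  the PSS, GAD-7 and PHQ-9 items respectively, and attitude factors
  ``B_fear`` (threat items) and ``B_coping`` (coping items);
* each ordinal item's latent value is
  ``loading_G * G + loading_B * B_block + shift(g) + noise_sd * eps``,
  cut into its response levels by fixed, strictly increasing thresholds;
* binary lifestyle/difficulty items are independent Bernoulli draws at
  per-grade prevalences (defaulting to the published cohort's observed
  proportions).

A planted hub replaces one ordinal item's latent value with the midpoint
of two block consensus signals, so that after z-scoring the item sits
between the two blocks' z-bands and bridges them in the thresholded
intra-individual covariance network.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .survey import (
    ANALYSIS_COLUMNS,
    ATTITUDE_COLUMNS,
    GAD7_COLUMNS,
    ITEM_RANGES,
    ONLINE_DIFFICULTY_COLUMNS,
    PHQ9_COLUMNS,
    PSS_COLUMNS,
    SPARE_TIME_COLUMNS,
)

__all__ = [
    "HubSpec",
    "SimulationConfig",
    "default_config",
    "null_config",
    "hub_test_config",
    "plant_hub_item",
    "generate_cohort",
    "implied_ordinal_marginals",
]

ORDINAL_COLUMNS = ATTITUDE_COLUMNS + PSS_COLUMNS + GAD7_COLUMNS + PHQ9_COLUMNS
BINARY_COLUMNS = ("dropout",) + SPARE_TIME_COLUMNS + ONLINE_DIFFICULTY_COLUMNS

#: Latent block factor of each ordinal item.
ITEM_BLOCK = {}
ITEM_BLOCK.update({c: "fear" for c in ATTITUDE_COLUMNS[:3]})
ITEM_BLOCK.update({c: "coping" for c in ATTITUDE_COLUMNS[3:]})
ITEM_BLOCK.update({c: "stress" for c in PSS_COLUMNS})
ITEM_BLOCK.update({c: "anxiety" for c in GAD7_COLUMNS})
ITEM_BLOCK.update({c: "depression" for c in PHQ9_COLUMNS})

BLOCK_NAMES = ("stress", "anxiety", "depression", "fear", "coping")
SYMPTOM_BLOCKS = ("stress", "anxiety", "depression")

# Published per-grade yes-proportions of the binary items (grade sizes
# 123/110/121/100); used as default Bernoulli prevalences.
_TABLE_PREVALENCE = {
    "dropout": (65 / 123, 51 / 110, 33 / 121, 14 / 100),
    "st_sleep": (63 / 123, 60 / 110, 82 / 131, 46 / 100),
    "st_game": (20 / 123, 33 / 110, 31 / 121, 25 / 100),
    "st_read": (9 / 123, 13 / 110, 14 / 121, 9 / 100),
    "st_study": (81 / 123, 46 / 110, 58 / 121, 34 / 100),
    "st_exercise": (26 / 123, 42 / 110, 49 / 121, 28 / 100),
    "st_friends": (40 / 123, 38 / 110, 53 / 121, 35 / 100),
    "od_routine": (40 / 123, 32 / 110, 21 / 121, 19 / 100),
    "od_interact": (31 / 123, 15 / 110, 23 / 121, 28 / 100),
    "od_social": (65 / 123, 62 / 110, 60 / 121, 46 / 100),
}
_MEN_PREVALENCE = (80 / 123, 70 / 110, 75 / 121, 64 / 100)

# Fixed ordinal cut-points (on the latent scale) per response format:
# symmetric for 5-level items, right-skewed for the 4-level screeners,
# whose symptom marginals concentrate at the low end.
_THRESHOLDS_5 = (-1.5, -0.5, 0.5, 1.5)
_THRESHOLDS_4 = (0.0, 1.0, 2.0)


@dataclass(frozen=True)
class HubSpec:
    """One planted bridge item between two latent blocks."""

    item: str
    block_a: str
    block_b: str
    strength: float

    def validate(self) -> None:
        if self.item not in ORDINAL_COLUMNS:
            raise ValueError(f"hub item must be ordinal, got {self.item!r}")
        for b in (self.block_a, self.block_b):
            if b not in BLOCK_NAMES:
                raise ValueError(f"unknown block {b!r}")
        if self.block_a == self.block_b:
            raise ValueError("hub must bridge two distinct blocks")
        if not 0.0 < self.strength <= 1.0:
            raise ValueError(f"strength must be in (0, 1], got {self.strength}")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator (defaults = study conditions)."""

    n_per_grade: tuple[int, int, int, int] = (123, 110, 121, 100)
    seed: int | None = None
    grade_shift: tuple[float, float, float, float] = (0.3, 0.1, -0.1, -0.3)
    general_loading: float = 0.6
    block_loading: float = 0.5
    attitude_loading: float = 0.8
    noise_sd: float = 0.8
    thresholds_5: tuple[float, ...] = _THRESHOLDS_5
    thresholds_4: tuple[float, ...] = _THRESHOLDS_4
    difficulty_spread: float = 0.3
    # per-block overrides of (general_loading, block_loading, noise_sd)
    block_overrides: dict[str, tuple[float, float, float]] = field(
        default_factory=dict)
    binary_prevalence: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_TABLE_PREVALENCE))
    men_prevalence: tuple[float, float, float, float] = _MEN_PREVALENCE
    hubs: tuple[HubSpec, ...] = ()

    def validate(self) -> None:
        if len(self.n_per_grade) != 4 or any(n < 1 for n in self.n_per_grade):
            raise ValueError("n_per_grade must be four integers >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for t in (self.thresholds_5, self.thresholds_4):
            if any(a >= b for a, b in zip(t, t[1:])):
                raise ValueError("thresholds must be strictly increasing")
        if len(self.thresholds_5) != 4 or len(self.thresholds_4) != 3:
            raise ValueError("need 4 cut-points for 5-level, 3 for 4-level items")
        for item, prev in self.binary_prevalence.items():
            if item not in BINARY_COLUMNS:
                raise ValueError(f"unknown binary item {item!r}")
            if len(prev) != 4 or any(not 0 <= p <= 1 for p in prev):
                raise ValueError(f"{item}: prevalences must be four values in [0, 1]")
        missing = set(BINARY_COLUMNS) - set(self.binary_prevalence)
        if missing:
            raise ValueError(f"missing prevalences for {sorted(missing)}")
        if any(not 0 <= p <= 1 for p in self.men_prevalence):
            raise ValueError("men_prevalence values must be in [0, 1]")
        for block, triple in self.block_overrides.items():
            if block not in BLOCK_NAMES:
                raise ValueError(f"unknown block {block!r} in overrides")
            if len(triple) != 3 or triple[2] < 0:
                raise ValueError(f"{block}: override must be (general, block, noise>=0)")
        for hub in self.hubs:
            hub.validate()

    # -- plain key-value round trip ------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("grade_shift", "thresholds_5", "thresholds_4", "men_prevalence"):
            d[key] = [float(v) for v in d[key]]
        d["n_per_grade"] = [int(v) for v in d["n_per_grade"]]
        d["binary_prevalence"] = {k: [float(x) for x in v]
                                  for k, v in self.binary_prevalence.items()}
        d["block_overrides"] = {k: [float(x) for x in v]
                                for k, v in self.block_overrides.items()}
        d["hubs"] = [{"item": h.item, "block_a": h.block_a, "block_b": h.block_b,
                      "strength": float(h.strength)} for h in self.hubs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "hubs" in d:
            d["hubs"] = tuple(HubSpec(**h) for h in d["hubs"])
        for key in ("n_per_grade", "grade_shift", "thresholds_5", "thresholds_4",
                    "men_prevalence"):
            if key in d:
                d[key] = tuple(d[key])
        if "binary_prevalence" in d:
            d["binary_prevalence"] = {k: tuple(v) for k, v in d["binary_prevalence"].items()}
        if "block_overrides" in d:
            d["block_overrides"] = {k: tuple(v) for k, v in d["block_overrides"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int | None = None, **overrides) -> SimulationConfig:
    """Study-condition defaults: grade sizes and binary prevalences from
    the published cohort, distress declining across grades."""
    return dataclasses.replace(SimulationConfig(seed=seed), **overrides)


def null_config(seed: int | None = None, **overrides) -> SimulationConfig:
    """No grade effects anywhere: flat latent shifts, prevalences pooled
    across grades. Used for type-I-error calibration."""
    pooled = {}
    for item, prev in _TABLE_PREVALENCE.items():
        ns = (123, 110, 121, 100)
        p = sum(p * n for p, n in zip(prev, ns)) / sum(ns)
        pooled[item] = (p, p, p, p)
    cfg = SimulationConfig(
        seed=seed, grade_shift=(0.0, 0.0, 0.0, 0.0), binary_prevalence=pooled)
    return dataclasses.replace(cfg, **overrides)


def hub_test_config(n_per_grade=(50, 50, 50, 50),
                    seed: int | None = None, **overrides) -> SimulationConfig:
    """Regime used for planted-hub coupling tests.

    Stress and depression items form tight correlated bands (shared
    general factor plus block factors, low item noise), anxiety items are
    scattered, and the binary prevalences are spread so each lifestyle
    item occupies its own z position. Against this background a planted
    mid-band item shows a clearly elevated similarity (and thresholded
    degree) to its two blocks.

    Note: with 4- and 5-level items the planted coupling does **not**
    reliably translate into top betweenness rank — see the methods
    documentation; tests assert the coupling signature, not rank dominance.
    """
    prevalence = {
        item: (float(p),) * 4
        for item, p in zip(BINARY_COLUMNS,
                           np.linspace(0.15, 0.7, len(BINARY_COLUMNS)))
    }
    cfg = SimulationConfig(
        n_per_grade=tuple(n_per_grade), seed=seed,
        grade_shift=(0.0, 0.0, 0.0, 0.0),
        general_loading=0.9, block_loading=0.7, attitude_loading=0.3,
        noise_sd=0.3, difficulty_spread=0.5,
        binary_prevalence=prevalence,
        block_overrides={"anxiety": (0.2, 0.2, 1.2)},
    )
    return dataclasses.replace(cfg, **overrides)


def plant_hub_item(config: SimulationConfig, hub_item: str, strength: float,
                   blocks: tuple[str, str] = ("stress", "depression")) -> SimulationConfig:
    """Return a config in which ``hub_item``'s latent tracks the midpoint
    of two block consensus signals with the given coupling strength."""
    spec = HubSpec(hub_item, blocks[0], blocks[1], strength)
    spec.validate()
    return dataclasses.replace(config, hubs=config.hubs + (spec,))


def _item_loadings(config: SimulationConfig,
                   item: str) -> tuple[float, float, float, str]:
    """(general loading, block loading, noise sd, block name) for one item."""
    block = ITEM_BLOCK[item]
    if block in config.block_overrides:
        lg, lb, ns = config.block_overrides[block]
        return lg, lb, ns, block
    if block in SYMPTOM_BLOCKS:
        return config.general_loading, config.block_loading, config.noise_sd, block
    return 0.0, config.attitude_loading, config.noise_sd, block


def _block_consensus(config: SimulationConfig, bname: str, g, blocks, shift):
    """The shared (noise-free) latent signal of a block's items."""
    if bname in config.block_overrides:
        lg, lb, _ = config.block_overrides[bname]
    elif bname in SYMPTOM_BLOCKS:
        lg, lb = config.general_loading, config.block_loading
    else:
        lg, lb = 0.0, config.attitude_loading
    return lg * g + lb * blocks[bname] + shift


_GOLDEN = 0.6180339887498949


def _difficulty(config: SimulationConfig, item: str) -> float:
    """Fixed per-item threshold shift (item 'difficulty').

    Real instruments mix easy and hard items; shifting each item's
    cut-points by a deterministic, irregular offset reproduces that
    heterogeneity and keeps the cohort z-scores of different items off a
    common discrete grid.
    """
    j = ORDINAL_COLUMNS.index(item)
    frac = ((j + 1) * _GOLDEN) % 1.0
    return config.difficulty_spread * (frac - 0.5)


def _thresholds(config: SimulationConfig, item: str) -> np.ndarray:
    lo, hi = ITEM_RANGES[item]
    base = np.asarray(config.thresholds_5 if hi - lo == 4 else config.thresholds_4)
    return base + _difficulty(config, item)


def generate_cohort(config: SimulationConfig,
                    seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort; identical seeds give identical frames.

    ``seed`` overrides ``config.seed``; one of them must be set.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (config.seed or argument)")
    rng = np.random.default_rng(seed)

    n = sum(config.n_per_grade)
    grades = np.repeat([1, 2, 3, 4], config.n_per_grade)
    shift = np.asarray(config.grade_shift)[grades - 1]

    g = rng.standard_normal(n)
    blocks = {name: rng.standard_normal(n) for name in BLOCK_NAMES}
    eps = rng.standard_normal((n, len(ORDINAL_COLUMNS)))

    latent = {}
    for j, item in enumerate(ORDINAL_COLUMNS):
        lg, lb, ns, block = _item_loadings(config, item)
        latent[item] = lg * g + lb * blocks[block] + shift + ns * eps[:, j]

    for hub in config.hubs:
        consensus = [
            _block_consensus(config, bname, g, blocks, shift)
            for bname in (hub.block_a, hub.block_b)
        ]
        mid = 0.5 * (consensus[0] + consensus[1])
        latent[hub.item] = hub.strength * mid + (1 - hub.strength) * latent[hub.item]

    data = {"id": [f"r{i + 1:04d}" for i in range(n)],
            "grade": grades.astype(int)}
    u_sex = rng.random(n)
    men_p = np.asarray(config.men_prevalence)[grades - 1]
    data["sex"] = np.where(u_sex < men_p, "men", "women")

    for item in ORDINAL_COLUMNS:
        lo, _ = ITEM_RANGES[item]
        codes = np.searchsorted(_thresholds(config, item), latent[item])
        data[item] = (codes + lo).astype(int)

    u_bin = rng.random((n, len(BINARY_COLUMNS)))
    for j, item in enumerate(BINARY_COLUMNS):
        p = np.asarray(config.binary_prevalence[item])[grades - 1]
        data[item] = (u_bin[:, j] < p).astype(int)

    frame = pd.DataFrame(data)
    return frame[["id", "grade", "sex"] + list(ANALYSIS_COLUMNS)]


def implied_ordinal_marginals(config: SimulationConfig, item: str,
                              grade: int) -> np.ndarray:
    """Exact response-level probabilities implied by the latent model."""
    from scipy.stats import norm

    lg, lb, ns, _ = _item_loadings(config, item)
    sd = float(np.sqrt(lg ** 2 + lb ** 2 + ns ** 2))
    mu = config.grade_shift[grade - 1]
    cuts = _thresholds(config, item)
    cdf = norm.cdf((cuts - mu) / sd)
    return np.diff(np.concatenate([[0.0], cdf, [1.0]]))
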