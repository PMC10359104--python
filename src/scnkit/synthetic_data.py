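"""Synthetic lifespan mouse cohorts with known planted structure.

Generates per-animal regional brain volumes and Y-maze trial sequences with
the statistical features the downstream analyses assume, so every stage can
be validated against known ground truth:

* total brain volume (TBV) draws, with region volumes built as
  TBV-proportional baselines — making TBV a genuine confounder that the
  covariate adjustment must remove;
* additive group mean shifts on selected regions, expressed in units of the
  residual noise SD;
* correlated residual noise with a block-constant correlation matrix
  (planted covariance communities), optionally attenuated region-wise per
  group to plant connectivity differences;
* trial-by-trial Bernoulli alternation behaviour whose log-odds may depend
  on standardized TBV-residualized volumes of selected regions (with no
  coupling, each post-first trial alternates with probability 1/2).

Default parameters emulate a three-group lifespan design (10/10/9 animals:
young, middle-aged, old) over 32 regions of interest, with planted
maturational and aging-related volume shifts whose standardized sizes match
the characteristic pattern of isocortical loss and brainstem/white-matter
gain, four anatomically coherent covariance communities, and a weak
brain-behaviour coupling through the anterior cingulate area (positive) and
hippocampal formation (negative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import TrialRecord, read_trials, write_trials
from .regions import DEFAULT_COMMUNITIES, ROI_NAMES
from .volumetrics import VolumeTable

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "DEFAULT_EFFECTS",
    "DEFAULT_BEHAVIOR_LINK",
]

GroupPair = tuple[str, str]

# Planted standardized mean shifts (units of noise_sd) for the default
# cohort: maturational (young -> middle) isocortical loss with brainstem,
# cerebellar-nuclei and white-matter gain, and a sparser aging-related
# (middle -> old) pattern of further isocortical loss and white-matter gain.
DEFAULT_EFFECTS: dict[GroupPair, dict[str, float]] = {
    ("young", "middle"): {
        "hypothalamus": 2.43,
        "medulla": 2.50,
        "midbrain": 1.97,
        "pons": 3.06,
        "cerebellar cortex": -1.34,
        "cerebellar nuclei": 2.59,
        "anterior cingulate area": -2.19,
        "auditory areas": -1.90,
        "prelimbic area": -1.35,
        "somatomotor areas": -1.66,
        "somatosensory areas": -2.16,
        "temporal association areas": -1.25,
        "visual areas": -1.21,
        "pallidum": 2.28,
        "cranial nerves": 2.62,
        "extrapyramidal fiber system": 1.52,
        "lateral forebrain bundle system": 1.46,
        "medial forebrain bundle system": 1.42,
    },
    ("middle", "old"): {
        "auditory areas": -1.22,
        "ectorhinal area": -1.43,
        "orbital area": -1.28,
        "temporal association areas": -1.20,
        "lateral forebrain bundle system": 1.38,
        "medial forebrain bundle system": 1.17,
    },
}

DEFAULT_BEHAVIOR_LINK: dict[str, float] = {
    "anterior cingulate area": 0.35,
    "hippocampal formation": -0.33,
}


def _normalize_pair(key) -> GroupPair:
    if isinstance(key, str):
        for sep in (" vs ", "|", ":"):
            if sep in key:
                a, b = key.split(sep, 1)
                return (a.strip(), b.strip())
        raise ValueError(f"cannot parse group pair {key!r}")
    a, b = key
    return (str(a), str(b))


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``n_per_group`` may be a single count or one count per group (allowing
    the unbalanced 10/10/9 design).  ``effect_table`` maps consecutive group
    pairs to per-region standardized mean shifts (accumulated along the
    group order).  ``within_community_r``/``between_community_r`` set the
    block-constant residual correlation targets.  ``behavior_link`` maps
    regions to slopes on the logit of the per-trial alternation probability
    (applied to standardized TBV-residualized volume); the intercept is 0 so
    an empty map yields chance-level (1/2) alternation.
    ``connectivity_attenuation`` maps group -> region -> factor in [0, 1]
    multiplying that region's residual correlations within that group, to
    plant group differences in network connectivity.
    """

    n_per_group: int | Sequence[int] = (10, 10, 9)
    groups: tuple[str, ...] = ("young", "middle", "old")
    n_regions: int = 32
    region_names: tuple[str, ...] | None = None
    tbv_mean: float = 450.0
    tbv_sd: float = 15.0
    effect_table: Mapping[GroupPair, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()}
    )
    community_assignment: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMMUNITIES)
    )
    within_community_r: float = 0.5
    between_community_r: float = 0.15
    noise_sd: float = 0.5
    n_trials: int = 7
    behavior_link: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_LINK)
    )
    connectivity_attenuation: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        if isinstance(self.n_per_group, (int, np.integer)):
            self.n_per_group = (int(self.n_per_group),) * len(self.groups)
        else:
            self.n_per_group = tuple(int(n) for n in self.n_per_group)
        if len(self.n_per_group) != len(self.groups):
            raise ValueError("need one group size per group")
        if any(n < 3 for n in self.n_per_group):
            raise ValueError("each group needs at least 3 animals")
        if self.region_names is None:
            if self.n_regions == len(ROI_NAMES):
                self.region_names = ROI_NAMES
            else:
                self.region_names = tuple(f"region{i:02d}" for i in range(self.n_regions))
        self.region_names = tuple(self.region_names)
        if len(self.region_names) != self.n_regions:
            raise ValueError("region_names length must equal n_regions")
        if self.n_trials < 2:
            raise ValueError("need at least 2 Y-maze trials")
        if not (0 <= self.between_community_r <= self.within_community_r < 1):
            raise ValueError(
                "require 0 <= between_community_r <= within_community_r < 1, got "
                f"within={self.within_community_r}, between={self.between_community_r}"
            )
        self.effect_table = {
            _normalize_pair(k): dict(v) for k, v in self.effect_table.items()
        }
        known = set(self.region_names)
        for pair, shifts in self.effect_table.items():
            if set(pair) - set(self.groups):
                raise ValueError(f"effect_table pair {pair} outside configured groups")
            missing = set(shifts) - known
            if missing:
                raise ValueError(f"effect_table regions not in region_names: {sorted(missing)}")
        extra = set(self.community_assignment) - known
        if extra:
            raise ValueError(f"community_assignment regions not in region_names: {sorted(extra)}")
        for g, att in self.connectivity_attenuation.items():
            if g not in self.groups:
                raise ValueError(f"attenuation group {g!r} unknown")
            bad = set(att) - known
            if bad:
                raise ValueError(f"attenuation regions not in region_names: {sorted(bad)}")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth that was planted into it."""

    volumes: VolumeTable
    trials: list[TrialRecord]
    truth: dict

    def __post_init__(self) -> None:
        vol_ids = set(self.volumes.animals)
        trial_ids = {t.animal_id for t in self.trials}
        if vol_ids != trial_ids:
            raise ValueError("volumes and trials cover different animals")


def _block_correlation(config: CohortConfig) -> np.ndarray:
    n = config.n_regions
    comm = np.array(
        [config.community_assignment.get(r, -1 - i) for i, r in enumerate(config.region_names)]
    )
    same = comm[:, None] == comm[None, :]
    R = np.where(same, config.within_community_r, config.between_community_r)
    np.fill_diagonal(R, 1.0)
    return R


def _group_correlation(config: CohortConfig, group: str) -> np.ndarray:
    R = _block_correlation(config)
    att = config.connectivity_attenuation.get(group, {})
    for region, factor in att.items():
        i = config.region_names.index(region)
        R[i, :] *= factor
        R[:, i] *= factor
        R[i, i] = 1.0
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValueError(
            "implied residual correlation matrix is not positive definite "
            f"(group={group!r}, within_r={config.within_community_r}, "
            f"between_r={config.between_community_r}, attenuation={dict(att)})"
        ) from None


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort; deterministic for a fixed config (including seed)."""
    rng = np.random.default_rng(config.seed)
    regions = config.region_names
    n_reg = config.n_regions
    fractions = np.linspace(0.010, 0.046, n_reg)

    # cumulative per-group standardized offsets along the ordered groups
    offsets: dict[str, np.ndarray] = {config.groups[0]: np.zeros(n_reg)}
    for prev, g in zip(config.groups, config.groups[1:]):
        step = np.zeros(n_reg)
        shifts = config.effect_table.get((prev, g), {})
        for region, delta in shifts.items():
            step[regions.index(region)] = delta
        offsets[g] = offsets[prev] + step

    rows, ids, labels = [], [], []
    for g, n_g in zip(config.groups, config.n_per_group):
        L = _group_correlation(config, g)
        tbv = rng.normal(config.tbv_mean, config.tbv_sd, n_g)
        z = rng.standard_normal((n_g, n_reg))
        noise = z @ L.T
        vols = tbv[:, None] * fractions[None, :] + (offsets[g] + noise) * config.noise_sd
        for i in range(n_g):
            ids.append(f"{g}_{i + 1:02d}")
            labels.append(g)
            rows.append(np.concatenate([[tbv[i]], vols[i]]))
    data = np.asarray(rows)
    frame = pd.DataFrame(data[:, 1:], columns=list(regions), index=pd.Index(ids, name="animal_id"))
    frame.insert(0, "group", labels)
    frame.insert(1, "tbv", data[:, 0])
    volumes = VolumeTable(frame, config.groups)

    # trial-by-trial alternation, log-odds linear in standardized residual volume
    eta = np.zeros(len(ids))
    if config.behavior_link:
        from .volumetrics import residualize_all

        resid = residualize_all(volumes, list(config.behavior_link))
        for region, slope in config.behavior_link.items():
            r = resid[region].to_numpy()
            sd = r.std()
            if sd > 0:
                eta += slope * (r / sd)
    p_alt = _logistic(eta)

    trials: list[TrialRecord] = []
    arms = np.array(["A", "B"])
    for i, animal in enumerate(ids):
        current = int(rng.integers(2))
        seq = [arms[current]]
        for _ in range(config.n_trials - 1):
            if rng.random() < p_alt[i]:
                current = 1 - current
            seq.append(arms[current])
        trials.append(TrialRecord(animal_id=animal, choices="".join(seq), group=labels[i]))

    truth = {
        "planted_effects": {
            f"{a} vs {b}": dict(v) for (a, b), v in config.effect_table.items()
        },
        "planted_partition": {r: int(config.community_assignment[r])
                              for r in regions if r in config.community_assignment},
        "behavior_slopes": dict(config.behavior_link),
        "connectivity_attenuation": {
            g: dict(v) for g, v in config.connectivity_attenuation.items()
        },
        "seed": config.seed,
    }
    return SyntheticCohort(volumes=volumes, trials=trials, truth=truth)


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write volumes.csv, trials.csv and truth.json into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "volumes": directory / "volumes.csv",
        "trials": directory / "trials.csv",
        "truth": directory / "truth.json",
    }
    cohort.volumes.to_csv(paths["volumes"])
    write_trials(cohort.trials, paths["trials"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_cohort(directory, group_order: Sequence[str] = ("young", "middle", "old")) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    volumes = VolumeTable.from_csv(directory / "volumes.csv", group_order)
    trials = read_trials(directory / "trials.csv")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return SyntheticCohort(volumes=volumes, trials=trials, truth=truth)
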