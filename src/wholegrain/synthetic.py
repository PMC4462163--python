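"""Synthetic diary-survey generator.

Emulates the statistical structure of a UK rolling diet survey so the whole
pipeline is testable without restricted survey data: 3–4-day diaries (2 %
three-day), a zero-inflated right-skewed whole-grain distribution (a
participant is an absolute non-consumer with a stated probability, default
18 % of adults and 15 % of children/teenagers; otherwise daily eating
occasions per food group with lognormal portion grams), age / sex / NS-SEC
gradients, ~2 % missing NS-SEC, and lognormal survey weights.

Each participant draws from an independent random stream keyed by
``(seed, participant index)``, so subsetting participants is reproducible.
The generator records ground-truth per-person intakes through its own
straightforward per-occasion loop over raw registry fields — deliberately
not the pipeline's code path — so pipeline output can be checked against an
independent computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import FoodGroup, Registry, default_registry
from .diary import DiaryOccasion, Participant
from .pipeline import (
    DEFAULT_TIER_THRESHOLDS,
    CutoffTier,
    estimate_all,
)
from .stats import age_band_label, summarize

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "CalibrationTargets",
    "generate",
    "calibrate",
]

# Daily probability that a consumer eats from each whole-grain food group
# (adult, child/teen). Bread and ready-to-eat cereals dominate, mirroring
# the observed UK pattern where wheat supplies roughly three-quarters of
# whole grain, mostly via bread and RTEC.
_DEFAULT_GROUP_DAY_PROB: dict[FoodGroup, tuple[float, float]] = {
    FoodGroup.BREAD: (0.50, 0.38),
    FoodGroup.RTEC: (0.28, 0.40),
    FoodGroup.PORRIDGE: (0.10, 0.06),
    FoodGroup.SWEET_SNACKS: (0.10, 0.14),
    FoodGroup.SAVOURY_SNACKS: (0.06, 0.05),
    FoodGroup.OTHER_CEREALS: (0.05, 0.03),
    FoodGroup.RICE: (0.03, 0.02),
    FoodGroup.PASTA: (0.02, 0.02),
    FoodGroup.BAKES: (0.02, 0.02),
}

# Lognormal location (log grams) of portion size per food group; sigma is
# shared. Typical UK portions: two slices of bread ~70 g, a bowl of RTEC
# ~40 g, made-up porridge ~150 g, cooked rice/pasta ~170 g, snacks 25-60 g.
_DEFAULT_PORTION_MU: dict[FoodGroup, float] = {
    FoodGroup.BREAD: math.log(70.0),
    FoodGroup.RTEC: math.log(40.0),
    FoodGroup.PORRIDGE: math.log(150.0),
    FoodGroup.SWEET_SNACKS: math.log(30.0),
    FoodGroup.SAVOURY_SNACKS: math.log(25.0),
    FoodGroup.OTHER_CEREALS: math.log(80.0),
    FoodGroup.RICE: math.log(170.0),
    FoodGroup.PASTA: math.log(170.0),
    FoodGroup.BAKES: math.log(60.0),
}

# Relative whole-grain consumption propensity by age band: lowest in
# teenagers and younger adults, rising through middle age, slight decline
# in the oldest band.
_DEFAULT_AGE_BAND_FACTOR: dict[str, float] = {
    "1.5-4": 1.0,
    "5-12": 1.0,
    "13-17": 0.70,
    "18-24": 0.70,
    "25-34": 0.80,
    "35-44": 1.00,
    "45-54": 1.10,
    "55-64": 1.20,
    "65+": 1.15,
}

# Household NS-SEC class distribution (classes 1..8) before the missing rate.
_DEFAULT_NSSEC_PROBS = (0.12, 0.20, 0.12, 0.10, 0.10, 0.14, 0.14, 0.08)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; the defaults are the study conditions.

    ``nonconsumer_prob`` is the marginal probability of consuming no
    whole-grain food over the diary, per adult/child stratum; within a
    stratum it is graded by NS-SEC (more non-consumers in less advantaged
    classes) with the gradient normalised to preserve the marginal.
    ``portion_mu_shift`` shifts every lognormal portion location per
    stratum and is the handle :func:`calibrate` adjusts.
    """

    n_participants: int = 3073
    seed: int = 0
    child_fraction: float = 1502 / 3073
    male_fraction_adult: float = 0.44
    male_fraction_child: float = 0.51
    nssec_probs: tuple[float, ...] = _DEFAULT_NSSEC_PROBS
    nssec_missing_rate: float = 0.02
    diary_day_probs: Mapping[int, float] = field(
        default_factory=lambda: {4: 0.98, 3: 0.02}
    )
    nonconsumer_prob: Mapping[str, float] = field(
        default_factory=lambda: {"adult": 0.18, "child_teen": 0.15}
    )
    nssec_nonconsumer_gradient: float = 0.95  # multiplier span class 1 -> 8
    group_day_prob: Mapping[FoodGroup, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_DAY_PROB)
    )
    portion_mu: Mapping[FoodGroup, float] = field(
        default_factory=lambda: dict(_DEFAULT_PORTION_MU)
    )
    portion_sigma: float = 0.5
    portion_mu_shift: Mapping[str, float] = field(
        default_factory=lambda: {"adult": 0.0, "child_teen": 0.0}
    )
    child_portion_factor: float = 0.65  # children eat smaller portions
    male_portion_log_shift: float = 0.10
    nssec_portion_log_step: float = -0.04  # per class away from class 1
    age_band_factor: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AGE_BAND_FACTOR)
    )
    # mean / sd of daily energy intake (MJ) per (stratum, sex)
    energy_MJ: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("adult", "male"): (9.0, 1.6),
            ("adult", "female"): (6.9, 1.3),
            ("child_teen", "male"): (6.8, 1.6),
            ("child_teen", "female"): (6.1, 1.4),
        }
    )
    weight_log_sigma: float = 0.3
    nonwg_occasions_per_day: float = 2.0  # Poisson mean of filler foods

    def __post_init__(self) -> None:
        probs = list(self.nonconsumer_prob.values()) + [
            self.child_fraction,
            self.male_fraction_adult,
            self.male_fraction_child,
            self.nssec_missing_rate,
            *self.nssec_probs,
            *self.diary_day_probs.values(),
        ]
        for pr in probs:
            if not 0.0 <= pr <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {pr}")
        for pa, pc in self.group_day_prob.values():
            if not (0.0 <= pa <= 1.0 and 0.0 <= pc <= 1.0):
                raise ValueError("group_day_prob entries must be in [0, 1]")
        if not self.portion_sigma > 0:
            raise ValueError("portion_sigma must be > 0")
        if abs(sum(self.nssec_probs) - 1.0) > 1e-9:
            raise ValueError("nssec_probs must sum to 1")


@dataclass
class SyntheticDataset:
    """Generated tables plus independently computed ground truth.

    ``ground_truth`` has one row per participant with columns
    ``true_g_per_day_<tier>`` computed by the generator's own loop.
    """

    registry: Registry
    participants: list[Participant]
    occasions: list[DiaryOccasion]
    ground_truth: pd.DataFrame


def _nssec_multipliers(cfg: SyntheticConfig) -> np.ndarray:
    """Non-consumer probability multipliers per class 1..8, mean-normalised.

    Linear gradient from (1 − g/2) at class 1 to (1 + g/2) at class 8,
    rescaled so the expectation over the class distribution is exactly 1 —
    the stratum marginal non-consumer probability is then preserved.
    """
    g = cfg.nssec_nonconsumer_gradient
    raw = np.array([1.0 - g / 2 + g * k / 7.0 for k in range(8)])
    probs = np.array(cfg.nssec_probs)
    mean = float(np.sum(raw * probs)) * (1 - cfg.nssec_missing_rate) + cfg.nssec_missing_rate
    # missing-NS-SEC participants get multiplier 1 and enter the mean above
    return raw / mean


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Draw a complete synthetic dataset; byte-identical under a fixed seed."""
    cfg = config or SyntheticConfig()
    registry = default_registry()
    group_foods: dict[FoodGroup, list[str]] = {g: [] for g in FoodGroup}
    for rec in registry:
        group_foods[rec.food_group].append(rec.food_code)
    groups = list(cfg.group_day_prob.keys())
    nc_mult = _nssec_multipliers(cfg)

    participants: list[Participant] = []
    occasions: list[DiaryOccasion] = []

    for i in range(cfg.n_participants):
        rng = np.random.default_rng((cfg.seed, i))
        pid = f"P{i:05d}"
        is_child = rng.random() < cfg.child_fraction
        stratum = "child_teen" if is_child else "adult"
        age = float(rng.uniform(1.5, 18.0)) if is_child else float(rng.uniform(18.0, 90.0))
        male_p = cfg.male_fraction_child if is_child else cfg.male_fraction_adult
        sex = "male" if rng.random() < male_p else "female"
        nssec: int | None
        if rng.random() < cfg.nssec_missing_rate:
            nssec = None
        else:
            nssec = 1 + int(rng.choice(8, p=np.array(cfg.nssec_probs)))
        weight = float(np.exp(rng.normal(0.0, cfg.weight_log_sigma)))
        days = list(cfg.diary_day_probs.keys())
        n_days = int(rng.choice(days, p=np.array(list(cfg.diary_day_probs.values()))))
        e_mean, e_sd = cfg.energy_MJ[(stratum, sex)]
        energy = float(max(2.0, rng.normal(e_mean, e_sd)))
        participants.append(
            Participant(pid, age, sex, nssec, weight, n_days, energy)
        )

        # zero-inflation: absolute non-consumer for the whole diary
        p_nc = cfg.nonconsumer_prob[stratum]
        if 0.0 < p_nc < 1.0:  # gradient leaves degenerate probabilities alone
            p_nc *= nc_mult[nssec - 1] if nssec is not None else 1.0
        is_nonconsumer = rng.random() < min(p_nc, 1.0)

        band_factor = cfg.age_band_factor.get(age_band_label(age), 1.0)
        mu_shift = cfg.portion_mu_shift[stratum]
        mu_shift += cfg.male_portion_log_shift if sex == "male" else 0.0
        mu_shift += cfg.nssec_portion_log_step * ((nssec - 1) if nssec else 3.5)
        mu_shift += math.log(cfg.child_portion_factor) if is_child else 0.0

        if not is_nonconsumer:
            # a consumer has, by definition, at least one whole-grain
            # occasion over the diary: redraw the (rare) all-empty diaries
            # so the stated non-consumer probability is the exact marginal
            wg_occasions: list[DiaryOccasion] = []
            for _attempt in range(1000):
                wg_occasions.clear()
                for day in range(1, n_days + 1):
                    eats = rng.random(len(groups))
                    for k, grp in enumerate(groups):
                        pa, pc = cfg.group_day_prob[grp]
                        if eats[k] < (pc if is_child else pa) * band_factor:
                            code = group_foods[grp][
                                int(rng.integers(len(group_foods[grp])))
                            ]
                            portion = float(
                                rng.lognormal(
                                    cfg.portion_mu[grp] + mu_shift, cfg.portion_sigma
                                )
                            )
                            wg_occasions.append(DiaryOccasion(pid, day, code, portion))
                if wg_occasions:
                    break
            occasions.extend(wg_occasions)
        # filler non-whole-grain foods (unknown to the registry)
        for day in range(1, n_days + 1):
            for _ in range(rng.poisson(cfg.nonwg_occasions_per_day)):
                portion = float(rng.lognormal(math.log(120.0), 0.5))
                occasions.append(
                    DiaryOccasion(pid, day, f"XWG{int(rng.integers(100)):03d}", portion)
                )

    ground_truth = _ground_truth(participants, occasions, registry)
    return SyntheticDataset(registry, participants, occasions, ground_truth)


def _ground_truth(
    participants: Sequence[Participant],
    occasions: Sequence[DiaryOccasion],
    registry: Registry,
) -> pd.DataFrame:
    """Per-person expected intakes via a plain loop over raw registry fields.

    Intentionally re-derives cooked-form resolution, tier thresholds and
    day-averaging from the record fields themselves rather than calling the
    pipeline, so the two computations are independent.
    """
    records = {rec.food_code: rec for rec in registry}
    tiers = list(DEFAULT_TIER_THRESHOLDS.items())
    totals = {
        p.participant_id: {tier: 0.0 for tier, _ in tiers} for p in participants
    }
    for occ in occasions:
        rec = records.get(occ.food_code)
        if rec is None:
            continue
        if rec.cooked_form_of is not None:
            parent = records[rec.cooked_form_of]
            basis_mass = occ.consumed_g / (1.0 - rec.cooking_loss_percent / 100.0)
            pct = sum(parent.grain_content.values())
            eff_pct = pct / (1.0 - rec.cooking_loss_percent / 100.0)
        else:
            basis_mass = occ.consumed_g
            pct = sum(rec.grain_content.values())
            eff_pct = pct
        if eff_pct <= 0:
            continue
        grams = basis_mass * pct / 100.0
        for tier, threshold in tiers:
            if threshold <= 0 or eff_pct >= threshold:
                totals[occ.participant_id][tier] += grams
    rows = []
    for p in participants:
        row = {"participant_id": p.participant_id}
        for tier, _ in tiers:
            row[f"true_g_per_day_{tier.value}"] = (
                totals[p.participant_id][tier] / p.n_diary_days
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CalibrationTargets:
    """Headline values the generator should reproduce at the configured n."""

    median_g_per_day: Mapping[str, float] = field(
        default_factory=lambda: {"adult": 20.0, "child_teen": 13.0}
    )
    nonconsumer_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"adult": 0.18, "child_teen": 0.15}
    )
    tolerance: float = 0.10  # relative tolerance on medians


def _pipeline_medians(dataset: SyntheticDataset) -> dict[str, float]:
    intakes = estimate_all(dataset.occasions, dataset.participants, dataset.registry)
    return {
        s.stratum: s.median
        for s in summarize(intakes, dataset.participants, by="adult_child")
    }


def calibrate(
    config: SyntheticConfig,
    targets: CalibrationTargets | None = None,
    max_iter: int = 12,
) -> SyntheticConfig:
    """Tune per-stratum portion locations until weighted medians hit targets.

    Non-consumer probabilities are set directly from the targets. The
    lognormal location shift per stratum is then adjusted by a monotone
    multiplicative search (intake scales with portion mass, so the median
    responds monotonically to the shift): each iteration regenerates the
    dataset at the configured n and moves the shift by
    ``log(target / achieved)``. Raises if the relative tolerance is not met
    within ``max_iter`` iterations, reporting the best achieved medians.
    """
    tg = targets or CalibrationTargets()
    for v in tg.median_g_per_day.values():
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"target median must be positive and finite: {v}")
    cfg = replace(config, nonconsumer_prob=dict(tg.nonconsumer_fraction))
    shifts = dict(cfg.portion_mu_shift)
    best: dict[str, float] | None = None
    for _ in range(max_iter):
        cfg = replace(cfg, portion_mu_shift=dict(shifts))
        medians = _pipeline_medians(generate(cfg))
        best = medians
        ok = all(
            abs(medians[s] - t) <= tg.tolerance * t
            for s, t in tg.median_g_per_day.items()
        )
        if ok:
            return cfg
        for s, t in tg.median_g_per_day.items():
            if medians[s] > 0:
                shifts[s] += math.log(t / medians[s])
            else:  # degenerate start: push upward
                shifts[s] += 1.0
    raise RuntimeError(
        f"calibration did not converge in {max_iter} iterations; "
        f"best achieved medians: {best}"
    )
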