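"""Synthetic cohorts of animal-period sleep summaries and activity traces.

The generator emulates the statistical structure the regression analysis
assumes.  Its central modeling commitment is the *regulated* mode: per
animal-period, a sleep bout count ``x`` is drawn from a calibrated
over-dispersed count distribution, total sleep ``T`` is drawn from a
truncated normal around the condition's mean, and mean bout length is set
to ``y = T / x`` — the identity that holds exactly in scored data.  All
scatter around the fitted power law then comes from variation in ``T``, so
the fit's R² directly reflects how tightly total sleep is held to the
condition mean: tight ``T`` gives R² near 1, and drawing ``y``
independently of ``x`` (the *unregulated* mode, emulating severely
fragmented mutants) drives R² toward 0.

Bout counts use a shifted (support >= 1) negative binomial, moment-matched
to the requested mean/SD: healthy-fly bout counts are over-dispersed (SD
comparable to the mean), which a Poisson cannot express.  Totals are
rounded to whole minutes and truncated to ``[5x, 720 - (x - 1)]`` so that
every generated summary can be realized as a minute-level trace (each bout
at least 5 min, one waking minute between bouts) and re-scored exactly.

Shipped presets parameterize wild-type control, the fragmented-sleep
mutant *insomniac*, the *iso31* quasi-wildtype and the severely
hyposomnolent *fumin* (unregulated mode), plus sleep-deprivation/rebound
scenarios; see ``PRESETS`` and ``REBOUND_PRESETS``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .dam import DAY_MINUTES, ActivityTrace
from .exceptions import InfeasibleSummaryError
from .scoring import DAY, NIGHT, AnimalPeriodSummary

logger = logging.getLogger(__name__)

#: Minimum sleep-bout length the scorer recognizes, in minutes.
MIN_BOUT = 5
#: Largest bout count realizable in a 720-min period with 5-min bouts and
#: one waking minute between bouts: 5x + (x - 1) <= 720.
MAX_COUNT = 120


@dataclass
class CohortSpec:
    """Generator parameters for one genotype/period condition.

    ``mean_total_sleep``/``sd_total_sleep`` are minutes per 12-h period;
    ``count_mean``/``count_sd`` describe the sleep-bout-count distribution;
    ``activity_rate`` is the expected beam breaks per awake minute used
    when realizing traces.  In ``"unregulated"`` mode mean bout length is
    drawn log-normally (median ``mean_total_sleep / count_mean``, log-SD
    ``unregulated_log_sd``) independently of the count.
    """

    genotype_label: str
    period: str
    n_animals: int
    n_periods: int
    mean_total_sleep: float
    sd_total_sleep: float
    count_mean: float
    count_sd: float
    regulation_mode: str = "regulated"
    activity_rate: float = 2.0
    unregulated_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.mean_total_sleep <= DAY_MINUTES:
            raise ValueError("mean_total_sleep must lie in (0, 720] minutes")
        if self.count_mean < 1:
            raise ValueError("count_mean must be >= 1")
        if self.sd_total_sleep < 0 or self.count_sd < 0:
            raise ValueError("SDs must be non-negative")
        if self.regulation_mode not in ("regulated", "unregulated"):
            raise ValueError("regulation_mode must be 'regulated' or 'unregulated'")
        if self.period not in (DAY, NIGHT):
            raise ValueError("period must be 'day' or 'night'")

    @property
    def n_pairs(self) -> int:
        return self.n_animals * self.n_periods


@dataclass
class ScenarioSpec:
    """Parameters of a sleep-deprivation/rebound experiment.

    Baseline day and night conditions run for days 1-4 / nights 1-3;
    night 4 is the deprivation night (near-zero sleep, modeled through its
    outcome only); day 5 is the rebound day, regulated around
    ``rebound_day_sleep_mean`` with a tighter relative spread than
    baseline daytime sleep.
    """

    day: CohortSpec
    night: CohortSpec
    deprivation_night_sleep_mean: float
    deprivation_sd: float
    rebound_day_sleep_mean: float
    rebound_sd: float
    seed: int = 0

    def __post_init__(self):
        if not self.deprivation_night_sleep_mean < 30:
            raise ValueError("deprivation night mean must be near zero (< 30 min)")
        if not self.rebound_day_sleep_mean > self.day.mean_total_sleep:
            raise ValueError("rebound mean must exceed the baseline day mean")


# ---------------------------------------------------------------------------
# bout-count distribution


@dataclass
class CountDistribution:
    """Calibrated sleep-bout-count distribution with support >= 1."""

    family: str  # "shifted-negbinom" | "shifted-poisson" | "point-mass"
    params: dict

    @property
    def mean(self) -> float:
        if self.family == "shifted-negbinom":
            r, p = self.params["r"], self.params["p"]
            return 1.0 + r * (1 - p) / p
        if self.family == "shifted-poisson":
            return 1.0 + self.params["lam"]
        return float(self.params["k"])

    @property
    def sd(self) -> float:
        if self.family == "shifted-negbinom":
            r, p = self.params["r"], self.params["p"]
            return float(np.sqrt(r * (1 - p) / p**2))
        if self.family == "shifted-poisson":
            return float(np.sqrt(self.params["lam"]))
        return 0.0

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "shifted-negbinom":
            draws = 1 + rng.negative_binomial(self.params["r"], self.params["p"], size)
        elif self.family == "shifted-poisson":
            draws = 1 + rng.poisson(self.params["lam"], size)
        else:
            draws = np.full(size, self.params["k"], dtype=np.int64)
        return np.minimum(draws, MAX_COUNT).astype(np.int64)


def calibrate_count_distribution(count_mean: float, count_sd: float) -> CountDistribution:
    """Moment-match a support->=1 count family to a target mean and SD.

    The first choice is a shifted negative binomial ``1 + NB(r, p)``, which
    can express the over-dispersion of printed bout-count SDs.  When the
    target SD is too small for that family (``sd**2 <= mean - 1``) the
    calibration falls back to a shifted Poisson (with a logged warning), and
    a near-zero SD collapses to a point mass at ``round(mean)``.
    """
    if count_mean < 1:
        raise ValueError("count_mean must be >= 1")
    if count_sd < 0:
        raise ValueError("count_sd must be non-negative")
    m = count_mean - 1.0
    var = count_sd**2
    if count_sd < 1e-6 or m < 1e-9:
        return CountDistribution("point-mass", {"k": int(round(count_mean))})
    if var > m:
        p = m / var
        r = m * p / (1 - p)
        return CountDistribution("shifted-negbinom", {"r": r, "p": p})
    logger.warning(
        "count SD %.3g infeasible for a shifted negative binomial at mean %.3g; "
        "falling back to a shifted Poisson (SD %.3g)",
        count_sd, count_mean, np.sqrt(m),
    )
    return CountDistribution("shifted-poisson", {"lam": m})


# ---------------------------------------------------------------------------
# cohort generation


def _truncated_normal(mean, sd, lo, hi, rng):
    """Vectorized truncated-normal draws; degenerate SD clips the mean."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if sd == 0:
        return np.clip(np.full(lo.shape, float(mean)), lo, hi)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=lo.shape, random_state=rng)


def make_cohort(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> list[AnimalPeriodSummary]:
    """Generate ``n_animals * n_periods`` animal-period summaries.

    Deterministic given ``spec.seed`` (or an explicit ``rng``).  Every
    summary satisfies the structural identity ``total = count * mean`` and
    is realizable as a trace by :func:`realize_trace`.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_pairs
    dist = calibrate_count_distribution(spec.count_mean, spec.count_sd)
    x = dist.rvs(n, rng)
    lo = (MIN_BOUT * x).astype(float)
    hi = (DAY_MINUTES - (x - 1)).astype(float)

    if spec.regulation_mode == "regulated":
        t = _truncated_normal(spec.mean_total_sleep, spec.sd_total_sleep, lo, hi, rng)
        t = np.clip(np.round(t), lo, hi)
    else:
        median = spec.mean_total_sleep / spec.count_mean
        y = median * np.exp(spec.unregulated_log_sd * rng.standard_normal(n))
        y = np.maximum(y, MIN_BOUT)  # a scored mean bout length cannot be < 5
        t = np.clip(np.round(x * y), lo, hi)

    out = []
    for i in range(n):
        animal = i % spec.n_animals
        day = 1 + i // spec.n_animals
        total = float(t[i])
        out.append(
            AnimalPeriodSummary(
                animal_id=f"{spec.genotype_label}-a{animal:03d}",
                day_index=day,
                period=spec.period,
                total_sleep=total,
                bout_count=int(x[i]),
                mean_bout_length=total / int(x[i]),
                genotype=spec.genotype_label,
            )
        )
    return out


def _uniform_composition(total: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform composition of ``total`` into ``k`` non-negative parts."""
    if k == 1:
        return np.array([total], dtype=np.int64)
    cuts = np.sort(rng.choice(total + k - 1, size=k - 1, replace=False))
    bounds = np.concatenate([[-1], cuts, [total + k - 1]])
    return np.diff(bounds) - 1


def realize_trace(
    summary: AnimalPeriodSummary,
    activity_rate: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ActivityTrace:
    """Materialize a summary as a 720-minute activity trace.

    Places ``bout_count`` zero runs (each >= 5 min, summing to
    ``total_sleep``) separated by at least one active minute, uniformly at
    random over all feasible arrangements; awake minutes receive
    positive-truncated Poisson(``activity_rate``) counts.  Re-scoring the
    trace with the standard 5-minute rule reproduces the summary exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    total = summary.total_sleep
    k = summary.bout_count
    if total != int(total):
        raise InfeasibleSummaryError("total_sleep must be whole minutes to realize a trace")
    total = int(total)
    if total > DAY_MINUTES or (k > 0 and (total < MIN_BOUT * k or total + (k - 1) > DAY_MINUTES)):
        raise InfeasibleSummaryError(
            f"cannot place {k} bouts >= {MIN_BOUT} min totalling {total} in {DAY_MINUTES} min"
        )
    if k == 0 and total != 0:
        raise InfeasibleSummaryError("zero bouts require zero total sleep")
    if activity_rate <= 0:
        raise ValueError("activity_rate must be positive")

    awake = DAY_MINUTES - total
    counts = np.zeros(DAY_MINUTES, dtype=np.int64)

    def awake_counts(size: int) -> np.ndarray:
        # positive-truncated Poisson: resample zeros until none remain
        c = rng.poisson(activity_rate, size)
        while (zero := c == 0).any():
            c[zero] = rng.poisson(activity_rate, int(zero.sum()))
        return c

    if k == 0:
        counts[:] = awake_counts(DAY_MINUTES)
    else:
        lengths = MIN_BOUT + _uniform_composition(total - MIN_BOUT * k, k, rng)
        gaps = _uniform_composition(awake - (k - 1), k + 1, rng)
        gaps[1:-1] += 1  # interior gaps must break the zero runs
        pos = 0
        active = awake_counts(awake)
        a_used = 0
        for i in range(k):
            g = int(gaps[i])
            counts[pos:pos + g] = active[a_used:a_used + g]
            pos += g
            a_used += g
            pos += int(lengths[i])  # zero run: already zeros
        g = int(gaps[-1])
        counts[pos:pos + g] = active[a_used:a_used + g]

    start_zt = 0 if summary.period == DAY else DAY_MINUTES
    return ActivityTrace(
        animal_id=summary.animal_id,
        counts=counts,
        start_day=summary.day_index,
        start_zt=start_zt,
    )


def make_rebound_scenario(spec: ScenarioSpec) -> list[AnimalPeriodSummary]:
    """Simulate a 5-day deprivation/rebound experiment.

    Returns summaries for days 1-5 and nights 1-4 of ``spec.day.n_animals``
    animals: baseline behavior through day 4 / night 3, near-zero sleep on
    the deprivation night 4, and regulated rebound sleep on day 5.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.day.n_animals
    out: list[AnimalPeriodSummary] = []

    days = replace(spec.day, n_periods=4)
    nights = replace(spec.night, n_animals=n, n_periods=3)
    out.extend(make_cohort(days, rng=rng))
    out.extend(make_cohort(nights, rng=rng))

    # deprivation night: sleep modeled through its outcome (forced near zero)
    dist = calibrate_count_distribution(spec.night.count_mean, spec.night.count_sd)
    t4 = np.round(_truncated_normal(
        spec.deprivation_night_sleep_mean, spec.deprivation_sd,
        np.zeros(n), np.full(n, float(DAY_MINUTES)), rng,
    ))
    c4 = dist.rvs(n, rng)
    for i in range(n):
        total = float(t4[i])
        if total < MIN_BOUT:
            total, count = 0.0, 0
        else:
            count = int(np.clip(c4[i], 1, total // MIN_BOUT))
        out.append(
            AnimalPeriodSummary(
                animal_id=f"{spec.night.genotype_label}-a{i:03d}",
                day_index=4,
                period=NIGHT,
                total_sleep=total,
                bout_count=count,
                mean_bout_length=total / count if count else None,
                genotype=spec.night.genotype_label,
            )
        )

    rebound = replace(
        spec.day,
        n_periods=1,
        mean_total_sleep=spec.rebound_day_sleep_mean,
        sd_total_sleep=spec.rebound_sd,
    )
    for s in make_cohort(rebound, rng=rng):
        s.day_index = 5
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# presets
#
# Sample sizes and total-sleep / bout-count means and SDs follow the printed
# summary statistics of the wild-type (w1118 control), insomniac, iso31 and
# fumin conditions: 31 animals x 4 periods per genotype in the main
# experiment, 7 (control) and 9 (insomniac) animals in the rebound
# experiment.  Where a condition's bout-count moments were never printed
# (iso31, fumin), control-like counts and plausibly fragmented counts are
# used; insomniac daytime totals are derived from the printed 24-h and
# nighttime moments assuming independent day and night totals.  fumin runs
# in unregulated mode: its near-zero fit quality is the signature of sleep
# with bout structure decoupled from total sleep.

_SEEDS = {
    "control_day": 11,
    "control_night": 12,
    "insomniac_day": 13,
    "insomniac_night": 14,
    "iso31_day": 15,
    "iso31_night": 16,
    "fumin_day": 17,
    "fumin_night": 18,
    "rebound_control": 19,
    "rebound_insomniac": 20,
}


def _preset(label, period, total, sd, cmean, csd, mode="regulated", n=31, periods=4, seed=0):
    return CohortSpec(
        genotype_label=label, period=period, n_animals=n, n_periods=periods,
        mean_total_sleep=total, sd_total_sleep=sd, count_mean=cmean, count_sd=csd,
        regulation_mode=mode, seed=seed,
    )


PRESETS: dict[str, CohortSpec] = {
    "control_day": _preset("control", DAY, 396.4, 82.9, 12.6, 4.6, seed=_SEEDS["control_day"]),
    "control_night": _preset("control", NIGHT, 672.6, 29.9, 4.9, 4.2, seed=_SEEDS["control_night"]),
    # day mean/SD derived from printed 24-h (770.1, 210.0) and night
    # (394.7, 148.7) moments: 770.1 - 394.7 and sqrt(210^2 - 148.7^2)
    "insomniac_day": _preset("insomniac", DAY, 375.4, 148.3, 23.1, 8.1, seed=_SEEDS["insomniac_day"]),
    "insomniac_night": _preset("insomniac", NIGHT, 394.7, 148.7, 16.8, 7.5, seed=_SEEDS["insomniac_night"]),
    "iso31_day": _preset("iso31", DAY, 500.1, 56.1, 12.6, 4.6, seed=_SEEDS["iso31_day"]),
    "iso31_night": _preset("iso31", NIGHT, 559.5, 49.5, 4.9, 4.2, seed=_SEEDS["iso31_night"]),
    "fumin_day": _preset("fumin", DAY, 199.4, 80.3, 18.0, 7.0, mode="unregulated", n=28, seed=_SEEDS["fumin_day"]),
    "fumin_night": _preset("fumin", NIGHT, 142.1, 115.4, 12.0, 7.0, mode="unregulated", n=28, seed=_SEEDS["fumin_night"]),
}

REBOUND_PRESETS: dict[str, ScenarioSpec] = {
    "rebound_control": ScenarioSpec(
        day=replace(PRESETS["control_day"], n_animals=7),
        night=replace(PRESETS["control_night"], n_animals=7),
        deprivation_night_sleep_mean=9.1,
        deprivation_sd=21.6,
        rebound_day_sleep_mean=496.0,
        rebound_sd=50.2,
        seed=_SEEDS["rebound_control"],
    ),
    "rebound_insomniac": ScenarioSpec(
        day=replace(PRESETS["insomniac_day"], n_animals=9),
        night=replace(PRESETS["insomniac_night"], n_animals=9),
        deprivation_night_sleep_mean=3.4,
        deprivation_sd=10.0,  # not printed; scaled below the control value
        rebound_day_sleep_mean=496.0,
        rebound_sd=126.0,
        seed=_SEEDS["rebound_insomniac"],
    ),
}


def derive_seed(base_seed: int, tag: str) -> int:
    """Stable per-condition seed (< 2**31) from a base seed and a name."""
    import hashlib

    digest = hashlib.sha256(f"{base_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def preset_reseed(spec: CohortSpec, base_seed: int, tag: str) -> CohortSpec:
    """Copy of ``spec`` with a seed derived from ``base_seed`` and ``tag``."""
    return replace(spec, seed=derive_seed(base_seed, tag))


def scenario_reseed(spec: ScenarioSpec, base_seed: int, tag: str) -> ScenarioSpec:
    """Copy of ``spec`` with a seed derived from ``base_seed`` and ``tag``."""
    return replace(spec, seed=derive_seed(base_seed, tag))


def preset(name: str, seed: int | None = None, **overrides) -> CohortSpec:
    """Fetch a shipped cohort preset, optionally reseeded or overridden."""
    spec = PRESETS[name]
    if seed is not None:
        overrides["seed"] = seed
    return replace(spec, **overrides) if overrides else spec
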