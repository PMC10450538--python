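"""Synthetic exposure series and death records with known interactions.

The study design this package implements needs two inputs that are not
publicly available: a daily series of suicide-related posts and
individual mortality records.  This module generates both from an
explicit Poisson model so every downstream stage can be tested against a
known ground truth.

Generating model
----------------
Daily death counts in characteristic stratum j follow

    log E[Y_tj] = beta0 + log p_j + beta2_j + seasonal(t) + weekday(t)
                  + (beta1 + beta3_j) * E(t - effect_lag_days)

where E(.) is the binary surge indicator of the exposure calendar, p_j
the stratum's population share, beta1 the surge main effect and beta3_j
the interaction of interest — the case-only estimator targets
exp(beta3_j).  ``seasonal`` is a single sinusoid and ``weekday`` seven
day-of-week offsets; both are shared across strata, which is exactly the
time-varying confounding structure the case-only design is immune to.

The exposure series is a lognormal multiplicative-noise process around a
constant baseline with rare injected spike days; spikes raise the
previous-day ratio so the surge classifier can be scored against the
injected ground truth.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict, replace
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exposure import ExposureCalendar, TweetSeries

__all__ = [
    "Characteristic",
    "SimScenario",
    "ScenarioError",
    "CalendarGapError",
    "default_scenario",
    "binary_scenario",
    "simulate_tweet_series",
    "simulate_deaths",
    "ground_truth",
    "write_inputs",
]

SUICIDE_CODES = [f"X{n}" for n in range(60, 85)]
UNEXPECTED_CODES = (
    [f"W{n:02d}" for n in range(100)]
    + [f"X{n:02d}" for n in range(60)]
    + [f"Y{n:02d}" for n in range(1, 60)]
)

#: constant attribute values used when a scenario does not model a field
_FILL = {
    "age": 50,
    "sex": "female",
    "occupation": "self-employed",
    "marital_status": "married",
    "area": "urban",
}

# RNG substream tags: toggling one component must not perturb the others
_STREAM_TWEETS = 1
_STREAM_DEATHS = 2
_STREAM_SENSITIVITY = 3


class ScenarioError(ValueError):
    """A scenario field failed validation (the message names the field)."""


class CalendarGapError(ValueError):
    """The exposure calendar does not cover the scenario's date span."""


@dataclass(frozen=True)
class Characteristic:
    """One individual characteristic: ordered levels, a reference level,
    population level shares and per-level main (beta2) and interaction
    (beta3) log-rate-ratio effects for the non-reference levels."""

    name: str
    levels: tuple
    reference: str
    proportions: dict
    beta2: dict = field(default_factory=dict)
    beta3: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(set(self.levels)) != len(self.levels):
            raise ScenarioError(f"characteristic {self.name!r}: duplicate levels")
        if self.levels.count(self.reference) != 1:
            raise ScenarioError(
                f"characteristic {self.name!r}: reference {self.reference!r} "
                "must appear exactly once in levels"
            )
        if set(self.proportions) != set(self.levels):
            raise ScenarioError(
                f"characteristic {self.name!r}: proportions must cover all levels"
            )
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ScenarioError(
                f"characteristic {self.name!r}: proportions sum to {total}, not 1"
            )
        for tag, coefs in (("beta2", self.beta2), ("beta3", self.beta3)):
            extra = set(coefs) - (set(self.levels) - {self.reference})
            if extra:
                raise ScenarioError(
                    f"characteristic {self.name!r}: {tag} given for {sorted(extra)} "
                    "(only non-reference levels may have effects)"
                )

    def effect(self, coefs: dict, level: str) -> float:
        return 0.0 if level == self.reference else float(coefs.get(level, 0.0))


@dataclass(frozen=True)
class SimScenario:
    """Full parameterization of the generating model."""

    n_days: int = 1461  # 2011-01-01 .. 2014-12-31
    start_date: date = date(2011, 1, 1)
    beta0: float = math.log(105.0)  # ~155k suicide records over the span
    beta1: float = math.log(1.10)
    characteristics: tuple = ()
    effect_lag_days: int = 3  # lag at which the surge acts on mortality
    seasonal_amplitude: float = 0.2
    seasonal_period_days: float = 365.25
    weekday_effects: tuple = (0.05, 0.01, -0.01, -0.02, -0.02, -0.03, 0.0)
    tweet_baseline: float = 1920.0
    tweet_noise_sd: float = 0.25
    spike_prob: float = 0.02
    spike_multiplier_range: tuple = (3.0, 6.0)
    sensitivity_stream: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "characteristics", tuple(self.characteristics))
        object.__setattr__(self, "weekday_effects", tuple(self.weekday_effects))
        object.__setattr__(
            self, "spike_multiplier_range", tuple(self.spike_multiplier_range)
        )
        if self.n_days < 2:
            raise ScenarioError("n_days: must be >= 2")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ScenarioError("spike_prob: must be in [0, 1]")
        if self.tweet_baseline <= 0:
            raise ScenarioError("tweet_baseline: must be positive")
        if self.tweet_noise_sd < 0:
            raise ScenarioError("tweet_noise_sd: must be non-negative")
        if len(self.weekday_effects) != 7:
            raise ScenarioError("weekday_effects: need exactly 7 offsets (Mon..Sun)")
        lo, hi = self.spike_multiplier_range
        if not (0 < lo <= hi):
            raise ScenarioError("spike_multiplier_range: need 0 < low <= high")
        if self.effect_lag_days < 0:
            raise ScenarioError("effect_lag_days: must be >= 0")
        names = [c.name for c in self.characteristics]
        if len(set(names)) != len(names):
            raise ScenarioError("characteristics: duplicate names")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def log_baseline(self) -> np.ndarray:
        """beta0 + seasonal(t) + weekday(t) for every day of the span."""
        t = np.arange(self.n_days)
        seasonal = self.seasonal_amplitude * np.sin(
            2 * np.pi * t / self.seasonal_period_days
        )
        wd = np.asarray(self.weekday_effects)[self.dates.weekday]
        return self.beta0 + seasonal + wd


def default_scenario(seed: int = 0, **overrides) -> SimScenario:
    """The standard study-scale scenario: 1461 days, five characteristics
    with population shares patterned on Japanese suicide statistics and
    plausible interaction effects of the size the method is meant to
    detect (|log OR| around 0.1-0.25)."""
    occ = {"self-employed": 8.3, "agriculture": 6.0, "corporate": 21.6,
           "other": 10.9, "unemployed": 41.8}
    occ_total = sum(occ.values())
    characteristics = (
        Characteristic(
            "age_group", ("old", "young"), "old",
            {"old": 0.778, "young": 0.222},
            beta3={"young": math.log(1.09)},
        ),
        Characteristic(
            "sex", ("female", "male"), "female",
            {"female": 0.349, "male": 0.651},
            beta3={"male": math.log(1.12)},
        ),
        Characteristic(
            "occupation",
            ("self-employed", "agriculture", "corporate", "other", "unemployed"),
            "self-employed",
            {k: v / occ_total for k, v in occ.items()},
            beta3={"agriculture": math.log(0.99), "corporate": math.log(1.02),
                   "other": math.log(1.07), "unemployed": math.log(1.12)},
        ),
        Characteristic(
            "marital_status",
            ("married", "unmarried", "widowed", "divorced", "other"),
            "married",
            {"married": 0.411, "unmarried": 0.271, "widowed": 0.176,
             "divorced": 0.13, "other": 0.012},
            beta3={"unmarried": math.log(1.04), "widowed": math.log(0.83),
                   "divorced": math.log(1.11)},
        ),
        Characteristic(
            "area", ("rural", "urban"), "rural",
            {"rural": 0.136, "urban": 0.864},
            beta3={"urban": math.log(1.26)},
        ),
    )
    return SimScenario(
        characteristics=characteristics,
        sensitivity_stream=True,
        seed=seed,
        **overrides,
    )


def binary_scenario(
    beta3: float, seed: int = 0, proportion: float = 0.5, **overrides
) -> SimScenario:
    """A single-binary-characteristic scenario used for parameter-recovery
    and type-I-error studies: one sex-like characteristic with interaction
    ``beta3`` on the non-reference level."""
    char = Characteristic(
        "sex", ("female", "male"), "female",
        {"female": 1.0 - proportion, "male": proportion},
        beta3={"male": beta3},
    )
    return SimScenario(characteristics=(char,), seed=seed, **overrides)


def _rng(scenario: SimScenario, stream: int, seed: Optional[int]) -> np.random.Generator:
    base = scenario.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence(base, spawn_key=(stream,)))


def simulate_tweet_series(
    scenario: SimScenario, seed: Optional[int] = None
) -> tuple[TweetSeries, set]:
    """Generate the daily post-count series.

    count(d) = round(baseline * lognormal noise * spike multiplier), with
    a spike injected independently per day with probability
    ``spike_prob``.  Returns the series and the set of injected spike
    dates as ground truth for classifier evaluation.
    """
    rng = _rng(scenario, _STREAM_TWEETS, seed)
    n = scenario.n_days
    noise = np.exp(rng.normal(0.0, scenario.tweet_noise_sd, n)) if scenario.tweet_noise_sd else np.ones(n)
    spiked = rng.random(n) < scenario.spike_prob
    lo, hi = scenario.spike_multiplier_range
    mult = np.where(spiked, rng.uniform(lo, hi, n), 1.0)
    counts = np.rint(scenario.tweet_baseline * noise * mult)
    dates = scenario.dates
    return TweetSeries(dates, counts), set(dates[spiked])


def _exposure_indicator(scenario: SimScenario, calendar: ExposureCalendar) -> np.ndarray:
    """Lagged binary exposure E(t - effect_lag_days) per scenario day.

    Undefined exposure (day 1 of the calendar, zero-denominator days, or
    lagged dates before the calendar start) counts as unexposed for
    generation.  Raises CalendarGapError if in-range dates are missing.
    """
    dates = scenario.dates
    lag = pd.Timedelta(days=scenario.effect_lag_days)
    lagged = dates - lag
    cal_start, cal_end = calendar.dates[0], calendar.dates[-1]
    in_range = (lagged >= cal_start) & (lagged <= cal_end)
    missing = [d for d in lagged[in_range] if d not in calendar._index]
    if missing:
        raise CalendarGapError(
            "exposure calendar has gaps at: "
            + ", ".join(str(d.date()) for d in missing[:10])
        )
    E = np.zeros(scenario.n_days)
    for i, d in enumerate(lagged):
        if in_range[i]:
            e = calendar.exposed[calendar._index[d]]
            if not math.isnan(e):
                E[i] = e
    return E


def _strata(characteristics: Sequence[Characteristic]):
    """Cross-product strata with joint share (independent characteristics),
    summed beta2 and summed beta3."""
    if not characteristics:
        return [((), 1.0, 0.0, 0.0)]
    out = []
    for combo in itertools.product(*(c.levels for c in characteristics)):
        p = 1.0
        b2 = b3 = 0.0
        for c, level in zip(characteristics, combo):
            p *= c.proportions[level]
            b2 += c.effect(c.beta2, level)
            b3 += c.effect(c.beta3, level)
        out.append((combo, p, b2, b3))
    return out


def _const_cat(value: str, n: int, categories: Sequence[str]) -> pd.Categorical:
    # all strata must share one category list per column or concat degrades
    code = list(categories).index(value)
    return pd.Categorical.from_codes(
        np.full(n, code, dtype=np.int8), categories=list(categories)
    )


def _draw_stream(
    scenario: SimScenario,
    E: np.ndarray,
    rng: np.random.Generator,
    codes: Sequence[str],
    null_interaction: bool,
) -> pd.DataFrame:
    dates = scenario.dates
    log_base = scenario.log_baseline()
    chars = scenario.characteristics
    frames = []
    for combo, p, b2, b3 in _strata(chars):
        if p == 0.0:
            continue
        if null_interaction:
            b3 = 0.0
        lam = np.exp(log_base + math.log(p) + b2 + (scenario.beta1 + b3) * E)
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        row = {"date": np.repeat(dates.values, counts)}
        attrs = dict(zip((c.name for c in chars), combo))
        if "age_group" in attrs:
            row["age"] = (
                rng.integers(10, 41, total)
                if attrs["age_group"] == "young"
                else rng.integers(41, 99, total)
            )
        else:
            row["age"] = np.full(total, _FILL["age"])
        # constant-per-stratum attributes as categoricals: building <U
        # string arrays dominates runtime in replicate sweeps otherwise
        levels_of = {c.name: c.levels for c in chars}
        for col in ("sex", "occupation", "marital_status", "area"):
            value = attrs.get(col, _FILL[col])
            row[col] = _const_cat(value, total, levels_of.get(col, (value,)))
        for name, level in attrs.items():
            if name not in ("age_group", "sex", "occupation", "marital_status", "area"):
                row[name] = _const_cat(level, total, levels_of[name])
        row["icd10"] = pd.Categorical.from_codes(
            rng.integers(0, len(codes), total), categories=list(codes)
        )
        frames.append(pd.DataFrame(row))
    if not frames:
        cols = ["date", "age", "sex", "occupation", "marital_status", "area", "icd10"]
        return pd.DataFrame(columns=cols)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values("date", kind="stable", ignore_index=True)


def simulate_deaths(
    scenario: SimScenario,
    calendar: ExposureCalendar,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Draw individual death records from the Poisson model.

    Counts are drawn per day and per characteristic stratum, then
    exploded to one row per death (columns: date, age, sex, occupation,
    marital_status, area, icd10).  Suicide-stream records carry codes in
    X60-X84.  If ``scenario.sensitivity_stream``, a parallel stream with
    all interactions set to zero and non-suicide external-cause codes
    (W00-X59, Y01-Y59) is appended; its rows are distinguished by code.
    """
    E = _exposure_indicator(scenario, calendar)
    df = _draw_stream(
        scenario, E, _rng(scenario, _STREAM_DEATHS, seed), SUICIDE_CODES, False
    )
    if scenario.sensitivity_stream:
        sens = _draw_stream(
            scenario,
            E,
            _rng(scenario, _STREAM_SENSITIVITY, seed),
            UNEXPECTED_CODES,
            True,
        )
        df = pd.concat([df, sens], ignore_index=True)
        df = df.sort_values("date", kind="stable", ignore_index=True)
    return df


def ground_truth(scenario: SimScenario) -> dict:
    """exp(beta3) per characteristic level (1.0 at the reference)."""
    return {
        c.name: {
            level: 1.0 if level == c.reference else math.exp(c.effect(c.beta3, level))
            for level in c.levels
        }
        for c in scenario.characteristics
    }


def write_inputs(
    scenario: SimScenario,
    outdir,
    seed: Optional[int] = None,
    percentile: float = 95.0,
) -> dict:
    """Simulate and write the pipeline's input files.

    Writes ``tweets.csv`` (date,count), ``deaths.csv`` (date,age,sex,
    occupation,marital_status,area,icd10) and ``ground_truth.json`` (the
    scenario plus the exp(beta3) map and injected spike dates) to
    *outdir*; the exposure calendar used for generation is classified
    from the simulated series at ``percentile``.  Returns the paths.
    """
    from .exposure import classify_surge

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series, spikes = simulate_tweet_series(scenario, seed)
    calendar = classify_surge(series, percentile)
    deaths = simulate_deaths(scenario, calendar, seed)

    tweets_path = outdir / "tweets.csv"
    deaths_path = outdir / "deaths.csv"
    truth_path = outdir / "ground_truth.json"

    frame = series.to_frame()
    frame["date"] = frame["date"].dt.strftime("%Y-%m-%d")
    frame.to_csv(tweets_path, index=False)

    out = deaths.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    cols = ["date", "age", "sex", "occupation", "marital_status", "area", "icd10"]
    extra = [c for c in out.columns if c not in cols]
    out[cols + extra].to_csv(deaths_path, index=False)

    scen = asdict(replace(scenario, characteristics=()))
    scen["start_date"] = scenario.start_date.isoformat()
    scen["characteristics"] = [asdict(c) for c in scenario.characteristics]
    payload = {
        "scenario": scen,
        "interaction_or": ground_truth(scenario),
        "effect_lag_days": scenario.effect_lag_days,
        "spike_dates": sorted(str(d.date()) for d in spikes),
        "n_records": int(len(deaths)),
    }
    truth_path.write_text(json.dumps(payload, indent=2))
    return {"tweets": tweets_path, "deaths": deaths_path, "ground_truth": truth_path}
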