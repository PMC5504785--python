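"""Synthetic linked EHR bundle: practices, patients, SCr series, admissions.

The generator emulates the statistical structure of a regional linked
database — not any real population's absolute counts — so the full
pipeline can be exercised end to end:

* an age gradient in biochemical testing (older patients are tested more,
  with a dip in the very oldest band);
* per-patient stable baseline creatinine (gender-specific lognormal) with
  multiplicative assay/biological noise on repeat tests;
* injected AKI episodes that multiply the baseline by a ramp up to a peak
  ratio and back down, arising either in hospital (an admission spell
  starting at onset, with daily in-spell testing) or in the community
  (sparse test draws, optionally followed by an admission after a short
  lag);
* a fraction of practices with deficient testing rates, to exercise the
  Tukey-fence practice filter, and a fraction of patients with incomplete
  registration, to exercise patient eligibility.

Ground truth for every injected episode is written alongside the data,
including whether the sampled test dates and values actually satisfy the
alerting criteria (``expected_alertable``), established by an independent
brute-force evaluation of the written series.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BANDS",
    "AGE_BAND_LABELS",
    "age_band",
    "SimulationConfig",
    "SimulatedDataset",
    "generate",
]

# Age bands of the demographic report (upper bound None = open-ended).
AGE_BANDS: list[tuple[int, int | None]] = [
    (18, 24), (25, 34), (35, 44), (45, 54), (55, 64),
    (65, 74), (75, 84), (85, 94), (95, None),
]
AGE_BAND_LABELS = [
    "18-24", "25-34", "35-44", "45-54", "55-64",
    "65-74", "75-84", "85-94", "95+",
]

# Adult age-band mix of a southern-England regional population, normalised.
_BAND_WEIGHTS = np.array(
    [67147, 100268, 102900, 120008, 98253, 83460, 49808, 19087, 1406], dtype=float
)
_BAND_WEIGHTS /= _BAND_WEIGHTS.sum()

# Community testing intensity per band, tests/person-year.  Chosen so that
# the two-year probability of holding >= 2 results rises from ~8% in young
# adults to ~68% at 85-94 and dips in the 95+ band, matching the observed
# regional gradient.
_BAND_TEST_RATES = (0.23, 0.27, 0.33, 0.43, 0.58, 0.79, 1.12, 1.20, 0.93)


def age_band(age: int) -> str:
    """Band label for an adult age; under-18s are outside the cohort."""
    if age < 18:
        raise ValueError(f"age bands are defined for adults only, got {age}")
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        if hi is None or age <= hi:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Rates are per person-year, dates are calendar dates, creatinine is in
    μmol/L.  ``seed`` drives a deterministic per-patient substream layout,
    so enlarging ``n_patients`` never perturbs existing patients.
    """

    seed: int = 0
    # population
    n_practices: int = 20
    anchor_fraction: float = 0.5
    n_patients: int = 10_000
    age_band_weights: tuple[float, ...] = tuple(_BAND_WEIGHTS)
    male_fraction: float = 0.487
    # testing behaviour
    band_test_rates: tuple[float, ...] = _BAND_TEST_RATES
    low_rate_practice_fraction: float = 0.15
    low_rate_multiplier: float = 0.1
    partial_registration_fraction: float = 0.05
    # creatinine model
    baseline_median_male: float = 80.0
    baseline_median_female: float = 65.0
    baseline_sigma: float = 0.18          # lognormal scale of ln(baseline)
    noise_cv: float = 0.07                # CV of repeat tests
    # AKI episodes
    episode_rate: float = 0.008           # episodes/person-year of observation
    peak_ratio_bins: tuple[tuple[float, float], ...] = (
        (1.2, 1.5), (1.5, 2.0), (2.0, 3.0), (3.0, 5.0),
    )
    peak_ratio_weights: tuple[float, ...] = (0.25, 0.40, 0.22, 0.13)
    onset_days: tuple[int, int] = (1, 3)
    recovery_days: tuple[int, int] = (5, 14)
    # admissions
    p_hospital_onset: float = 0.35
    p_community_admitted: float = 0.55
    admission_lag_weights: tuple[float, ...] = (
        0.35, 0.20, 0.12, 0.09, 0.07, 0.06, 0.06, 0.05,   # lag 0..7 days
    )
    los_days: tuple[int, int] = (3, 10)
    # calendar
    study_start: date = date(2013, 1, 1)
    obs_start: date = date(2014, 1, 1)
    obs_end: date = date(2014, 12, 31)

    def __post_init__(self) -> None:
        errors = []
        for name in (
            "anchor_fraction", "male_fraction", "low_rate_practice_fraction",
            "low_rate_multiplier", "partial_registration_fraction",
            "p_hospital_onset", "p_community_admitted",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name} must be in [0, 1], got {v}")
        for name in ("episode_rate", "noise_cv", "baseline_sigma"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        if self.n_practices < 1:
            errors.append("n_practices must be >= 1")
        if self.n_patients < 0:
            errors.append("n_patients must be >= 0")
        if len(self.age_band_weights) != len(AGE_BANDS):
            errors.append(f"age_band_weights needs {len(AGE_BANDS)} entries")
        elif min(self.age_band_weights) < 0 or sum(self.age_band_weights) <= 0:
            errors.append("age_band_weights must be non-negative and sum > 0")
        if len(self.band_test_rates) != len(AGE_BANDS):
            errors.append(f"band_test_rates needs {len(AGE_BANDS)} entries")
        elif min(self.band_test_rates) < 0:
            errors.append("band_test_rates must be non-negative")
        if len(self.peak_ratio_weights) != len(self.peak_ratio_bins):
            errors.append("peak_ratio_weights must match peak_ratio_bins")
        if len(self.admission_lag_weights) != 8:
            errors.append("admission_lag_weights needs 8 entries (lags 0..7)")
        if not (self.study_start <= self.obs_start <= self.obs_end):
            errors.append("require study_start <= obs_start <= obs_end")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))

    @property
    def n_days(self) -> int:
        return (self.obs_end - self.study_start).days + 1


@dataclass
class SimulatedDataset:
    """The four linked input tables plus the episode ground-truth table."""

    patients: pd.DataFrame
    practices: pd.DataFrame
    scr_results: pd.DataFrame
    admissions: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("patients", "practices", "scr_results", "admissions", "truth"):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


# ---------------------------------------------------------------------------
# Independent episode-detectability check
# ---------------------------------------------------------------------------
# Deliberately re-derives the alerting criteria with plain loops over the
# written series (no reuse of the algorithm module), so the truth labels
# are an independent statement of what the data guarantee.

def _independent_first_alert(
    tests: list[tuple[int, int, float]], lo_day: int, hi_day: int
) -> tuple[int, int] | None:
    for i, (d, s, v) in enumerate(tests):
        if not (lo_day <= d <= hi_day):
            continue
        prior = tests[:i]
        short = [pv for pd_, _, pv in prior if d - 7 <= pd_ <= d]
        long_ = [pv for pd_, _, pv in prior if d - 365 <= pd_ <= d - 8]
        risew = [pv for pd_, _, pv in prior if d - 2 <= pd_ <= d]
        ratios = []
        if short:
            ratios.append(v / min(short))
        if long_:
            ratios.append(v / statistics.median(long_))
        ratio_alert = bool(ratios) and max(ratios) >= 1.5
        rise_alert = bool(risew) and (v - min(risew)) > 26
        if ratio_alert or rise_alert:
            return d, s
    return None


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _episode_multiplier(day: int, onset: int, peak: float, up: int, down: int) -> float:
    if day < onset or day > onset + up + down:
        return 1.0
    if day <= onset + up:
        return 1.0 + (peak - 1.0) * (day - onset) / up
    return peak + (1.0 - peak) * (day - onset - up) / down


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full linked bundle deterministically from the config."""
    n_days = config.n_days
    obs_lo = (config.obs_start - config.study_start).days
    obs_hi = (config.obs_end - config.study_start).days
    d0 = config.study_start

    # --- practices (substream 0) ---------------------------------------
    prng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    n_anchor = max(1, round(config.anchor_fraction * config.n_practices))
    anchor = np.zeros(config.n_practices, dtype=bool)
    anchor[:n_anchor] = True
    non_anchor = np.flatnonzero(~anchor)
    n_low = min(len(non_anchor),
                int(round(config.low_rate_practice_fraction * config.n_practices)))
    low_rate = np.zeros(config.n_practices, dtype=bool)
    if n_low:
        low_rate[prng.choice(non_anchor, size=n_low, replace=False)] = True
    practice_ids = [f"P{i:03d}" for i in range(config.n_practices)]

    sigma_noise = (
        float(np.sqrt(np.log1p(config.noise_cv**2))) if config.noise_cv > 0 else 0.0
    )

    pat_rows, scr_rows, adm_rows, truth_rows = [], [], [], []
    list_sizes = np.zeros(config.n_practices, dtype=int)

    for i in range(config.n_patients):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1, i))
        )
        pid = f"PT{i:06d}"
        gender = "M" if rng.random() < config.male_fraction else "F"
        band = int(rng.choice(len(AGE_BANDS),
                              p=np.asarray(config.age_band_weights)
                              / sum(config.age_band_weights)))
        lo, hi = AGE_BANDS[band]
        age = int(rng.integers(lo, (hi if hi is not None else lo + 9) + 1))
        birth_year = config.obs_start.year - age
        prac = int(rng.integers(config.n_practices))
        list_sizes[prac] += 1

        partial = rng.random() < config.partial_registration_fraction
        if partial:
            if rng.random() < 0.5:
                reg_start = d0 + timedelta(days=int(rng.integers(30, 400)))
                reg_end = config.obs_end + timedelta(days=int(rng.integers(0, 3650)))
            else:
                reg_start = d0 - timedelta(days=int(rng.integers(0, 3650)))
                reg_end = config.obs_end - timedelta(days=int(rng.integers(30, 400)))
        else:
            reg_start = d0 - timedelta(days=int(rng.integers(1, 3650)))
            reg_end = config.obs_end + timedelta(days=int(rng.integers(1, 3650)))
        pat_rows.append((pid, gender, birth_year, practice_ids[prac],
                         reg_start.isoformat(), reg_end.isoformat()))

        median = (config.baseline_median_male if gender == "M"
                  else config.baseline_median_female)
        baseline = float(median * np.exp(rng.normal(0.0, config.baseline_sigma)))

        rate = config.band_test_rates[band]
        if low_rate[prac]:
            rate *= config.low_rate_multiplier
        n_tests = rng.poisson(rate * n_days / 365.0)
        test_days = list(rng.integers(0, n_days, size=n_tests))

        # episodes only in cohort-eligible patients so ground truth is clean
        eligible = not partial and not low_rate[prac]
        episodes = []
        if eligible and config.episode_rate > 0:
            n_ep = rng.poisson(config.episode_rate)
            for _ in range(n_ep):
                up = int(rng.integers(config.onset_days[0], config.onset_days[1] + 1))
                down = int(rng.integers(config.recovery_days[0],
                                        config.recovery_days[1] + 1))
                onset = int(rng.integers(obs_lo, obs_hi - (up + down + 10) + 1))
                b = int(rng.choice(len(config.peak_ratio_bins),
                                   p=np.asarray(config.peak_ratio_weights)
                                   / sum(config.peak_ratio_weights)))
                plo, phi = config.peak_ratio_bins[b]
                peak = float(rng.uniform(plo, phi))
                hospital = rng.random() < config.p_hospital_onset

                # a primary-care baseline draw months before onset
                test_days.append(onset - int(rng.integers(30, 180)))

                admitted = False
                admit_day = None
                if hospital:
                    admitted = True
                    admit_day = onset
                else:
                    # sparse community testing through the episode
                    test_days.append(onset + up)
                    if rng.random() < 0.7:
                        test_days.append(onset + up + int(rng.integers(1, down + 1)))
                    if rng.random() < config.p_community_admitted:
                        admitted = True
                        lags = np.asarray(config.admission_lag_weights)
                        admit_day = onset + int(rng.choice(8, p=lags / lags.sum()))
                if admitted:
                    los = int(rng.integers(config.los_days[0], config.los_days[1] + 1))
                    los = max(los, up + 1)
                    discharge = admit_day + los
                    adm_rows.append(
                        (pid, (d0 + timedelta(days=admit_day)).isoformat(),
                         (d0 + timedelta(days=min(discharge, obs_hi))).isoformat())
                    )
                    # inpatient biochemistry is near-daily
                    test_days.extend(range(admit_day, min(discharge, obs_hi) + 1))
                episodes.append((onset, peak, up, down, hospital, admitted))

        # occasional non-episode admissions keep HA/CA typing honest
        if eligible and rng.random() < 0.01:
            a = int(rng.integers(obs_lo, obs_hi - 12))
            los = int(rng.integers(config.los_days[0], config.los_days[1] + 1))
            adm_rows.append((pid, (d0 + timedelta(days=a)).isoformat(),
                             (d0 + timedelta(days=a + los)).isoformat()))
            test_days.extend(range(a, a + los + 1))

        if not test_days:
            continue
        test_days = [int(d) for d in test_days if 0 <= d <= obs_hi]
        test_days.sort()
        tests: list[tuple[int, int, float]] = []
        prev_day, seq = None, 0
        for day in test_days:
            seq = seq + 1 if day == prev_day else 0
            prev_day = day
            mult = 1.0
            for onset, peak, up, down, *_ in episodes:
                mult = max(mult, _episode_multiplier(day, onset, peak, up, down))
            noise = float(np.exp(rng.normal(0.0, sigma_noise))) if sigma_noise else 1.0
            value = max(6, int(round(baseline * mult * noise)))
            tests.append((day, seq, value))
            scr_rows.append(
                (pid, (d0 + timedelta(days=day)).isoformat(), seq, value)
            )

        for onset, peak, up, down, hospital, admitted in episodes:
            hit = _independent_first_alert(
                tests, max(onset, obs_lo), min(onset + up + down, obs_hi)
            )
            truth_rows.append(
                (
                    pid,
                    (d0 + timedelta(days=onset)).isoformat(),
                    round(peak, 4),
                    "hospital" if hospital else "community",
                    int(admitted),
                    int(hit is not None),
                    (d0 + timedelta(days=hit[0])).isoformat() if hit else "",
                )
            )

    patients = pd.DataFrame(
        pat_rows,
        columns=["patient_id", "gender", "birth_year", "practice_id",
                 "reg_start", "reg_end"],
    )
    practices = pd.DataFrame(
        {
            "practice_id": practice_ids,
            "list_size": list_sizes,
            "anchor": anchor.astype(int),
            # ground-truth flag for the deficient-tester simulation;
            # ignored by the pipeline
            "low_rate": low_rate.astype(int),
        }
    )
    scr = pd.DataFrame(
        scr_rows, columns=["patient_id", "test_date", "seq", "value_umol_l"]
    )
    admissions = pd.DataFrame(
        adm_rows, columns=["patient_id", "admit_date", "discharge_date"]
    )
    admissions = admissions.sort_values(
        ["patient_id", "admit_date"], kind="mergesort"
    ).reset_index(drop=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "onset_date", "peak_ratio", "setting",
                 "admitted", "expected_alertable", "expected_alert_date"],
    )
    return SimulatedDataset(patients, practices, scr, admissions, truth, config)
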