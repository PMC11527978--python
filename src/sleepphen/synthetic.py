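"""Seeded synthetic cohorts of nightly sleep records with planted phenotypes.

The generator emulates the statistical structure the downstream analysis
assumes: two cohorts (a clinical PLWD cohort and a general-population pool),
participant-level sleep phenotypes expressed as shifts of the nightly feature
means, between- and within-participant Gaussian variation, and whole-night
missingness.  Generation starts at the nightly-summary level; no raw pressure
signal or epoch-level staging is simulated.

Feature order is fixed package-wide (see :data:`FEATURES`): four sleep-stage
durations in seconds (NREM, REM, light, WASO) followed by the nightly
minimum/average/maximum heart rate (beats/min) and respiratory rate
(breaths/min).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical feature order used by every stage of the pipeline.
FEATURES: tuple[str, ...] = (
    "nrem_s", "rem_s", "light_s", "waso_s",
    "hr_min", "hr_avg", "hr_max",
    "rr_min", "rr_avg", "rr_max",
)
DURATION_FEATURES = FEATURES[:4]
HR_TRIPLET = ("hr_min", "hr_avg", "hr_max")
RR_TRIPLET = ("rr_min", "rr_avg", "rr_max")

COHORT_PLWD = "PLWD"
COHORT_GP = "GP"

# MMSE by primary diagnosis (percent of clinical cohort, score mean +/- sd).
# Scores are clipped to the 0-30 instrument range and rounded to integers.
MMSE_DIAGNOSIS_TABLE = (
    ("alzheimers", 0.55, 13.32, 5.92),
    ("vascular", 0.15, 21.83, 3.54),
    ("mixed", 0.075, 7.00, 7.55),
    ("mci", 0.10, 25.75, 5.97),
    ("frontotemporal", 0.025, 29.00, 0.00),
    ("other", 0.10, 27.50, 1.73),
)


class GeneratorError(ValueError):
    """Invalid generator configuration or inputs."""


def _as_vec(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (len(FEATURES),):
        raise GeneratorError(f"{name} must be a length-{len(FEATURES)} vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class PhenotypeSpec:
    """One planted sleep phenotype.

    ``nightly_mean`` is the population nightly feature mean for the phenotype;
    ``between_participant_sd`` spreads personal means around it and
    ``within_participant_sd`` adds independent night-to-night noise.
    ``prob_plwd``/``prob_female`` are descriptive probabilities used when
    deriving cohort weights, and for sex assignment.
    """

    phenotype_id: int
    nightly_mean: np.ndarray
    between_participant_sd: np.ndarray
    within_participant_sd: np.ndarray
    age_mean: float
    age_sd: float
    prob_plwd: float
    prob_female: float

    def __post_init__(self):
        object.__setattr__(self, "nightly_mean", _as_vec(self.nightly_mean, "nightly_mean"))
        object.__setattr__(self, "between_participant_sd",
                           _as_vec(self.between_participant_sd, "between_participant_sd"))
        object.__setattr__(self, "within_participant_sd",
                           _as_vec(self.within_participant_sd, "within_participant_sd"))
        if (self.between_participant_sd < 0).any() or (self.within_participant_sd < 0).any():
            raise GeneratorError("SDs must be non-negative")
        if self.age_sd < 0:
            raise GeneratorError("age_sd must be non-negative")
        for p, nm in ((self.prob_plwd, "prob_plwd"), (self.prob_female, "prob_female")):
            if not 0.0 <= p <= 1.0:
                raise GeneratorError(f"{nm} must lie in [0, 1]")
        m = dict(zip(FEATURES, self.nightly_mean))
        if not (m["hr_min"] <= m["hr_avg"] <= m["hr_max"]):
            raise GeneratorError("nightly_mean must satisfy hr_min <= hr_avg <= hr_max")
        if not (m["rr_min"] <= m["rr_avg"] <= m["rr_max"]):
            raise GeneratorError("nightly_mean must satisfy rr_min <= rr_avg <= rr_max")
        if any(m[f] < 0 for f in DURATION_FEATURES):
            raise GeneratorError("duration means must be non-negative")


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generation settings.

    Defaults reproduce the analysed study scale: 50 clinical participants, a
    250-participant general-population pool, 120 consecutive nights each, and
    a mean whole-night missingness rate of 10%.
    """

    n_plwd: int = 50
    n_gp_pool: int = 250
    n_nights: int = 120
    start_date: date = date(2022, 10, 31)
    phenotype_weights_per_cohort: dict = field(
        default_factory=lambda: dict(DEFAULT_COHORT_WEIGHTS))
    missing_night_prob_range: tuple[float, float] = (0.08, 0.12)
    frac_excludable: float = 0.0
    age_range: tuple[float, float] = (60.0, 98.0)
    ar1_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.missing_night_prob_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise GeneratorError("missing_night_prob_range must be within [0, 1] with lo <= hi")
        if not 0.0 <= self.frac_excludable <= 1.0:
            raise GeneratorError("frac_excludable must lie in [0, 1]")
        if self.n_plwd < 0 or self.n_gp_pool < 0 or self.n_nights < 0:
            raise GeneratorError("counts must be non-negative")
        if not -1.0 < self.ar1_rho < 1.0:
            raise GeneratorError("ar1_rho must lie in (-1, 1)")
        for cohort, w in self.phenotype_weights_per_cohort.items():
            w = np.asarray(w, dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise GeneratorError(f"phenotype weights for {cohort!r} must be a probability vector")


def default_phenotypes() -> list[PhenotypeSpec]:
    """Three default phenotypes with well-separated, norm-ordered signatures.

    Phenotype 1 (dementia-enriched, the most extreme profile): more light
    sleep and WASO, less REM/NREM, elevated HR and RR.  Phenotype 2: deeper
    sleep (more NREM/REM, less WASO/light) with raised minimum/average HR and
    minimum RR.  Phenotype 3: all durations and rates moderately low.
    Signature magnitudes are 2.2 / 1.7 / 1.1 between-participant SD per
    affected feature; with within-participant SD equal to the
    between-participant SD the pairwise Mahalanobis separations are
    8.7 / 9.5 / 6.6 within-SD units (well separated), and the graded
    magnitudes give the three phenotype centroids distinct distances from
    the origin of the scaled space so cross-fold label harmonisation is
    stable while the three-cluster structure still maximises the silhouette.
    """
    baseline = np.array([4200.0, 5400.0, 14400.0, 3600.0,   # durations (s)
                         52.0, 62.0, 78.0,                   # HR (bpm)
                         12.5, 15.5, 19.0])                  # RR (brpm)
    between = np.array([600.0, 600.0, 900.0, 900.0,
                        4.0, 4.0, 5.0,
                        1.0, 1.0, 1.2])
    within = between.copy()
    signatures = {
        1: 2.2 * np.array([-1, -1, +1, +1, +1, +1, +1, +1, +1, +1], float),
        2: 1.7 * np.array([+1, +1, -1, -1, +1, +1, 0, +1, 0, 0], float),
        3: 1.1 * np.array([-1, -1, -1, -1, -1, -1, -1, -1, -1, -1], float),
    }
    # Demographic defaults follow the per-cluster profile of the study
    # population (ages ~78/73.5/72, female fraction 0.41/0.19/0.16).
    demo = {1: (77.96, 6.6, 0.72, 0.41),
            2: (73.53, 6.6, 0.46, 0.19),
            3: (71.86, 6.6, 0.33, 0.16)}
    specs = []
    for pid, sig in signatures.items():
        age_mean, age_sd, p_plwd, p_female = demo[pid]
        specs.append(PhenotypeSpec(
            phenotype_id=pid,
            nightly_mean=baseline + sig * between,
            between_participant_sd=between,
            within_participant_sd=within,
            age_mean=age_mean, age_sd=age_sd,
            prob_plwd=p_plwd, prob_female=p_female,
        ))
    return specs


#: Default cohort-specific phenotype weights, derived from the study's
#: per-cluster cohort split (72/46/33 % clinical) and cluster shares
#: (28.5/39.1/28.5 %, renormalised).
DEFAULT_COHORT_WEIGHTS = {
    COHORT_PLWD: (0.4283, 0.3754, 0.1963),
    COHORT_GP: (0.1656, 0.4382, 0.3962),
}


def phenotype_separation(specs: Sequence[PhenotypeSpec]) -> float:
    """Minimum pairwise Mahalanobis distance between phenotype means,
    in within-participant-SD units (pooled diagonal)."""
    d = np.inf
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            sd = np.sqrt(0.5 * (specs[i].within_participant_sd ** 2
                                + specs[j].within_participant_sd ** 2))
            with np.errstate(divide="ignore"):
                z = (specs[i].nightly_mean - specs[j].nightly_mean) / sd
            d = min(d, float(np.linalg.norm(z[np.isfinite(z)])))
    return d


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    return {name: np.random.default_rng(k)
            for name, k in zip(("participants", "nights", "missingness"), kids)}


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_participants(config: GeneratorConfig,
                        specs: Sequence[PhenotypeSpec]) -> pd.DataFrame:
    """Draw the participant table: id, cohort, age, sex, MMSE, true phenotype.

    Phenotypes are drawn from cohort-specific weights; ages from each
    phenotype's normal law truncated to ``config.age_range``; sex from the
    phenotype's ``prob_female``.  MMSE is sampled for PLWD participants only,
    from the diagnosis-band mixture of :data:`MMSE_DIAGNOSIS_TABLE`.
    ``true_phenotype`` exists for evaluation; the pipeline never reads it.
    """
    if not specs:
        raise GeneratorError("specs must be non-empty")
    ids_by_pid = {s.phenotype_id: s for s in specs}
    rng = _stage_rngs(config.seed)["participants"]
    rows = []
    for cohort, n, prefix in ((COHORT_PLWD, config.n_plwd, "P"),
                              (COHORT_GP, config.n_gp_pool, "G")):
        if n == 0:
            continue
        try:
            weights = np.asarray(config.phenotype_weights_per_cohort[cohort], dtype=float)
        except KeyError:
            raise GeneratorError(f"no phenotype weights for cohort {cohort!r}") from None
        if len(weights) != len(specs):
            raise GeneratorError(
                f"{cohort}: {len(weights)} weights for {len(specs)} phenotypes")
        weights = weights / weights.sum()
        pids = rng.choice([s.phenotype_id for s in specs], size=n, p=weights)
        for i, pid in enumerate(pids):
            spec = ids_by_pid[pid]
            age = float(_truncnorm(rng, spec.age_mean, spec.age_sd,
                                   *config.age_range, size=1)[0])
            sex = "F" if rng.random() < spec.prob_female else "M"
            mmse = None
            if cohort == COHORT_PLWD:
                probs = np.array([r[1] for r in MMSE_DIAGNOSIS_TABLE])
                band = MMSE_DIAGNOSIS_TABLE[rng.choice(len(probs), p=probs / probs.sum())]
                mmse = int(np.clip(round(rng.normal(band[2], band[3])), 0, 30))
            rows.append({
                "participant_id": f"{prefix}{i + 1:04d}",
                "cohort": cohort,
                "age": age,
                "sex": sex,
                "mmse": mmse,
                "true_phenotype": int(pid),
            })
    df = pd.DataFrame(rows, columns=["participant_id", "cohort", "age", "sex",
                                     "mmse", "true_phenotype"])
    return df


def simulate_nights(participants: pd.DataFrame,
                    specs: Sequence[PhenotypeSpec],
                    config: GeneratorConfig) -> pd.DataFrame:
    """Simulate ``n_nights`` consecutive nightly records per participant.

    Personal mean = phenotype mean + between-participant noise; each night =
    personal mean + within-participant noise (optionally AR(1) across nights
    when ``config.ar1_rho`` is non-zero).  HR/RR triplets are repaired to
    preserve min <= avg <= max (min = avg - |delta1|, max = avg + |delta2|)
    and durations are truncated at zero.
    """
    ids_by_pid = {s.phenotype_id: s for s in specs}
    missing = set(participants["true_phenotype"]) - set(ids_by_pid)
    if missing:
        raise GeneratorError(f"no PhenotypeSpec for phenotype(s) {sorted(missing)}")
    rng = _stage_rngs(config.seed)["nights"]
    dates = [config.start_date + timedelta(days=d) for d in range(config.n_nights)]
    frames = []
    idx = {f: i for i, f in enumerate(FEATURES)}
    for row in participants.itertuples(index=False):
        spec = ids_by_pid[row.true_phenotype]
        personal = spec.nightly_mean + rng.normal(0.0, 1.0, len(FEATURES)) * spec.between_participant_sd
        eps = rng.normal(0.0, 1.0, (config.n_nights, len(FEATURES)))
        if config.ar1_rho:
            rho = config.ar1_rho
            for t in range(1, config.n_nights):
                eps[t] = rho * eps[t - 1] + np.sqrt(1 - rho ** 2) * eps[t]
        nights = personal + eps * spec.within_participant_sd
        # repair min/avg/max ordering around the generated average
        for trip in (HR_TRIPLET, RR_TRIPLET):
            lo, mid, hi = (idx[f] for f in trip)
            nights[:, lo] = nights[:, mid] - np.abs(nights[:, lo] - nights[:, mid])
            nights[:, hi] = nights[:, mid] + np.abs(nights[:, hi] - nights[:, mid])
        for f in DURATION_FEATURES:
            nights[:, idx[f]] = np.maximum(nights[:, idx[f]], 0.0)
        frame = pd.DataFrame(nights, columns=list(FEATURES))
        frame.insert(0, "participant_id", row.participant_id)
        frame.insert(1, "night_date", dates)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["participant_id", "night_date", *FEATURES])
    return pd.concat(frames, ignore_index=True)


def inject_missingness(records: pd.DataFrame,
                       participants: pd.DataFrame,
                       config: GeneratorConfig) -> pd.DataFrame:
    """Blank whole nights at random (MCAR), keeping the record count fixed.

    Each participant receives a missing-night probability drawn uniformly from
    ``missing_night_prob_range``.  A ``frac_excludable`` subset is forced over
    the downstream exclusion threshold: their first 12 nights are blanked
    outright (guaranteeing >= 12 missing nights in the first 30-night window)
    in addition to an elevated random rate.
    """
    if records[list(FEATURES)].isna().any().any():
        raise GeneratorError("records must be complete before missingness injection")
    rng = _stage_rngs(config.seed)["missingness"]
    lo, hi = config.missing_night_prob_range
    out = records.copy()
    pids = list(participants["participant_id"])
    n_excl = int(round(config.frac_excludable * len(pids)))
    forced = set(rng.choice(pids, size=n_excl, replace=False)) if n_excl else set()
    feat_cols = list(FEATURES)
    for pid, grp_idx in out.groupby("participant_id", sort=False).groups.items():
        rate = rng.uniform(lo, hi)
        mask = rng.random(len(grp_idx)) < rate
        if pid in forced:
            mask[:12] = True
        out.loc[np.asarray(grp_idx)[mask], feat_cols] = np.nan
    return out


def generate_dataset(config: GeneratorConfig,
                     specs: Sequence[PhenotypeSpec] | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full generation: participants and (missingness-injected) nights."""
    if specs is None:
        specs = default_phenotypes()
    participants = sample_participants(config, specs)
    nights = simulate_nights(participants, specs, config)
    nights = inject_missingness(nights, participants, config)
    return participants, nights


def write_dataset(out_dir, participants: pd.DataFrame, nights: pd.DataFrame,
                  config: GeneratorConfig) -> dict[str, str]:
    """Write participants.csv, nights.csv and a JSON sidecar; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p_path = out / "participants.csv"
    n_path = out / "nights.csv"
    participants.to_csv(p_path, index=False)
    nights.to_csv(n_path, index=False, date_format="%Y-%m-%d")
    cfg = dataclasses.asdict(config)
    cfg["start_date"] = config.start_date.isoformat()
    side = out / "generator_config.json"
    side.write_text(json.dumps(cfg, indent=2, sort_keys=True, default=list) + "\n")
    return {"participants": str(p_path), "nights": str(n_path), "config": str(side)}
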