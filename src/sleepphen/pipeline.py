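"""End-to-end orchestration: simulate -> preprocess -> sample-folds ->
cluster -> profile, with YAML configuration, derived per-stage seeds, CSV/JSON
stage interfaces and a deterministic run manifest.

The pipeline is a pure function of (input files, config, seed): a single
global seed deterministically derives one sub-seed per stage, and the
manifest records config, seeds and SHA-256 digests of every output file.
Wall-clock stage timings go to a separate ``timings.json`` so the manifest
itself is byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, stats
from .folds import FoldPlan, build_folds
from .preprocessing import PipelineConfig, preprocess
from .synthetic import (FEATURES, GeneratorConfig, default_phenotypes,
                        generate_dataset, write_dataset)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

STAGES = ("simulate", "preprocess", "folds", "cluster", "profile")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class ClusteringConfig:
    algorithms: tuple[str, ...] = clustering.ALGORITHMS
    k_min: int = 2
    k_max: int = 25
    n_runs: int = 15


@dataclass
class RunManifest:
    version: str
    seed: int
    stage_seeds: dict
    config: dict
    counts: dict
    selected_model: dict
    outputs: dict  # path (relative) -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str) + "\n"


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """One reproducible sub-seed (< 2**31) per pipeline stage."""
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(len(STAGES))
    return {name: int(k.generate_state(1)[0] % 2 ** 31)
            for name, k in zip(STAGES, kids)}


# -- configuration ----------------------------------------------------------

_SECTION_TYPES = {
    "simulate": GeneratorConfig,
    "preprocess": PipelineConfig,
    "folds": FoldPlan,
    "cluster": ClusteringConfig,
}


def _build_section(cls, raw: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(section, f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    for key in ("start_date", "analysis_start_date"):
        if isinstance(kwargs.get(key), str):
            kwargs[key] = date.fromisoformat(kwargs[key])
    for key in ("missing_night_prob_range", "winsor_limits", "age_range",
                "algorithms"):
        if isinstance(kwargs.get(key), list):
            kwargs[key] = tuple(kwargs[key])
    if isinstance(kwargs.get("age_bins"), list):
        kwargs["age_bins"] = np.asarray(kwargs["age_bins"], dtype=float)
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Parse a sectioned YAML config into typed stage configs.

    Sections: ``simulate``, ``preprocess``, ``folds``, ``cluster`` — each
    optional, defaults documented on the corresponding dataclass.  Unknown
    sections or keys are rejected.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for sec, kv in overrides.items():
            raw.setdefault(sec, {}).update(kv)
    unknown = set(raw) - set(_SECTION_TYPES)
    if unknown:
        raise PipelineError("config", f"unknown config sections: {sorted(unknown)}")
    return {sec: _build_section(cls, raw.get(sec, {}) or {}, sec)
            for sec, cls in _SECTION_TYPES.items()}


def validate_night_csv(path) -> list[str]:
    """Schema and plausibility checks on a nights.csv; returns issue strings."""
    issues: list[str] = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - report, not raise
        return [f"unreadable CSV: {exc}"]
    required = ["participant_id", "night_date", *FEATURES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    try:
        dates = pd.to_datetime(df["night_date"])
    except (ValueError, TypeError) as exc:
        return [f"unparseable night_date: {exc}"]
    dup = df.duplicated(["participant_id", "night_date"])
    if dup.any():
        issues.append(f"{int(dup.sum())} duplicate (participant, date) rows")
    present = df[list(FEATURES)].notna().any(axis=1)
    obs = df[present]
    for lo_c, mid_c, hi_c in (("hr_min", "hr_avg", "hr_max"),
                              ("rr_min", "rr_avg", "rr_max")):
        bad = obs[(obs[lo_c] > obs[mid_c]) | (obs[mid_c] > obs[hi_c])]
        for row in bad.itertuples(index=False):
            issues.append(
                f"{lo_c[:2]} ordering violated for participant "
                f"{row.participant_id} on {row.night_date}")
    for col, lo, hi, what in (("hr_avg", 20, 300, "heart rate"),
                              ("rr_avg", 4, 60, "respiratory rate")):
        odd = obs[(obs[col] < lo) | (obs[col] > hi)]
        if len(odd):
            issues.append(f"{len(odd)} nights with implausible {what}")
    neg = obs[(obs[list(FEATURES)[:4]] < 0).any(axis=1)]
    if len(neg):
        issues.append(f"{len(neg)} nights with negative durations")
    gaps = (df.assign(_d=dates).sort_values(["participant_id", "_d"])
            .groupby("participant_id")["_d"].agg(lambda s: (s.diff().dt.days > 1).sum()))
    for pid, g in gaps[gaps > 0].items():
        issues.append(f"participant {pid}: {int(g)} date gap(s)")
    return issues


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# -- end-to-end run ---------------------------------------------------------

def run_pipeline(config_path=None, seed: int = 0, out_dir="run",
                 overrides: dict | None = None) -> RunManifest:
    """Execute all stages, writing each stage's interface files under
    ``out_dir``; fails fast with the failing stage named and drops a
    ``<stage>.failed`` marker next to any partial outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfgs = load_config(config_path, overrides)
    stage_seeds = derive_stage_seeds(seed)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    outputs: list[Path] = []

    def _run(stage, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            (out / f"{stage}.failed").write_text(f"{type(exc).__name__}: {exc}\n")
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError(stage, str(exc)) from exc
        timings[stage] = time.perf_counter() - t0
        return result

    # simulate
    def _simulate():
        gen_cfg = dataclasses.replace(cfgs["simulate"], seed=stage_seeds["simulate"])
        if gen_cfg.n_nights < cfgs["preprocess"].span:
            raise ValueError(
                f"n_nights={gen_cfg.n_nights} < windows span {cfgs['preprocess'].span}")
        participants, nights = generate_dataset(gen_cfg, default_phenotypes())
        paths = write_dataset(out, participants, nights, gen_cfg)
        outputs.extend(Path(p) for p in paths.values())
        return participants, nights

    participants, nights = _run("simulate", _simulate)
    counts["n_participants"] = len(participants)

    # preprocess
    def _preprocess():
        samples, exclusions = preprocess(nights, participants, cfgs["preprocess"])
        samples.to_csv(out / "window_samples.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        outputs.extend([out / "window_samples.csv", out / "exclusions.csv"])
        return samples, exclusions

    samples, exclusions = _run("preprocess", _preprocess)
    plwd_retained = samples.loc[samples["cohort"] == "PLWD", "participant_id"].nunique()
    counts["n_plwd_retained"] = int(plwd_retained)
    counts["n_plwd_samples"] = int((samples["cohort"] == "PLWD").sum())
    counts["n_excluded"] = int(exclusions["participant_id"].nunique())

    # folds
    def _folds():
        plan = dataclasses.replace(cfgs["folds"], seed=stage_seeds["folds"])
        fold_sets = build_folds(samples, participants, plan, cfgs["preprocess"])
        ids = {f"fold_{d.fold_index}": sorted(
                   d.metadata.loc[d.metadata["cohort"] == "GP",
                                  "participant_id"].unique())
               for d in fold_sets}
        (out / "folds.json").write_text(json.dumps(
            {"seed": plan.seed, "per_fold": plan.per_fold, "gp_ids": ids},
            indent=2, sort_keys=True) + "\n")
        outputs.append(out / "folds.json")
        for d in fold_sets:
            m = pd.concat([d.metadata,
                           pd.DataFrame(d.matrix, columns=list(FEATURES))], axis=1)
            p = out / f"fold_{d.fold_index}_matrix.csv"
            m.to_csv(p, index=False)
            outputs.append(p)
        return fold_sets

    fold_sets = _run("folds", _folds)
    counts["n_folds"] = len(fold_sets)
    counts["rows_per_fold"] = int(fold_sets[0].matrix.shape[0])
    counts["participants_per_fold"] = int(
        fold_sets[0].metadata["participant_id"].nunique())

    # cluster: sweep every fold, average point metrics, select once, refit
    def _cluster():
        ccfg = cfgs["cluster"]
        tables = []
        for d in fold_sets:
            tbl = clustering.sweep_models(
                d.matrix, algorithms=ccfg.algorithms,
                k_range=(ccfg.k_min, ccfg.k_max), n_runs=ccfg.n_runs,
                seed=stage_seeds["cluster"] + d.fold_index)
            tbl.insert(0, "fold", d.fold_index)
            tables.append(tbl)
        sel_table = pd.concat(tables, ignore_index=True)
        sel_table.to_csv(out / "selection_table.csv", index=False)
        outputs.append(out / "selection_table.csv")
        # rank on the mean-over-bootstrap-runs scores, averaged across folds
        mean_table = (sel_table.groupby(["algorithm", "k"], sort=False)
                      [["sc_boot_mean", "ch_boot_mean", "db_boot_mean"]]
                      .mean().reset_index()
                      .rename(columns={"sc_boot_mean": "sc",
                                       "ch_boot_mean": "ch",
                                       "db_boot_mean": "db"}))
        algorithm, k, audit = clustering.select_model(mean_table)
        results = [clustering.fit(algorithm, d.matrix, k,
                                  seed=stage_seeds["cluster"] + d.fold_index)
                   for d in fold_sets]
        maps = clustering.harmonize_labels([r.centroids for r in results])
        frames = []
        for d, r, mp in zip(fold_sets, results, maps):
            dfc = d.metadata.copy()
            dfc["raw_label"] = r.labels
            dfc["cluster"] = clustering.apply_harmonization(r.labels, mp)
            dfc.insert(0, "fold", d.fold_index)
            p = out / f"clusters_fold_{d.fold_index}.csv"
            dfc.to_csv(p, index=False)
            outputs.append(p)
            frames.append(dfc)
        (out / "model.json").write_text(json.dumps(
            {"algorithm": algorithm, "k": k,
             "audit": audit.to_dict(orient="records")},
            indent=2, sort_keys=True) + "\n")
        outputs.append(out / "model.json")
        return algorithm, k, pd.concat(frames, ignore_index=True), fold_sets

    algorithm, k, assignments, fold_sets = _run("cluster", _cluster)

    # profile
    def _profile():
        profiles = stats.profile_clusters(assignments, participants,
                                          n_folds=len(fold_sets))
        profiles.to_csv(out / "profiles.csv", index=False)
        outputs.append(out / "profiles.csv")
        scaled = assignments.merge(
            pd.concat([d.metadata.assign(
                fold=d.fold_index,
                **{f: d.matrix[:, i] for i, f in enumerate(FEATURES)})
                for d in fold_sets], ignore_index=True)
            [["fold", "participant_id", "window_index", *FEATURES]],
            on=["fold", "participant_id", "window_index"])
        feat_rows = []
        for feat in FEATURES:
            res = stats.one_way_anova(scaled[feat].to_numpy(float),
                                      scaled["cluster"].to_numpy())
            row = {"feature": feat, "anova_F": res.statistic,
                   "df1": res.df[0], "df2": res.df[1], "anova_p": res.pvalue}
            if res.statistic > 0 and np.isfinite(res.statistic):
                tk = stats.tukey_hsd(scaled[feat].to_numpy(float),
                                     scaled["cluster"].to_numpy())
                for pw in tk.pairwise.itertuples(index=False):
                    row[f"p_{pw.group_a}v{pw.group_b}"] = pw.p_adj
            feat_rows.append(row)
        pd.DataFrame(feat_rows).to_csv(out / "stats_features.csv", index=False)
        outputs.append(out / "stats_features.csv")
        demo_rows = []
        res = stats.one_way_anova(assignments["age"].to_numpy(float),
                                  assignments["cluster"].to_numpy())
        demo_rows.append({"variable": "age", "anova_F": res.statistic,
                          "df1": res.df[0], "df2": res.df[1],
                          "anova_p": res.pvalue})
        pd.DataFrame(demo_rows).to_csv(out / "stats_demographics.csv", index=False)
        outputs.append(out / "stats_demographics.csv")
        return profiles

    _run("profile", _profile)

    cfg_snapshot = {sec: {f.name: getattr(c, f.name)
                          for f in dataclasses.fields(c)}
                    for sec, c in cfgs.items()}
    for sec in cfg_snapshot.values():
        for key, v in sec.items():
            if isinstance(v, np.ndarray):
                sec[key] = v.tolist()
    manifest = RunManifest(
        version=__version__, seed=seed, stage_seeds=stage_seeds,
        config=cfg_snapshot, counts=counts,
        selected_model={"algorithm": algorithm, "k": k},
        outputs={p.name: _sha256(p) for p in sorted(set(outputs))})
    (out / "manifest.json").write_text(manifest.to_json())
    (out / "timings.json").write_text(
        json.dumps(timings, indent=2, sort_keys=True) + "\n")
    return manifest
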