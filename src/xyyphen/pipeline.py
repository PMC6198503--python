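"""One-config orchestration: simulate -> describe -> psychometrics ->
profile -> network, with a manifest of checksums for reproducibility.

Every tabular output is UTF-8 CSV/TSV with a leading schema-version comment
line; the manifest records the config hash, package version, per-stage
outputs with SHA-256 checksums, wall-clock, and any warnings, so two runs
with the same config and seed can be verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    ModuleSpec,
    ScreenerSpec,
    VariableDef,
    default_modules,
    default_screeners,
    default_variables,
    generate_cohort,
    generate_reference_norms,
)
from .descriptives import (
    ClassificationRule,
    classify_delays_and_sld,
    gated_group_contrast,
    one_sample_t,
    summarize_variable,
)
from .network import (
    bootstrap_cocluster,
    export_network,
    filter_variables,
    louvain_consensus,
    pairwise_correlations,
    versatility_curve,
)
from .profiles import (
    ReferenceNorms,
    diagnostic_subgroups,
    restrict_by_age,
    subgroup_profile_contrasts,
    z_normalize,
)
from .psychometrics import InstrumentSpec, StratumSpec, stratified_performance

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger(__name__)

SCHEMA_COMMENT = "# xyyphen-schema=1"

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "xyyphen_run",
    "stages": ["simulate", "describe", "psychometrics", "profile", "network"],
    "simulate": {"n_participants": 64, "r_in": 0.5, "r_out": 0.15},
    "describe": {"alpha": 0.05, "variance_rule": "folded_f"},
    "psychometrics": {"auc_mode": "score", "cbcl_cutoff": 64.0},
    "profile": {"age_max": 18.0},
    "network": {
        "n_boot": 1000,
        "louvain_runs": 1000,
        "gamma": 1.2,  # or "auto" for versatility-curve selection
        "tau": -2.0,
        "k_max": 8,
        "n_ref": 50,
        "edge_threshold": 0.05,
    },
}

_KNOWN_KEYS = {
    None: {"seed", "out_dir", "stages", "table", "dictionary",
           "simulate", "describe", "psychometrics", "profile", "network"},
    "simulate": {"n_participants", "r_in", "r_out", "group_fraction", "asd_prevalence",
                 "missing_by_group", "instrument_noise"},
    "describe": {"alpha", "variance_rule"},
    "psychometrics": {"auc_mode", "cbcl_cutoff", "instruments"},
    "profile": {"age_max", "harmonize_direction"},
    "network": {"n_boot", "louvain_runs", "gamma", "tau", "k_max", "n_ref",
                "edge_threshold", "gamma_grid", "use_abs"},
}


class RunConfig:
    """Validated pipeline configuration (single YAML/dict, per-stage blocks).

    Unknown keys are rejected; a seed is mandatory when simulating so no
    run is silently nondeterministic.
    """

    def __init__(self, raw: dict):
        unknown = set(raw) - _KNOWN_KEYS[None]
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for block, allowed in _KNOWN_KEYS.items():
            if block and block in raw and isinstance(raw[block], dict):
                bad = set(raw[block]) - allowed
                if bad:
                    raise ValueError(f"unknown keys in {block!r} block: {sorted(bad)}")
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        for k, v in raw.items():
            if isinstance(v, dict) and k in merged:
                merged[k].update(v)
            else:
                merged[k] = v
        self.raw = merged
        self.stages = list(merged["stages"])
        if "simulate" in self.stages and "seed" not in raw:
            raise ValueError("synthetic mode requires an explicit seed")
        if merged.get("seed") is None:
            raise ValueError("seed must not be null")
        bad_stages = set(self.stages) - {"simulate", "describe", "psychometrics", "profile", "network"}
        if bad_stages:
            raise ValueError(f"unknown stages: {sorted(bad_stages)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        return cls(raw)

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, sep: str = ",") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        df.to_csv(fh, index=False, float_format="%.10g", sep=sep)


def read_csv(path, **kw) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the schema comment line."""
    return pd.read_csv(path, comment="#", **kw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(cfg: RunConfig):
    table_path, dict_path = cfg.raw.get("table"), cfg.raw.get("dictionary")
    if not table_path or not dict_path:
        raise ValueError("cohort mode needs 'table' and 'dictionary' paths")
    data = read_csv(table_path)
    dictionary = read_csv(dict_path)
    required = {"variable", "scale_type", "family", "higher_worse"}
    missing = required - set(dictionary.columns)
    if missing:
        raise ValueError(f"dictionary lacks columns: {sorted(missing)}")
    absent = set(dictionary["variable"]) - set(data.columns)
    if absent:
        raise ValueError(f"dictionary names columns absent from the table: {sorted(absent)}")
    return data, dictionary


def _stage_simulate(cfg: RunConfig, out: Path):
    s = cfg.raw["simulate"]
    cohort_cfg = CohortConfig(
        n_participants=int(s.get("n_participants", 64)),
        variables=default_variables(),
        modules=default_modules(float(s.get("r_in", 0.5)), float(s.get("r_out", 0.15))),
        group_fraction=float(s.get("group_fraction", 25 / 64)),
        asd_prevalence=float(s.get("asd_prevalence", 9 / 63)),
        screeners=default_screeners(),
        missing_by_group=float(s.get("missing_by_group", 1.0)),
        instrument_noise=dict(s.get("instrument_noise", {})),
        seed=cfg.seed,
    )
    table, truth = generate_cohort(cohort_cfg)
    _write_csv(table.data, out / "cohort.csv")
    _write_csv(table.dictionary, out / "dictionary.csv")
    norms = generate_reference_norms(cohort_cfg)
    _write_csv(norms, out / "reference_norms.csv")
    (out / "ground_truth.json").write_text(truth.to_json())
    from .cohort import config_to_json

    (out / "cohort_config.json").write_text(config_to_json(cohort_cfg))
    return table.data, table.dictionary, norms


def _stage_describe(cfg: RunConfig, out: Path, data, dictionary):
    alpha = float(cfg.raw["describe"]["alpha"])
    vrule = cfg.raw["describe"]["variance_rule"]
    rows = []
    groups = data["group"]
    for _, meta in dictionary.iterrows():
        var = meta["variable"]
        x = data[var]
        try:
            summ = summarize_variable(x, alpha=alpha)
        except Exception as err:  # degenerate column: report and move on
            rows.append({"variable": var, "error": str(err)})
            continue
        row = {
            "variable": var,
            "n": summ.n,
            "mean": summ.mean,
            "sd": summ.sd,
            "median": summ.median,
            "q1": summ.q1,
            "q3": summ.q3,
            "shapiro_p": summ.shapiro_p,
            "is_normal": summ.is_normal,
            "summary": summ.describe(),
        }
        if pd.notna(meta.get("pop_norm_mean", np.nan)):
            r1 = one_sample_t(summ.mean, summ.sd, summ.n, float(meta["pop_norm_mean"]))
            row.update(norm_t=r1.statistic, norm_df=r1.df, norm_p=r1.p)
        a = x[groups == "prenatal"]
        b = x[groups == "postnatal"]
        try:
            res, _ = gated_group_contrast(a.dropna(), b.dropna(), alpha=alpha, variance_rule=vrule)
            row.update(group_method=res.method, group_statistic=res.statistic,
                       group_df=res.df, group_p=res.p)
            log.info("gate[%s]: %s (shapiro_p=%.4g)", var, res.method, summ.shapiro_p)
        except Exception as err:
            row.update(group_method="skipped", group_statistic=np.nan, group_p=np.nan)
            log.warning("group contrast skipped for %s: %s", var, err)
        rows.append(row)
    table1 = pd.DataFrame(rows)
    _write_csv(table1, out / "table1.csv")
    flags, rates = classify_delays_and_sld(data, ClassificationRule())
    _write_csv(flags.assign(participant_id=data["participant_id"]), out / "delay_sld_flags.csv")
    (out / "delay_sld_rates.json").write_text(json.dumps(rates, indent=2, sort_keys=True))
    return table1


def _default_instruments(data) -> list[InstrumentSpec]:
    specs = []
    pairs = [
        ("ADI-R", "adi_r_positive", None),
        ("ADOS-2", "ados2_positive", "ados_css"),
        ("SRS-2", "srs2_positive", "srs2_total"),
        ("SCQ", "scq_positive", "scq_total"),
    ]
    for name, call, score in pairs:
        if call in data.columns:
            specs.append(InstrumentSpec(name, call_col=call,
                                        score_col=score if score in data.columns else None))
    return specs


def _stage_psychometrics(cfg: RunConfig, out: Path, data):
    p = cfg.raw["psychometrics"]
    insts_cfg = p.get("instruments")
    if insts_cfg:
        instruments = [InstrumentSpec(**i) for i in insts_cfg]
    else:
        instruments = _default_instruments(data)
    if not instruments:
        raise ValueError("no instruments available for psychometrics stage")
    cutoff = float(p["cbcl_cutoff"])
    strata = [StratumSpec(c, cutoff) for c in ("cbcl_externalizing", "cbcl_internalizing")
              if c in data.columns]
    table2 = stratified_performance(
        data, instruments, dx_col="dsm5_asd", strata=strata,
        auc_mode=p["auc_mode"], seed=cfg.seed,
    )
    _write_csv(table2, out / "table2.csv")
    return table2


def _stage_profile(cfg: RunConfig, out: Path, data, dictionary, norms_df):
    age_max = float(cfg.raw["profile"]["age_max"])
    harmonize = bool(cfg.raw["profile"].get("harmonize_direction", False))
    norms = ReferenceNorms(norms_df, population="asd-reference")
    young = restrict_by_age(data, age_max)
    direction = dict(zip(dictionary["variable"], dictionary["higher_worse"].astype(bool)))
    z = z_normalize(young, norms, direction=direction, harmonize_direction=harmonize)
    zp = z.copy()
    zp.insert(0, "participant_id", young["participant_id"].to_numpy())
    _write_csv(zp, out / "zprofile.csv")
    subgroups = diagnostic_subgroups(young)
    contrasts = subgroup_profile_contrasts(z, subgroups)
    _write_csv(contrasts, out / "subgroup_contrasts.csv")
    return z, contrasts


def _stage_network(cfg: RunConfig, out: Path, data, dictionary):
    ncfg = cfg.raw["network"]
    variables = [v for v in dictionary["variable"] if v in data.columns]
    X = data[variables]
    corr = pairwise_correlations(X)
    report = filter_variables(corr, tau=float(ncfg["tau"]))
    _write_csv(report.table, out / "filter_report.csv")
    log.info("filter removed: %s", report.removed)
    kept = X[report.kept]
    pset, consensus = bootstrap_cocluster(
        kept, n_boot=int(ncfg["n_boot"]), seed=cfg.seed,
        k_max=int(ncfg["k_max"]), n_ref=int(ncfg["n_ref"]),
        use_abs=bool(ncfg.get("use_abs", False)),
    )
    cdf = consensus.c.reset_index(names="variable")
    _write_csv(cdf, out / "consensus_matrix.tsv", sep="\t")
    gamma_cfg = ncfg["gamma"]
    L = int(ncfg["louvain_runs"])
    if gamma_cfg == "auto":
        grid = ncfg.get("gamma_grid")
        grid = np.asarray(grid, dtype=float) if grid else None
        curve, gamma = versatility_curve(consensus, grid, n_runs=L, seed=cfg.seed)
        _write_csv(curve, out / "versatility_curve.csv")
        log.info("gamma selected from versatility curve: %s", gamma)
    else:
        gamma = float(gamma_cfg)
    partition = louvain_consensus(consensus, gamma=gamma, n_runs=L, seed=cfg.seed,
                                  corr=pairwise_correlations(kept))
    part_df = pd.DataFrame(
        {
            "variable": partition.labels.index,
            "module": partition.labels.to_numpy(),
            "versatility": partition.versatility.to_numpy(),
            "strength": partition.strength.to_numpy(),
        }
    )
    _write_csv(part_df, out / "modules.csv")
    export_network(consensus, partition, out, edge_threshold=float(ncfg["edge_threshold"]),
                   layout_seed=cfg.seed)
    return partition


def run_pipeline(config: RunConfig | dict, out_dir=None) -> dict:
    """Execute the enabled stages in order; returns the manifest (also
    written to ``manifest.json``).  Any stage failure halts the run with a
    stage-attributed error before later stages write anything."""
    if isinstance(config, dict):
        config = RunConfig(config)
    out = Path(out_dir if out_dir is not None else config.raw["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.raw,
        "config_hash": config.hash(),
        "stages": {},
        "warnings": [],
    }
    data = dictionary = norms_df = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage in ["simulate", "describe", "psychometrics", "profile", "network"]:
            if stage not in config.stages:
                manifest["stages"][stage] = {"skipped": True}
                continue
            t0 = time.perf_counter()
            before = set(out.iterdir())
            try:
                if stage == "simulate":
                    data, dictionary, norms_df = _stage_simulate(config, out)
                else:
                    if data is None:
                        data, dictionary = _load_cohort(config)
                        norms_path = config.raw.get("table", "")
                        norms_file = Path(str(norms_path)).with_name("reference_norms.csv")
                        norms_df = read_csv(norms_file) if norms_file.exists() else None
                    if stage == "describe":
                        _stage_describe(config, out, data, dictionary)
                    elif stage == "psychometrics":
                        _stage_psychometrics(config, out, data)
                    elif stage == "profile":
                        if norms_df is None:
                            raise ValueError("profile stage needs reference norms")
                        _stage_profile(config, out, data, dictionary, norms_df)
                    elif stage == "network":
                        _stage_network(config, out, data, dictionary)
            except Exception as err:
                raise RuntimeError(f"stage {stage!r} failed: {err}") from err
            new_files = sorted(str(p.name) for p in set(out.iterdir()) - before)
            manifest["stages"][stage] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": {
                    name: _sha256(out / name) for name in new_files
                },
            }
        manifest["warnings"] = sorted({str(w.message) for w in caught})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
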