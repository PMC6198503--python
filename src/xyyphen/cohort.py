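"""Seeded synthetic XYY-like phenotype cohorts.

Generates participant-by-variable tables that emulate the marginal
distributions, missingness, diagnostic-timing subgroup effects, and modular
correlation structure of a densely phenotyped sex-chromosome-aneuploidy
cohort (n = 64, 25 prenatal/birth vs 39 later diagnoses, DSM-5 ASD
prevalence 9/63).  Correlated variables are drawn from a Gaussian copula and
pushed through per-variable marginals: normal for standard scores (IQ-like
mean 100 / SD 15, T-like mean 50 / SD 10), log-normal for developmental
milestones (ages in months, right-skewed) and skewed symptom totals.

Every draw is reproducible from one master seed; sub-streams are derived
with ``numpy.random.SeedSequence`` so that independent pieces (latent
scores, ages, missingness, screener calls) do not reshuffle each other.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableDef",
    "ModuleSpec",
    "ScreenerSpec",
    "CohortConfig",
    "GroundTruth",
    "PhenotypeTable",
    "default_variables",
    "default_modules",
    "default_screeners",
    "build_target_correlation",
    "nearest_psd",
    "generate_cohort",
    "generate_reference_norms",
]


@dataclass(frozen=True)
class VariableDef:
    """One phenotype variable and its marginal model.

    ``kind`` is ``"standard"`` (normal score with cohort marginal ``mean``/``sd``
    and instrument population norms ``pop_mean``/``pop_sd``) or
    ``"lognormal"`` (positive right-skewed, ``log_location``/``log_scale``
    on the natural-log scale, months or raw totals).  ``admissible`` is the
    instrument floor/ceiling; generated values outside it are clipped and
    the clip recorded.  ``higher_worse`` flags symptom-direction variables
    (T-scored questionnaires, milestone ages).
    """

    name: str
    kind: str  # "standard" | "lognormal"
    mean: float = 100.0        # cohort marginal mean (standard kind)
    sd: float = 15.0           # cohort marginal SD (standard kind)
    pop_mean: float = float("nan")  # instrument population norm (e.g. 100 or 50)
    pop_sd: float = float("nan")
    log_location: float = 0.0
    log_scale: float = 0.5
    family: str = "misc"
    higher_worse: bool = False
    admissible: tuple[float, float] | None = None
    integer: bool = False
    missing_rate: float = 0.0
    # Standardized postnatal-group deficit: how many marginal SDs worse the
    # later-diagnosis group scores than the prenatal/birth group.
    group_effect: float = 0.0


@dataclass(frozen=True)
class ModuleSpec:
    name: str
    members: tuple[str, ...]
    r_in: float = 0.5
    r_out: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_in < 1.0):
            raise ValueError(f"module {self.name!r}: r_in must be in [0,1), got {self.r_in}")
        if not (0.0 <= self.r_out < 1.0):
            raise ValueError(f"module {self.name!r}: r_out must be in [0,1), got {self.r_out}")
        if self.r_out >= self.r_in:
            raise ValueError(
                f"module {self.name!r}: r_out ({self.r_out}) must be < r_in ({self.r_in})"
            )


@dataclass(frozen=True)
class ScreenerSpec:
    """A binary ASD screening/diagnostic call with a planted operating point.

    ``spec_drop_high_cbcl`` lowers specificity among participants whose CBCL
    internalizing or externalizing T is >= 64, emulating the vulnerability of
    questionnaire measures to co-occurring behavior problems.
    """

    name: str
    sensitivity: float = 0.9
    specificity: float = 0.9
    spec_drop_high_cbcl: float = 0.0

    def __post_init__(self) -> None:
        for v, lbl in [(self.sensitivity, "sensitivity"), (self.specificity, "specificity")]:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"screener {self.name!r}: {lbl} must be in [0,1]")
        if not (0.0 <= self.specificity - self.spec_drop_high_cbcl <= 1.0):
            raise ValueError(f"screener {self.name!r}: spec_drop_high_cbcl leaves specificity outside [0,1]")


def default_variables() -> list[VariableDef]:
    """Variable battery emulating the study's Table-1 marginals."""
    def ms(name, median, q1, q3, effect=0.0, rate=0.05):
        # log-normal located at the observed median; scale from the IQR.
        sigma = (np.log(q3) - np.log(q1)) / (2 * 0.6745)
        return VariableDef(
            name, "lognormal", log_location=float(np.log(median)), log_scale=float(sigma),
            family="milestone", higher_worse=True, missing_rate=rate, group_effect=effect,
        )

    v = [
        # Cognition (Wechsler indices; full-sample mean/SD as printed).
        VariableDef("visual_spatial", "standard", 97.0, 13.0, family="wechsler", admissible=(40.0, 160.0), group_effect=0.50, missing_rate=0.05),
        VariableDef("fluid_reasoning", "standard", 93.0, 14.46, family="wechsler", admissible=(40.0, 160.0), group_effect=0.44, missing_rate=0.26),
        VariableDef("working_memory", "standard", 88.92, 14.53, family="wechsler", admissible=(40.0, 160.0), group_effect=0.24, missing_rate=0.06),
        VariableDef("processing_speed", "standard", 83.67, 14.17, family="wechsler", admissible=(40.0, 160.0), group_effect=0.72, missing_rate=0.06),
        VariableDef("nviq", "standard", 91.81, 15.56, family="wechsler", admissible=(40.0, 160.0), group_effect=0.42),
        VariableDef("viq", "standard", 85.89, 14.18, family="wechsler", admissible=(40.0, 160.0), group_effect=0.66, missing_rate=0.02),
        VariableDef("fsiq", "standard", 86.24, 13.49, family="wechsler", admissible=(40.0, 160.0), group_effect=0.51, missing_rate=0.02),
        # Academic achievement (WJ-IV; Table 1 medians mapped to normal marginals).
        VariableDef("wj_math", "standard", 87.0, 15.0, family="woodcock_johnson", admissible=(40.0, 160.0), group_effect=0.40, missing_rate=0.17),
        VariableDef("wj_writing", "standard", 89.0, 15.0, family="woodcock_johnson", admissible=(40.0, 160.0), group_effect=0.25, missing_rate=0.22),
        VariableDef("wj_reading", "standard", 82.0, 15.0, family="woodcock_johnson", admissible=(40.0, 160.0), group_effect=0.30, missing_rate=0.19),
        # Adaptive behavior (Vineland).
        VariableDef("vabs_communication", "standard", 77.69, 15.04, family="vineland", admissible=(20.0, 160.0), group_effect=0.45),
        VariableDef("vabs_daily_living", "standard", 79.11, 14.55, family="vineland", admissible=(20.0, 160.0), group_effect=0.34),
        VariableDef("vabs_socialization", "standard", 77.20, 14.01, family="vineland", admissible=(20.0, 160.0), group_effect=0.52),
        VariableDef("vabs_abc", "standard", 76.22, 12.95, family="vineland", admissible=(20.0, 160.0), group_effect=0.44),
        # Broad psychopathology (CBCL/ABCL T scores).
        VariableDef("cbcl_internalizing", "standard", 61.40, 8.29, family="cbcl", higher_worse=True, admissible=(30.0, 100.0), group_effect=0.67, missing_rate=0.03),
        VariableDef("cbcl_externalizing", "standard", 59.39, 12.31, family="cbcl", higher_worse=True, admissible=(30.0, 100.0), group_effect=0.36, missing_rate=0.03),
        # Developmental milestones (months; median [IQR] as printed).
        ms("age_first_words", 24, 18, 36, effect=0.35),
        ms("age_phrases", 36, 26, 42, effect=0.87),
        ms("age_walked", 14, 13, 18, effect=0.0),
        ms("daytime_continence", 37.5, 31, 45, effect=0.0, rate=0.08),
        ms("nighttime_continence", 42, 36, 72, effect=0.0, rate=0.10),
        ms("bowel_continence", 37.5, 31, 45, effect=0.10, rate=0.08),
        # ASD-related features.
        VariableDef("srs2_total", "standard", 66.21, 7.86, family="srs2", higher_worse=True, admissible=(30.0, 100.0), group_effect=0.86, missing_rate=0.03),
        VariableDef("srs2_awareness", "standard", 62.0, 8.0, family="srs2", higher_worse=True, admissible=(30.0, 100.0), group_effect=0.40, missing_rate=0.03),
        VariableDef("ados_sa_css", "lognormal", log_location=float(np.log(2.5)), log_scale=0.55, family="ados2", higher_worse=True, admissible=(1.0, 10.0), integer=True, group_effect=0.15),
        VariableDef("ados_rrb_css", "lognormal", log_location=float(np.log(2.5)), log_scale=0.75, family="ados2", higher_worse=True, admissible=(1.0, 10.0), integer=True, group_effect=0.55),
        VariableDef("ados_css", "lognormal", log_location=float(np.log(2.0)), log_scale=0.55, family="ados2", higher_worse=True, admissible=(1.0, 10.0), integer=True, group_effect=0.25),
        VariableDef("rbs_r_total", "lognormal", log_location=float(np.log(13.0)), log_scale=0.95, family="rbsr", higher_worse=True, admissible=(0.0, 135.0), integer=True, group_effect=0.70, missing_rate=0.03),
        VariableDef("scq_total", "lognormal", log_location=float(np.log(9.0)), log_scale=0.65, family="scq", higher_worse=True, admissible=(0.0, 39.0), integer=True, group_effect=0.40, missing_rate=0.03),
    ]
    # Instrument population norms by family: standard-score families are
    # 100/15, T-scored questionnaires 50/10; raw totals/CSS have no norm.
    pop = {
        "wechsler": (100.0, 15.0),
        "woodcock_johnson": (100.0, 15.0),
        "vineland": (100.0, 15.0),
        "cbcl": (50.0, 10.0),
        "srs2": (50.0, 10.0),
    }
    return [
        dataclasses.replace(x, pop_mean=pop[x.family][0], pop_sd=pop[x.family][1])
        if x.family in pop
        else x
        for x in v
    ]


def default_modules(r_in: float = 0.5, r_out: float = 0.15) -> list[ModuleSpec]:
    """Three planted phenotype modules: cognition/achievement, adaptive
    behavior + broad psychopathology + milestones, and ASD features."""
    return [
        ModuleSpec(
            "cognition_achievement",
            ("visual_spatial", "fluid_reasoning", "working_memory", "processing_speed",
             "nviq", "viq", "fsiq", "wj_math", "wj_writing", "wj_reading"),
            r_in, r_out,
        ),
        ModuleSpec(
            "adaptive_psychopathology",
            ("vabs_communication", "vabs_daily_living", "vabs_socialization", "vabs_abc",
             "cbcl_internalizing", "cbcl_externalizing", "age_first_words", "age_phrases",
             "age_walked", "daytime_continence", "nighttime_continence", "bowel_continence"),
            r_in, r_out,
        ),
        ModuleSpec(
            "asd_features",
            ("srs2_total", "srs2_awareness", "ados_sa_css", "ados_rrb_css", "ados_css",
             "rbs_r_total", "scq_total"),
            r_in, r_out,
        ),
    ]


def default_screeners() -> list[ScreenerSpec]:
    """Planted operating points emulating Table 2's full-sample rows.

    Interview/observation instruments are robust; questionnaire screeners
    lose specificity among participants with clinically significant CBCL
    scores (T >= 64).
    """
    return [
        ScreenerSpec("adi_r_positive", sensitivity=1.00, specificity=0.87, spec_drop_high_cbcl=0.05),
        ScreenerSpec("ados2_positive", sensitivity=0.89, specificity=0.98, spec_drop_high_cbcl=0.07),
        ScreenerSpec("srs2_positive", sensitivity=1.00, specificity=0.59, spec_drop_high_cbcl=0.20),
        ScreenerSpec("scq_positive", sensitivity=0.78, specificity=0.73, spec_drop_high_cbcl=0.13),
    ]


# ASD latent-liability loadings: which features carry diagnostic signal.
_DEFAULT_ASD_LOADINGS = {
    "srs2_total": 1.0,
    "scq_total": 1.0,
    "ados_sa_css": 1.0,
    "ados_rrb_css": 0.7,
    "ados_css": 1.0,
    "rbs_r_total": 0.7,
}


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort."""

    n_participants: int = 64
    variables: list[VariableDef] = field(default_factory=default_variables)
    modules: list[ModuleSpec] = field(default_factory=default_modules)
    group_fraction: float = 25 / 64  # proportion prenatal/birth-diagnosed
    asd_prevalence: float = 9 / 63
    asd_loadings: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ASD_LOADINGS))
    asd_liability_noise: float = 1.0
    screeners: list[ScreenerSpec] = field(default_factory=default_screeners)
    instrument_noise: dict[str, float] = field(default_factory=dict)  # family -> noise variance share in [0,1)
    community_dx_extra: float = 0.25  # extra community-diagnosis probability among non-DSM-5 cases
    age_mean: float = 13.10
    age_sd: float = 5.72
    age_range: tuple[float, float] = (5.0, 25.0)
    missing_by_group: float = 1.0  # multiplier on missing rates for the postnatal group
    psd_repair: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not (0.0 < self.group_fraction < 1.0):
            raise ValueError("group_fraction must be in (0,1)")
        if not (0.0 < self.asd_prevalence < 1.0):
            raise ValueError("asd_prevalence must be in (0,1)")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        known = set(names)
        for m in self.modules:
            extra = set(m.members) - known
            if extra:
                raise ValueError(f"module {m.name!r} references unknown variables: {sorted(extra)}")
        covered: set[str] = set()
        for m in self.modules:
            if covered & set(m.members):
                raise ValueError("modules must not overlap")
            covered |= set(m.members)
        for fam, share in self.instrument_noise.items():
            if not (0.0 <= share < 1.0):
                raise ValueError(f"instrument_noise[{fam!r}] must be in [0,1)")
        # Validate the implied target correlation at construction.
        self.target_correlation()

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def target_correlation(self) -> pd.DataFrame:
        """Target correlation of the *observed* variables on the latent
        (copula) scale, including measurement-noise attenuation."""
        R = build_target_correlation(self.variable_names, self.modules, repair=self.psd_repair)
        if self.instrument_noise:
            lam = np.array(
                [np.sqrt(1.0 - self.instrument_noise.get(v.family, 0.0)) for v in self.variables]
            )
            A = R.to_numpy() * np.outer(lam, lam)
            np.fill_diagonal(A, 1.0)
            R = pd.DataFrame(A, index=R.index, columns=R.columns)
        return R


def build_target_correlation(
    names: list[str], modules: list[ModuleSpec], repair: bool = True
) -> pd.DataFrame:
    """Block correlation matrix from module specs; unassigned variables are
    uncorrelated with everything.  Non-PSD targets are repaired by
    eigenvalue clipping (with a warning) or rejected naming the blocks."""
    p = len(names)
    idx = {n: i for i, n in enumerate(names)}
    R = np.zeros((p, p))
    label = np.full(p, "", dtype=object)
    for m in modules:
        for n in m.members:
            label[idx[n]] = m.name
    for a, ma in enumerate(modules):
        ia = [idx[n] for n in ma.members]
        R[np.ix_(ia, ia)] = ma.r_in
        for mb in modules[a + 1:]:
            ib = [idx[n] for n in mb.members]
            r_between = min(ma.r_out, mb.r_out)
            R[np.ix_(ia, ib)] = r_between
            R[np.ix_(ib, ia)] = r_between
    np.fill_diagonal(R, 1.0)
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-10:
        blocks = ", ".join(f"{m.name}(r_in={m.r_in}, r_out={m.r_out})" for m in modules)
        if not repair:
            raise ValueError(
                f"target correlation matrix is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g}); offending blocks: {blocks}"
            )
        warnings.warn(
            f"target correlation not PSD (min eigenvalue {w.min():.3g}); "
            f"applying nearest-PSD repair to blocks: {blocks}",
            stacklevel=2,
        )
        R = nearest_psd(R)
    return pd.DataFrame(R, index=names, columns=names)


def nearest_psd(a: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Nearest positive semi-definite correlation matrix by eigenvalue
    clipping followed by re-scaling to a unit diagonal."""
    w, v = np.linalg.eigh((a + a.T) / 2)
    w = np.clip(w, eps, None)
    b = (v * w) @ v.T
    d = np.sqrt(np.diag(b))
    b = b / np.outer(d, d)
    np.fill_diagonal(b, 1.0)
    return b


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would have to infer."""

    true_partition: dict[str, str]
    true_group_effects: dict[str, float]
    true_correlation: pd.DataFrame
    true_sensitivity: dict[str, float]
    true_specificity: dict[str, float]
    true_specificity_high_cbcl: dict[str, float]
    asd_threshold: float
    clipped: pd.DataFrame  # boolean mask, participants x variables

    def __post_init__(self) -> None:
        for d in (self.true_sensitivity, self.true_specificity):
            for k, v in d.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"operating point for {k!r} outside [0,1]")

    def to_json(self) -> str:
        payload = {
            "true_partition": self.true_partition,
            "true_group_effects": self.true_group_effects,
            "true_correlation": self.true_correlation.round(10).to_dict(),
            "true_sensitivity": self.true_sensitivity,
            "true_specificity": self.true_specificity,
            "true_specificity_high_cbcl": self.true_specificity_high_cbcl,
            "asd_threshold": self.asd_threshold,
            "n_clipped_cells": int(self.clipped.to_numpy().sum()),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class PhenotypeTable:
    """Participants x variables with the data dictionary alongside.

    ``data`` holds one row per participant: ``participant_id`` first, then
    ``group`` (prenatal/postnatal), ``age_years``, diagnosis labels, screener
    calls, then the phenotype variables.  ``dictionary`` holds one row per
    phenotype variable (scale type, norm mean/SD, family, direction flag).
    """

    data: pd.DataFrame
    dictionary: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.dictionary["variable"]) - set(self.data.columns)
        if missing:
            raise ValueError(f"dictionary references absent columns: {sorted(missing)}")
        ages = self.data["age_years"].dropna()
        if ((ages < 0) | (ages > 120)).any():
            raise ValueError("ages outside [0, 120]")

    @property
    def variables(self) -> list[str]:
        return list(self.dictionary["variable"])

    def phenotypes(self) -> pd.DataFrame:
        return self.data[self.variables]

    def write(self, data_path, dict_path) -> None:
        self.data.to_csv(data_path, index=False, float_format="%.10g")
        self.dictionary.to_csv(dict_path, index=False, float_format="%.10g")


def _marginal_transform(z: np.ndarray, v: VariableDef) -> np.ndarray:
    if v.kind == "standard":
        x = v.mean + v.sd * z
    elif v.kind == "lognormal":
        x = np.exp(v.log_location + v.log_scale * z)
    else:
        raise ValueError(f"unknown marginal kind {v.kind!r} for {v.name!r}")
    return x


def generate_cohort(config: CohortConfig) -> tuple[PhenotypeTable, GroundTruth]:
    """Draw one cohort.

    Returns the phenotype table and the ground truth used to draw it.
    Reproducible: a fixed config (including its seed) always yields the
    identical table.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_age, rng_miss, rng_screen, rng_dx = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    n = config.n_participants
    names = config.variable_names
    vdefs = {v.name: v for v in config.variables}
    R_target = config.target_correlation()

    # Latent copula scores with the (noise-attenuated) target correlation.
    L = np.linalg.cholesky(R_target.to_numpy() + 1e-12 * np.eye(len(names)))
    Z = rng_latent.standard_normal((n, len(names))) @ L.T

    # Group labels: first ceil(f*n) prenatal by construction, then the rows
    # are shuffled so ids carry no group information.
    n_pre = int(round(config.group_fraction * n))
    n_pre = min(max(n_pre, 1), n - 1)
    group = np.array(["prenatal"] * n_pre + ["postnatal"] * (n - n_pre))
    perm = rng_latent.permutation(n)
    group = group[perm]
    is_post = group == "postnatal"

    # Group effects on the latent (SD) scale, centred so the full-sample
    # marginal is preserved: prenatal + (1-f)*d, postnatal - f*d, where d is
    # the standardized prenatal advantage (worse direction per variable).
    f_pre = n_pre / n
    for j, name in enumerate(names):
        v = vdefs[name]
        d = v.group_effect
        if d == 0.0:
            continue
        sign = 1.0 if v.higher_worse else -1.0  # postnatal worse
        Z[~is_post, j] += -sign * (1 - f_pre) * d
        Z[is_post, j] += sign * f_pre * d

    # Marginal transforms + clipping.
    X = np.empty_like(Z)
    clipped = np.zeros_like(Z, dtype=bool)
    for j, name in enumerate(names):
        v = vdefs[name]
        x = _marginal_transform(Z[:, j], v)
        if v.admissible is not None:
            lo, hi = v.admissible
            clipped[:, j] = (x < lo) | (x > hi)
            x = np.clip(x, lo, hi)
        if v.integer:
            x = np.round(x)
        X[:, j] = x

    # DSM-5 ASD via a latent liability threshold on ASD-feature scores.
    load = np.zeros(len(names))
    for name, w in config.asd_loadings.items():
        if name in vdefs:
            load[names.index(name)] = w
    if not load.any():
        raise ValueError("asd_loadings reference no generated variables")
    liability = Z @ load + config.asd_liability_noise * rng_dx.standard_normal(n)
    k_cases = int(round(config.asd_prevalence * n))
    if not (0 < k_cases < n):
        raise ValueError(
            f"target prevalence {config.asd_prevalence:.3f} unreachable at n={n} "
            f"(implies {k_cases} cases)"
        )
    threshold = np.sort(liability)[n - k_cases]
    dsm5_asd = liability >= threshold

    # Community ASD diagnosis: all DSM-5 cases plus an over-diagnosed tail.
    community = dsm5_asd | (
        (~dsm5_asd) & (rng_dx.random(n) < config.community_dx_extra)
    )

    # Screener calls against the latent diagnosis; specificity optionally
    # degraded among participants with CBCL int/ext T >= 64.
    cbcl_cols = [c for c in ("cbcl_internalizing", "cbcl_externalizing") if c in vdefs]
    if cbcl_cols:
        cbcl_high = np.zeros(n, dtype=bool)
        for c in cbcl_cols:
            cbcl_high |= X[:, names.index(c)] >= 64.0
    else:
        cbcl_high = np.zeros(n, dtype=bool)
    screener_calls = {}
    for s in config.screeners:
        u = rng_screen.random(n)
        spec_eff = np.where(cbcl_high, s.specificity - s.spec_drop_high_cbcl, s.specificity)
        pos = np.where(dsm5_asd, u < s.sensitivity, u < 1.0 - spec_eff)
        screener_calls[s.name] = pos.astype(int)

    # Ages: truncated normal over the study's recruitment window.
    a, b = config.age_range
    alpha, beta = (a - config.age_mean) / config.age_sd, (b - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(
        alpha, beta, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng_age
    )

    # Missingness: MCAR per variable; optional extra loss in the postnatal
    # group (Table-1-style domain-specific n attrition).
    Xm = X.astype(float).copy()
    for j, name in enumerate(names):
        rate = vdefs[name].missing_rate
        if rate <= 0:
            continue
        r = np.where(is_post, min(rate * config.missing_by_group, 1.0), rate)
        Xm[rng_miss.random(n) < r, j] = np.nan

    ids = [f"P{i + 1:03d}" for i in range(n)]
    data = pd.DataFrame({"participant_id": ids, "group": group, "age_years": ages})
    data["dsm5_asd"] = dsm5_asd.astype(int)
    data["community_asd"] = community.astype(int)
    for k, vcol in screener_calls.items():
        data[k] = vcol
    for j, name in enumerate(names):
        data[name] = Xm[:, j]

    dictionary = pd.DataFrame(
        {
            "variable": names,
            "scale_type": [vdefs[m].kind for m in names],
            "pop_norm_mean": [vdefs[m].pop_mean for m in names],
            "pop_norm_sd": [vdefs[m].pop_sd for m in names],
            "family": [vdefs[m].family for m in names],
            "higher_worse": [vdefs[m].higher_worse for m in names],
        }
    )

    partition = {}
    for m in config.modules:
        for name in m.members:
            partition[name] = m.name
    for name in names:
        partition.setdefault(name, "unassigned")

    truth = GroundTruth(
        true_partition=partition,
        true_group_effects={v.name: v.group_effect for v in config.variables},
        true_correlation=R_target,
        true_sensitivity={s.name: s.sensitivity for s in config.screeners},
        true_specificity={s.name: s.specificity for s in config.screeners},
        true_specificity_high_cbcl={
            s.name: s.specificity - s.spec_drop_high_cbcl for s in config.screeners
        },
        asd_threshold=float(threshold),
        clipped=pd.DataFrame(clipped, index=ids, columns=names),
    )
    return PhenotypeTable(data=data, dictionary=dictionary), truth


def generate_reference_norms(
    config: CohortConfig,
    reference_n: int = 1877,
    impairment_shift: float = 0.3,
    sd_inflation: float = 1.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic reference-population norms (an SSC-like all-male ASD sample).

    For each generated variable, draws ``reference_n`` scores from the
    variable's marginal shifted toward impairment by ``impairment_shift``
    marginal SDs and reports the empirical mean/SD.  Deterministic for a
    seed (defaults to the cohort seed); the declared reference size defaults
    to 1877 males.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed if seed is None else seed, 1877]))
    rows = []
    for v in config.variables:
        sign = 1.0 if v.higher_worse else -1.0
        z = rng.standard_normal(reference_n) + sign * impairment_shift
        x = _marginal_transform(z * sd_inflation if v.kind == "standard" else z, v)
        if v.admissible is not None:
            x = np.clip(x, *v.admissible)
        rows.append(
            {
                "variable": v.name,
                "ref_mean": float(np.mean(x)),
                "ref_sd": float(np.std(x, ddof=1)),
                "ref_n": reference_n,
                "population": "synthetic-asd-reference",
                "age_min": 0.0,
                "age_max": 18.0,
            }
        )
    return pd.DataFrame(rows)


def config_to_json(config: CohortConfig) -> str:
    """Serialize a config (for run manifests); dataclasses become dicts."""

    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    return json.dumps(dataclasses.asdict(config), default=enc, indent=2, sort_keys=True)
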