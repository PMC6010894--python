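"""Synthetic prospective-cohort generator for biomarker-correction studies.

Emulates the statistical structure the analysis assumes: Hardy-Weinberg
genotypes at configured allele frequencies, a right-skewed (log-normal) serum
AFP whose heritable component is multiplicative in genotype, an assay
detection-limit floor, a rare binary incident-HCC outcome driven by the
genotype-free AFP component through a logistic model with a configurable odds
ratio per 10 ng/mL, and independent baseline covariates matching configured
prevalences.  The generative model for participant *i* is

    ln AFP_i = ln(median) + sum_s d_is ln(a_s) - c + eps_i,
    eps_i ~ Normal(0, sigma^2),   c = sum_s ln(E_s),

so the multiplicative genetic term equals the mean-1 normalized factor G_i and
the genotype-free component ``signal_i = median * exp(eps_i)`` has median
``afp_median``.  The observed value is floored at the detection limit.
Outcomes follow ``P(case|x) = expit(alpha + ln(OR10) * x / 10)`` with ``x``
the genotype-free component and ``alpha`` solved so the marginal incidence
matches the configured rate.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .effects import genotype_effects

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpSpec:
    """Generative truth for one panel SNP: effect-allele frequency ``p`` and
    relative allelic effect ``a`` (multiplicative per-allele factor)."""
    snp_id: str
    p: float
    a: float

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"{self.snp_id}: allele frequency must be in "
                             f"[0,1], got {self.p}")
        if self.a <= 0:
            raise ValueError(f"{self.snp_id}: allelic effect must be > 0, "
                             f"got {self.a}")


DEFAULT_SNP_PANEL = (SnpSpec("rs12506899", 0.33, 1.08),
                     SnpSpec("rs2251844", 0.47, 1.10))

#: Baseline covariate marginals: binary prevalences, and (mean, SD) for
#: continuous covariates.  Sex is generated as male with the given prevalence.
DEFAULT_COVARIATES: dict = {
    "age": (62.09, 7.78),
    "sex_male": 0.469,
    "bmi": (24.33, 3.32),
    "smoking": 0.303,
    "drinking": 0.272,
    "marriage": 0.899,
    "education": 0.104,
    "physical_activity": 0.885,
    "family_history": 0.030,
}

_BINARY_COVARIATES = ("smoking", "drinking", "marriage", "education",
                      "physical_activity", "family_history")

COHORT_COLUMNS = ("id", "age", "sex", "bmi") + _BINARY_COVARIATES + (
    "afp_ng_ml", "hcc")


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    Identical config + seed produces a bit-identical cohort.
    """
    n_participants: int = 9819
    seed: int = 0
    snp_panel: Sequence[SnpSpec] = DEFAULT_SNP_PANEL
    log_noise_sd: float = 1.0          # SD of the natural-log AFP residual
    afp_median: float = 2.70           # ng/mL
    detection_limit: float = 0.005     # ng/mL assay floor
    baseline_incidence: float = 0.00581
    true_or_per_10: float = 5.0        # OR per 10 ng/mL of the genotype-free component
    covariate_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    covariate_log_odds: dict = field(default_factory=dict)
    genotype_missing_rate: float = 0.0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.log_noise_sd <= 0:
            raise ValueError("log_noise_sd must be strictly positive")
        if self.afp_median <= 0 or self.detection_limit <= 0:
            raise ValueError("afp_median and detection_limit must be > 0")
        if not 0.0 < self.baseline_incidence < 1.0:
            raise ValueError("baseline_incidence must be in (0,1)")
        if self.true_or_per_10 <= 0:
            raise ValueError("true_or_per_10 must be > 0")
        if not 0.0 <= self.genotype_missing_rate < 1.0:
            raise ValueError("genotype_missing_rate must be in [0,1)")
        self.snp_panel = tuple(
            s if isinstance(s, SnpSpec) else SnpSpec(**s) for s in self.snp_panel)
        self.covariate_prevalences = {
            k: tuple(float(x) for x in v) if isinstance(v, (list, tuple))
            else float(v)
            for k, v in self.covariate_prevalences.items()}
        unknown = set(self.covariate_prevalences) - set(DEFAULT_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariate name(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "snp_panel" in raw:
            raw["snp_panel"] = [SnpSpec(**s) if isinstance(s, dict) else SnpSpec(*s)
                                for s in raw["snp_panel"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["snp_panel"] = [dataclasses.asdict(s) for s in self.snp_panel]
        d["covariate_prevalences"] = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in self.covariate_prevalences.items()}
        return d


class AfpDraws(NamedTuple):
    """Latent and observed AFP plus their generative decomposition."""
    latent: np.ndarray        # pre-floor AFP, ng/mL
    observed: np.ndarray      # floored at the detection limit
    genetic_factor: np.ndarray  # mean-1 multiplicative genetic term G
    signal: np.ndarray        # genotype-free component latent/G


def simulate_genotypes(n: int, snp_panel: Sequence[SnpSpec],
                       rng: np.random.Generator) -> pd.DataFrame:
    """Draw Hardy-Weinberg genotype dosages, SNPs mutually independent.

    Each SNP's dosage is Binomial(2, p), i.e. P(2)=p^2, P(1)=2p(1-p),
    P(0)=(1-p)^2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cols = {}
    for snp in snp_panel:
        if not 0.0 <= snp.p <= 1.0:
            raise ValueError(f"{snp.snp_id}: invalid effect-allele frequency {snp.p}")
        cols[snp.snp_id] = rng.binomial(2, snp.p, size=n)
    return pd.DataFrame(cols)


def genetic_factors(dosages: pd.DataFrame,
                    snp_panel: Sequence[SnpSpec]) -> np.ndarray:
    """Mean-1 combined genetic factor G_i from true panel parameters
    (HWE-normalized genotype effects; missing dosage -> neutral factor)."""
    g = np.ones(len(dosages))
    for snp in snp_panel:
        if snp.a == 1.0 or snp.p in (0.0, 1.0):
            continue  # neutral or monomorphic: factor 1 by normalization
        lut = np.array(genotype_effects(snp.p, snp.a, "hwe"))
        d = dosages[snp.snp_id].to_numpy(dtype=float)
        miss = np.isnan(d)
        g *= np.where(miss, 1.0, lut[np.nan_to_num(d).astype(int)])
    return g


def simulate_afp(dosages: pd.DataFrame, snp_panel: Sequence[SnpSpec],
                 afp_median: float, log_noise_sd: float,
                 detection_limit: float,
                 rng: np.random.Generator) -> AfpDraws:
    """Draw AFP with a multiplicative genotype term and log-normal residual.

    ``ln latent = ln(afp_median) + ln(G) + eps`` where G is the mean-1
    normalized genetic factor (the per-dosage term ``sum d ln(a)`` centred by
    ``c = sum ln(E_s)``); the observed value is floored at the detection
    limit.
    """
    if afp_median <= 0 or log_noise_sd <= 0 or detection_limit <= 0:
        raise ValueError("afp_median, log_noise_sd and detection_limit must be > 0")
    missing_cols = [s.snp_id for s in snp_panel if s.snp_id not in dosages]
    if missing_cols:
        raise ValueError(f"dosage matrix lacks panel SNP(s) {missing_cols}")
    g = genetic_factors(dosages, snp_panel)
    eps = rng.normal(0.0, log_noise_sd, size=len(dosages))
    signal = afp_median * np.exp(eps)
    latent = signal * g
    observed = np.maximum(latent, detection_limit)
    return AfpDraws(latent=latent, observed=observed,
                    genetic_factor=g, signal=signal)


def solve_marginal_intercept(linear_term: np.ndarray, target: float) -> float:
    """Intercept alpha such that mean(expit(alpha + linear_term)) == target
    to within 1e-6 (bisection on a monotone function)."""
    if not 0.0 < target < 1.0:
        raise ValueError("target marginal incidence must be in (0,1)")
    t = np.asarray(linear_term, dtype=float)

    def f(alpha: float) -> float:
        return float(np.mean(expit(alpha + t))) - target

    lo, hi = -50.0, 50.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("requested marginal incidence is unattainable for "
                         "the given linear term")
    return float(brentq(f, lo, hi, xtol=1e-12))


def simulate_outcome(x: np.ndarray, true_or_per_10: float,
                     baseline_incidence: float, rng: np.random.Generator,
                     offset: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, float]:
    """Draw the binary incident outcome from a logistic model on ``x``.

    ``P(case) = expit(alpha + ln(true_or_per_10) * x/10 + offset)`` with alpha
    solved so the marginal incidence equals ``baseline_incidence``.  Returns
    ``(outcome, alpha)``.
    """
    if true_or_per_10 <= 0:
        raise ValueError("true_or_per_10 must be > 0")
    beta = math.log(true_or_per_10)
    lin = beta * np.asarray(x, dtype=float) / 10.0
    if offset is not None:
        lin = lin + np.asarray(offset, dtype=float)
    alpha = solve_marginal_intercept(lin, baseline_incidence)
    prob = expit(alpha + lin)
    return (rng.random(len(prob)) < prob).astype(int), alpha


def simulate_covariates(n: int, covariate_prevalences: dict,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Independent baseline covariates at configured marginals.

    Binary covariates are Bernoulli(prevalence); ``age``/``bmi`` are Normal
    with the configured (mean, SD); ``sex_male`` yields a categorical ``sex``
    column with values male/female.
    """
    unknown = set(covariate_prevalences) - set(DEFAULT_COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariate name(s): {sorted(unknown)}")
    out: dict = {}
    for name in DEFAULT_COVARIATES:
        spec = covariate_prevalences.get(name, DEFAULT_COVARIATES[name])
        if name in ("age", "bmi"):
            mean, sd = spec
            out[name] = rng.normal(mean, sd, size=n)
        elif name == "sex_male":
            male = rng.random(n) < float(spec)
            out["sex"] = np.where(male, "male", "female")
        else:
            out[name] = (rng.random(n) < float(spec)).astype(int)
    return pd.DataFrame(out)[["age", "sex", "bmi", *_BINARY_COVARIATES]]


class SimulatedCohort(NamedTuple):
    cohort: pd.DataFrame   # the participant table written to TSV
    truth: pd.DataFrame    # latent AFP, genetic factor, genotype-free signal
    intercept: float       # solved logistic intercept alpha


def simulate_cohort(config: SimulationConfig,
                    seed: int | None = None) -> SimulatedCohort:
    """Generate a full cohort: covariates, genotypes, AFP, outcome.

    All randomness comes from one ``numpy.random.default_rng`` seeded with
    ``seed`` (falling back to ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants
    cov = simulate_covariates(n, config.covariate_prevalences, rng)
    dose = simulate_genotypes(n, config.snp_panel, rng)
    afp = simulate_afp(dose, config.snp_panel, config.afp_median,
                       config.log_noise_sd, config.detection_limit, rng)
    offset = None
    if config.covariate_log_odds:
        offset = np.zeros(n)
        indic = {"sex_male": (cov["sex"] == "male").astype(float)}
        for name, beta in config.covariate_log_odds.items():
            col = indic.get(name, cov.get(name))
            if col is None:
                raise ValueError(f"covariate_log_odds names unknown covariate {name!r}")
            offset += float(beta) * np.asarray(col, dtype=float)
    outcome, alpha = simulate_outcome(afp.signal, config.true_or_per_10,
                                      config.baseline_incidence, rng,
                                      offset=offset)

    dose = dose.astype("Int64")
    if config.genotype_missing_rate > 0:
        for snp in config.snp_panel:
            mask = rng.random(n) < config.genotype_missing_rate
            col = dose[snp.snp_id].copy()
            col[mask] = pd.NA
            dose[snp.snp_id] = col

    cohort = pd.concat([
        pd.DataFrame({"id": [f"P{i:06d}" for i in range(1, n + 1)]}),
        cov,
        pd.DataFrame({"afp_ng_ml": afp.observed, "hcc": outcome}),
        dose,
    ], axis=1)
    truth = pd.DataFrame({
        "id": cohort["id"],
        "latent_afp": afp.latent,
        "genetic_factor": afp.genetic_factor,
        "signal": afp.signal,
    })
    logger.info("simulate_cohort: n=%d, cases=%d (%.2f/1000), alpha=%.3f",
                n, int(outcome.sum()), 1000 * outcome.mean(), alpha)
    return SimulatedCohort(cohort=cohort, truth=truth, intercept=alpha)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as TSV; missing genotypes are encoded as NA."""
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(path, detection_limit: float = 0.005) -> pd.DataFrame:
    """Read and validate a cohort TSV.

    Rejects malformed rows (non-numeric AFP, dosages outside {0,1,2,NA},
    non-binary outcome, duplicate ids) with the offending 1-based data row
    number; AFP values below the detection limit are accepted but logged.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"id": str})
    required = {"id", "afp_ng_ml", "hcc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")

    dup = df["id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicated id at row {int(dup.idxmax()) + 1}")

    afp = pd.to_numeric(df["afp_ng_ml"], errors="coerce")
    bad = afp.isna() & df["afp_ng_ml"].notna() | df["afp_ng_ml"].isna()
    if bad.any():
        raise ValueError(f"{path}: non-numeric AFP at row {int(bad.idxmax()) + 1}")
    df["afp_ng_ml"] = afp
    low = afp < detection_limit
    if low.any():
        logger.warning("%s: %d AFP value(s) below the detection limit %g "
                       "(first at row %d)", path, int(low.sum()),
                       detection_limit, int(low.idxmax()) + 1)

    if not df["hcc"].isin([0, 1]).all():
        row = int((~df["hcc"].isin([0, 1])).idxmax()) + 1
        raise ValueError(f"{path}: outcome must be 0/1, offending row {row}")

    snp_cols = [c for c in df.columns if c not in COHORT_COLUMNS]
    for c in snp_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = (~vals.isin([0, 1, 2])) & df[c].notna()
        if bad.any():
            raise ValueError(f"{path}: dosage outside {{0,1,2,NA}} in column "
                             f"{c!r} at row {int(bad.idxmax()) + 1}")
        df[c] = vals.astype("Int64")
    logger.info("read_cohort: %s, n=%d, %d SNP column(s)", path, len(df),
                len(snp_cols))
    return df
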