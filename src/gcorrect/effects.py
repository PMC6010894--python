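"""Multiplicative genotype effects on a serum biomarker and genetic correction.

A biallelic SNP with effect-allele frequency ``p`` acts multiplicatively on a
serum biomarker: each copy of the effect allele scales the level by the
*relative allelic effect* ``a`` (estimated as ``exp(slope)`` from an ordinary
least-squares regression of the natural-log biomarker on allele count).  The
three genotype classes then carry unnormalized effects ``(1, a, a**2)`` for
non-carriers (OO), heterozygotes (OX) and homozygous carriers (XX).  Dividing
by the population-mean effect

    E = w_OO * 1 + w_OX * a + w_XX * a**2

with genotype weights ``w`` (Hardy-Weinberg proportions from ``p``, or the
empirical genotype proportions of a cohort) yields normalized genotype effects
whose population mean is exactly 1, so an individual's combined factor

    G_i = prod_s e_s(genotype_is)

averages ~1 over the population and the *genetically corrected* biomarker
``corrected_i = measured_i / G_i`` is on the same scale as the raw
measurement.  Correction removes the heritable component of inter-individual
biomarker variation, sharpening the biomarker's relationship with disease.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Tolerance for the multiplicative-ratio invariants when effects are built
#: from exact arithmetic, and when they come from values published rounded to
#: two decimals.
_RATIO_TOL_EXACT = 1e-12
_RATIO_TOL_ROUNDED = 0.005

PANEL_COLUMNS = ("snp_id", "chrom", "pos_bp", "effect_allele",
                 "allele_freq", "allelic_effect")


def hwe_weights(p: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype proportions (w_OO, w_OX, w_XX) for
    effect-allele frequency ``p``."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"effect-allele frequency must be in (0,1), got {p}")
    q = 1.0 - p
    return (q * q, 2.0 * p * q, p * p)


def genotype_effects(p: float, a: float,
                     weights: str | Sequence[float] = "hwe",
                     ) -> tuple[float, float, float]:
    """Normalized genotype effects (e_OO, e_OX, e_XX) with population mean 1.

    Parameters
    ----------
    p : effect-allele frequency in (0, 1).
    a : relative allelic effect (> 0); ``a < 1`` denotes a decreasing allele
        for the stated effect allele (no re-orientation is performed).
    weights : ``"hwe"`` to derive (w_OO, w_OX, w_XX) from ``p`` under
        Hardy-Weinberg equilibrium, or an explicit length-3 sequence of
        empirical genotype proportions summing to 1.

    Returns
    -------
    ``(1/E, a/E, a**2/E)`` where ``E`` is the weighted mean of the
    unnormalized effects ``(1, a, a**2)``.
    """
    if a <= 0:
        raise ValueError(f"relative allelic effect must be > 0, got {a}")
    if isinstance(weights, str):
        if weights != "hwe":
            raise ValueError(f"unknown weights mode {weights!r}")
        w = hwe_weights(p)
    else:
        w = tuple(float(x) for x in weights)
        if len(w) != 3 or any(x < 0 for x in w):
            raise ValueError(f"degenerate genotype weights {w}")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"genotype weights must sum to 1, got {sum(w)}")
    e = w[0] + w[1] * a + w[2] * a * a
    return (1.0 / e, a / e, a * a / e)


@dataclass(frozen=True)
class SnpEffect:
    """One SNP's effect-allele metadata and normalized genotype effects.

    ``e_OO, e_OX, e_XX`` are the multiplicative factors applied to the
    biomarker for non-carriers, heterozygotes and homozygous carriers of the
    effect allele, normalized so their population mean (under the weights used
    at construction) is 1.
    """

    snp_id: str
    p: float
    a: float
    e_OO: float
    e_OX: float
    e_XX: float
    chrom: str = ""
    pos: int = 0
    effect_allele: str = ""
    #: Widened consistency tolerance for effects read from rounded published
    #: values (2 dp) rather than constructed exactly.
    rounded: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(
                f"{self.snp_id}: allele frequency must be in (0,1), got {self.p}")
        if min(self.a, self.e_OO, self.e_OX, self.e_XX) <= 0:
            raise ValueError(f"{self.snp_id}: effects must be strictly positive")
        tol = _RATIO_TOL_ROUNDED if self.rounded else _RATIO_TOL_EXACT
        if (abs(self.e_OX / self.e_OO - self.a) > tol
                or abs(self.e_XX / self.e_OO - self.a * self.a) > tol * 2):
            raise ValueError(
                f"{self.snp_id}: genotype effects violate the multiplicative "
                f"model e_OX/e_OO = a, e_XX/e_OO = a**2 beyond tolerance {tol}")

    @classmethod
    def from_allelic_effect(cls, snp_id: str, p: float, a: float,
                            weights: str | Sequence[float] = "hwe",
                            **meta) -> "SnpEffect":
        """Construct with effects normalized to population mean 1."""
        e_oo, e_ox, e_xx = genotype_effects(p, a, weights)
        return cls(snp_id=snp_id, p=p, a=a,
                   e_OO=e_oo, e_OX=e_ox, e_XX=e_xx, **meta)

    def effect_of(self, dosage: float | None) -> float:
        """Genotype effect for an effect-allele dosage in {0, 1, 2};
        missing (None/NaN) contributes the neutral factor 1."""
        if dosage is None or (isinstance(dosage, float) and math.isnan(dosage)):
            return 1.0
        d = int(dosage)
        if d == 0:
            return self.e_OO
        if d == 1:
            return self.e_OX
        if d == 2:
            return self.e_XX
        raise ValueError(f"{self.snp_id}: dosage must be 0, 1, 2 or missing, got {dosage}")

    def population_mean(self, weights: str | Sequence[float] = "hwe") -> float:
        w = hwe_weights(self.p) if weights == "hwe" else tuple(weights)
        return w[0] * self.e_OO + w[1] * self.e_OX + w[2] * self.e_XX


#: The two-SNP AFP panel: (snp_id, chrom, pos_bp, effect_allele,
#: effect-allele frequency, relative allelic effect).
DEFAULT_PANEL = pd.DataFrame(
    [("rs12506899", "4", 74_538_147, "T", 0.33, 1.08),
     ("rs2251844", "15", 41_623_770, "T", 0.47, 1.10)],
    columns=list(PANEL_COLUMNS),
)


def read_panel(path) -> pd.DataFrame:
    """Read a SNP panel TSV (columns: snp_id, chrom, pos_bp, effect_allele,
    allele_freq, allelic_effect)."""
    panel = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel file {path} is missing columns {sorted(missing)}")
    return panel


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def panel_effects(panel: pd.DataFrame,
                  weights_mode: str = "hwe",
                  dosages: pd.DataFrame | None = None) -> list[SnpEffect]:
    """Build :class:`SnpEffect` objects for every panel row.

    ``weights_mode="hwe"`` derives normalization weights from the panel allele
    frequency; ``"empirical"`` uses observed genotype proportions in
    ``dosages`` (one column per SNP, values 0/1/2/NaN).
    """
    effects = []
    for row in panel.itertuples(index=False):
        if weights_mode == "hwe":
            w: str | tuple = "hwe"
        elif weights_mode == "empirical":
            if dosages is None or row.snp_id not in dosages:
                raise ValueError(
                    f"empirical weights requested but no dosages for {row.snp_id}")
            d = pd.to_numeric(dosages[row.snp_id], errors="coerce").dropna()
            counts = np.array([(d == k).sum() for k in (0, 1, 2)], dtype=float)
            if counts.sum() == 0:
                raise ValueError(f"{row.snp_id}: no observed genotypes")
            w = tuple(counts / counts.sum())
        else:
            raise ValueError(f"unknown weights mode {weights_mode!r}")
        effects.append(SnpEffect.from_allelic_effect(
            row.snp_id, float(row.allele_freq), float(row.allelic_effect),
            weights=w, chrom=str(row.chrom), pos=int(row.pos_bp),
            effect_allele=str(row.effect_allele)))
    return effects


def fit_allelic_effect(dosages, biomarker) -> tuple[float, float]:
    """Estimate the relative allelic effect by OLS of ln(biomarker) on dosage.

    Returns ``(a_hat, se)`` where ``a_hat = exp(slope)`` and ``se`` is the
    standard error of the slope on the natural-log scale.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(biomarker, dtype=float)
    if d.shape != y.shape:
        raise ValueError("dosage and biomarker vectors differ in length")
    keep = ~np.isnan(d)
    d, y = d[keep], y[keep]
    if np.any(~(y > 0)):
        raise ValueError(
            "biomarker values must be strictly positive; apply the assay "
            "detection-limit floor (e.g. 0.005 ng/mL) before fitting")
    levels = np.unique(d)
    if levels.size < 2:
        raise ValueError("allelic effect unidentifiable: SNP is monomorphic "
                         "in this sample")
    if levels.size == 2 and d.size < 10:
        raise ValueError("allelic effect unidentifiable: only two dosage "
                         f"levels observed with n={d.size} < 10")
    res = sm.OLS(np.log(y), sm.add_constant(d)).fit()
    return float(math.exp(res.params[1])), float(res.bse[1])


def combine_effects(snp_effects: Iterable[SnpEffect],
                    dosages_row: Sequence[float | None],
                    ) -> tuple[float, list[str]]:
    """Combined genetic factor G for one individual.

    G is the product over the panel of the individual's genotype effects; a
    missing genotype contributes the neutral factor 1 and adds the SNP id to
    the returned flag list.
    """
    effects = list(snp_effects)
    if len(effects) != len(dosages_row):
        raise ValueError("dosage row length does not match panel size")
    g = 1.0
    flags: list[str] = []
    for eff, d in zip(effects, dosages_row):
        if d is None or (isinstance(d, float) and math.isnan(d)) or d is pd.NA:
            flags.append(eff.snp_id)
            continue
        g *= eff.effect_of(d)
    return g, flags


def correct_biomarker(biomarker, g):
    """Genetically corrected biomarker value(s): ``biomarker / G``.

    ``corrected * G`` returns the measured value exactly.
    """
    b = np.asarray(biomarker, dtype=float)
    gv = np.asarray(g, dtype=float)
    if np.any(~(gv > 0)):
        raise ValueError("combined genetic factor G must be strictly positive")
    if np.any(~(b > 0)):
        raise ValueError("biomarker must be strictly positive (detection-limit "
                         "floored values are > 0)")
    out = b / gv
    return float(out) if out.ndim == 0 else out


def relative_reduction_pct(before: float, after: float) -> float:
    """Relative reduction 100*(before - after)/before, one decimal."""
    if before <= 0:
        raise ValueError("reference value must be positive")
    return round(100.0 * (before - after) / before, 1)


def cohort_correction(cohort: pd.DataFrame, panel: pd.DataFrame,
                      weights_mode: str = "hwe",
                      biomarker_col: str = "afp_ng_ml",
                      ) -> tuple[pd.DataFrame, dict]:
    """Apply the genetic correction to every participant of a cohort.

    Returns ``(result, summary)``: ``result`` has one row per participant
    (id, measured value, G, corrected value, n_snps_used, flags) and
    ``summary`` reports mean/median/IQR of the original and corrected values
    plus the relative change ``100*(mean_orig - mean_corr)/mean_orig``.
    """
    snp_ids = list(panel["snp_id"])
    absent = [s for s in snp_ids if s not in cohort.columns]
    if absent:
        raise ValueError(f"panel SNP(s) absent from cohort table: {absent}")
    if biomarker_col not in cohort.columns:
        raise ValueError(f"cohort table has no column {biomarker_col!r}")

    dose = cohort[snp_ids].apply(pd.to_numeric, errors="coerce")
    effects = panel_effects(panel, weights_mode=weights_mode, dosages=dose)

    g = np.ones(len(cohort))
    n_used = np.zeros(len(cohort), dtype=int)
    flags = [[] for _ in range(len(cohort))]
    for eff in effects:
        d = dose[eff.snp_id].to_numpy(dtype=float)
        bad = ~(np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError(
                f"{eff.snp_id}: dosages outside {{0,1,2,NA}} at rows "
                f"{np.flatnonzero(bad)[:5] + 1}")
        lut = np.array([eff.e_OO, eff.e_OX, eff.e_XX])
        miss = np.isnan(d)
        factor = np.where(miss, 1.0, lut[np.nan_to_num(d).astype(int)])
        g *= factor
        n_used += (~miss).astype(int)
        for i in np.flatnonzero(miss):
            flags[i].append(eff.snp_id)

    measured = cohort[biomarker_col].to_numpy(dtype=float)
    corrected = correct_biomarker(measured, g)
    result = pd.DataFrame({
        "id": cohort["id"] if "id" in cohort.columns else np.arange(len(cohort)),
        biomarker_col: measured,
        "genetic_factor": g,
        "afp_corrected": corrected,
        "n_snps_used": n_used,
        "flags": [";".join(f) for f in flags],
    })

    def _stats(x: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"mean": float(np.mean(x)), "median": float(med),
                "q1": float(q1), "q3": float(q3)}

    orig, corr = _stats(measured), _stats(corrected)
    summary = {
        "n": int(len(cohort)),
        "original": orig,
        "corrected": corr,
        "relative_change_pct": relative_reduction_pct(orig["mean"], corr["mean"]),
        "n_flagged": int(sum(bool(f) for f in flags)),
    }
    logger.info("cohort_correction: n=%d, mean %.3f -> %.3f (%.1f%% change), "
                "%d rows with missing genotypes", summary["n"], orig["mean"],
                corr["mean"], summary["relative_change_pct"], summary["n_flagged"])
    return result, summary
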