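"""Pedigree / time-to-event simulation framework.

Generates every input the statistical claims need, without external data:
founder genotypes drawn Binomial(2, MAF) per independent "pseudo" variant,
gene-dropping through configurable pedigrees (default: 10 members over
three generations), Gaussian frailties b ~ N(0, tau*psi) with psi the
pedigree relationship matrix, and exponential event/censoring times

    T_f = -log(U) / (lambda * exp(eta)),   T_c ~ Exp(lambda_c),
    t = min(T_f, T_c),  delta = 1{T_f <= T_c},

with lambda calibrated so the realized censoring fraction (share of
subjects with delta = 0) hits a target.  Harnesses for empirical type-I
error and power drive the full two-step pipeline on these inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .association import TestOptions, estimate_variance_ratio, test_dosage_matrix
from .association import AssociationEngine, ExactVarianceCalculator
from .genotype_io import GenotypeBlock, VariantInfo, write_plink
from .grm import GRMOperator
from .null_model import NullModelConfig, SurvivalPhenotype, fit_null

__all__ = [
    "PedigreeMember",
    "Pedigree",
    "SimConfig",
    "default_pedigree",
    "simulate_founders",
    "gene_drop",
    "simulate_cohort_genotypes",
    "simulate_frailty",
    "simulate_tte",
    "calibrate_lambda",
    "draw_maf",
    "simulate_phenotypes",
    "run_type1_harness",
    "run_power_harness",
    "simulate_dataset",
]


# ---------------------------------------------------------------------
# pedigree


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    father: Optional[str] = None
    mother: Optional[str] = None

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """An acyclic pedigree; parents must be listed before their children."""

    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if (m.father is None) != (m.mother is None):
                raise ValueError(f"{m.id}: both parents or neither must be given")
            for parent in (m.father, m.mother):
                if parent is not None and parent not in seen:
                    raise ValueError(f"{m.id}: parent {parent} not defined earlier")
            if m.id in seen:
                raise ValueError(f"duplicate member id {m.id}")
            seen.add(m.id)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def founder_indices(self) -> list[int]:
        return [i for i, m in enumerate(self.members) if m.is_founder]

    def kinship(self) -> np.ndarray:
        """Kinship matrix by the recursive tabular method (founders unrelated,
        non-inbred)."""
        n = self.size
        idx = {m.id: i for i, m in enumerate(self.members)}
        phi = np.zeros((n, n))
        for i, m in enumerate(self.members):
            if m.is_founder:
                phi[i, i] = 0.5
            else:
                f, g = idx[m.father], idx[m.mother]
                phi[i, i] = 0.5 * (1.0 + phi[f, g])
                for j in range(i):
                    phi[i, j] = phi[j, i] = 0.5 * (phi[f, j] + phi[g, j])
        return phi

    def relationship(self) -> np.ndarray:
        """Expected genetic relationship matrix, 2 * kinship."""
        return 2.0 * self.kinship()


def default_pedigree() -> Pedigree:
    """Ten members over three generations: a founder couple, three children,
    two married-in founders, and three grandchildren."""
    return Pedigree(
        [
            PedigreeMember("p1"),
            PedigreeMember("p2"),
            PedigreeMember("s1"),
            PedigreeMember("s2"),
            PedigreeMember("c1", "p1", "p2"),
            PedigreeMember("c2", "p1", "p2"),
            PedigreeMember("c3", "p1", "p2"),
            PedigreeMember("g1", "c1", "s1"),
            PedigreeMember("g2", "c1", "s1"),
            PedigreeMember("g3", "c2", "s2"),
        ]
    )


# ---------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Study-design knobs for the simulation framework."""

    n_families: int = 500
    n_singletons: int = 5000
    m_grm: int = 2000
    m_test: int = 10000
    grm_maf_range: tuple[float, float] = (0.01, 0.5)
    test_maf_range: tuple[float, float] = (5e-4, 0.5)
    tau: float = 0.25
    target_censoring: float = 0.5
    lambda_c: float = 1.0
    alpha: float = 0.5  # covariate effect on the log hazard
    pedigree: Pedigree = field(default_factory=default_pedigree)
    seed: int = 1
    # stopping threshold for the variance-ratio protocol; the 0.001 default
    # presumes biobank-scale n, where per-marker ratios are nearly constant
    vr_cv_threshold: float = 0.001

    def __post_init__(self) -> None:
        if min(self.n_families, self.n_singletons) < 0 or self.n_families + self.n_singletons == 0:
            raise ValueError("need a positive number of samples")
        if not 0 < self.target_censoring < 1:
            raise ValueError("target_censoring must be in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_families * self.pedigree.size + self.n_singletons


# ---------------------------------------------------------------------
# genotypes


def draw_maf(rng: np.random.Generator, size: int, low: float, high: float) -> np.ndarray:
    """Log-uniform MAF spectrum on [low, high] (heavy at low frequencies)."""
    return np.exp(rng.uniform(np.log(low), np.log(high), size=size))


def simulate_founders(n_founders: int, maf, rng: np.random.Generator) -> np.ndarray:
    """Founder dosages, i.i.d. Binomial(2, MAF) per founder per variant."""
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("MAF must be in the open interval (0, 1)")
    return rng.binomial(2, maf, size=(n_founders, len(maf))).astype(np.int8)


def gene_drop(
    pedigree: Pedigree,
    founder_genotypes: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop founder alleles through a pedigree, independently per variant.

    ``founder_genotypes`` has shape (..., n_founders, M); leading axes (for
    example a family axis) are broadcast.  Each non-founder receives one
    allele from each parent, drawn Binomial(1, parent_dosage / 2).
    """
    founder_genotypes = np.asarray(founder_genotypes)
    f_idx = pedigree.founder_indices
    if founder_genotypes.shape[-2] != len(f_idx):
        raise ValueError(
            f"founder genotypes cover {founder_genotypes.shape[-2]} founders, "
            f"pedigree has {len(f_idx)}"
        )
    out_shape = founder_genotypes.shape[:-2] + (pedigree.size, founder_genotypes.shape[-1])
    geno = np.zeros(out_shape, dtype=np.int8)
    pos = {m.id: i for i, m in enumerate(pedigree.members)}
    for k, i in enumerate(f_idx):
        geno[..., i, :] = founder_genotypes[..., k, :]
    for i, m in enumerate(pedigree.members):
        if m.is_founder:
            continue
        gf = geno[..., pos[m.father], :]
        gm = geno[..., pos[m.mother], :]
        geno[..., i, :] = rng.binomial(1, gf / 2.0) + rng.binomial(1, gm / 2.0)
    return geno


def simulate_cohort_genotypes(
    cfg: SimConfig,
    mafs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotype matrix (n_samples, M): gene-dropped families then singletons."""
    mafs = np.asarray(mafs, dtype=float)
    m = len(mafs)
    parts = []
    if cfg.n_families:
        n_f = len(cfg.pedigree.founder_indices)
        founders = rng.binomial(2, mafs, size=(cfg.n_families, n_f, m)).astype(np.int8)
        fams = gene_drop(cfg.pedigree, founders, rng)
        parts.append(fams.reshape(cfg.n_families * cfg.pedigree.size, m))
    if cfg.n_singletons:
        parts.append(rng.binomial(2, mafs, size=(cfg.n_singletons, m)).astype(np.int8))
    return np.concatenate(parts, axis=0)


# ---------------------------------------------------------------------
# frailty and survival times


def simulate_frailty(psi: np.ndarray, tau: float, rng: np.random.Generator) -> np.ndarray:
    """b = sqrt(tau) * L z with L the (jittered) Cholesky factor of psi."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    psi = np.asarray(psi, dtype=float)
    n = psi.shape[0]
    if tau == 0:
        return np.zeros(n)
    try:
        L = np.linalg.cholesky(psi)
    except np.linalg.LinAlgError:
        try:
            L = np.linalg.cholesky(psi + 1e-8 * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError("relationship matrix is not PSD even after jitter") from exc
    return np.sqrt(tau) * (L @ rng.standard_normal(n))


def simulate_cohort_frailty(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Frailties for the family-plus-singleton design (block structure)."""
    if cfg.tau == 0:
        return np.zeros(cfg.n_samples)
    parts = []
    if cfg.n_families:
        rel = cfg.pedigree.relationship()
        L = np.linalg.cholesky(rel + 1e-10 * np.eye(cfg.pedigree.size))
        z = rng.standard_normal((cfg.n_families, cfg.pedigree.size))
        parts.append(np.sqrt(cfg.tau) * (z @ L.T).reshape(-1))
    if cfg.n_singletons:
        parts.append(np.sqrt(cfg.tau) * rng.standard_normal(cfg.n_singletons))
    return np.concatenate(parts)


def simulate_tte(
    eta: np.ndarray,
    lambda_hazard: float,
    lambda_c: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential failure/censoring competition given a linear predictor."""
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("linear predictor contains non-finite values")
    if lambda_hazard <= 0 or lambda_c <= 0:
        raise ValueError("hazard rates must be positive")
    u = rng.uniform(size=len(eta))
    t_fail = -np.log(u) / (lambda_hazard * np.exp(eta))
    t_cens = rng.exponential(1.0 / lambda_c, size=len(eta))
    t = np.minimum(t_fail, t_cens)
    delta = (t_fail <= t_cens).astype(np.int64)
    return t, delta


def calibrate_lambda(
    eta: np.ndarray,
    lambda_c: float,
    target_censoring: float,
    tol: float = 0.005,
) -> float:
    """Baseline rate lambda achieving the target censored fraction.

    Competing exponentials give the closed-form event probability
    P(delta=1 | eta_i) = lam*exp(eta_i) / (lam*exp(eta_i) + lambda_c);
    the expected event fraction is strictly increasing in lam, so the
    root of mean_i P - (1 - target) is found by bracketing bisection.
    """
    if not 0 < target_censoring < 1:
        raise ValueError("target censoring must be in (0, 1)")
    eta = np.asarray(eta, dtype=float)
    w = np.exp(np.clip(eta, -500, 500))
    target_events = 1.0 - target_censoring

    def event_fraction(log_lam: float) -> float:
        lw = np.exp(log_lam) * w
        return float(np.mean(lw / (lw + lambda_c)))

    lo, hi = np.log(1e-8), np.log(1e8)
    if event_fraction(lo) > target_events or event_fraction(hi) < target_events:
        raise ValueError("cannot bracket the target censoring rate")
    log_lam = brentq(lambda x: event_fraction(x) - target_events, lo, hi, xtol=1e-10)
    assert abs(event_fraction(log_lam) - target_events) < tol
    return float(np.exp(log_lam))


def simulate_phenotypes(
    cfg: SimConfig,
    rng: np.random.Generator,
    causal: Optional[tuple[np.ndarray, float]] = None,
    power_design: bool = False,
) -> tuple[SurvivalPhenotype, np.ndarray]:
    """One phenotype replicate under the configured design.

    Null design: eta = 0.5 * X1 + b with X1 ~ N(0, 1).  The power design
    adds X2 ~ Bernoulli(0.5)-coded covariate per the alternative layout:
    eta = X1*a1 + X2*a2 + b + causal term.  ``causal`` supplies
    (dosage matrix, log hazard ratio) summed into eta.  Returns the
    phenotype and the frailty vector.
    """
    n = cfg.n_samples
    b = simulate_cohort_frailty(cfg, rng)
    if power_design:
        x1 = rng.binomial(1, 0.5, size=n).astype(float)
        x2 = rng.standard_normal(n)
        X = np.column_stack([x1, x2])
        eta = cfg.alpha * x1 + cfg.alpha * x2 + b
    else:
        x1 = rng.standard_normal(n)
        X = x1[:, None]
        eta = cfg.alpha * x1 + b
    if causal is not None:
        gmat, gamma = causal
        eta = eta + gmat @ np.full(gmat.shape[1], gamma)
    lam = calibrate_lambda(eta, cfg.lambda_c, cfg.target_censoring)
    t, delta = simulate_tte(eta, lam, cfg.lambda_c, rng)
    ids = [f"id{i + 1}" for i in range(n)]
    return SurvivalPhenotype(ids, t, delta, X), b


# ---------------------------------------------------------------------
# harnesses


def _grm_from_matrix(calls: np.ndarray) -> GRMOperator:
    return GRMOperator(GenotypeBlock.from_matrix(calls))


def _fit_pipeline(cfg: SimConfig, rng: np.random.Generator, phen: SurvivalPhenotype,
                  null_config: NullModelConfig | None = None):
    """Simulate a GRM panel, fit the null model and the variance ratio."""
    grm_mafs = draw_maf(rng, cfg.m_grm, *cfg.grm_maf_range)
    grm_calls = simulate_cohort_genotypes(cfg, grm_mafs, rng)
    grm_block = GenotypeBlock.from_matrix(grm_calls)
    grm = GRMOperator(grm_block)
    nm_cfg = null_config or NullModelConfig(seed=int(rng.integers(2**31 - 1)))
    fit = fit_null(phen, grm, nm_cfg)
    vr = estimate_variance_ratio(
        fit, grm, grm_block, seed=int(rng.integers(2**31 - 1)),
        cv_threshold=cfg.vr_cv_threshold,
    )
    return fit, grm, grm_block, vr


def run_type1_harness(
    cfg: SimConfig,
    n_null_variants: int,
    alphas: Sequence[float] = (0.05, 1e-2, 1e-3, 1e-4),
    mac_range: tuple[int, int] | None = None,
    chunk: int = 20000,
    null_config: NullModelConfig | None = None,
) -> pd.DataFrame:
    """Empirical type-I error of the SPA and normal branches under the null.

    Fits one null model, then tests fresh variants uncorrelated with the
    phenotype.  ``mac_range`` restricts the realized minor-allele counts
    (e.g. (20, 50) targets the rare-variant regime).  Returns exceedance
    proportions with 95% binomial confidence intervals per alpha.
    """
    rng = np.random.default_rng(cfg.seed)
    phen, _ = simulate_phenotypes(cfg, rng)
    fit, grm, grm_block, vr = _fit_pipeline(cfg, rng, phen, null_config)
    engine = AssociationEngine(fit, vr)
    opts = TestOptions()

    n = cfg.n_samples
    if mac_range is not None:
        lo_maf = max(mac_range[0] / (2.0 * n), 1e-5)
        hi_maf = mac_range[1] / (2.0 * n)
    else:
        lo_maf, hi_maf = cfg.test_maf_range

    p_spa_list, p_norm_list = [], []
    n_done = 0
    while n_done < n_null_variants:
        m = min(chunk, n_null_variants - n_done)
        mafs = draw_maf(rng, m, lo_maf, hi_maf)
        calls = simulate_cohort_genotypes(cfg, mafs, rng)
        res = test_dosage_matrix(calls.astype(float), fit, vr, opts, engine)
        keep = res["tested"]
        if mac_range is not None:
            keep &= (res["mac"] >= mac_range[0]) & (res["mac"] <= mac_range[1])
        p_spa_list.append(res["p_spa"][keep])
        p_norm_list.append(res["p_norm"][keep])
        n_done += m
    p_spa = np.concatenate(p_spa_list)
    p_norm = np.concatenate(p_norm_list)

    rows = []
    B = len(p_spa)
    for a in alphas:
        half = 1.96 * np.sqrt(a * (1 - a) / B)
        rows.append(
            {
                "alpha": a,
                "n_tests": B,
                "rate_spa": float(np.mean(p_spa < a)),
                "rate_norm": float(np.mean(p_norm < a)),
                "ci_low": a - half,
                "ci_high": a + half,
            }
        )
    return pd.DataFrame(rows)


def run_power_harness(
    cfg: SimConfig,
    gamma_grid: Sequence[float],
    maf_list: Sequence[float],
    n_reps: int = 20,
    n_markers: int = 10,
    alpha: float = 5e-8,
    compare_exact: bool = False,
    null_config: NullModelConfig | None = None,
) -> pd.DataFrame:
    """Empirical power of the SPA test (and optionally the exact-variance
    frailty score test on the same data) per (gamma, MAF) cell."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for gamma in gamma_grid:
        for maf in maf_list:
            hits_spa = hits_exact = total = 0
            for _ in range(n_reps):
                causal = simulate_cohort_genotypes(cfg, np.full(n_markers, maf), rng).astype(float)
                phen, _ = simulate_phenotypes(cfg, rng, causal=(causal, gamma), power_design=True)
                fit, grm, grm_block, vr = _fit_pipeline(cfg, rng, phen, null_config)
                res = test_dosage_matrix(causal, fit, vr, TestOptions(), None)
                tested = res["tested"]
                hits_spa += int(np.sum(res["p_spa"][tested] < alpha))
                total += int(tested.sum())
                if compare_exact:
                    calc = ExactVarianceCalculator(fit, grm)
                    from scipy.stats import norm as _norm

                    for j in np.flatnonzero(tested):
                        var_exact = calc.variance(res["Gtilde"][:, j])
                        s = res["T"][j] / np.sqrt(var_exact)
                        p = 2.0 * float(_norm.sf(abs(s)))
                        hits_exact += int(p < alpha)
            row = {
                "gamma": gamma,
                "maf": maf,
                "n_tests": total,
                "power_spa": hits_spa / max(total, 1),
            }
            if compare_exact:
                row["power_exact"] = hits_exact / max(total, 1)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# dataset emission (PLINK + phenotype TSV for the CLI path)


def simulate_dataset(cfg: SimConfig, prefix) -> dict:
    """Write GRM/test PLINK filesets and a phenotype table under ``prefix``."""
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    phen, _ = simulate_phenotypes(cfg, rng)

    def emit(mafs, tag):
        calls = simulate_cohort_genotypes(cfg, mafs, rng)
        variants = [
            VariantInfo("1", j + 1, f"{tag}{j + 1}", "A", "C") for j in range(len(mafs))
        ]
        block = GenotypeBlock.from_matrix(calls, variants, phen.sample_ids)
        write_plink(block, prefix.parent / f"{prefix.name}_{tag}")
        return prefix.parent / f"{prefix.name}_{tag}"

    grm_prefix = emit(draw_maf(rng, cfg.m_grm, *cfg.grm_maf_range), "grm")
    test_prefix = emit(draw_maf(rng, cfg.m_test, *cfg.test_maf_range), "test")

    pheno_path = prefix.parent / f"{prefix.name}_pheno.tsv"
    df = pd.DataFrame({"id": phen.sample_ids, "time": phen.t, "status": phen.delta})
    for k in range(phen.X.shape[1]):
        df[f"x{k + 1}"] = phen.X[:, k]
    df.to_csv(pheno_path, sep="\t", index=False)
    return {"grm": grm_prefix, "test": test_prefix, "pheno": pheno_path}
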