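"""Synthetic cohorts and GWAS summary statistics with known ground truth.

Two generators make every pipeline stage testable offline:

* :func:`simulate_summary_stats` draws a standard two-sample MR generative
  model: per-SNP exposure effects gamma_j, direct (pleiotropic) outcome
  effects alpha_j, true outcome effects Gamma_j = theta*gamma_j + alpha_j,
  and noisy estimates with sampling errors implied by the GWAS sample sizes
  and allele frequencies (sigma ~ 1/sqrt(2*n*f*(1-f)) on the standardised
  scale). Allele labels include configurable fractions of palindromic and
  strand-mislabelled variants so harmonisation is genuinely exercised.

* :func:`simulate_cohort` draws individual smoking histories with the
  UK-Biobank-like status mix (54% never / 36% former / 11% current by
  default), plausible ages and cigarettes/day, and a binary outcome from a
  logistic model on the true lifetime smoking index at a known half-life.

Both are deterministic given (config, seed) and round-trip through the
package's readers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smoking_index import lifetime_smoking_index
from .summary_stats import SummaryStatRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Generative parameters for two-sample summary statistics.

    ``pleiotropy`` selects the validity scenario: ``none`` (all instruments
    valid), ``balanced`` (direct effects with mean 0), ``directional``
    (non-zero mean, InSIDE holds), or ``inside_violating`` (direct effects
    correlated with instrument strength via ``inside_rho``). Default effect
    scale gives a mean instrument F statistic of roughly 30-60 at the default
    sample sizes, mirroring a well-powered instrument.
    """

    n_snp: int = 100
    theta: float = 0.5
    pleiotropy: str = "none"  # none | balanced | directional | inside_violating
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    inside_rho: float = 0.0
    gamma_sd: float = 0.03
    gamma_orientation: str = "signed"  # signed | positive (exposure-increasing allele)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    palindromic_frac: float = 0.1
    strand_flip_frac: float = 0.1
    allele_swap_frac: float = 0.1
    invalid_frac: float = 1.0  # fraction of SNPs receiving pleiotropic effects
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise ValueError("eaf_range must be within (0, 1)")
        if self.pleiotropy not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if self.gamma_orientation not in ("signed", "positive"):
            raise ValueError(f"unknown gamma_orientation {self.gamma_orientation!r}")
        for name in ("palindromic_frac", "strand_flip_frac", "allele_swap_frac", "invalid_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be within [0, 1]")


def simulate_summary_stats(
    cfg: SimulationConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], pd.DataFrame]:
    """Draw exposure and outcome summary statistics plus the latent truth.

    Returns ``(exposure_records, outcome_records, truth)`` where truth holds
    per-SNP gamma_j, alpha_j, Gamma_j, the validity flag and the bookkeeping
    flags (palindromic, strand-flipped, allele-swapped) used to mutate the
    outcome records' allele labels.
    """
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snp
    eaf = rng.uniform(*cfg.eaf_range, J)

    gamma = rng.normal(0.0, cfg.gamma_sd, J)
    if cfg.gamma_orientation == "positive":
        # instruments reported for the exposure-increasing allele, as GWAS
        # instrument tables conventionally are
        gamma = np.abs(gamma)
    invalid = rng.random(J) < cfg.invalid_frac
    if cfg.pleiotropy == "none":
        alpha = np.zeros(J)
        invalid = np.zeros(J, dtype=bool)
    elif cfg.pleiotropy == "balanced":
        alpha = np.where(invalid, rng.normal(0.0, cfg.alpha_sd, J), 0.0)
    elif cfg.pleiotropy == "directional":
        alpha = np.where(invalid, rng.normal(cfg.alpha_mean, cfg.alpha_sd, J), 0.0)
    else:  # inside_violating: direct effect correlated with instrument strength
        z = rng.normal(0.0, 1.0, J)
        std_g = (gamma - gamma.mean()) / (gamma.std() or 1.0)
        raw = cfg.inside_rho * std_g + np.sqrt(max(0.0, 1 - cfg.inside_rho**2)) * z
        alpha = np.where(invalid, cfg.alpha_mean + cfg.alpha_sd * raw, 0.0)
    Gamma = cfg.theta * gamma + alpha

    se_g = 1.0 / np.sqrt(2.0 * cfg.n_exposure * eaf * (1 - eaf))
    se_G = 1.0 / np.sqrt(2.0 * cfg.n_outcome * eaf * (1 - eaf))
    gamma_hat = gamma + se_g * rng.standard_normal(J)
    Gamma_hat = Gamma + se_G * rng.standard_normal(J)

    palindromic = rng.random(J) < cfg.palindromic_frac
    strand_flip = (rng.random(J) < cfg.strand_flip_frac) & ~palindromic
    allele_swap = rng.random(J) < cfg.allele_swap_frac

    # palindromic SNPs must have MAF < 0.3 to be resolvable downstream;
    # generated frequencies keep a mix so the MAF rule is exercised too
    ea = np.empty(J, dtype=object)
    oa = np.empty(J, dtype=object)
    for j in range(J):
        pairs = PALINDROMIC_PAIRS if palindromic[j] else NON_PALINDROMIC_PAIRS
        ea[j], oa[j] = pairs[rng.integers(0, len(pairs))]

    exposure, outcome = [], []
    for j in range(J):
        snp = f"rs{j + 1:06d}"
        chrom = str(1 + j % 22)
        pos = 1_000_000 + 20_000_000 * (j // 22)
        zstat = gamma_hat[j] / se_g[j]
        exposure.append(
            SummaryStatRecord(
                snp_id=snp, chrom=chrom, pos=pos, ea=ea[j], oa=oa[j],
                eaf=float(eaf[j]), beta=float(gamma_hat[j]), se=float(se_g[j]),
                pval=_two_sided_p(zstat), n=cfg.n_exposure,
            )
        )
        o_ea, o_oa, o_beta, o_eaf = ea[j], oa[j], Gamma_hat[j], eaf[j]
        if allele_swap[j]:
            o_ea, o_oa, o_beta, o_eaf = o_oa, o_ea, -o_beta, 1 - o_eaf
        if strand_flip[j]:
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        outcome.append(
            SummaryStatRecord(
                snp_id=snp, chrom=chrom, pos=pos, ea=o_ea, oa=o_oa,
                eaf=float(o_eaf), beta=float(o_beta), se=float(se_G[j]),
                pval=_two_sided_p(Gamma_hat[j] / se_G[j]), n=cfg.n_outcome,
            )
        )

    truth = pd.DataFrame(
        {
            "snp": [r.snp_id for r in exposure],
            "gamma": gamma,
            "alpha": alpha,
            "Gamma": Gamma,
            "eaf": eaf,
            "invalid": invalid,
            "palindromic": palindromic,
            "strand_flipped": strand_flip,
            "allele_swapped": allele_swap,
        }
    )
    truth.attrs["theta"] = cfg.theta
    return exposure, outcome, truth


def _two_sided_p(z: float) -> float:
    from scipy import stats

    return float(max(2 * stats.norm.sf(abs(z)), 5e-324))


# ---------------------------------------------------------------------------
# Individual-level cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Generative parameters for a synthetic smoking cohort.

    The default status mix matches the lifetime-smoking GWAS sample
    (54% never / 36% former / 11% current); assessment ages mimic a 40-69
    recruitment window; cigarettes/day are log-normal, clipped to [1, 150];
    the binary outcome follows a logistic model on the true index computed
    at ``tau_true``.
    """

    n_individuals: int = 10_000
    # exact never/former/current counts behind the published 54/36/11%
    status_mix: tuple[float, float, float] = (
        249_318 / 462_690,
        164_649 / 462_690,
        48_723 / 462_690,
    )
    cpd_log_mean: float = np.log(15.0)
    cpd_log_sd: float = 0.5
    age_assess_mean: float = 56.7
    age_assess_sd: float = 8.0
    age_init_mean: float = 17.0
    age_init_sd: float = 3.0
    tau_true: float = 18.0
    outcome_intercept: float = -3.0
    outcome_slope: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.status_mix) - 1.0) > 1e-9:
            raise ValueError("status_mix proportions must sum to 1")
        if any(p < 0 for p in self.status_mix):
            raise ValueError("status_mix proportions must be non-negative")



def simulate_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw smoking histories, a binary outcome, and the generative truth.

    Returns ``(histories, outcome, truth)``: histories with columns
    id/status/cpd/age_init/age_cess/age_assess (missing = NaN), outcome with
    id/outcome/true_score, and a truth dict holding tau_true and the logistic
    coefficients.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    status = rng.choice(["never", "former", "current"], size=n, p=cfg.status_mix)

    age_assess = np.clip(rng.normal(cfg.age_assess_mean, cfg.age_assess_sd, n), 40, 69)
    ever = status != "never"
    age_init = np.where(
        ever, np.clip(rng.normal(cfg.age_init_mean, cfg.age_init_sd, n), 10, 35), np.nan
    )
    # guarantee at least a year of smoking before assessment
    age_init = np.where(ever, np.minimum(age_init, age_assess - 1.0), np.nan)
    frac = rng.uniform(0.05, 0.95, n)
    age_cess = np.where(
        status == "former", age_init + frac * (age_assess - age_init), np.nan
    )
    cpd = np.where(
        ever,
        np.clip(np.round(rng.lognormal(cfg.cpd_log_mean, cfg.cpd_log_sd, n)), 1, 150),
        np.nan,
    )

    dur = np.where(status == "current", age_assess - age_init,
                   np.where(status == "former", age_cess - age_init, 0.0))
    tsc = np.where(status == "former", age_assess - age_cess, 0.0)
    score = np.array(
        [
            lifetime_smoking_index(d, t, c, cfg.tau_true) if e else 0.0
            for d, t, c, e in zip(dur, tsc, np.nan_to_num(cpd), ever)
        ]
    )
    logit = cfg.outcome_intercept + cfg.outcome_slope * score
    prob = 1.0 / (1.0 + np.exp(-logit))
    y = (rng.random(n) < prob).astype(int)

    ids = [f"id{i + 1:06d}" for i in range(n)]
    histories = pd.DataFrame(
        {
            "id": ids,
            "status": status,
            "cpd": cpd,
            "age_init": age_init,
            "age_cess": age_cess,
            "age_assess": age_assess,
        }
    )
    outcome = pd.DataFrame({"id": ids, "outcome": y, "true_score": score})
    truth = {
        "tau_true": cfg.tau_true,
        "outcome_intercept": cfg.outcome_intercept,
        "outcome_slope": cfg.outcome_slope,
    }
    return histories, outcome, truth


def write_truth(truth, path) -> None:
    """Write a truth record (DataFrame or dict) as a sidecar TSV."""
    if isinstance(truth, pd.DataFrame):
        truth.to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame([truth]).to_csv(path, sep="\t", index=False)
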