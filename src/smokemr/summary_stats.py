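"""GWAS summary statistics: reading, instrument selection and harmonisation.

Two-sample MR needs per-SNP effect estimates from two independent GWAS — the
SNP-exposure effects (gamma_hat, sigma_gamma) and the SNP-outcome effects
(Gamma_hat, sigma_Gamma) — expressed for the *same* effect allele. This module
reads heterogeneous summary-stat dialects into a common record, selects
independent genome-wide-significant instruments, and aligns the two studies:
sign-flipping swapped alleles, resolving strand complements, aligning
palindromic (A/T, C/G) variants by allele-frequency agreement when both minor
allele frequencies are below a limit (default 0.3), and substituting
user-supplied LD proxies for instruments missing from the outcome study.
Every input SNP is accounted for: retained, or dropped with a reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("smokemr")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# candidate header names per canonical column, tried case-insensitively
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "snp_id": ("snp", "snp_id", "rsid", "markername", "variant_id", "id"),
    "chrom": ("chr", "chrom", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "ea": ("ea", "a1", "effect_allele", "allele1", "alt"),
    "oa": ("oa", "a2", "other_allele", "allele2", "ref", "non_effect_allele"),
    "eaf": ("eaf", "frq", "freq", "af", "effect_allele_frequency", "maf"),
    "beta": ("beta", "b", "effect", "effect_size", "beta_hat"),
    "or": ("or", "odds_ratio"),
    "se": ("se", "stderr", "standard_error", "sebeta"),
    "pval": ("p", "pval", "pvalue", "p_value", "p-value"),
    "n": ("n", "samplesize", "sample_size", "neff"),
}

MANDATORY = ("snp_id", "ea", "oa", "se", "pval")


class SummaryStatFormatError(ValueError):
    """The summary-statistics file cannot be interpreted."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association estimate in one GWAS (effect-allele coded)."""

    snp_id: str
    ea: str
    oa: str
    beta: float
    se: float
    pval: float
    chrom: str = ""
    pos: int = 0
    eaf: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self) -> None:
        ea, oa = self.ea.upper(), self.oa.upper()
        object.__setattr__(self, "ea", ea)
        object.__setattr__(self, "oa", oa)
        if ea == oa:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: standard error must be positive")
        if not 0 < self.pval <= 1:
            raise ValueError(f"{self.snp_id}: p-value outside (0, 1]")
        if self.eaf is not None and not 0 <= self.eaf <= 1:
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]")


@dataclass
class InstrumentSet:
    """Instruments passing significance and LD-independence filters."""

    records: list[SummaryStatRecord]
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]


def read_summary_stats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> tuple[list[SummaryStatRecord], list[str]]:
    """Read a summary-statistics table into validated records.

    ``column_map`` maps canonical names (``snp_id``, ``ea``, ``oa``, ``beta``,
    ``or``, ``se``, ``pval``, ``eaf``, ``n``, ``chrom``, ``pos``) to the file's
    header names; anything not mapped is resolved through common aliases. A
    file carrying odds ratios instead of betas (an ``or`` column and no
    ``beta``) is log-transformed on read.

    Returns ``(records, rejection_log)``; malformed rows are rejected with a
    line-numbered message rather than aborting the read.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+", engine="python")
    resolved = _resolve_columns(df.columns, column_map)
    missing = [c for c in MANDATORY if c not in resolved]
    if "beta" not in resolved and "or" not in resolved:
        missing.append("beta")
    if missing:
        tried = {c: DEFAULT_ALIASES.get(c, ()) for c in missing}
        raise SummaryStatFormatError(
            f"missing mandatory column(s) {missing}; header names tried: {tried}"
        )

    use_or = "beta" not in resolved
    records: list[SummaryStatRecord] = []
    rejected: list[str] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            if use_or:
                or_val = float(row[resolved["or"]])
                if or_val <= 0:
                    raise ValueError("odds ratio must be positive")
                beta = math.log(or_val)
            else:
                beta = float(row[resolved["beta"]])
            rec = SummaryStatRecord(
                snp_id=str(row[resolved["snp_id"]]),
                ea=str(row[resolved["ea"]]),
                oa=str(row[resolved["oa"]]),
                beta=beta,
                se=float(row[resolved["se"]]),
                pval=float(row[resolved["pval"]]),
                chrom=str(row[resolved["chrom"]]) if "chrom" in resolved else "",
                pos=int(row[resolved["pos"]]) if "pos" in resolved else 0,
                eaf=_opt_float(row, resolved.get("eaf")),
                n=_opt_float(row, resolved.get("n")),
            )
        except (ValueError, TypeError, KeyError) as exc:
            msg = f"line {line_no}: rejected ({exc})"
            rejected.append(msg)
            logger.warning("%s: %s", path, msg)
            continue
        records.append(rec)
    return records, rejected


def _opt_float(row, col):
    if col is None:
        return None
    v = row[col]
    if pd.isna(v):
        return None
    return float(v)


def _resolve_columns(columns, column_map):
    lower = {str(c).lower(): c for c in columns}
    resolved: dict[str, str] = {}
    if column_map:
        for canon, name in column_map.items():
            if name in columns:
                resolved[canon] = name
            elif str(name).lower() in lower:
                resolved[canon] = lower[str(name).lower()]
    for canon, aliases in DEFAULT_ALIASES.items():
        if canon in resolved:
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    return resolved


def write_summary_stats(records: Iterable[SummaryStatRecord], path) -> None:
    """Write records as a TSV readable by :func:`read_summary_stats`."""
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "POS": [r.pos for r in records],
            "EA": [r.ea for r in records],
            "OA": [r.oa for r in records],
            "EAF": [r.eaf for r in records],
            "BETA": [r.beta for r in records],
            "SE": [r.se for r in records],
            "PVAL": [r.pval for r in records],
            "N": [r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Instrument selection (significance + clumping)
# ---------------------------------------------------------------------------

def select_instruments(
    records: Sequence[SummaryStatRecord],
    p_threshold: float = 5e-8,
    ld_info: Optional[pd.DataFrame] = None,
    distance_kb: float = 10_000.0,
    r2_threshold: float = 0.001,
) -> InstrumentSet:
    """Keep genome-wide-significant SNPs, greedily clumped for independence.

    SNPs with ``pval < p_threshold`` are sorted by p-value and retained
    unless within ``distance_kb`` of an already-retained SNP on the same
    chromosome *and* in LD with it at ``r² >= r2_threshold``. ``ld_info`` is a
    precomputed pairwise table with columns ``snp_a, snp_b, r2``; when a
    pair's r² is unknown the distance rule alone decides, logged as
    approximate.
    """
    provenance = [f"significance filter p < {p_threshold:g}"]
    sig = sorted((r for r in records if r.pval < p_threshold), key=lambda r: r.pval)
    provenance.append(f"{len(sig)}/{len(records)} SNPs pass significance")

    r2_lookup: dict[frozenset, float] = {}
    if ld_info is not None:
        for _, row in ld_info.iterrows():
            r2_lookup[frozenset((str(row["snp_a"]), str(row["snp_b"])))] = float(row["r2"])
    else:
        msg = (
            "no LD table supplied: clumping degrades to distance-only pruning "
            "(approximate — supply pairwise r2 for exact clumping)"
        )
        logger.warning(msg)
        provenance.append(msg)

    kept: list[SummaryStatRecord] = []
    for rec in sig:
        independent = True
        for other in kept:
            if rec.chrom != other.chrom:
                continue
            if abs(rec.pos - other.pos) > distance_kb * 1000:
                continue
            r2 = r2_lookup.get(frozenset((rec.snp_id, other.snp_id)))
            if r2 is None:
                if ld_info is not None:
                    logger.warning(
                        "r2 unknown for pair (%s, %s): applying distance rule only",
                        rec.snp_id,
                        other.snp_id,
                    )
                independent = False  # within window, no r2 to exonerate
                break
            if r2 >= r2_threshold:
                independent = False
                break
        if independent:
            kept.append(rec)
        else:
            provenance.append(f"{rec.snp_id} clumped (dependent on a retained SNP)")
    if not kept:
        logger.warning("instrument selection produced an empty set")
    provenance.append(f"{len(kept)} independent instruments retained")
    return InstrumentSet(records=kept, provenance=provenance)


# ---------------------------------------------------------------------------
# Harmonisation
# ---------------------------------------------------------------------------

def is_palindromic(ea: str, oa: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    return {ea.upper(), oa.upper()} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonisedPair:
    """An exposure/outcome record pair aligned to the exposure effect allele."""

    snp_id: str
    gamma_hat: float
    sigma_gamma: float
    Gamma_hat: float
    sigma_Gamma: float
    eaf: Optional[float]
    outcome_eaf: Optional[float] = None
    palindromic: bool = False
    flipped: bool = False
    proxied: bool = False
    proxy_id: Optional[str] = None


@dataclass(frozen=True)
class Dropped:
    snp_id: str
    reason: str


def harmonise(
    exposure: SummaryStatRecord,
    outcome: SummaryStatRecord,
    maf_limit: float = 0.3,
) -> HarmonisedPair | Dropped:
    """Align one outcome record to the exposure's effect allele.

    Alignment order: direct match; swapped alleles (flip beta sign, eaf :=
    1 − eaf); strand complement; complement-then-swap. Palindromic SNPs carry
    no strand information in their alleles, so they are oriented by allele
    frequency instead: kept only when both studies' minor allele frequencies
    are below ``maf_limit`` (frequencies near 0.5 cannot resolve the strand),
    and flipped when the effect-allele frequencies disagree across studies.
    Irreconcilable allele sets are dropped; drops are data, not errors.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValueError("harmonise() requires records for the same SNP")
    ea, oa = exposure.ea, exposure.oa

    if is_palindromic(ea, oa):
        if {outcome.ea, outcome.oa} != {ea, oa}:
            return Dropped(exposure.snp_id, "palindromic with irreconcilable alleles")
        if exposure.eaf is None or outcome.eaf is None:
            return Dropped(exposure.snp_id, "palindromic with missing allele frequency")
        maf_exp = min(exposure.eaf, 1 - exposure.eaf)
        maf_out = min(outcome.eaf, 1 - outcome.eaf)
        if maf_exp >= maf_limit or maf_out >= maf_limit:
            return Dropped(
                exposure.snp_id, f"palindromic with MAF >= {maf_limit:g} (ambiguous strand)"
            )
        # allele letters carry no strand information here: orient purely by
        # which side of 0.5 each study's effect-allele frequency falls on
        flip = (exposure.eaf < 0.5) != (outcome.eaf < 0.5)
        return _build_pair(exposure, outcome, flip=flip, palindromic=True)

    if (outcome.ea, outcome.oa) == (ea, oa):
        return _build_pair(exposure, outcome, flip=False)
    if (outcome.ea, outcome.oa) == (oa, ea):
        return _build_pair(exposure, outcome, flip=True)
    comp_ea, comp_oa = COMPLEMENT.get(outcome.ea), COMPLEMENT.get(outcome.oa)
    if (comp_ea, comp_oa) == (ea, oa):
        return _build_pair(exposure, outcome, flip=False)
    if (comp_ea, comp_oa) == (oa, ea):
        return _build_pair(exposure, outcome, flip=True)
    return Dropped(exposure.snp_id, "irreconcilable allele sets")


def _build_pair(exposure, outcome, flip: bool, palindromic: bool = False) -> HarmonisedPair:
    beta = -outcome.beta if flip else outcome.beta
    out_eaf = outcome.eaf
    if flip and out_eaf is not None:
        out_eaf = 1 - out_eaf
    return HarmonisedPair(
        snp_id=exposure.snp_id,
        gamma_hat=exposure.beta,
        sigma_gamma=exposure.se,
        Gamma_hat=beta,
        sigma_Gamma=outcome.se,
        eaf=exposure.eaf,
        outcome_eaf=out_eaf,
        palindromic=palindromic or is_palindromic(exposure.ea, exposure.oa),
        flipped=flip,
    )


@dataclass
class HarmonisedDataset:
    """Per-SNP aligned exposure/outcome effect pairs plus drop bookkeeping."""

    pairs: list[HarmonisedPair]
    dropped: list[Dropped] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def snp_ids(self) -> np.ndarray:
        return np.array([p.snp_id for p in self.pairs])

    @property
    def gamma_hat(self) -> np.ndarray:
        return np.array([p.gamma_hat for p in self.pairs])

    @property
    def sigma_gamma(self) -> np.ndarray:
        return np.array([p.sigma_gamma for p in self.pairs])

    @property
    def Gamma_hat(self) -> np.ndarray:
        return np.array([p.Gamma_hat for p in self.pairs])

    @property
    def sigma_Gamma(self) -> np.ndarray:
        return np.array([p.sigma_Gamma for p in self.pairs])

    @property
    def eaf(self) -> np.ndarray:
        return np.array([np.nan if p.eaf is None else p.eaf for p in self.pairs])

    def exclude(self, snp_ids: Iterable[str], reason: str = "excluded by request") -> "HarmonisedDataset":
        """Sensitivity-analysis filter: drop named SNPs (e.g. a gene region)."""
        excl = set(snp_ids)
        kept = [p for p in self.pairs if p.snp_id not in excl]
        dropped = list(self.dropped) + [
            Dropped(p.snp_id, reason) for p in self.pairs if p.snp_id in excl
        ]
        return HarmonisedDataset(pairs=kept, dropped=dropped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "gamma_hat": self.gamma_hat,
                "sigma_gamma": self.sigma_gamma,
                "Gamma_hat": self.Gamma_hat,
                "sigma_Gamma": self.sigma_Gamma,
                "eaf": self.eaf,
                "palindromic": [p.palindromic for p in self.pairs],
                "flipped": [p.flipped for p in self.pairs],
                "proxied": [p.proxied for p in self.pairs],
            }
        )

    def drop_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp": [d.snp_id for d in self.dropped], "reason": [d.reason for d in self.dropped]}
        )


def substitute_proxies(
    missing_snps: Sequence[str],
    proxy_table: pd.DataFrame,
    r2_min: float = 0.8,
) -> tuple[dict[str, tuple[str, dict[str, str]]], list[Dropped]]:
    """Resolve instruments absent from the outcome study via LD proxies.

    ``proxy_table`` is user-supplied (the package computes no LD) with columns
    ``target_snp, proxy_snp, r2, target_ea, proxy_ea, target_oa, proxy_oa``.
    For each missing SNP the best proxy with ``r² >= r2_min`` is chosen;
    otherwise the SNP is dropped with a logged reason. Returns a mapping
    ``target -> (proxy, allele_map)`` and the drop list, where ``allele_map``
    translates proxy alleles back to target alleles.
    """
    required = {"target_snp", "proxy_snp", "r2", "target_ea", "proxy_ea", "target_oa", "proxy_oa"}
    if not required.issubset(proxy_table.columns):
        raise SummaryStatFormatError(
            f"proxy table missing columns: {sorted(required - set(proxy_table.columns))}"
        )
    subs: dict[str, tuple[str, dict[str, str]]] = {}
    dropped: list[Dropped] = []
    for snp in missing_snps:
        candidates = proxy_table[
            (proxy_table["target_snp"] == snp) & (proxy_table["r2"] >= r2_min)
        ]
        if candidates.empty:
            dropped.append(Dropped(snp, f"absent from outcome, no proxy with r2 >= {r2_min:g}"))
            logger.warning("no proxy for %s at r2 >= %g", snp, r2_min)
            continue
        best = candidates.loc[candidates["r2"].idxmax()]
        allele_map = {
            str(best["proxy_ea"]).upper(): str(best["target_ea"]).upper(),
            str(best["proxy_oa"]).upper(): str(best["target_oa"]).upper(),
        }
        subs[snp] = (str(best["proxy_snp"]), allele_map)
    return subs, dropped


def harmonise_datasets(
    exposure_records: Sequence[SummaryStatRecord],
    outcome_records: Sequence[SummaryStatRecord],
    maf_limit: float = 0.3,
    proxy_table: Optional[pd.DataFrame] = None,
    r2_min: float = 0.8,
) -> HarmonisedDataset:
    """Align an instrument set against an outcome GWAS, proxying missing SNPs.

    Every exposure SNP ends up either in the harmonised pairs or in the drop
    log with a reason.
    """
    outcome_by_id = {r.snp_id: r for r in outcome_records}
    missing = [r.snp_id for r in exposure_records if r.snp_id not in outcome_by_id]
    subs: dict[str, tuple[str, dict[str, str]]] = {}
    dropped: list[Dropped] = []
    if missing and proxy_table is not None:
        subs, dropped = substitute_proxies(missing, proxy_table, r2_min=r2_min)
    elif missing:
        dropped = [Dropped(s, "absent from outcome study (no proxy table)") for s in missing]

    pairs: list[HarmonisedPair] = []
    for exp in exposure_records:
        if exp.snp_id in outcome_by_id:
            res = harmonise(exp, outcome_by_id[exp.snp_id], maf_limit=maf_limit)
            if isinstance(res, Dropped):
                dropped.append(res)
            else:
                pairs.append(res)
        elif exp.snp_id in subs:
            proxy_id, allele_map = subs[exp.snp_id]
            proxy_rec = outcome_by_id.get(proxy_id)
            if proxy_rec is None:
                dropped.append(Dropped(exp.snp_id, f"proxy {proxy_id} also absent from outcome"))
                continue
            try:
                mapped = replace(
                    proxy_rec,
                    snp_id=exp.snp_id,
                    ea=allele_map.get(proxy_rec.ea, proxy_rec.ea),
                    oa=allele_map.get(proxy_rec.oa, proxy_rec.oa),
                )
            except ValueError as exc:
                dropped.append(Dropped(exp.snp_id, f"proxy allele mapping failed ({exc})"))
                continue
            res = harmonise(exp, mapped, maf_limit=maf_limit)
            if isinstance(res, Dropped):
                dropped.append(res)
            else:
                pairs.append(
                    replace(res, proxied=True, proxy_id=proxy_id)
                )
        # SNPs in `missing` without a sub are already in `dropped`
    return HarmonisedDataset(pairs=pairs, dropped=dropped)
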