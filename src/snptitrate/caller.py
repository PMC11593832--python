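"""Diploid genotype-likelihood calling, joint allele-frequency EM and filtering.

The model is the standard count-based diploid caller for a biallelic SNP:
with r reads supporting ref, a reads supporting alt and per-read allele-flip
error rate e,

    l_RR = r*log(1-e) + a*log(e)
    l_RA = (r+a)*log(1/2)
    l_AA = r*log(e) + a*log(1-e)

Reads supporting neither allele carry no genotype information and are
ignored. Two calling modes are provided:

* ``"ml"``   - per-individual maximum likelihood (uniform genotype prior);
* ``"joint"`` - population-joint calling: the site's alt frequency p is
  estimated by EM over all individuals under a Hardy-Weinberg genotype
  prior, and each genotype is the posterior argmax under HWE(p).

Per-genotype quality GQ is the Phred-scaled probability that the chosen
genotype is wrong; per-site QUAL is the Phred-scaled joint posterior
probability that every individual is hom-ref (i.e. that the site is not a
variant) under HWE(p-hat).

Site filtering mirrors the standard VCFtools-style pass rules (call rate,
minor-allele frequency and count, biallelic, minimum QUAL) and the GATK-style
hard-filter bounds on INFO annotations for callsets read from real VCFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .errors import ConfigError, DataError, UndefinedMetricError
from .simcore import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, PileupMatrix

__all__ = [
    "CallSet",
    "FilterSpec",
    "HARD_FILTER_DEFAULTS",
    "genotype_log_likelihoods",
    "estimate_alt_frequency",
    "estimate_alt_frequencies",
    "joint_call",
    "site_filter",
    "hard_filter",
]

logger = logging.getLogger(__name__)

MAX_GQ = 99.0
_LOG10 = np.log(10.0)

#: GATK-style hard-filter bounds: a site FAILS if annotation op bound holds.
HARD_FILTER_DEFAULTS: Mapping[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "HaplotypeScore": (">", 13.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}


@dataclass
class CallSet:
    """Called genotypes plus per-site and per-genotype quality metadata.

    ``sites`` is a DataFrame with columns chrom, pos, ref, alt, qual, af,
    filter (and any INFO annotations carried from a VCF). ``gt`` is an int8
    matrix of shape (n_individuals, n_sites) using the package genotype
    codes; ``gq`` matches ``gt``. Filter status "." means not yet filtered.
    """

    sites: pd.DataFrame
    gt: np.ndarray
    gq: np.ndarray
    samples: list[str]
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None
    dp: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gt.shape != (len(self.samples), len(self.sites)):
            raise DataError(
                f"callset: gt shape {self.gt.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    def pass_mask(self) -> np.ndarray:
        """True for sites whose filter status is PASS (or not yet filtered)."""
        return self.sites["filter"].isin(("PASS", ".")).to_numpy()

    def subset(self, mask: np.ndarray) -> "CallSet":
        idx = np.asarray(mask)
        return CallSet(
            sites=self.sites.loc[idx].reset_index(drop=True),
            gt=self.gt[:, idx],
            gq=self.gq[:, idx],
            samples=list(self.samples),
            ad_ref=None if self.ad_ref is None else self.ad_ref[:, idx],
            ad_alt=None if self.ad_alt is None else self.ad_alt[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
            meta=dict(self.meta),
        )

    def passing(self) -> "CallSet":
        return self.subset(self.pass_mask())


@dataclass(frozen=True)
class FilterSpec:
    """Site-level pass rules; defaults are the standard stringent set.

    ``max_missing`` is the maximum missing-genotype fraction (0.05 means a
    >=95% call rate, the usual ``--max-missing 0.95`` convention, stored as
    a missing fraction to avoid double negatives). MAF/MAC are computed over
    called genotypes only.
    """

    max_missing: float = 0.05
    min_maf: float = 0.05
    min_mac: int = 3
    min_alleles: int = 2
    max_alleles: int = 2
    min_qual: float = 30.0
    hard_thresholds: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(HARD_FILTER_DEFAULTS)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing <= 1.0:
            raise ConfigError(f"max_missing: must be in [0, 1] (got {self.max_missing})")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ConfigError(f"min_maf: must be in [0, 0.5] (got {self.min_maf})")
        if self.min_mac < 0:
            raise ConfigError(f"min_mac: must be >= 0 (got {self.min_mac})")
        if self.min_qual < 0:
            raise ConfigError(f"min_qual: must be >= 0 (got {self.min_qual})")
        if not 1 <= self.min_alleles <= self.max_alleles:
            raise ConfigError("min_alleles/max_alleles: need 1 <= min <= max")


def genotype_log_likelihoods(ref_count, alt_count, error_rate: float) -> np.ndarray:
    """Log-likelihoods (l_RR, l_RA, l_AA) of the three diploid genotypes.

    Accepts scalars or arrays (broadcast); the genotype axis is appended
    last. With ``error_rate == 0`` a genotype contradicted by any read gets
    -inf, which is representable and handled downstream. (0, 0) reads give
    (0, 0, 0): no data, all genotypes equally likely.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ConfigError(f"error_rate: must be in [0, 0.5) (got {error_rate})")
    r = np.asarray(ref_count, dtype=np.float64)
    a = np.asarray(alt_count, dtype=np.float64)
    if np.any(r < 0) or np.any(a < 0):
        raise ConfigError("read counts must be >= 0")
    e = error_rate
    with np.errstate(divide="ignore"):
        ll_rr = xlogy(r, 1.0 - e) + xlogy(a, e)
        ll_ra = (r + a) * np.log(0.5)
        ll_aa = xlogy(r, e) + xlogy(a, 1.0 - e)
    return np.stack([ll_rr, ll_ra, ll_aa], axis=-1)


def _likelihoods(ref: np.ndarray, alt: np.ndarray, error_rate: float) -> np.ndarray:
    """Per-entry genotype likelihoods rescaled so the max is 1 (safe in e=0)."""
    ll = genotype_log_likelihoods(ref, alt, error_rate)
    m = ll.max(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        lik = np.exp(ll - m)
    return np.nan_to_num(lik, nan=0.0)  # -inf - -inf never happens; max is finite


def _hwe_priors(p: np.ndarray) -> np.ndarray:
    q = 1.0 - p
    return np.stack([q * q, 2.0 * p * q, p * p], axis=-1)


def estimate_alt_frequencies(
    ref: np.ndarray,
    alt: np.ndarray,
    error_rate: float,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """EM estimate of the population alt frequency at each site.

    ``ref``/``alt`` have shape (n_individuals, n_sites). Iterates posterior
    genotype responsibilities under an HWE(p) prior and updates p as the
    mean posterior alt dose, until max |delta p| < tol or ``max_iter``.
    Sites where no individual has informative reads return NaN.
    """
    ref = np.atleast_2d(ref)
    alt = np.atleast_2d(alt)
    lik = _likelihoods(ref, alt, error_rate)
    n_ind = ref.shape[0]

    covered = (ref + alt).sum(axis=0) > 0
    tot_ref = ref.sum(axis=0).astype(float)
    tot_alt = alt.sum(axis=0).astype(float)
    # initialise from pooled counts (add-one smoothing keeps p in (0,1))
    p = (tot_alt + 1.0) / (tot_ref + tot_alt + 2.0)

    for _ in range(max_iter):
        w = _hwe_priors(p)[None, :, :] * lik  # (I, S, 3)
        denom = w.sum(axis=-1, keepdims=True)
        gamma = w / np.where(denom > 0, denom, 1.0)
        p_new = (0.5 * gamma[..., 1] + gamma[..., 2]).mean(axis=0)
        delta = np.abs(p_new - p).max() if p.size else 0.0
        p = p_new
        if delta < tol:
            break
    p = np.where(covered, p, np.nan)
    return p


def estimate_alt_frequency(ref: np.ndarray, alt: np.ndarray, error_rate: float) -> float:
    """Single-site EM allele frequency from per-individual (ref, alt) counts."""
    ref = np.asarray(ref, dtype=np.int64).reshape(-1, 1)
    alt = np.asarray(alt, dtype=np.int64).reshape(-1, 1)
    p = estimate_alt_frequencies(ref, alt, error_rate)[0]
    if np.isnan(p):
        raise UndefinedMetricError("no individual has informative reads at this site")
    return float(p)


def _phred(prob_wrong: np.ndarray) -> np.ndarray:
    return -10.0 * np.log10(np.clip(prob_wrong, 1e-300, None))


def joint_call(
    pileups: PileupMatrix,
    sites: pd.DataFrame,
    error_rate: float = 0.01,
    mode: str = "ml",
    samples: Sequence[str] | None = None,
) -> CallSet:
    """Call genotypes at every site and emit the variant sites as a CallSet.

    ``mode="ml"`` takes the per-individual likelihood argmax (uniform
    prior); ``mode="joint"`` uses an HWE prior at the EM-estimated alt
    frequency. Entries with zero informative reads are missing. Argmax ties
    resolve to the lowest genotype code (hom-ref < het < hom-alt). A site is
    emitted as a SNP iff QUAL > 0 and at least one called genotype carries
    the alt allele.
    """
    if mode not in ("ml", "joint"):
        raise ConfigError(f"mode: must be 'ml' or 'joint' (got {mode!r})")
    ref, alt = pileups.ref, pileups.alt
    if ref.shape[1] != len(sites):
        raise DataError(f"pileups have {ref.shape[1]} sites, table has {len(sites)}")
    n_ind = ref.shape[0]
    if samples is None:
        samples = [f"ind{i + 1}" for i in range(n_ind)]

    lik = _likelihoods(ref, alt, error_rate)
    p_hat = estimate_alt_frequencies(ref, alt, error_rate)
    p_safe = np.nan_to_num(p_hat, nan=0.0)

    joint_prior = _hwe_priors(p_safe)[None, :, :]
    post_joint = joint_prior * lik
    post_joint = post_joint / np.clip(post_joint.sum(axis=-1, keepdims=True), 1e-300, None)

    if mode == "joint":
        post = post_joint
    else:
        post = lik / np.clip(lik.sum(axis=-1, keepdims=True), 1e-300, None)

    call = post.argmax(axis=-1).astype(np.int8)  # first max wins: RR < RA < AA
    best = np.take_along_axis(post, call[..., None].astype(np.int64), axis=-1)[..., 0]
    gq = np.minimum(_phred(1.0 - best), MAX_GQ)

    missing = pileups.informative() == 0
    call[missing] = GT_MISSING
    gq[missing] = 0.0

    # QUAL: Phred of P(all individuals hom-ref | data, p-hat) under the HWE prior
    qual = _phred(post_joint[..., 0]).sum(axis=0)
    qual = np.where(np.isnan(p_hat), 0.0, qual)

    called_variant = ((call == GT_HET) | (call == GT_HOM_ALT)).any(axis=0)
    emit = (qual > 0) & called_variant

    out_sites = sites.loc[emit, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    out_sites["qual"] = qual[emit]
    out_sites["af"] = p_safe[emit]
    out_sites["filter"] = "."
    return CallSet(
        sites=out_sites,
        gt=call[:, emit],
        gq=gq[:, emit],
        samples=list(samples),
        ad_ref=ref[:, emit],
        ad_alt=alt[:, emit],
        dp=pileups.total()[:, emit],
        meta={"mode": mode, "error_rate": error_rate},
    )


def _allele_stats(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (missing fraction, MAF, MAC) over called genotypes."""
    called = gt != GT_MISSING
    n_called = called.sum(axis=0)
    miss_frac = 1.0 - n_called / gt.shape[0]
    alt_dose = np.where(called, gt, 0).sum(axis=0)
    n_alleles = 2 * n_called
    mac = np.minimum(alt_dose, n_alleles - alt_dose)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n_alleles > 0, mac / np.maximum(n_alleles, 1), 0.0)
    return miss_frac, maf, mac


def site_filter(callset: CallSet, spec: FilterSpec | None = None) -> CallSet:
    """Assign PASS / named-failure labels site by site; genotypes unchanged.

    Rules are checked in order max_missing, maf, mac, biallelic, minQ and a
    failing site is labelled with the first violated rule.
    """
    spec = spec if spec is not None else FilterSpec()
    if callset.n_sites == 0:
        out = replace(callset)
        out.sites = callset.sites.copy()
        return out

    miss_frac, maf, mac = _allele_stats(callset.gt)
    ref_len = callset.sites["ref"].str.len().to_numpy()
    alt_ok = callset.sites["alt"].isin(("A", "C", "G", "T")).to_numpy()
    biallelic = (ref_len == 1) & alt_ok & (2 >= spec.min_alleles) & (2 <= spec.max_alleles)
    qual = callset.sites["qual"].to_numpy()

    labels = np.full(callset.n_sites, "PASS", dtype=object)
    checks = [
        ("max_missing", miss_frac > spec.max_missing + 1e-12),
        ("maf", maf < spec.min_maf - 1e-12),
        ("mac", mac < spec.min_mac),
        ("not_biallelic", ~biallelic),
        ("minQ", qual < spec.min_qual),
    ]
    for label, failed in reversed(checks):
        labels[failed] = label

    out = replace(callset)
    out.sites = callset.sites.copy()
    out.sites["filter"] = labels
    return out


def hard_filter(
    callset: CallSet, thresholds: Mapping[str, tuple[str, float]] | None = None
) -> CallSet:
    """Apply hard bounds on per-site INFO annotations (real-VCF callsets).

    A site fails if any *present* annotation violates its bound, with the
    bound direction as given ("<" means fail when value < bound, ">" fail
    when value > bound; both strict). Absent annotation columns skip their
    rule with a logged warning; unparseable values fail as ``hard:parse``.
    """
    thresholds = thresholds if thresholds is not None else HARD_FILTER_DEFAULTS
    out = replace(callset)
    out.sites = callset.sites.copy()
    labels = np.asarray(out.sites.get("filter", "."), dtype=object)
    if labels.ndim == 0:
        labels = np.full(callset.n_sites, ".", dtype=object)
    labels = np.where(np.isin(labels, (".",)), "PASS", labels)

    applied = 0
    for name, (op, bound) in thresholds.items():
        if name not in out.sites.columns:
            logger.warning("hard_filter: annotation %s absent, rule skipped", name)
            continue
        applied += 1
        raw = out.sites[name]
        vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        malformed = np.isnan(vals) & raw.notna().to_numpy()
        present = ~np.isnan(vals)
        violated = np.zeros(callset.n_sites, dtype=bool)
        if op == "<":
            violated[present] = vals[present] < bound
        elif op == ">":
            violated[present] = vals[present] > bound
        else:
            raise ConfigError(f"hard_thresholds: unknown operator {op!r} for {name}")
        newly = violated & (labels == "PASS")
        labels[newly] = f"hard:{name}"
        bad = malformed & (labels == "PASS")
        labels[bad] = "hard:parse"
    if applied == 0:
        logger.warning("hard_filter: no annotations present; all sites pass vacuously")
    out.sites["filter"] = labels
    return out
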