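"""Concordance statistics between a query callset and a reference callset.

The reference is normally the highest-depth (20x) callset, mirroring the
standard titration design: SNP calling rate is the ratio of SNP-site counts,
genotyping accuracy is the proportion of matched genotype pairs that agree
(pairs missing on either side are excluded from the denominator and reported
separately), and discordant pairs are classified by error type, with the
heterozygote-called-homozygous categories being the signature of allele
dropout at low coverage. Site identity is the full (chrom, pos, ref, alt)
key: records whose alleles differ (including ref/alt swaps) are never
harmonized, they are counted as allele mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import CallSet
from .errors import DataError, UndefinedMetricError
from .simcore import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, is_transition

__all__ = [
    "PairedLoci",
    "ErrorBreakdown",
    "match_sites",
    "snp_calling_rate",
    "genotyping_accuracy",
    "classify_errors",
    "zygosity_proportions",
    "titv_ratio",
    "region_breakdown",
    "confusion_matrix",
]

ERROR_CATEGORIES = (
    "het_to_hom_ref",
    "het_to_hom_alt",
    "hom_to_het",
    "hom_ref_to_hom_alt",
    "to_missing",
)


@dataclass
class PairedLoci:
    """Genotype pairs at sites shared (by full allele key) between callsets.

    ``ref_gt`` and ``qry_gt`` have shape (n_individuals, n_matched).
    ``query_only`` / ``reference_only`` count unmatched SNP sites;
    ``allele_mismatch`` counts positions present in both callsets whose
    ref/alt alleles differ.
    """

    keys: pd.DataFrame
    ref_gt: np.ndarray
    qry_gt: np.ndarray
    samples: list[str]
    query_only: int = 0
    reference_only: int = 0
    allele_mismatch: int = 0

    @property
    def n_matched(self) -> int:
        return len(self.keys)


@dataclass
class ErrorBreakdown:
    """Counts of discordant genotype-pair categories (reference -> query).

    ``to_missing`` counts pairs called in the reference but missing in the
    query (the "NA" category); whether it enters the denominator of
    ``proportions`` is controlled by ``include_na``.
    """

    counts: dict = field(default_factory=lambda: {c: 0 for c in ERROR_CATEGORIES})
    include_na: bool = False

    @property
    def n_discordant(self) -> int:
        """Discordant pairs with both genotypes called."""
        return sum(self.counts[c] for c in ERROR_CATEGORIES if c != "to_missing")

    def denominator(self) -> int:
        return self.n_discordant + (self.counts["to_missing"] if self.include_na else 0)

    def proportions(self) -> dict:
        denom = self.denominator()
        cats = ERROR_CATEGORIES if self.include_na else ERROR_CATEGORIES[:-1]
        if denom == 0:
            return {c: 0.0 for c in cats}
        return {c: self.counts[c] / denom for c in cats}

    @property
    def het_to_hom_share(self) -> float:
        """Share of errors that are a heterozygote called homozygous."""
        props = self.proportions()
        return props["het_to_hom_ref"] + props["het_to_hom_alt"]


def _site_keys(cs: CallSet) -> pd.DataFrame:
    keys = cs.sites[["chrom", "pos", "ref", "alt"]].copy()
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].head()
        raise DataError(f"duplicate site keys in callset, e.g.\n{dup}")
    return keys


def match_sites(query: CallSet, reference: CallSet) -> PairedLoci:
    """Inner-join the two callsets on (chrom, pos, ref, alt).

    Sites sharing a position but not the allele pair (e.g. ref/alt swapped)
    are counted in ``allele_mismatch`` and excluded from the pairing.
    """
    if query.samples != reference.samples:
        raise DataError(
            "sample lists differ between callsets; align samples before matching"
        )
    qk = _site_keys(query).reset_index(names="qi")
    rk = _site_keys(reference).reset_index(names="ri")
    merged = qk.merge(rk, on=["chrom", "pos", "ref", "alt"], how="inner")
    pos_shared = qk.merge(rk, on=["chrom", "pos"], how="inner", suffixes=("_q", "_r"))
    allele_mismatch = int(len(pos_shared) - len(merged))

    qi = merged["qi"].to_numpy()
    ri = merged["ri"].to_numpy()
    # positions are unique within a callset, so each allele mismatch consumes
    # exactly one query and one reference site
    return PairedLoci(
        keys=merged[["chrom", "pos", "ref", "alt"]].reset_index(drop=True),
        ref_gt=reference.gt[:, ri],
        qry_gt=query.gt[:, qi],
        samples=list(query.samples),
        query_only=int(len(qk) - len(pos_shared)),
        reference_only=int(len(rk) - len(pos_shared)),
        allele_mismatch=allele_mismatch,
    )


def snp_calling_rate(query: CallSet, reference: CallSet) -> float:
    """Count of query SNP sites over count of reference SNP sites."""
    if reference.n_sites == 0:
        raise UndefinedMetricError("reference callset has no SNP sites")
    return query.n_sites / reference.n_sites


def genotyping_accuracy(paired: PairedLoci) -> float:
    """Fraction of matched genotype pairs, called on both sides, that agree."""
    both = (paired.ref_gt != GT_MISSING) & (paired.qry_gt != GT_MISSING)
    n_both = int(both.sum())
    if n_both == 0:
        raise UndefinedMetricError("no genotype pair is called on both sides")
    return float((paired.ref_gt[both] == paired.qry_gt[both]).mean())


def classify_errors(paired: PairedLoci, include_na: bool = False) -> ErrorBreakdown:
    """Assign every discordant (reference -> query) pair to one error category.

    Categories: het called hom-ref, het called hom-alt, any homozygote
    called het, hom-ref/hom-alt confusion (either direction), and reference
    calls missing in the query (NA). ``include_na`` adds the NA category to
    the proportion denominator.
    """
    r, q = paired.ref_gt, paired.qry_gt
    ref_called = r != GT_MISSING
    both = ref_called & (q != GT_MISSING)
    disc = both & (r != q)

    counts = {
        "het_to_hom_ref": int((disc & (r == GT_HET) & (q == GT_HOM_REF)).sum()),
        "het_to_hom_alt": int((disc & (r == GT_HET) & (q == GT_HOM_ALT)).sum()),
        "hom_to_het": int((disc & (r != GT_HET) & (q == GT_HET)).sum()),
        "hom_ref_to_hom_alt": int(
            (disc & (((r == GT_HOM_REF) & (q == GT_HOM_ALT)) | ((r == GT_HOM_ALT) & (q == GT_HOM_REF)))).sum()
        ),
        "to_missing": int((ref_called & (q == GT_MISSING)).sum()),
    }
    return ErrorBreakdown(counts=counts, include_na=include_na)


def confusion_matrix(paired: PairedLoci) -> pd.DataFrame:
    """4x4 table of (reference genotype x query genotype) pair counts."""
    order = [GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING]
    names = ["hom_ref", "het", "hom_alt", "missing"]
    table = np.zeros((4, 4), dtype=np.int64)
    for i, rg in enumerate(order):
        for j, qg in enumerate(order):
            table[i, j] = int(((paired.ref_gt == rg) & (paired.qry_gt == qg)).sum())
    return pd.DataFrame(table, index=pd.Index(names, name="reference"), columns=pd.Index(names, name="query"))


def zygosity_proportions(callset: CallSet, pass_only: bool = True) -> tuple[float, float, float]:
    """(het, hom, missing) proportions over genotype entries at SNP sites."""
    cs = callset.passing() if pass_only else callset
    if cs.n_sites == 0:
        raise UndefinedMetricError("no SNP sites in callset")
    gt = cs.gt
    n = gt.size
    het = float((gt == GT_HET).sum() / n)
    hom = float(((gt == GT_HOM_REF) | (gt == GT_HOM_ALT)).sum() / n)
    missing = float((gt == GT_MISSING).sum() / n)
    return het, hom, missing


def titv_ratio(callset: CallSet, pass_only: bool = True) -> float:
    """Transitions (A<->G, C<->T) over transversions among SNP sites."""
    cs = callset.passing() if pass_only else callset
    if cs.n_sites == 0:
        raise UndefinedMetricError("no SNP sites in callset")
    ti = is_transition(cs.sites["ref"].to_numpy(), cs.sites["alt"].to_numpy())
    n_tv = int((~ti).sum())
    if n_tv == 0:
        raise UndefinedMetricError("no transversion sites; Ti/Tv undefined")
    return float(ti.sum() / n_tv)


def region_breakdown(
    callset: CallSet, annotations: pd.DataFrame, pass_only: bool = True
) -> tuple[dict, dict]:
    """Region proportions over SNP sites, plus nested exonic effect classes.

    ``annotations`` must carry chrom, pos, region (and effect for exonic
    sites), e.g. the simulation truth sidecar. Sites without a region label
    raise a data error listing offending positions.
    """
    cs = callset.passing() if pass_only else callset
    if cs.n_sites == 0:
        raise UndefinedMetricError("no SNP sites in callset")
    ann_cols = ["chrom", "pos", "region"] + (["effect"] if "effect" in annotations else [])
    joined = cs.sites[["chrom", "pos"]].merge(annotations[ann_cols], on=["chrom", "pos"], how="left")
    unlabeled = joined["region"].isna()
    if unlabeled.any():
        where = joined.loc[unlabeled, ["chrom", "pos"]].head(10).to_records(index=False)
        raise DataError(f"sites without region label, e.g. {list(where)}")
    region_props = joined["region"].value_counts(normalize=True).to_dict()
    effect_props: dict = {}
    if "effect" in joined:
        exonic = joined[joined["region"] == "exonic"]
        if len(exonic):
            effect_props = exonic["effect"].value_counts(normalize=True).to_dict()
    return region_props, effect_props
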