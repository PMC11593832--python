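"""Titration driver, VCF/TSV input-output and run configuration.

``run_titration`` reproduces the depth-gradient experiment end to end:
simulate population truth and 20x-depth pileups once, binomially thin them
to each gradient depth, call and filter genotypes per depth, and score every
depth against the base-depth callset (SNP calling rate, genotyping accuracy,
error-type breakdown, Ti/Tv, zygosity and region proportions). Because the
simulation knows the truth, truth-based accuracy is reported alongside the
reference-based numbers that a real titration can compute.

``concord_vcfs`` is the real-data entry point: two VCF 4.2 files (a
low-depth callset and a high-depth reference) are read, optionally
filtered, matched on the full allele key and scored with the same metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics as mt
from .caller import CallSet, FilterSpec, hard_filter, joint_call, site_filter
from .errors import ConfigError, DataError, UndefinedMetricError, VCFFormatError
from .simcore import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    PileupMatrix,
    SimConfig,
    downsample_pileups,
    simulate_genotypes,
    simulate_pileups,
    simulate_sites,
    stage_rng,
)

__all__ = [
    "DEFAULT_GRADIENT",
    "RunConfig",
    "TitrationRun",
    "run_titration",
    "concord_vcfs",
    "read_vcf",
    "write_vcf",
    "write_truth_vcf",
    "write_sites_tsv",
    "read_sites_tsv",
    "write_pileups_tsv",
    "read_pileups_tsv",
    "load_run_config",
    "plot_titration",
]

logger = logging.getLogger(__name__)

#: the standard 13-step depth gradient (x coverage)
DEFAULT_GRADIENT = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 15.0, 18.0, 20.0)


@dataclass(frozen=True)
class RunConfig:
    """Everything a titration run needs, reproducible from ``sim.seed``."""

    sim: SimConfig = field(default_factory=SimConfig)
    base_depth: float = 20.0
    depth_gradient: tuple = DEFAULT_GRADIENT
    caller_mode: str = "ml"
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    compare_prefilter: bool = False

    def __post_init__(self) -> None:
        if self.base_depth <= 0:
            raise ConfigError(f"base_depth: must be > 0 (got {self.base_depth})")
        grad = tuple(float(d) for d in self.depth_gradient)
        if len(grad) == 0:
            raise ConfigError("depth_gradient: must be non-empty")
        if any(d <= 0 for d in grad):
            raise ConfigError("depth_gradient: depths must be > 0")
        if any(d > self.base_depth for d in grad):
            raise ConfigError(
                f"depth_gradient: every depth must be <= base_depth {self.base_depth}"
            )
        if list(grad) != sorted(grad):
            raise ConfigError("depth_gradient: must be sorted ascending")
        if self.caller_mode not in ("ml", "joint"):
            raise ConfigError(f"caller_mode: must be 'ml' or 'joint' (got {self.caller_mode!r})")
        object.__setattr__(self, "depth_gradient", grad)


@dataclass
class TitrationRun:
    """Output bundle of :func:`run_titration`."""

    table: pd.DataFrame
    sites: pd.DataFrame
    truth_gt: np.ndarray
    base_callset: CallSet
    callsets: dict = field(default_factory=dict)
    confusions: dict = field(default_factory=dict)
    breakdowns: dict = field(default_factory=dict)


def _truth_accuracy(callset: CallSet, sites: pd.DataFrame, truth_gt: np.ndarray) -> float:
    """Accuracy of called genotypes against the simulation truth."""
    idx = sites.reset_index().set_index("pos").loc[callset.sites["pos"], "index"].to_numpy()
    truth = truth_gt[:, idx]
    called = callset.gt != GT_MISSING
    if not called.any():
        return float("nan")
    return float((callset.gt[called] == truth[called]).mean())


def _depth_row(
    depth: float,
    query: CallSet,
    reference: CallSet,
    sites: pd.DataFrame,
    truth_gt: np.ndarray,
) -> tuple[dict, mt.PairedLoci, mt.ErrorBreakdown]:
    paired = mt.match_sites(query, reference)
    row: dict = {"depth": depth, "n_snps": query.n_sites}
    row["calling_rate"] = (
        mt.snp_calling_rate(query, reference) if reference.n_sites else float("nan")
    )
    try:
        row["accuracy"] = mt.genotyping_accuracy(paired)
    except UndefinedMetricError:
        row["accuracy"] = float("nan")
    row["n_pairs_compared"] = int(
        ((paired.ref_gt != GT_MISSING) & (paired.qry_gt != GT_MISSING)).sum()
    )

    breakdown = mt.classify_errors(paired, include_na=False)
    props = breakdown.proportions()
    for cat, val in props.items():
        row[f"err_{cat}"] = val
    row["err_het_to_hom_share"] = breakdown.het_to_hom_share
    row["n_discordant"] = breakdown.n_discordant
    row["n_to_missing"] = breakdown.counts["to_missing"]
    with_na = mt.classify_errors(paired, include_na=True)
    row["err_het_to_hom_share_with_na"] = with_na.het_to_hom_share

    try:
        row["titv"] = mt.titv_ratio(query)
    except UndefinedMetricError:
        row["titv"] = float("nan")
    try:
        het, hom, missing = mt.zygosity_proportions(query)
        row.update({"het_prop": het, "hom_prop": hom, "missing_prop": missing})
    except UndefinedMetricError:
        row.update({"het_prop": float("nan"), "hom_prop": float("nan"), "missing_prop": float("nan")})
    try:
        regions, effects = mt.region_breakdown(query, sites)
        for r in ("intergenic", "intronic", "exonic"):
            row[f"prop_{r}"] = regions.get(r, 0.0)
        row["prop_nonsynonymous_in_exonic"] = effects.get("nonsynonymous", 0.0)
    except (UndefinedMetricError, DataError):
        for r in ("intergenic", "intronic", "exonic"):
            row[f"prop_{r}"] = float("nan")
        row["prop_nonsynonymous_in_exonic"] = float("nan")

    row["accuracy_vs_truth"] = _truth_accuracy(query, sites, truth_gt)
    row["novel_at_depth"] = paired.query_only
    row["allele_mismatch"] = paired.allele_mismatch
    return row, paired, breakdown


def run_titration(
    config: RunConfig,
    outdir: str | Path | None = None,
    keep_callsets: bool = False,
) -> TitrationRun:
    """Run the full depth-titration experiment; one result row per depth.

    Truth and base-depth pileups are simulated once at ``base_depth``; each
    gradient depth d reuses them thinned by d/base_depth, so depths are
    nested subsamples of the same reads exactly as in a read-level
    down-sampling design. Both callsets are site-filtered before comparison
    unless ``compare_prefilter`` is set. Fully reproducible from the seed.
    """
    sim = config.sim.with_depth(config.base_depth)
    sites = simulate_sites(sim)
    truth_gt = simulate_genotypes(sites, sim)
    base_pileups = simulate_pileups(truth_gt, sim)
    logger.info("simulated %d sites x %d individuals at %gx", sim.n_sites, sim.n_individuals, config.base_depth)

    def call_and_filter(pileups: PileupMatrix) -> CallSet:
        cs = joint_call(pileups, sites, error_rate=sim.error_rate, mode=config.caller_mode)
        cs = site_filter(cs, config.filter_spec)
        logger.info(
            "called %d SNP sites, %d PASS", cs.n_sites, int(cs.pass_mask().sum())
        )
        return cs.passing() if not config.compare_prefilter else cs

    base_cs = call_and_filter(base_pileups)

    rows = []
    run = TitrationRun(table=pd.DataFrame(), sites=sites, truth_gt=truth_gt, base_callset=base_cs)
    for i, depth in enumerate(config.depth_gradient):
        frac = depth / config.base_depth
        seed_d = int(
            stage_rng(sim.seed, "downsample", i).integers(0, 2**31 - 1)
        )
        thinned = downsample_pileups(base_pileups, frac, seed=seed_d)
        cs = call_and_filter(thinned) if frac < 1.0 else base_cs
        row, paired, breakdown = _depth_row(depth, cs, base_cs, sites, truth_gt)
        rows.append(row)
        run.confusions[depth] = mt.confusion_matrix(paired)
        run.breakdowns[depth] = breakdown
        if keep_callsets:
            run.callsets[depth] = cs

    run.table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        run.table.to_csv(outdir / "titration.tsv", sep="\t", index=False, float_format="%.10g")
        for depth, conf in run.confusions.items():
            conf.to_csv(outdir / f"confusion_{depth:g}x.tsv", sep="\t")
    return run


# ---------------------------------------------------------------------------
# VCF input / output


def write_vcf(callset: CallSet, path: str | Path) -> None:
    """Write a CallSet as plain-text VCF 4.2 with GT:DP:GQ:AD fields."""
    path = Path(path)
    sites = callset.sites
    have_counts = callset.ad_ref is not None and callset.ad_alt is not None
    fmt = "GT:DP:GQ:AD" if have_counts else "GT:GQ"
    filters = sorted(
        set(sites["filter"].unique()) - {"PASS", "."}
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snptitrate\n")
        for f in filters:
            fh.write(f'##FILTER=<ID={f},Description="Failed {f} site filter">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Estimated alt allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(callset.samples) + "\n")
        gt_str = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", GT_MISSING: "./."}
        for j in range(callset.n_sites):
            rec = sites.iloc[j]
            filt = rec["filter"] if rec["filter"] != "." else "."
            info = f"AF={rec['af']:.6g}" if "af" in sites.columns and pd.notna(rec.get("af")) else "."
            cols = [
                str(rec["chrom"]),
                str(int(rec["pos"])),
                ".",
                str(rec["ref"]),
                str(rec["alt"]),
                f"{rec['qual']:.4f}" if pd.notna(rec["qual"]) else ".",
                filt,
                info,
                fmt,
            ]
            for i in range(callset.n_individuals):
                g = gt_str[int(callset.gt[i, j])]
                if have_counts:
                    dp = int(callset.dp[i, j]) if callset.dp is not None else int(
                        callset.ad_ref[i, j] + callset.ad_alt[i, j]
                    )
                    cols.append(
                        f"{g}:{dp}:{int(round(callset.gq[i, j]))}:"
                        f"{int(callset.ad_ref[i, j])},{int(callset.ad_alt[i, j])}"
                    )
                else:
                    cols.append(f"{g}:{int(round(callset.gq[i, j]))}")
            fh.write("\t".join(cols) + "\n")


# cyvcf2 gt_types codes
_CYVCF2_GT = {0: GT_HOM_REF, 1: GT_HET, 2: GT_MISSING, 3: GT_HOM_ALT}

_INFO_ANNOTATIONS = ("QD", "FS", "MQ", "HaplotypeScore", "MQRankSum", "ReadPosRankSum")


def read_vcf(path: str | Path) -> CallSet:
    """Read a VCF 4.2 into a CallSet; biallelic SNP records only.

    Multiallelic, indel and symbolic-ALT records are skipped and counted in
    ``callset.meta["skipped"]``. Missing genotypes ("./.") map to the
    package missing code. Hard-filter INFO annotations (QD, FS, MQ, ...)
    are carried into the site table when present.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise VCFFormatError(f"{path}: no such file")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VCFFormatError(f"{path}: cannot parse VCF header ({exc})") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VCFFormatError(f"{path}: VCF has no sample columns / GT field")

    recs = []
    gts, gqs, adr, ada, dps = [], [], [], [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or v.ALT[0] not in ("A", "C", "G", "T") or len(v.REF) != 1:
            skipped += 1
            continue
        rec = {
            "chrom": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": v.ALT[0],
            "qual": v.QUAL if v.QUAL is not None else float("nan"),
            "af": v.INFO.get("AF", float("nan")),
            "filter": v.FILTER if v.FILTER is not None else "PASS",
        }
        for name in _INFO_ANNOTATIONS:
            val = v.INFO.get(name)
            if val is not None:
                rec[name] = val
        recs.append(rec)
        gts.append([_CYVCF2_GT[t] for t in v.gt_types])

        def fmt(field):  # cyvcf2 raises KeyError for fields absent from the header
            try:
                return v.format(field)
            except KeyError:
                return None

        gq = fmt("GQ")
        gqs.append(
            [0.0] * len(samples) if gq is None else np.nan_to_num(gq.reshape(-1).astype(float)).tolist()
        )
        ad = fmt("AD")
        if ad is not None and ad.shape[1] >= 2:
            adr.append(ad[:, 0].clip(min=0).tolist())
            ada.append(ad[:, 1].clip(min=0).tolist())
        dp = fmt("DP")
        if dp is not None:
            dps.append(dp.reshape(-1).clip(min=0).tolist())
    if skipped:
        logger.warning("%s: skipped %d non-biallelic-SNP records", path, skipped)

    sites = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt", "qual", "af", "filter"] if not recs else None)
    if not recs:
        sites = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "qual", "af", "filter"])
    gt = np.asarray(gts, dtype=np.int8).T if gts else np.zeros((len(samples), 0), dtype=np.int8)
    gq = np.asarray(gqs, dtype=float).T if gqs else np.zeros((len(samples), 0))
    return CallSet(
        sites=sites,
        gt=gt,
        gq=gq,
        samples=samples,
        ad_ref=np.asarray(adr, dtype=np.int64).T if len(adr) == len(recs) and recs else None,
        ad_alt=np.asarray(ada, dtype=np.int64).T if len(ada) == len(recs) and recs else None,
        dp=np.asarray(dps, dtype=np.int64).T if len(dps) == len(recs) and recs else None,
        meta={"skipped": skipped, "path": str(path)},
    )


def write_truth_vcf(
    sites: pd.DataFrame, truth_gt: np.ndarray, path: str | Path, samples: Sequence[str] | None = None
) -> None:
    """Export the simulation truth (genotypes as GT) as VCF 4.2."""
    n_ind = truth_gt.shape[0]
    samples = list(samples) if samples is not None else [f"ind{i + 1}" for i in range(n_ind)]
    truth_sites = sites[["chrom", "pos", "ref", "alt"]].copy()
    truth_sites["qual"] = float("nan")
    truth_sites["af"] = sites["alt_freq"]
    truth_sites["filter"] = "."
    cs = CallSet(
        sites=truth_sites,
        gt=truth_gt,
        gq=np.zeros_like(truth_gt, dtype=float),
        samples=samples,
    )
    write_vcf(cs, path)


def write_sites_tsv(sites: pd.DataFrame, path: str | Path) -> None:
    """Truth sidecar: chrom, pos, alt_freq, mut_class, region, effect."""
    sites.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pileups_tsv(
    pileups: PileupMatrix, sites: pd.DataFrame, path: str | Path, samples: Sequence[str] | None = None
) -> None:
    """Long-format pileup export: chrom, pos, individual, ref/alt/error counts."""
    n_ind, n_sites = pileups.shape
    samples = list(samples) if samples is not None else [f"ind{i + 1}" for i in range(n_ind)]
    df = pd.DataFrame(
        {
            "chrom": np.repeat(sites["chrom"].to_numpy(), n_ind),
            "pos": np.repeat(sites["pos"].to_numpy(), n_ind),
            "individual": np.tile(np.asarray(samples), n_sites),
            "ref_count": pileups.ref.T.reshape(-1),
            "alt_count": pileups.alt.T.reshape(-1),
            "error_count": pileups.err.T.reshape(-1),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pileups_tsv(path: str | Path) -> tuple[PileupMatrix, pd.DataFrame, list]:
    """Inverse of :func:`write_pileups_tsv`; returns (pileups, site keys, samples)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "individual", "ref_count", "alt_count", "error_count"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: pileup TSV missing columns {sorted(required - set(df.columns))}")
    samples = list(pd.unique(df["individual"]))
    keys = df[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    n_ind, n_sites = len(samples), len(keys)
    if len(df) != n_ind * n_sites:
        raise DataError(f"{path}: expected {n_ind * n_sites} rows, found {len(df)}")
    pivot = {c: df[c].to_numpy().reshape(n_sites, n_ind).T for c in ("ref_count", "alt_count", "error_count")}
    return PileupMatrix(pivot["ref_count"], pivot["alt_count"], pivot["error_count"]), keys, samples


# ---------------------------------------------------------------------------
# real-data concordance


def concord_vcfs(
    query_vcf: str | Path,
    reference_vcf: str | Path,
    apply_filters: bool = True,
    filter_spec: FilterSpec | None = None,
    out_tsv: str | Path | None = None,
) -> dict:
    """Genotype concordance between two VCF callsets (query vs reference).

    With ``apply_filters`` both callsets get the hard filter (on whatever
    annotations they carry) followed by the site filter, and only PASS
    sites are compared. Sample sets must agree; query samples are reordered
    to the reference order.
    """
    q = read_vcf(query_vcf)
    r = read_vcf(reference_vcf)
    if set(q.samples) != set(r.samples):
        only_q = sorted(set(q.samples) - set(r.samples))
        only_r = sorted(set(r.samples) - set(q.samples))
        raise DataError(
            f"sample sets differ: query-only {only_q}, reference-only {only_r}"
        )
    if q.samples != r.samples:
        order = [q.samples.index(s) for s in r.samples]
        q = CallSet(
            sites=q.sites, gt=q.gt[order], gq=q.gq[order], samples=list(r.samples),
            ad_ref=None if q.ad_ref is None else q.ad_ref[order],
            ad_alt=None if q.ad_alt is None else q.ad_alt[order],
            dp=None if q.dp is None else q.dp[order], meta=q.meta,
        )

    if apply_filters:
        spec = filter_spec if filter_spec is not None else FilterSpec()
        q = site_filter(hard_filter(q, spec.hard_thresholds), spec).passing()
        r = site_filter(hard_filter(r, spec.hard_thresholds), spec).passing()

    paired = mt.match_sites(q, r)
    report: dict = {
        "n_query_snps": q.n_sites,
        "n_reference_snps": r.n_sites,
        "n_matched": paired.n_matched,
        "novel_in_query": paired.query_only,
        "reference_only": paired.reference_only,
        "allele_mismatch": paired.allele_mismatch,
    }
    try:
        report["calling_rate"] = mt.snp_calling_rate(q, r)
    except UndefinedMetricError:
        report["calling_rate"] = float("nan")
    try:
        report["accuracy"] = mt.genotyping_accuracy(paired)
    except UndefinedMetricError:
        report["accuracy"] = float("nan")
    breakdown = mt.classify_errors(paired, include_na=False)
    report.update({f"err_{k}": v for k, v in breakdown.counts.items()})
    report["err_het_to_hom_share"] = breakdown.het_to_hom_share
    for cs, tag in ((q, "query"), (r, "reference")):
        try:
            report[f"titv_{tag}"] = mt.titv_ratio(cs, pass_only=False)
        except UndefinedMetricError:
            report[f"titv_{tag}"] = float("nan")
    if out_tsv is not None:
        pd.DataFrame([report]).to_csv(out_tsv, sep="\t", index=False, float_format="%.10g")
    return report


# ---------------------------------------------------------------------------
# configuration and plotting


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML/JSON document with explicit validation."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: config document must be a mapping")
    doc = dict(doc)
    sim_keys = {f for f in SimConfig.__dataclass_fields__}
    sim_doc = {k: doc.pop(k) for k in list(doc) if k in sim_keys}
    if "afs_spec" in sim_doc and isinstance(sim_doc["afs_spec"], (list, tuple)):
        sim_doc["afs_spec"] = tuple(sim_doc["afs_spec"])
    filt_doc = doc.pop("filter", {}) or {}
    run_keys = {"base_depth", "depth_gradient", "caller_mode", "compare_prefilter"}
    unknown = set(doc) - run_keys
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    try:
        sim = SimConfig(**sim_doc)
        spec = FilterSpec(**filt_doc)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    if "depth_gradient" in doc:
        doc["depth_gradient"] = tuple(doc["depth_gradient"])
    return RunConfig(sim=sim, filter_spec=spec, **doc)


def plot_titration(table: pd.DataFrame, outdir: str | Path) -> list:
    """Optional figures: discovery, accuracy/TiTv and error-share curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].plot(table["depth"], table["n_snps"], "o-")
    axes[0].set(xlabel="depth (x)", ylabel="PASS SNP sites", title="SNP discovery")
    axes[1].plot(table["depth"], table["calling_rate"], "o-")
    axes[1].set(xlabel="depth (x)", ylabel="calling rate vs base", title="Detection rate")
    fig.tight_layout()
    p = outdir / "discovery.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].plot(table["depth"], table["accuracy"], "o-")
    axes[0].set(xlabel="depth (x)", ylabel="genotyping accuracy", title="Accuracy vs base callset")
    axes[1].plot(table["depth"], table["titv"], "o-")
    axes[1].set(xlabel="depth (x)", ylabel="Ti/Tv", title="Ti/Tv ratio")
    fig.tight_layout()
    p = outdir / "accuracy.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(table["depth"], table["err_het_to_hom_share"], "o-", label="het->hom share")
    ax.plot(table["depth"], table["err_hom_to_het"], "s-", label="hom->het share")
    ax.set(xlabel="depth (x)", ylabel="share of discordant pairs", title="Error types")
    ax.legend()
    fig.tight_layout()
    p = outdir / "errors.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
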