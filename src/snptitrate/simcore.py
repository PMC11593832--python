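"""Synthetic population truth and per-site read pileups.

The generator produces, in order:

1. a table of biallelic SNP sites (alleles, population alt-allele frequency,
   transition/transversion class, genomic region, exonic effect class),
2. a diploid genotype matrix drawn under Hardy-Weinberg equilibrium at each
   site's alt frequency, independently across individuals and sites,
3. a per-individual, per-site read pileup: total depth is Poisson (or fixed)
   and each read reports the true allele, flipped to the other allele with a
   per-read error probability.

Down-sampling to a lower target depth is binomial thinning of the counts,
which is distributionally identical to read-level subsampling for per-site
count statistics: thinning Poisson(lambda) coverage by f yields
Poisson(lambda * f) coverage.

Genotypes are encoded as ``int8``: 0 = hom-ref, 1 = het, 2 = hom-alt,
-1 = missing. Truth matrices contain no missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "GT_HOM_REF",
    "GT_HET",
    "GT_HOM_ALT",
    "GT_MISSING",
    "SimConfig",
    "PileupMatrix",
    "stage_rng",
    "simulate_sites",
    "simulate_genotypes",
    "simulate_pileups",
    "downsample_pileups",
    "is_transition",
]

GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

BASES = ("A", "C", "G", "T")
#: transition partner of each base (A<->G, C<->T)
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSION_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

REGIONS = ("intergenic", "intronic", "exonic")
EFFECT_CLASSES = (
    "nonsynonymous",
    "synonymous",
    "stopgain",
    "stoploss",
    "frameshift",
    "splice",
)

#: schema of the site-truth table returned by :func:`simulate_sites`
SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "alt_freq", "mut_class", "region", "effect")

# deterministic sub-stream labels for the master seed
_STAGES = {"sites": 0, "genotypes": 1, "pileups": 2, "downsample": 3}


def stage_rng(seed: int, stage: str, *keys: int) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream for a pipeline stage.

    A single master ``seed`` plus a (stage, \\*keys) label maps to a fixed
    :class:`numpy.random.SeedSequence` spawn key, so adding or reordering
    down-sampling calls never perturbs the streams of other stages.
    """
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGES[stage], *keys))
    )


def _check_props(name: str, props: Mapping[str, float], labels: Sequence[str]) -> None:
    if set(props) != set(labels):
        raise ConfigError(f"{name}: expected labels {sorted(labels)}, got {sorted(props)}")
    vals = np.asarray([props[k] for k in labels], dtype=float)
    if np.any(vals < 0):
        raise ConfigError(f"{name}: proportions must be non-negative")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{name}: proportions must sum to 1 (got {vals.sum():.12g})")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic population and sequencing model.

    Defaults describe a population of 31 diploid individuals with ~20%
    heterozygous genotypes (alt frequencies uniform on [0.05, 0.18]),
    transition:transversion odds 1.55, region proportions ~84/11/5%
    intergenic/intronic/exonic, 20x mean Poisson coverage and a 1% per-read
    allele-flip error rate.
    """

    n_individuals: int = 31
    n_sites: int = 100_000
    #: ("uniform", lo, hi) or ("beta", a, b) over the alt-allele frequency
    afs_spec: tuple = ("uniform", 0.05, 0.18)
    #: transition:transversion odds; P(transition) = titv / (1 + titv)
    titv_param: float = 1.55
    region_props: Mapping[str, float] = field(
        default_factory=lambda: {"intergenic": 0.8445, "intronic": 0.1059, "exonic": 0.0496}
    )
    lof_props: Mapping[str, float] = field(
        default_factory=lambda: {
            "nonsynonymous": 0.60,
            "synonymous": 0.30,
            "splice": 0.04,
            "frameshift": 0.03,
            "stopgain": 0.02,
            "stoploss": 0.01,
        }
    )
    mean_depth: float = 20.0
    error_rate: float = 0.01
    depth_model: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError(f"n_individuals: must be >= 1 (got {self.n_individuals})")
        if self.n_sites < 1:
            raise ConfigError(f"n_sites: must be >= 1 (got {self.n_sites})")
        if self.mean_depth < 0:
            raise ConfigError(f"mean_depth: must be >= 0 (got {self.mean_depth})")
        if not 0.0 <= self.error_rate < 0.5:
            raise ConfigError(f"error_rate: must be in [0, 0.5) (got {self.error_rate})")
        if self.titv_param < 0:
            raise ConfigError(f"titv_param: must be >= 0 (got {self.titv_param})")
        if self.depth_model not in ("poisson", "fixed"):
            raise ConfigError(f"depth_model: must be 'poisson' or 'fixed' (got {self.depth_model!r})")
        if self.depth_model == "fixed" and abs(self.mean_depth - round(self.mean_depth)) > 1e-12:
            raise ConfigError(f"mean_depth: fixed depth model requires an integer (got {self.mean_depth})")
        self._check_afs()
        _check_props("region_props", self.region_props, REGIONS)
        _check_props("lof_props", self.lof_props, EFFECT_CLASSES)

    def _check_afs(self) -> None:
        spec = tuple(self.afs_spec)
        if len(spec) != 3 or spec[0] not in ("uniform", "beta"):
            raise ConfigError(
                f"afs_spec: expected ('uniform', lo, hi) or ('beta', a, b), got {spec!r}"
            )
        kind, p1, p2 = spec
        if kind == "uniform":
            if not (0 < p1 <= p2 < 1):
                raise ConfigError(f"afs_spec: uniform bounds need 0 < lo <= hi < 1, got {spec!r}")
        else:
            if p1 <= 0 or p2 <= 0:
                raise ConfigError(f"afs_spec: beta parameters must be positive, got {spec!r}")

    def with_depth(self, mean_depth: float) -> "SimConfig":
        return replace(self, mean_depth=mean_depth)

    def draw_alt_freqs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        kind, p1, p2 = tuple(self.afs_spec)
        if kind == "uniform":
            p = rng.uniform(p1, p2, size=n)
        else:
            p = rng.beta(p1, p2, size=n)
        # keep frequencies in the open interval so HWE genotype draws stay diploid
        return np.clip(p, 1e-12, 1.0 - 1e-12)


@dataclass
class PileupMatrix:
    """Per-individual, per-site allele-support counts.

    ``ref`` / ``alt`` count reads supporting the two site alleles;
    ``err`` counts reads supporting neither (third-allele artefacts). The
    total of the three is the sequenced depth at that entry.
    """

    ref: np.ndarray
    alt: np.ndarray
    err: np.ndarray

    def __post_init__(self) -> None:
        if not (self.ref.shape == self.alt.shape == self.err.shape):
            raise ConfigError("pileup: ref/alt/err shapes differ")
        for name in ("ref", "alt", "err"):
            arr = getattr(self, name)
            if np.any(arr < 0):
                raise ConfigError(f"pileup: negative {name} counts")

    @property
    def shape(self) -> tuple:
        return self.ref.shape

    def total(self) -> np.ndarray:
        """Sequenced depth per entry."""
        return self.ref + self.alt + self.err

    def informative(self) -> np.ndarray:
        """Reads supporting ref or alt (what genotype likelihoods use)."""
        return self.ref + self.alt

    def copy(self) -> "PileupMatrix":
        return PileupMatrix(self.ref.copy(), self.alt.copy(), self.err.copy())


def simulate_sites(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the site-truth table: one row per biallelic SNP site.

    Positions are strictly increasing on a single chromosome. Each site is a
    transition with probability titv/(1+titv); the ref base is uniform over
    ACGT and the alt base is the transition partner or a uniformly chosen
    transversion partner. Region labels are multinomial over
    ``region_props``; exonic sites additionally get an effect class from
    ``lof_props``, all other sites have effect ``"none"``.
    """
    rng = rng if rng is not None else stage_rng(config.seed, "sites")
    n = config.n_sites

    pos = np.cumsum(rng.integers(1, 1000, size=n))
    ref_idx = rng.integers(0, 4, size=n)
    ref = np.asarray(BASES)[ref_idx]

    p_ti = config.titv_param / (1.0 + config.titv_param)
    is_ti = rng.random(n) < p_ti
    tv_pick = rng.integers(0, 2, size=n)
    alt = np.empty(n, dtype=object)
    for i, base in enumerate(BASES):
        m = ref == base
        alt[m & is_ti] = TRANSITION_PARTNER[base]
        for j in (0, 1):
            alt[m & ~is_ti & (tv_pick == j)] = TRANSVERSION_PARTNERS[base][j]

    alt_freq = config.draw_alt_freqs(n, rng)
    region_probs = [config.region_props[r] for r in REGIONS]
    region = rng.choice(REGIONS, size=n, p=region_probs)
    effect = np.full(n, "none", dtype=object)
    exonic = region == "exonic"
    if exonic.any():
        eff_probs = [config.lof_props[c] for c in EFFECT_CLASSES]
        effect[exonic] = rng.choice(EFFECT_CLASSES, size=int(exonic.sum()), p=eff_probs)

    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos.astype(np.int64),
            "ref": ref,
            "alt": alt.astype(str),
            "alt_freq": alt_freq,
            "mut_class": np.where(is_ti, "transition", "transversion"),
            "region": region,
            "effect": effect,
        }
    )


def is_transition(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Boolean mask: True where ref->alt is A<->G or C<->T."""
    ref = np.asarray(ref, dtype=str)
    alt = np.asarray(alt, dtype=str)
    purine = np.isin(ref, ("A", "G"))
    purine_alt = np.isin(alt, ("A", "G"))
    return purine == purine_alt


def simulate_genotypes(
    sites: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the truth genotype matrix under HWE at each site's alt frequency.

    Returns an int8 array of shape (n_individuals, n_sites) with no missing
    entries; genotype probabilities are ((1-p)^2, 2p(1-p), p^2).
    """
    if len(sites) == 0:
        raise ConfigError("sites: must be non-empty")
    rng = rng if rng is not None else stage_rng(config.seed, "genotypes")
    p = sites["alt_freq"].to_numpy()
    u = rng.random((config.n_individuals, len(sites)))
    p_hom_alt = p * p
    p_not_ref = p_hom_alt + 2.0 * p * (1.0 - p)
    gt = np.where(u < p_hom_alt, GT_HOM_ALT, np.where(u < p_not_ref, GT_HET, GT_HOM_REF))
    return gt.astype(np.int8)


def simulate_pileups(
    genotypes: np.ndarray, config: SimConfig, rng: np.random.Generator | None = None
) -> PileupMatrix:
    """Draw read pileups given truth genotypes.

    Depth per entry is Poisson(mean_depth) (or exactly ``mean_depth`` with
    the fixed depth model). Each read reports the allele carried by the
    sampled chromosome, flipped to the other allele with probability
    ``error_rate``; for heterozygotes the two alleles are equally likely and
    the flip leaves the 1/2:1/2 split unchanged.
    """
    rng = rng if rng is not None else stage_rng(config.seed, "pileups")
    gt = np.asarray(genotypes)
    if np.any(gt == GT_MISSING):
        raise ConfigError("genotypes: truth matrix must not contain missing entries")

    if config.depth_model == "fixed":
        depth = np.full(gt.shape, int(round(config.mean_depth)), dtype=np.int64)
    else:
        depth = rng.poisson(config.mean_depth, size=gt.shape)

    e = config.error_rate
    alt = np.zeros(gt.shape, dtype=np.int64)
    hom_ref = gt == GT_HOM_REF
    het = gt == GT_HET
    hom_alt = gt == GT_HOM_ALT
    # binomial() broadcasts over the masked depth arrays
    alt[hom_ref] = rng.binomial(depth[hom_ref], e)
    alt[het] = rng.binomial(depth[het], 0.5)
    alt[hom_alt] = depth[hom_alt] - rng.binomial(depth[hom_alt], e)
    ref = depth - alt
    return PileupMatrix(ref=ref, alt=alt, err=np.zeros_like(ref))


def downsample_pileups(pileups: PileupMatrix, fraction: float, seed: int) -> PileupMatrix:
    """Binomially thin every count by ``fraction``.

    Equivalent in distribution to read-level subsampling: each read is kept
    independently with probability ``fraction``, so Poisson(lambda) coverage
    becomes Poisson(lambda * fraction).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(f"fraction: must be in [0, 1] (got {fraction})")
    if fraction == 1.0:
        return pileups.copy()
    if fraction == 0.0:
        z = np.zeros_like(pileups.ref)
        return PileupMatrix(z, z.copy(), z.copy())
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES["downsample"],)))
    return PileupMatrix(
        ref=rng.binomial(pileups.ref, fraction),
        alt=rng.binomial(pileups.alt, fraction),
        err=rng.binomial(pileups.err, fraction),
    )
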