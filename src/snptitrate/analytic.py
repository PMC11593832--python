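"""Closed-form allele-dropout probabilities and expected-accuracy curves.

At a heterozygous site, each error-free read is drawn from one of the two
chromosomes with probability 1/2. With exactly k >= 1 reads the probability
that every read comes from the same chromosome — so an error-free ML caller
returns a homozygote — is

    P(dropout | k) = 2 * (1/2)^k = 2^(1-k).

Under Poisson(lambda) coverage the unconditional dropout probability (the
k >= 1 terms summed) has the closed form

    P(dropout) = sum_k Pois(k; lambda) * 2^(1-k)   (k >= 1)
               = 2 * (exp(-lambda/2) - exp(-lambda)),

and conditioning on the site being covered divides by 1 - exp(-lambda).
These are the design oracles for the central low-depth failure mode
(heterozygotes miscalled as homozygotes); with read errors e > 0 or a
population prior they become bounds rather than equalities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "p_missing",
    "p_dropout_fixed",
    "p_dropout_poisson",
    "expected_accuracy",
    "design_table",
]


def p_missing(lam: float) -> float:
    """Probability a genotype has no reads at all: exp(-lambda)."""
    if lam < 0:
        raise ConfigError(f"lam: must be >= 0 (got {lam})")
    return float(np.exp(-lam))


def p_dropout_fixed(k) -> float | np.ndarray:
    """Dropout probability with exactly ``k`` error-free reads: 2^(1-k)."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 1) or not np.issubdtype(k_arr.dtype, np.integer):
        raise ConfigError(f"k: must be an integer >= 1 (got {k!r})")
    out = 2.0 ** (1.0 - k_arr)
    return float(out) if np.isscalar(k) else out


def p_dropout_poisson(lam, conditional: bool = False):
    """Dropout probability under Poisson(lambda) coverage.

    Unconditional form (k >= 1 summed): 2*(exp(-lambda/2) - exp(-lambda)).
    With ``conditional=True`` the probability is taken given the site is
    covered (divided by 1 - exp(-lambda)).
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ConfigError(f"lam: must be > 0 (got {lam!r})")
    out = 2.0 * (np.exp(-lam_arr / 2.0) - np.exp(-lam_arr))
    if conditional:
        out = out / (1.0 - np.exp(-lam_arr))
    return float(out) if np.isscalar(lam) else out


def expected_accuracy(lam: float, het_fraction: float, error_rate: float = 0.0) -> float:
    """Expected genotype accuracy among covered genotypes, error-free ML caller.

    Homozygotes are always called correctly at ``error_rate = 0``; the only
    error is heterozygote dropout, so accuracy = 1 - het_fraction *
    P(dropout | covered). Only ``error_rate == 0`` has a closed form; the
    argument is kept explicit so callers state the assumption.
    """
    if not 0.0 <= het_fraction <= 1.0:
        raise ConfigError(f"het_fraction: must be in [0, 1] (got {het_fraction})")
    if error_rate != 0.0:
        raise ConfigError("expected_accuracy: closed form assumes error_rate = 0")
    return 1.0 - het_fraction * p_dropout_poisson(lam, conditional=True)


def design_table(depths, het_fractions) -> pd.DataFrame:
    """Depth-design grid: dropout, missingness and expected accuracy.

    One row per (mean depth, het fraction) pair; the TSV the CLI ``design``
    subcommand prints.
    """
    rows = []
    for lam in depths:
        for h in het_fractions:
            rows.append(
                {
                    "mean_depth": lam,
                    "het_fraction": h,
                    "p_missing": p_missing(lam),
                    "p_dropout": p_dropout_poisson(lam),
                    "p_dropout_covered": p_dropout_poisson(lam, conditional=True),
                    "expected_accuracy": expected_accuracy(lam, h),
                }
            )
    return pd.DataFrame(rows)
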