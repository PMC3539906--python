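"""Binomial model of hexamer site occurrence in random DNA.

In a uniform i.i.d. base model a fixed 6-mer matches a given window with
probability p = 4^-6 = 1/4096, and an L-bp fragment offers n = L - 5
overlapping windows.  Treating windows as independent Bernoulli trials gives
the standard binomial approximations used when sizing assembly modules:

* P(no site in 5000 bp) = (1-p)^4995 ~ 29.5%,
* P(two or more sites in 5000 bp) ~ 34.4%,
* P(a given enzyme's site falls inside its own 500 / 1000-bp module)
  is bounded by the expected count L*p ~ 12.5% / 25%.

Overlapping windows are not truly independent; the Monte Carlo routine
quantifies how small that error is for hexamers.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

from .errors import MacPlanError
from .seqtools import validate_dna

SITE_LENGTH = 6
ALPHABET_SIZE = 4
P_MATCH = ALPHABET_SIZE ** -SITE_LENGTH  # 1/4096


def n_trials(length: int) -> int:
    """Number of 6-mer windows in an L-bp fragment: max(0, L - 5)."""
    if length < 0:
        raise MacPlanError(f"fragment length must be >= 0, got {length}")
    return max(0, length - SITE_LENGTH + 1)


def prob_no_site(length: int) -> float:
    """Probability that a given hexamer site is absent from an L-bp fragment."""
    return float(binom.pmf(0, n_trials(length), P_MATCH))


def prob_single_site(length: int) -> float:
    """Probability of exactly one occurrence."""
    return float(binom.pmf(1, n_trials(length), P_MATCH))


def prob_multi_site(length: int) -> float:
    """Probability of two or more occurrences in an L-bp fragment."""
    return float(binom.sf(1, n_trials(length), P_MATCH))


def prob_at_least_one(length: int, method: str = "exact") -> float:
    """Probability that a site occurs at least once in an L-bp module.

    ``exact`` is the binomial complement 1 - (1-p)^n; ``linear`` is the
    expected-count bound min(1, L*p), the back-of-envelope figure usually
    quoted when judging whether a junction enzyme will also cut inside its
    own module.  exact <= linear always (union bound).
    """
    if method == "exact":
        return float(binom.sf(0, n_trials(length), P_MATCH))
    if method == "linear":
        if length < 0:
            raise MacPlanError(f"fragment length must be >= 0, got {length}")
        return min(1.0, length * P_MATCH)
    raise MacPlanError(f"unknown method {method!r}")


def expected_spacing(n_distinct_sites: int) -> float:
    """Mean bp between occurrences of any of ``n_distinct_sites`` hexamers.

    One site family recurs every 4^6 = 4096 bp; the 64 palindromes jointly
    every 64 bp; the 256 hybrid-site 6-mers jointly every 16 bp.
    """
    if n_distinct_sites < 1:
        raise MacPlanError("need at least one site family")
    return ALPHABET_SIZE**SITE_LENGTH / n_distinct_sites


def monte_carlo_site_freq(
    n_sequences: int, length: int, site: str, seed: int
) -> tuple[float, float]:
    """Empirical (absence fraction, >=2-occurrence fraction) by simulation.

    Draws ``n_sequences`` i.i.d. uniform ACGT sequences of ``length`` bp,
    counts overlapping occurrences of ``site`` in each, and returns the
    fraction with zero and with two or more occurrences.  Bit-reproducible
    for a fixed seed.
    """
    if n_sequences < 1:
        raise MacPlanError("n_sequences must be >= 1")
    if length < 0:
        raise MacPlanError("length must be >= 0")
    validate_dna(site, what="site")
    if len(site) != SITE_LENGTH:
        raise MacPlanError(f"site must be {SITE_LENGTH} bp")
    rng = np.random.default_rng(seed)
    if length < SITE_LENGTH:
        return 1.0, 0.0
    base_codes = rng.integers(0, 4, size=(n_sequences, length), dtype=np.uint8)
    pattern = np.frombuffer(site.encode(), dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.uint8)
    for code, base in enumerate(b"ACGT"):
        code_of[base] = code
    pattern_codes = code_of[pattern]
    match = np.ones((n_sequences, length - SITE_LENGTH + 1), dtype=bool)
    for k in range(SITE_LENGTH):
        match &= base_codes[:, k : length - SITE_LENGTH + 1 + k] == pattern_codes[k]
    counts = match.sum(axis=1)
    return float(np.mean(counts == 0)), float(np.mean(counts >= 2))
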