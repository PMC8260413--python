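"""Independent oracle implementations used only by the test suite.

These are literal, scalar transcriptions of the published formulas, written
without reference to the package internals, so that agreement between the
two code paths is meaningful.
"""

from __future__ import annotations

import numpy as np


def wc_abc_literal(n1, p1, h1, n2, p2, h2):
    """Scalar two-population Weir-Cockerham (1984) components a, b, c."""
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def window_fst_literal(sites):
    """Ratio-of-sums FST over a list of (n1, p1, h1, n2, p2, h2) tuples,
    dropping sites monomorphic for the same allele in both populations."""
    num = den = 0.0
    for n1, p1, h1, n2, p2, h2 in sites:
        polymorphic = not (
            (p1 in (0.0, 1.0)) and (p2 == p1) and h1 == 0.0 and h2 == 0.0
        )
        if not polymorphic:
            continue
        a, b, c = wc_abc_literal(n1, p1, h1, n2, p2, h2)
        num += a
        den += a + b + c
    if den <= 0:
        return None
    return num / den


def sample_bn_site_counts(F1, F2, n1, n2, n_sites, rng, low=0.05, high=0.95):
    """Monte-Carlo draw of per-site (n, p, h) pairs under the Beta model.

    Written independently of the package generator: explicit per-site loops
    over Beta and binomial draws, genotype sampling as two allele draws.
    """
    out = []
    for _ in range(n_sites):
        p_anc = rng.uniform(low, high)
        row = []
        for F, n in ((F1, n1), (F2, n2)):
            shape_a = p_anc * (1 - F) / F
            shape_b = (1 - p_anc) * (1 - F) / F
            pk = rng.beta(shape_a, shape_b)
            allele1 = rng.random(n) < pk
            allele2 = rng.random(n) < pk
            dosage = allele1.astype(int) + allele2.astype(int)
            row.extend([
                n,
                dosage.sum() / (2.0 * n),
                np.mean(dosage == 1),
            ])
        out.append(tuple(row))
    return out


def mc_expected_window_fst(F1, F2, n1, n2, rng, n_sites=120_000, low=0.05, high=0.95):
    """Monte-Carlo expectation of the ratio-of-sums WC FST under the Beta model."""
    sites = sample_bn_site_counts(F1, F2, n1, n2, n_sites, rng, low, high)
    return window_fst_literal(sites)


def hwe_exact_enumeration(n_het, n_hom_ref, n_hom_alt):
    """Two-sided exact HWE p-value by direct enumeration with exact rationals
    of factorial ratios (floating point, but built from first principles)."""
    from math import comb

    n = n_het + n_hom_ref + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0
    total = comb(2 * n, n_alt)
    probs = {}
    h_min = n_alt % 2
    for h in range(h_min, min(n_alt, 2 * n - n_alt) + 1, 2):
        hom_alt = (n_alt - h) // 2
        hom_ref = n - h - hom_alt
        if hom_ref < 0:
            continue
        ways = (
            2**h
            * _multinomial(n, (h, hom_alt, hom_ref))
        )
        probs[h] = ways / total
    obs = probs[n_het]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


def _multinomial(n, ks):
    from math import comb

    total = 1
    rest = n
    for k in ks:
        total *= comb(rest, k)
        rest -= k
    return total
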