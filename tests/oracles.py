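"""Independent brute-force oracles used only by the tests.

Each oracle deliberately avoids the code path it checks: exact rational
arithmetic for the HWE test, per-cell Python loops for the vectorised
counting/expected-heterozygosity routines, and a two-stage likelihood grid
search for the logistic fitter.
"""

from fractions import Fraction
from math import comb, exp, log

import numpy as np

from hetassoc.io import MISSING


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE p-value via rational enumeration.

    P(n_het = h | allele counts) ∝ n! / (n_aa! h! n_bb!) * 2^h with the
    homozygote counts implied by the fixed allele counts; exact Fractions
    throughout, converted to float only at the end.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    n_major = 2 * n - n_minor

    weights = {}
    for h in range(n_minor % 2, min(n_minor, n_major) + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = (n_major - h) // 2
        # multinomial weight: n! / (hom_minor! h! hom_major!) * 2^h
        w = Fraction(comb(n, h) * comb(n - h, hom_minor)) * Fraction(2) ** h
        weights[h] = w
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def genotype_counts_oracle(g):
    """Per-sample genotype counts by an explicit per-cell loop (autosomes)."""
    auto = g.autosomal_mask()
    out = []
    for i in range(g.n_samples):
        n_het = n_ref = n_alt = n_miss = 0
        for j in range(g.n_variants):
            if not auto[j]:
                continue
            c = int(g.calls[i, j])
            if c == MISSING:
                n_miss += 1
            elif c == 1:
                n_het += 1
            elif c == 0:
                n_ref += 1
            else:
                n_alt += 1
        out.append((n_het, n_ref, n_alt, n_miss))
    return out


def expected_het_oracle(g, correction: bool):
    """Per-sample expected heterozygosity by per-variant loops (autosomes)."""
    auto = g.autosomal_mask()
    cols = [j for j in range(g.n_variants) if auto[j]]
    p = {}
    n_called = {}
    for j in cols:
        alt = tot = 0
        for i in range(g.n_samples):
            c = int(g.calls[i, j])
            if c != MISSING:
                alt += c
                tot += 1
        n_called[j] = tot
        p[j] = alt / (2 * tot) if tot else float("nan")
    out = []
    for i in range(g.n_samples):
        us, k = 0.0, 0
        for j in cols:
            if int(g.calls[i, j]) == MISSING or n_called[j] == 0:
                continue
            u = 2 * p[j] * (1 - p[j])
            if correction:
                u *= 2 * n_called[j] / (2 * n_called[j] - 1)
            us += u
            k += 1
        out.append(us / k if k else float("nan"))
    return np.array(out)


def logistic_grid_oracle(y, x, span=6.0):
    """Maximise the 2-parameter logistic likelihood by nested grid search.

    Returns (beta0, beta1, loglik) refined to ~1e-4 resolution.
    """

    def ll(b0, b1):
        s = 0.0
        for yi, xi in zip(y, x):
            eta = b0 + b1 * xi
            # stable log(1+e^eta)
            m = max(eta, 0.0)
            s += yi * eta - (m + log(exp(-m) + exp(eta - m)))
        return s

    best = (0.0, 0.0)
    step = span / 30
    for _ in range(8):
        b0s = np.arange(best[0] - 30 * step, best[0] + 30 * step + 1e-12, step)
        b1s = np.arange(best[1] - 30 * step, best[1] + 30 * step + 1e-12, step)
        vals = [(ll(b0, b1), b0, b1) for b0 in b0s for b1 in b1s]
        _, b0, b1 = max(vals)
        best = (b0, b1)
        step /= 6
    return best[0], best[1], ll(*best)
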