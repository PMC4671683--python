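"""Independent brute-force oracles used to validate the fast implementations.

Each oracle deliberately avoids the code path it checks: isotope envelopes
are enumerated isotopologue-by-isotopologue instead of convolved by FFT, the
conditional NB exact test is rebuilt from scipy.stats.nbinom products, and
hypergeometric tail probabilities are counted over explicitly enumerated
draws.
"""

from __future__ import annotations

import itertools
from math import comb, factorial

import numpy as np
from scipy import stats

from ripitome.isotopes import ISOTOPE_TABLE, N14_MASS, N15_MASS, ElementalComposition


def enumerate_envelope(
    comp: ElementalComposition,
    n15_enrichment: float | None = None,
    prune: float = 1e-30,
) -> np.ndarray:
    """Aggregated envelope by multinomial enumeration of isotopologues.

    For every element, all isotope count vectors are enumerated with their
    multinomial probabilities and accumulated by total neutron offset; the
    per-element distributions are then combined by explicit nested summation
    (no FFT anywhere).
    """

    def element_distribution(element: str, count: int) -> dict[int, float]:
        if element == "N" and n15_enrichment is not None:
            e = float(n15_enrichment)
            isotopes = [(0, N14_MASS, 1.0 - e), (1, N15_MASS, e)]
        else:
            isotopes = list(ISOTOPE_TABLE[element])
        isotopes = [t for t in isotopes if t[2] > 0.0]
        offsets = [t[0] for t in isotopes]
        abundances = [t[2] for t in isotopes]
        k = len(isotopes)
        dist: dict[int, float] = {}

        def recurse(i: int, remaining: int, offset: int, weight: float) -> None:
            if i == k - 1:
                w = weight * abundances[i] ** remaining / factorial(remaining)
                key = offset + offsets[i] * remaining
                dist[key] = dist.get(key, 0.0) + w * factorial(count)
                return
            for n_i in range(remaining + 1):
                recurse(
                    i + 1,
                    remaining - n_i,
                    offset + offsets[i] * n_i,
                    weight * abundances[i] ** n_i / factorial(n_i),
                )

        recurse(0, count, 0, 1.0)
        return dist

    total: dict[int, float] = {0: 1.0}
    for element, count in comp.as_dict().items():
        if count == 0:
            continue
        elem = element_distribution(element, count)
        merged: dict[int, float] = {}
        for o1, p1 in total.items():
            for o2, p2 in elem.items():
                p = p1 * p2
                if p < prune:
                    continue
                merged[o1 + o2] = merged.get(o1 + o2, 0.0) + p
        total = merged

    arr = np.zeros(max(total) + 1)
    for offset, p in total.items():
        arr[offset] = p
    # index offsets from the lightest populated isotopologue (matches the
    # implementation's convention of rebasing fully-enriched elements)
    first = int(np.argmax(arr > 0.0))
    return arr[first:]


def nb_exact_pvalue_bruteforce(
    sum_a: int, sum_b: int, n_a: int, n_b: int, dispersion: float
) -> float:
    """Conditional NB exact p-value by direct enumeration of count splits.

    Builds the conditional law of the group-A sum from products of
    ``scipy.stats.nbinom`` pmfs at an arbitrary common success probability
    (which cancels on conditioning) and sums every split whose probability
    does not exceed the observed one.
    """
    phi = max(float(dispersion), 1e-8)
    r_a, r_b = n_a / phi, n_b / phi
    total = sum_a + sum_b
    s = np.arange(total + 1)
    p0 = 0.5
    joint = stats.nbinom.pmf(s, r_a, p0) * stats.nbinom.pmf(total - s, r_b, p0)
    cond = joint / joint.sum()
    obs = cond[sum_a]
    return float(min(1.0, cond[cond <= obs * (1.0 + 1e-10)].sum()))


def hypergeom_sf_bruteforce(k: int, N: int, K: int, n: int) -> float:
    """P(overlap >= k) by enumerating all C(N, n) draws of the query."""
    marked = set(range(K))
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if len(marked.intersection(draw)) >= k
    )
    return hits / comb(N, n)


def overlap_distribution_bruteforce(N: int, K: int, n: int) -> np.ndarray:
    """Distribution of |query ∩ pathway| over all C(N, n) draws."""
    marked = set(range(K))
    counts = np.zeros(min(K, n) + 1)
    for draw in itertools.combinations(range(N), n):
        counts[len(marked.intersection(draw))] += 1
    return counts / counts.sum()
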