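"""Shared test utilities: random phantom inputs and brute-force statistical
oracles (independent of the implementations they check)."""

import itertools

import numpy as np
from scipy import stats as sps

from lusaug import generate_phantom
from lusaug.phantom import PhantomSpec, random_geometry


def random_phantom_image(rng, shape=(48, 48)):
    """A phantom frame with random FOV geometry, label, and artifacts."""
    geometry = random_geometry(rng, shape)
    label = "B" if rng.random() < 0.5 else "A"
    spec = PhantomSpec(
        geometry=geometry,
        pleural_depth=float(
            rng.uniform(max(0.15, geometry.r_min / geometry.r_max + 0.05), 0.55)
        ),
        n_alines=int(rng.integers(0, 3)) if label == "A" else 0,
        n_blines=int(rng.integers(1, 3)) if label == "B" else 0,
        label=label,
    )
    return generate_phantom(spec, rng, shape=shape)


def wilcoxon_p_bruteforce(d):
    """Exact two-sided signed-rank p by naive enumeration of sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = min(ranks[d > 0].sum(), total - ranks[d > 0].sum())
    count = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w_plus = sum(r for s, r in zip(signs, ranks) if s)
        if min(w_plus, total - w_plus) <= w_obs + 1e-12:
            count += 1
    return count / 2 ** len(d)


def friedman_stat_bruteforce(matrix):
    """Friedman chi-square via explicit rank loops (tie-corrected)."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    ranks = np.array([sps.rankdata(row) for row in matrix])
    stat = 0.0
    for j in range(k):
        stat += (ranks[:, j].mean() - (k + 1) / 2) ** 2
    stat *= 12.0 * n / (k * (k + 1))
    tie = sum(
        (c**3 - c)
        for row in ranks
        for c in np.unique(row, return_counts=True)[1]
    )
    denom = 1 - tie / (n * k * (k**2 - 1))
    return 0.0 if denom <= 0 else stat / denom
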