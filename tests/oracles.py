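"""Independent brute-force re-implementations used as test oracles.

Everything here is deliberately written as plain nested loops over scalar
arithmetic, sharing no code path with the package's vectorized
implementations.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_relations(mz, mp, constants, tol, losses_enabled):
    """All (i, j, kind, z) relation tuples by direct scalar enumeration."""
    losses = [constants.h2o, constants.nh3, constants.co, constants.nh]
    shifts_sum = [0.0] + (losses if losses_enabled else [])
    shifts_12 = [0.0] + (losses + [2 * l for l in losses] if losses_enabled else [])
    out = []
    n = len(mz)
    for i in range(n):
        for j in range(i + 1, n):
            m1, m2 = mz[i], mz[j]
            for z in (2, 3):
                t11 = 2 * mp if z == 2 else 3 * mp - constants.proton
                t12 = 2 * mp + constants.proton if z == 2 else 3 * mp
                if any(abs(m1 + m2 + s - t11) <= tol for s in shifts_sum):
                    out.append((i, j, "CP11", z))
                if any(abs(2 * m1 + m2 + s - t12) <= tol for s in shifts_12):
                    out.append((i, j, "CP12_LOW2", z))
                if any(abs(m1 + 2 * m2 + s - t12) <= tol for s in shifts_12):
                    out.append((i, j, "CP12_HIGH2", z))
    return sorted(out)


def brute_force_doubly_charged(mz, mp, constants, tol):
    """Per-peak +2 flags by direct scalar enumeration (no losses)."""
    n = len(mz)
    flags = [False] * n
    for k in range(n):
        for l in range(n):
            if l != k and abs(2 * mz[k] - constants.proton - mz[l]) <= tol:
                flags[k] = True
    t12_3 = 3 * mp
    for i in range(n):
        for j in range(i + 1, n):
            if abs(2 * mz[i] + mz[j] - t12_3) <= tol:
                flags[i] = True
            if abs(mz[i] + 2 * mz[j] - t12_3) <= tol:
                flags[j] = True
    return flags


def brute_force_basic_site_count(mz, constants, tol, losses_enabled):
    """Unordered peak pairs whose m/z difference matches a K/R/H mass."""
    losses = [constants.h2o, constants.nh3, constants.co, constants.nh]
    shifts = [0.0] + (losses + [-l for l in losses] if losses_enabled else [])
    residues = [constants.residue_masses[r] for r in ("K", "R", "H")]
    count = 0
    n = len(mz)
    for i in range(n):
        for j in range(i + 1, n):
            diff = mz[j] - mz[i]
            if any(abs(diff + s - r) <= tol for s in shifts for r in residues):
                count += 1
    return count


def brute_force_delta_rcp(spectrum, relations, ratio_offset=0.5):
    """delta_rcp recomputed from an explicit relation list.

    ``relations`` are (i, j, kind, z) tuples; the implementation under
    test produces them via enumerate_pair_relations.
    """
    intensity = spectrum.intensity
    cp1 = {(i, j) for i, j, kind, _ in relations if kind == "CP11"}
    cp2 = set()
    for i, j, kind, _ in relations:
        if kind == "CP12_LOW2":
            cp2.add((i, j))
        elif kind == "CP12_HIGH2":
            cp2.add((j, i))
    term1 = term2 = 0.0
    if cp1:
        low = sum(intensity[k] for k in {i for i, _ in cp1})
        high = sum(intensity[k] for k in {j for _, j in cp1})
        term1 = (low / high if high > 0 else 0.0) + ratio_offset
    if cp2:
        plus2 = sum(intensity[k] for k in {p for p, _ in cp2})
        plus1 = sum(intensity[k] for k in {q for _, q in cp2})
        term2 = plus2 / plus1 if plus1 > 0 else 0.0
    return term1 - term2


def pairwise_auc(scores, labels):
    """AUC as concordant pairs plus half the ties over all pos*neg pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 3]
    neg = scores[labels == 2]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_gmm_log_likelihood(data, means, variances, mixing):
    """Direct-density mixture log-likelihood without log-sum-exp."""
    data = np.atleast_2d(data)
    total = 0.0
    d = data.shape[1]
    for x in data:
        acc = 0.0
        for mu, var, pk in zip(means, variances, mixing):
            sq = float(np.sum((x - mu) ** 2))
            acc += pk * math.exp(-sq / (2 * var)) / (2 * math.pi * var) ** (d / 2)
        total += math.log(acc)
    return total


def random_spectrum(rng, n_peaks=None, spectrum_id="rand"):
    """A random test spectrum with plausible precursor and peak ranges."""
    from cidcharge import Spectrum

    if n_peaks is None:
        n_peaks = int(rng.integers(2, 30))
    mp = float(rng.uniform(400.0, 700.0))
    mz = rng.uniform(50.0, 2.0 * mp, size=n_peaks)
    intensity = rng.uniform(0.1, 10.0, size=n_peaks)
    return Spectrum(spectrum_id=spectrum_id, precursor_mz=mp, mz=mz, intensity=intensity)
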