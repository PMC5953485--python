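"""Independent oracles used across the test suite.

Everything here is deliberately naive: the tabular relationship-matrix
construction, path-enumeration contributions and gene-dropping Monte
Carlo are slow brute-force counterparts to the package's recursive /
vectorized implementations.
"""

from __future__ import annotations

import numpy as np

from pedcontrib import Pedigree, topological_order


def tabular_relationship(ped: Pedigree):
    """Additive relationship matrix A by the classical tabular method.

    Returns (ids, A) with ids in topological order.  A[i,i] = 1 + F_i;
    off-diagonals are twice the kinship.
    """
    ids = topological_order(ped)
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, aid in enumerate(ids):
        rec = ped[aid]
        s = pos.get(rec.sire_id) if rec.sire_id else None
        d = pos.get(rec.dam_id) if rec.dam_id else None
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
        for j in range(i):
            val = 0.0
            if s is not None:
                val += 0.5 * A[j, s]
            if d is not None:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return ids, A


def path_contribution(ped: Pedigree, ancestor: str, descendant: str) -> float:
    """Sum of (1/2)^length over all distinct parent-link paths.

    Explicit path enumeration, independent of the level-pass machinery.
    """
    total = 0.0
    stack = [(descendant, 0)]
    while stack:
        aid, length = stack.pop()
        if aid == ancestor:
            total += 0.5 ** length
            continue
        rec = ped[aid]
        for parent in (rec.sire_id, rec.dam_id):
            if parent is not None:
                stack.append((parent, length + 1))
    return total


def gene_drop_contribution(ped, ancestor, cohort, n_drops, rng):
    """Monte-Carlo estimate of an ancestor's contribution to a cohort.

    Drops marker alleles down the pedigree: the focal ancestor's two
    alleles are marked, every other origin is unmarked, inheritance picks
    one parental allele uniformly.  Returns (estimate, standard_error)
    of the cohort-average marked-allele fraction.
    """
    order = topological_order(ped)
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    zeros = np.zeros(n_drops, dtype=np.int8)
    for aid in order:
        if aid == ancestor:
            one = np.ones(n_drops, dtype=np.int8)
            alleles[aid] = (one, one)
            continue
        rec = ped[aid]
        got = []
        for parent in (rec.sire_id, rec.dam_id):
            if parent is None:
                got.append(zeros)
            else:
                p1, p2 = alleles[parent]
                pick = rng.integers(0, 2, size=n_drops, dtype=np.int8)
                got.append(np.where(pick == 1, p1, p2))
        alleles[aid] = (got[0], got[1])
    members = sorted(set(cohort))
    per_drop = np.zeros(n_drops)
    for m in members:
        a1, a2 = alleles[m]
        per_drop += (a1.astype(float) + a2.astype(float)) / 2.0
    per_drop /= len(members)
    return float(per_drop.mean()), float(per_drop.std(ddof=1) / np.sqrt(n_drops))


def bh_stepup_naive(pvals, q):
    """Brute-force Benjamini-Hochberg step-up rejection flags."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    flags = np.zeros(m, dtype=bool)
    if k_star:
        flags[order[:k_star]] = True
    return flags
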