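"""Shared fixtures and the independent brute-force mixture oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pangem.genome import Contig, Gene, Genome


def brute_force_mixture(X, pi, mu, eps):
    """Term-by-term evaluation of the Bernoulli mixture in plain Python.

    Returns (posteriors, total log-likelihood) computed directly from the
    mixture density Σ_k π_k Π_j ε^|x−μ| (1−ε)^(1−|x−μ|), independent of
    the package's vectorized log-space implementation.
    """
    F, N = len(X), len(X[0])
    K = len(pi)
    T = []
    loglik = 0.0
    for i in range(F):
        joints = []
        for k in range(K):
            p = pi[k]
            for j in range(N):
                d = abs(X[i][j] - mu[k][j])
                p *= eps[k][j] ** d * (1 - eps[k][j]) ** (1 - d)
            joints.append(p)
        total = sum(joints)
        loglik += math.log(total)
        T.append([p / total for p in joints])
    return np.array(T), loglik


@pytest.fixture
def toy_genomes():
    """Two tiny genomes sharing families A,B; C private to genome g1."""

    def mk(gid, contig, fams, circular=False):
        genes = [
            Gene(f"{gid}_{i}", gid, contig, 1 + 100 * i, 50 + 100 * i, "+", fam)
            for i, fam in enumerate(fams)
        ]
        return Genome(gid, [Contig(contig, genes, circular=circular)])

    return [mk("g1", "c1", ["A", "B", "C"]), mk("g2", "c1", ["A", "B"])]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
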