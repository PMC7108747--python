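"""Synthetic pangenomes with known ground truth.

Families are drawn from a K-component Bernoulli mixture (component 1
all-present = persistent, component K all-absent = cloud, intermediate
components shell), optionally in blocks whose members share presence
draws with probability ``rho_block`` — emulating mobile islands of
co-transferred genes.  Genomes are then laid out the way prokaryotic
chromosomes behave: a conserved circular backbone of persistent families
in a fixed reference order, interrupted at a small number of hotspot
positions by the shell/cloud islands, each island inserting at the same
hotspot in every genome that carries it.  The backbone is linearized at
a random origin per genome so edge sets vary realistically.  A
``degrade`` step emulates fragmented, incomplete assemblies by breaking
contigs and dropping genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bmm import BMMParams
from .genome import Contig, Gene, Genome
from .matrix import PAMatrix
from .partition import component_label

__all__ = [
    "SyntheticTruth",
    "mixture_params",
    "three_pattern_params",
    "four_pattern_params",
    "generate_pa",
    "generate_genomes",
    "degrade",
    "generate_pangenome",
    "degraded_island_scenario",
]


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated pangenome."""

    params_true: BMMParams
    components_true: np.ndarray  # 1-based component per family
    labels_true: np.ndarray  # persistent/shell/cloud strings
    family_ids: list[str]
    block_ids: np.ndarray
    seed: int | None = None
    n_redrawn: int = 0


def mixture_params(pi, mu_patterns, eps, N: int) -> BMMParams:
    """Assemble constrained BMMParams from per-component scalar ε and
    centroid patterns ('all', 'none', 'first_half', 'second_half')."""
    K = len(pi)
    mu = np.zeros((K, N), dtype=np.int8)
    half = N // 2
    for k, pat in enumerate(mu_patterns):
        if pat == "all":
            mu[k] = 1
        elif pat == "none":
            mu[k] = 0
        elif pat == "first_half":
            mu[k, :half] = 1
        elif pat == "second_half":
            mu[k, half:] = 1
        else:
            raise ValueError(f"unknown centroid pattern {pat!r}")
    epsilon = np.broadcast_to(np.asarray(eps, dtype=float)[:, None], (K, N)).copy()
    return BMMParams(np.asarray(pi, dtype=float), mu, epsilon, constrained_dispersion=True)


def three_pattern_params(
    N: int, pi=(0.3, 0.2, 0.5), eps=(0.05, 0.3, 0.05)
) -> BMMParams:
    """Canonical 3-pattern pangenome: persistent, one shell block, cloud."""
    return mixture_params(pi, ("all", "first_half", "none"), eps, N)


def four_pattern_params(
    N: int, pi=(0.3, 0.2, 0.2, 0.3), eps=(0.05, 0.15, 0.15, 0.05)
) -> BMMParams:
    """Pangenome with two antagonistic shell blocks (families present in
    one half of the genomes or the complementary half)."""
    return mixture_params(pi, ("all", "first_half", "second_half", "none"), eps, N)


def degraded_island_scenario(seed=None):
    """Island-structured pangenome with a degraded P/A signal.

    The benchmark condition for graph smoothing: 300 families over 20
    genomes, a diffuse shell (ε = 0.35) organized in 6-family islands at
    5 hotspots (ρ_block = 0.8), observed through a poor assembly
    (20% of adjacencies broken, 15% of genes lost).  P/A alone is
    ambiguous for part of the shell while graph neighbors remain
    consistent.  Returns (pa, genomes, truth) with the P/A matrix
    rebuilt from the degraded genomes.
    """
    params = mixture_params(
        (0.3, 0.2, 0.5), ("all", "first_half", "none"), (0.05, 0.35, 0.05), 20
    )
    return generate_pangenome(
        F=300,
        N=20,
        params_true=params,
        hotspots=5,
        block_size=6,
        rho_block=0.8,
        fragmentation_rate=0.2,
        loss_rate=0.15,
        seed=seed,
    )


def generate_pa(
    F: int,
    N: int,
    params_true: BMMParams,
    seed=None,
    block_size: int = 1,
    rho_block: float = 0.8,
    family_prefix: str = "fam",
) -> tuple[PAMatrix, SyntheticTruth]:
    """Draw an F×N presence/absence matrix from the mixture.

    Each family picks a component k ~ π and sets x_ij = μ_kj flipped
    with probability ε_kj.  With ``block_size > 1`` families come in
    consecutive blocks sharing a component; each member copies the
    block's draw per genome with probability ``rho_block`` and redraws
    independently otherwise, so marginals still follow the mixture while
    block-mates co-occur.  All-zero rows are redrawn (a family absent
    everywhere is unobservable); the count is recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    K = params_true.K
    if params_true.n_genomes != N:
        raise ValueError("params_true genome dimension differs from N")
    n_blocks = int(np.ceil(F / block_size))
    block_ids = np.repeat(np.arange(n_blocks), block_size)[:F]
    comp_of_block = rng.choice(K, size=n_blocks, p=params_true.pi)
    comps = comp_of_block[block_ids]  # 0-based

    mu_bool = params_true.mu.astype(bool)
    X = np.zeros((F, N), dtype=np.int8)
    for b in range(n_blocks):
        k = comp_of_block[b]
        members = np.flatnonzero(block_ids == b)
        base = (rng.random(N) < params_true.epsilon[k]) ^ mu_bool[k]
        for i in members:
            if block_size == 1:
                row = base
            else:
                indiv = (rng.random(N) < params_true.epsilon[k]) ^ mu_bool[k]
                row = np.where(rng.random(N) < rho_block, base, indiv)
            X[i] = row

    n_redrawn = 0
    for i in np.flatnonzero(X.sum(axis=1) == 0):
        k = comps[i]
        row = X[i]
        while row.sum() == 0:
            row = ((rng.random(N) < params_true.epsilon[k]) ^ mu_bool[k]).astype(np.int8)
        X[i] = row
        n_redrawn += 1

    width = len(str(F))
    family_ids = [f"{family_prefix}{i:0{width}d}" for i in range(F)]
    genome_ids = [f"genome{j:03d}" for j in range(N)]
    components = comps + 1
    truth = SyntheticTruth(
        params_true=params_true,
        components_true=components,
        labels_true=np.array([component_label(k, K) for k in components], dtype=object),
        family_ids=family_ids,
        block_ids=block_ids,
        seed=seed if isinstance(seed, int) else None,
        n_redrawn=n_redrawn,
    )
    return PAMatrix(X, family_ids, genome_ids), truth


def generate_genomes(
    pa: PAMatrix,
    truth: SyntheticTruth,
    hotspots: int = 5,
    seed=None,
    gene_length: int = 900,
    gene_spacing: int = 100,
) -> list[Genome]:
    """Lay out each genome's present families on one chromosome.

    Persistent families keep a fixed circular reference order in every
    genome; shell and cloud families present in a genome are inserted as
    islands at hotspot positions of the backbone (families of a block
    share their hotspot and stay adjacent).  Each genome is linearized
    at a random origin into a single linear contig.
    """
    rng = np.random.default_rng(seed)
    comps = truth.components_true
    persistent_rows = np.flatnonzero(comps == 1)
    if len(persistent_rows) == 0:
        raise ValueError("no persistent families: cannot build a backbone")
    accessory_rows = np.flatnonzero(comps != 1)
    backbone = list(persistent_rows)  # reference order = matrix order
    P = len(backbone)
    hotspots = max(1, min(hotspots, P))
    hotspot_positions = np.unique(np.linspace(0, P, hotspots, endpoint=False).astype(int))
    # map hotspot backbone position -> accessory rows inserted there, block-contiguous
    acc_at: dict[int, list[int]] = {int(p): [] for p in hotspot_positions}
    for row in accessory_rows:
        hs = hotspot_positions[truth.block_ids[row] % len(hotspot_positions)]
        acc_at[int(hs)].append(int(row))

    genomes: list[Genome] = []
    step = gene_length + gene_spacing
    for j, gid in enumerate(pa.genome_ids):
        present = pa.X[:, j] == 1
        order: list[int] = []
        for pos, row in enumerate(backbone):
            if pos in acc_at:
                order.extend(r for r in acc_at[pos] if present[r])
            if present[row]:
                order.append(row)
        if not order:
            genomes.append(Genome(gid, []))
            continue
        origin = int(rng.integers(len(order)))
        order = order[origin:] + order[:origin]
        genes = []
        for idx, row in enumerate(order):
            start = 1 + idx * step
            genes.append(
                Gene(
                    gene_id=f"{gid}_{idx:05d}",
                    genome_id=gid,
                    contig_id=f"{gid}_chr",
                    start=start,
                    end=start + gene_length - 1,
                    strand="+",
                    family_id=pa.family_ids[row],
                )
            )
        genomes.append(Genome(gid, [Contig(f"{gid}_chr", genes, circular=False)]))
    return genomes


def degrade(
    genomes: list[Genome],
    fragmentation_rate: float = 0.0,
    loss_rate: float = 0.0,
    seed=None,
) -> list[Genome]:
    """Emulate incomplete assemblies: drop genes and break contigs.

    Each gene is lost independently with ``loss_rate``; each remaining
    adjacency is broken with ``fragmentation_rate``, splitting the
    contig (a broken circular closure just linearizes the contig).
    """
    if not 0 <= fragmentation_rate <= 1 or not 0 <= loss_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[Genome] = []
    for genome in genomes:
        contigs: list[Contig] = []
        for contig in genome.contigs:
            kept = [g for g in contig.genes if rng.random() >= loss_rate]
            if not kept:
                continue
            circular = contig.circular
            if circular and rng.random() < fragmentation_rate:
                circular = False
            pieces: list[list[Gene]] = [[kept[0]]]
            for gene in kept[1:]:
                if rng.random() < fragmentation_rate:
                    pieces.append([gene])
                else:
                    pieces[-1].append(gene)
            if len(pieces) == 1:
                contigs.append(Contig(contig.contig_id, pieces[0], circular))
            else:
                for p, piece in enumerate(pieces):
                    contigs.append(Contig(f"{contig.contig_id}_frag{p}", piece, False))
        out.append(Genome(genome.genome_id, contigs))
    return out


def generate_pangenome(
    F: int = 500,
    N: int = 30,
    params_true: BMMParams | None = None,
    hotspots: int = 5,
    block_size: int = 5,
    rho_block: float = 0.8,
    fragmentation_rate: float = 0.0,
    loss_rate: float = 0.0,
    seed=None,
):
    """One-call generator: (pa, genomes, truth) under the 3-pattern model.

    The returned P/A matrix is rebuilt from the (possibly degraded)
    genomes so it reflects exactly what an analysis would observe.
    """
    from .matrix import build_pa_matrix

    rng = np.random.default_rng(seed)
    if params_true is None:
        params_true = three_pattern_params(N)
    pa, truth = generate_pa(
        F, N, params_true, seed=rng, block_size=block_size, rho_block=rho_block
    )
    genomes = generate_genomes(pa, truth, hotspots=hotspots, seed=rng)
    if fragmentation_rate or loss_rate:
        genomes = degrade(genomes, fragmentation_rate, loss_rate, seed=rng)
        pa_obs = build_pa_matrix(genomes)
    else:
        pa_obs = pa
    return pa_obs, genomes, truth
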