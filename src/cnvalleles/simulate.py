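"""Synthetic data generators for the copy-unit allele model.

Two study designs are emulated:

* a fixed four-allele locus with 16 variable sites and 12 samples (four
  samples carrying two copy units, four carrying three, four carrying four),
  each copy unit drawn uniformly from the allele set;
* a population-style design in which samples draw copy units *without
  replacement* from a pool of 45 haplotype tokens spanning 9 distinct
  sequences over 21 variable sites, under lower/middle/higher copy-number
  configurations that each exhaust the 45-token pool.

Read depth at each variable site is an independent Poisson per copy unit, and
each read's base is corrupted with a fixed error probability to one of the
other three bases uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import BASE_INDEX, BASES, N_BASES, BaseCountTensor

#: The four fixed copy-unit alleles of the small benchmark locus (M = 16).
SIM1_ALLELES: tuple[str, ...] = (
    "ATTGCGATATTGCGAT",
    "ACGGATTTACGGATTT",
    "CTTCGGAACTTCGGAA",
    "CGATTGAACGTCGTAC",
)

#: Copy-number configurations as (copy_number, n_samples) pairs; every preset
#: totals 45 copy units, matching the 45-token haplotype pool.
TABLE2_CONFIGS: dict[str, tuple[tuple[int, int], ...]] = {
    "a": ((1, 5), (2, 11), (3, 6)),       # lower copy number, 22 samples
    "b": ((2, 2), (3, 3), (4, 4), (5, 2), (6, 1)),  # middle, 12 samples
    "c": ((3, 1), (4, 2), (5, 3), (6, 2), (7, 1)),  # higher, 9 samples
}


@dataclass
class AlleleSet:
    """K allele sequences over {A, C, G, T}, all of equal length."""

    sequences: tuple[str, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.sequences = tuple(str(s).upper() for s in self.sequences)
        if not self.sequences:
            raise ValueError("allele set must be non-empty")
        m = len(self.sequences[0])
        for s in self.sequences:
            if len(s) != m:
                raise ValueError("allele sequences must share one length")
            if any(ch not in BASE_INDEX for ch in s):
                raise ValueError(f"non-ACGT character in allele sequence {s!r}")
        if self.labels is None:
            self.labels = tuple(f"allele_{i + 1}" for i in range(len(self.sequences)))
        else:
            self.labels = tuple(str(x) for x in self.labels)
            if len(self.labels) != len(self.sequences):
                raise ValueError("labels length must match sequences")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def as_index_matrix(self) -> np.ndarray:
        """(K, M) integer base indices in A, C, G, T order."""
        return np.array([[BASE_INDEX[ch] for ch in s] for s in self.sequences])


@dataclass
class SampleAlleleConfig:
    """Which copy units each sample carries, as indices into a sequence list.

    ``samples[n]`` holds one index per copy unit of sample n; for the
    pool-based design these are token indices (no token appears twice across
    the whole configuration), for the fixed-allele design they index the
    four-allele set directly and may repeat.
    """

    samples: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        self.samples = tuple(tuple(int(i) for i in units) for units in self.samples)
        if not self.samples:
            raise ValueError("need at least one sample")
        for units in self.samples:
            if len(units) < 1:
                raise ValueError("every sample needs at least one copy unit")
            if any(i < 0 for i in units):
                raise ValueError("negative allele index")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def total_copies(self) -> np.ndarray:
        return np.array([len(units) for units in self.samples])


@dataclass
class SimTruth:
    """Ground truth behind a simulated count tensor."""

    alleles: AlleleSet              # distinct sequences actually present
    config: SampleAlleleConfig      # indices into ``alleles``
    theta_true: np.ndarray          # (N, K0) copy proportions c_nk / C_n
    copy_numbers: np.ndarray        # (N, K0) integer c_nk
    mean_depth: float
    error_rate: float
    seed: int

    def __post_init__(self) -> None:
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        if not np.allclose(self.theta_true.sum(axis=1), 1.0):
            raise ValueError("theta_true rows must sum to 1")


@dataclass
class HaplotypePool:
    """A pool of haplotype tokens; several tokens may share one sequence."""

    tokens: tuple[str, ...]

    @property
    def distinct_sequences(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.tokens:
            seen.setdefault(t, None)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.tokens)


def simulate_counts(config: SampleAlleleConfig, alleles: AlleleSet,
                    mean_depth: float, error_rate: float = 0.01,
                    seed: int = 0) -> BaseCountTensor:
    """Generate the per-site base-count tensor for a sample configuration.

    For every (sample, copy unit, site) the read count is Poisson with mean
    ``mean_depth``; each read reports the unit's true base except with
    probability ``error_rate``, in which case one of the other three bases is
    reported uniformly at random.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng([seed, 0x5EED])
    m = alleles.n_sites
    seq_idx = alleles.as_index_matrix()
    counts = np.zeros((config.n_samples, m, N_BASES), dtype=np.int64)
    err_split = np.full(3, 1.0 / 3.0)

    for n, units in enumerate(config.samples):
        for unit in units:
            bases = seq_idx[unit]
            depth = rng.poisson(mean_depth, size=m)
            n_err = rng.binomial(depth, error_rate) if error_rate > 0 else np.zeros(m, dtype=np.int64)
            errs = rng.multinomial(n_err, err_split)  # (m, 3)
            np.add.at(counts[n], (np.arange(m), bases), depth - n_err)
            for b in range(N_BASES):
                sites = np.flatnonzero(bases == b)
                if sites.size == 0:
                    continue
                others = [o for o in range(N_BASES) if o != b]
                counts[n][np.ix_(sites, others)] += errs[sites]

    sample_ids = tuple(f"sample_{i + 1}" for i in range(config.n_samples))
    return BaseCountTensor(counts, sample_ids, tuple(range(1, m + 1)))


def _truth_from_config(config: SampleAlleleConfig, sequences: tuple[str, ...],
                       mean_depth: float, error_rate: float,
                       seed: int) -> SimTruth:
    """Collapse token/allele indices onto the distinct sequences present."""
    present: dict[str, int] = {}
    for units in config.samples:
        for i in units:
            present.setdefault(sequences[i], len(present))
    distinct = tuple(present)
    k0 = len(distinct)
    cn = np.zeros((config.n_samples, k0), dtype=np.int64)
    remapped = []
    for n, units in enumerate(config.samples):
        row = tuple(present[sequences[i]] for i in units)
        remapped.append(row)
        for k in row:
            cn[n, k] += 1
    theta = cn / cn.sum(axis=1, keepdims=True)
    return SimTruth(
        alleles=AlleleSet(distinct),
        config=SampleAlleleConfig(tuple(remapped)),
        theta_true=theta,
        copy_numbers=cn,
        mean_depth=mean_depth,
        error_rate=error_rate,
        seed=seed,
    )


def make_sim1_dataset(mean_depth: float = 15.0, error_rate: float = 0.01,
                      seed: int = 0) -> tuple[BaseCountTensor, SimTruth]:
    """The fixed-allele benchmark: 12 samples over the four-allele locus.

    Four samples carry two copy units, four carry three, four carry four; each
    copy unit is an i.i.d. uniform draw from the four alleles (duplicates
    allowed within a sample).
    """
    rng = np.random.default_rng([seed, 1])
    sizes = [2] * 4 + [3] * 4 + [4] * 4
    samples = tuple(tuple(rng.integers(0, len(SIM1_ALLELES), size=s)) for s in sizes)
    config = SampleAlleleConfig(samples)
    alleles = AlleleSet(SIM1_ALLELES)
    counts = simulate_counts(config, alleles, mean_depth, error_rate, seed=seed)
    truth = _truth_from_config(config, alleles.sequences, mean_depth,
                               error_rate, seed)
    return counts, truth


def make_haplotype_pool(n_distinct: int = 9, pool_size: int = 45,
                        M: int = 21, seed: int = 0,
                        min_minor: int = 2) -> HaplotypePool:
    """Build a synthetic haplotype pool standing in for population haplotypes.

    Sites are biallelic with the minor base carried by at least ``min_minor``
    of the distinct sequences (population-style variable sites); every pair of
    distinct sequences differs somewhere.  Each distinct haplotype receives at
    least one token; the remaining tokens are split proportionally to a
    Dirichlet(1) draw by largest-remainder rounding, so both common and rare
    haplotypes occur.  The multiplicities are a seeded stand-in, not an
    estimate of any real population's frequencies.
    """
    if not 1 <= n_distinct <= pool_size:
        raise ValueError("need 1 <= n_distinct <= pool_size")
    if 4.0 ** M < n_distinct:
        raise ValueError("more distinct haplotypes than possible sequences")
    rng = np.random.default_rng([seed, 2])

    if n_distinct == 1:
        warnings.warn("single-haplotype pool: sites cannot be variable")
        seq = "".join(BASES[i] for i in rng.integers(0, N_BASES, size=M))
        return HaplotypePool(tokens=(seq,) * pool_size)

    # the minor base is by definition carried by at most half the haplotypes
    lo = min(min_minor, n_distinct - 1)
    hi = max(lo, n_distinct // 2)
    for _ in range(1000):
        mat = np.empty((n_distinct, M), dtype=np.int64)
        for x in range(M):
            major, minor = rng.choice(N_BASES, size=2, replace=False)
            mat[:, x] = major
            carriers = rng.choice(n_distinct, size=rng.integers(lo, hi + 1),
                                  replace=False)
            mat[carriers, x] = minor
        if len({tuple(row) for row in mat}) == n_distinct:
            break
    else:  # pragma: no cover - astronomically unlikely for sane configs
        raise RuntimeError("failed to draw distinct haplotypes")

    weights = rng.dirichlet(np.ones(n_distinct))
    extra = pool_size - n_distinct
    ideal = weights * extra
    mult = np.ones(n_distinct, dtype=np.int64) + np.floor(ideal).astype(np.int64)
    short = pool_size - mult.sum()
    order = np.argsort(-(ideal - np.floor(ideal)), kind="stable")
    mult[order[:short]] += 1

    seqs = ["".join(BASES[i] for i in row) for row in mat]
    tokens: list[str] = []
    for s, m in zip(seqs, mult):
        tokens.extend([s] * m)
    return HaplotypePool(tokens=tuple(tokens))


def assign_alleles(pool: HaplotypePool,
                   cn_config: tuple[tuple[int, int], ...] | list,
                   seed: int = 0) -> SampleAlleleConfig:
    """Deal pool tokens to samples without replacement.

    ``cn_config`` lists (copy_number, n_samples) pairs; each sample with copy
    number c receives c tokens drawn uniformly without replacement from the
    remaining pool.
    """
    demand = sum(c * n for c, n in cn_config)
    if demand > len(pool):
        raise ValueError(
            f"configuration needs {demand} copy units but pool has {len(pool)}"
        )
    rng = np.random.default_rng([seed, 3])
    order = rng.permutation(len(pool))
    samples = []
    cursor = 0
    for copy_number, n_samples in cn_config:
        if copy_number < 1:
            raise ValueError("copy numbers must be >= 1")
        for _ in range(n_samples):
            samples.append(tuple(int(i) for i in order[cursor:cursor + copy_number]))
            cursor += copy_number
    return SampleAlleleConfig(tuple(samples))


def make_table2_dataset(dataset: str, mean_depth: float = 10.0,
                        error_rate: float = 0.01, seed: int = 0,
                        pool: HaplotypePool | None = None,
                        ) -> tuple[BaseCountTensor, SimTruth]:
    """Generate one of the lower/middle/higher copy-number benchmark designs."""
    if dataset not in TABLE2_CONFIGS:
        raise ValueError(f"dataset must be one of {sorted(TABLE2_CONFIGS)}")
    if pool is None:
        pool = make_haplotype_pool(seed=seed)
    config = assign_alleles(pool, TABLE2_CONFIGS[dataset], seed=seed)
    token_set = AlleleSet(pool.tokens)
    counts = simulate_counts(config, token_set, mean_depth, error_rate, seed=seed)
    truth = _truth_from_config(config, pool.tokens, mean_depth, error_rate, seed)
    return counts, truth
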