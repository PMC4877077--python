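"""Synthetic RNA-seq count data with known gene-set truth.

Emulates a small-n multi-group bulk RNA-seq experiment — by default three
groups (vehicle and two post-treatment time points) of four biological
replicates over ~12,000 genes — as negative-binomial counts:

    count_gj ~ NB(mean = s_j * mu_g * 2**shift[g, group(j)], dispersion)

with per-gene base means drawn log-uniformly, per-sample library-size
factors s_j drawn uniformly, and a single common dispersion.  Gene sets
are random draws from the gene universe; "spiked" sets additionally give
their member genes a log2 group-mean shift in designated groups, which is
the known truth that calibration and power tests check against.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import CountMatrix, GeneSetCollection, SampleDesign

__all__ = [
    "SimulationTruth",
    "DEFAULT_GROUP_SIZES",
    "SMALL_N_GROUP_SIZES",
    "make_design",
    "simulate_counts",
    "simulate_gene_sets",
    "simulate_dataset",
]

#: The study-like design: three groups of four replicates.
DEFAULT_GROUP_SIZES: dict[str, int] = {"vehicle": 4, "GTN-30": 4, "GTN-90": 4}

#: Post-QC stress design: unbalanced small groups.
SMALL_N_GROUP_SIZES: dict[str, int] = {"vehicle": 2, "GTN-30": 4, "GTN-90": 3}


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset."""

    spiked_set_names: list[str] = field(default_factory=list)
    shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    dispersion: float = 0.1
    size_factors: np.ndarray | None = None
    rng_seed: int = 0
    group_sizes: dict[str, int] = field(default_factory=dict)


def make_design(group_sizes: dict[str, int]) -> SampleDesign:
    """Design with samples named ``<group>-<replicate>`` in group order."""
    sample_ids = []
    group_of = {}
    for group, size in group_sizes.items():
        if size < 1:
            raise ValueError(f"group {group!r} must have >= 1 sample")
        for i in range(1, size + 1):
            sid = f"{group}-{i}"
            sample_ids.append(sid)
            group_of[sid] = group
    return SampleDesign(sample_ids, group_of)


def simulate_counts(
    n_genes: int = 12000,
    group_sizes: dict[str, int] | None = None,
    base_mean_range: tuple[float, float] = (10.0, 1000.0),
    dispersion: float = 0.1,
    size_factor_range: tuple[float, float] = (0.7, 1.4),
    shifts: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[CountMatrix, SampleDesign, SimulationTruth]:
    """Negative-binomial count matrix with optional group-mean shifts.

    Parameters
    ----------
    shifts : mapping gene_id -> {group: log2 shift}
        Genes absent from the mapping (or groups absent from a gene's
        entry) have shift 0.
    dispersion : float
        NB dispersion alpha; variance = mu + alpha * mu**2.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    lo, hi = base_mean_range
    if not 0 < lo <= hi:
        raise ValueError(f"invalid base_mean_range {base_mean_range}")
    slo, shi = size_factor_range
    if not 0 < slo <= shi:
        raise ValueError(f"invalid size_factor_range {size_factor_range}")
    group_sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    design = make_design(group_sizes)
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    s = rng.uniform(slo, shi, size=design.n)
    groups = design.groups
    shift_matrix = np.zeros((n_genes, len(groups)))
    if shifts:
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        group_pos = {g: i for i, g in enumerate(groups)}
        for gene, per_group in shifts.items():
            if gene not in gene_pos:
                raise KeyError(f"shifted gene {gene!r} not in gene universe")
            for group, shift in per_group.items():
                shift_matrix[gene_pos[gene], group_pos[group]] = shift

    labels = design.labels()
    mean = s[np.newaxis, :] * mu[:, np.newaxis] * 2.0 ** shift_matrix[:, labels]
    r = 1.0 / dispersion  # NB number of successes
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    cm = CountMatrix(gene_ids, design.sample_ids, counts.astype(np.int64))
    truth = SimulationTruth(
        spiked_set_names=[],
        shifts={g: dict(v) for g, v in (shifts or {}).items()},
        dispersion=dispersion,
        size_factors=s,
        rng_seed=seed,
        group_sizes=group_sizes,
    )
    return cm, design, truth


def simulate_gene_sets(
    universe: list[str],
    n_sets: int = 100,
    size_range: tuple[int, int] = (10, 50),
    n_spiked: int = 0,
    spike_shift: float = 1.0,
    spike_groups: tuple[str, ...] = ("GTN-90",),
    spiked_size: int | None = None,
    seed: int = 0,
) -> tuple[GeneSetCollection, SimulationTruth]:
    """Random gene sets over ``universe``, the first ``n_spiked`` spiked.

    Spiked sets' members get a ``spike_shift`` log2 group-mean shift in
    each group of ``spike_groups`` (recorded in the returned truth; apply
    it by passing ``truth.shifts`` to :func:`simulate_counts`).  Sets may
    overlap; sizes are drawn uniformly from ``size_range`` except spiked
    sets, which use ``spiked_size`` when given.
    """
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError(f"invalid size_range {size_range} for universe of {len(universe)}")
    if not 0 <= n_spiked <= n_sets:
        raise ValueError("n_spiked must be in [0, n_sets]")
    if spiked_size is not None and not 1 <= spiked_size <= len(universe):
        raise ValueError(f"spiked_size {spiked_size} infeasible")
    rng = np.random.default_rng(seed)
    universe_arr = np.asarray(universe)
    coll = GeneSetCollection()
    truth = SimulationTruth(rng_seed=seed)
    width = len(str(n_sets))
    for i in range(n_sets):
        spiked = i < n_spiked
        if spiked and spiked_size is not None:
            size = spiked_size
        else:
            size = int(rng.integers(lo, hi + 1))
        members = universe_arr[rng.choice(len(universe_arr), size=size, replace=False)]
        name = f"set_{i + 1:0{width}d}"
        desc = "spiked" if spiked else "null"
        coll.add(name, members.tolist(), desc)
        if spiked:
            truth.spiked_set_names.append(name)
            for gene in members:
                entry = truth.shifts.setdefault(str(gene), {})
                for group in spike_groups:
                    entry[group] = spike_shift
    return coll, truth


def simulate_dataset(
    preset: str = "null",
    seed: int = 0,
    n_genes: int = 12000,
    n_sets: int = 100,
    **overrides,
) -> tuple[CountMatrix, SampleDesign, GeneSetCollection, SimulationTruth]:
    """One-call dataset: counts, design, gene sets and truth.

    Presets: ``"null"`` (no shifted sets), ``"spiked"`` (one set of 30
    genes shifted +1.0 log2 units in the last group), ``"small-n"``
    (null data on the unbalanced 2/4/3 design).
    """
    ss = np.random.SeedSequence(seed)
    seed_sets, seed_counts = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    group_sizes = dict(DEFAULT_GROUP_SIZES)
    sim_kwargs = dict(n_spiked=0)
    if preset == "spiked":
        sim_kwargs = dict(n_spiked=1, spike_shift=1.0, spiked_size=30)
    elif preset == "small-n":
        group_sizes = dict(SMALL_N_GROUP_SIZES)
    elif preset != "null":
        raise ValueError(f"unknown preset {preset!r}")
    sim_kwargs.update({k: v for k, v in overrides.items() if k in (
        "size_range", "spike_shift", "spike_groups", "spiked_size", "n_spiked")})
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    last_group = list(group_sizes)[-1]
    if "spike_groups" not in sim_kwargs:
        sim_kwargs["spike_groups"] = (last_group,)
    sets, set_truth = simulate_gene_sets(
        gene_ids, n_sets=n_sets, seed=seed_sets, **sim_kwargs
    )
    count_kwargs = {k: v for k, v in overrides.items() if k in (
        "base_mean_range", "dispersion", "size_factor_range")}
    cm, design, count_truth = simulate_counts(
        n_genes=n_genes,
        group_sizes=group_sizes,
        shifts=set_truth.shifts,
        seed=seed_counts,
        gene_ids=gene_ids,
        **count_kwargs,
    )
    truth = SimulationTruth(
        spiked_set_names=set_truth.spiked_set_names,
        shifts=set_truth.shifts,
        dispersion=count_truth.dispersion,
        size_factors=count_truth.size_factors,
        rng_seed=seed,
        group_sizes=group_sizes,
    )
    return cm, design, sets, truth
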