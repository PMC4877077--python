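"""Gene Set Analysis of Variance (GSANOVA).

Scores each gene with the one-way ANOVA F-statistic across the k sample
groups — the ratio of between-group to within-group variation — so that
expression changes over more than two conditions (for example two
post-treatment time points against vehicle) contribute to a single
gene-level score.  A gene set's raw enrichment score is the mean F over
its members; it is standardized by the mean and standard deviation of the
scores of random gene sets of identical size, and inference comes from
permutations of the group labels: a nominal p-value per set from its own
permutation distribution, a pooled p-value from the global null obtained
by combining permutation scores across all sets, and q-values computed
from the pooled p-values.  Sets with q below the cutoff (default 0.25)
are called enriched.

For a gene with values :math:`x_{ij}` (group i, replicate j), group means
:math:`\\bar x_i`, global mean :math:`\\bar x`, group sizes :math:`n_i`,
:math:`n` samples and :math:`k` groups:

.. math::

    f = \\frac{n-k}{k-1}\\;
        \\frac{\\sum_i n_i(\\bar x_i - \\bar x)^2}
             {\\sum_i \\sum_j (x_{ij} - \\bar x_i)^2}

Unexpressed genes are assigned f = 0.  A zero within-group sum of squares
with a positive between-group sum gives f equal to a large finite cap
rather than infinity, so set means stay finite.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, GeneSetCollection, SampleDesign
from .normalize import ExpressionMatrix, vst_log

logger = logging.getLogger(__name__)

__all__ = [
    "GeneLevelStats",
    "GsanovaParams",
    "EnrichmentResult",
    "GsanovaResults",
    "expressed_mask",
    "gene_f_statistics",
    "raw_set_score",
    "standardize_score",
    "permutation_null",
    "exhaustive_permutation_null",
    "nominal_p",
    "pooled_p",
    "qvalues",
    "estimate_pi0",
    "run_gsanova",
]

#: Finite stand-in for an infinite F (zero within-group variance with a
#: nonzero between-group difference).
F_CAP_DEFAULT = 1e12


@dataclass
class GeneLevelStats:
    """Per-gene F-statistics over an expression matrix."""

    gene_ids: list[str]
    f: np.ndarray
    expressed: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.expressed = np.asarray(self.expressed, dtype=bool)
        if len(self.gene_ids) != self.f.size or self.f.size != self.expressed.size:
            raise ValueError("gene_ids, f and expressed must have equal length")
        if (self.f < 0).any():
            raise ValueError("f-statistics must be non-negative")
        if self.f[~self.expressed].any():
            raise ValueError("unexpressed genes must have f = 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class GsanovaParams:
    """Tuning knobs for a GSANOVA run.

    Defaults follow the method's reference settings: 1000 random gene sets
    for standardization, 1000 label permutations, and an enrichment call
    at q < 0.25.
    """

    n_random_sets: int = 1000
    n_permutations: int = 1000
    q_cutoff: float = 0.25
    rng_seed: int = 0
    pi0_method: str = "fixed_one"  # or "storey_smoother"
    reuse_random_sets: bool = False
    f_cap: float = F_CAP_DEFAULT
    expressed_min_total: int = 1  # gene is expressed iff total count >= this
    min_set_size: int | None = None
    max_set_size: int | None = None
    pseudocount: float = 1.0
    threads: int = 1

    def __post_init__(self) -> None:
        if self.n_random_sets < 1:
            raise ValueError("n_random_sets must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.q_cutoff <= 1:
            raise ValueError("q_cutoff must be in (0, 1]")
        if self.pi0_method not in ("fixed_one", "storey_smoother"):
            raise ValueError(f"unknown pi0_method {self.pi0_method!r}")


@dataclass
class EnrichmentResult:
    set_name: str
    set_size_in_universe: int
    raw_score: float
    standardized_score: float
    p_nominal: float
    p_pooled: float
    q_value: float
    significant: bool


class GsanovaResults(list):
    """List of :class:`EnrichmentResult` with a run log attached."""

    def __init__(self, results, log: dict | None = None):
        super().__init__(results)
        self.log: dict = log or {}


def expressed_mask(cm: CountMatrix, min_total: int = 1) -> np.ndarray:
    """Boolean per-gene mask: total count across samples >= ``min_total``."""
    return cm.counts.sum(axis=1) >= min_total


def _f_from_values(
    values: np.ndarray, labels: np.ndarray, k: int, f_cap: float
) -> np.ndarray:
    """Vectorized one-way ANOVA F per row of ``values``.

    0/0 (no variation at all) yields 0; x/0 yields ``f_cap``.
    """
    n = values.shape[1]
    n_i = np.bincount(labels, minlength=k).astype(float)
    indicator = np.zeros((n, k))
    indicator[np.arange(n), labels] = 1.0
    group_means = (values @ indicator) / n_i
    grand = values.mean(axis=1, keepdims=True)
    between = ((group_means - grand) ** 2 * n_i).sum(axis=1)
    within = ((values - group_means[:, labels]) ** 2).sum(axis=1)
    # sums of squares below this are rounding dust, not variation
    tiny = 1e-12 * ((values**2).mean(axis=1) + 1.0)
    no_within = within <= tiny
    no_between = between <= tiny
    scale = (n - k) / (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = scale * between / within
    f = np.where(no_within & no_between, 0.0, f)
    f = np.where(no_within & ~no_between, f_cap, f)
    return np.minimum(f, f_cap)


def gene_f_statistics(
    em: ExpressionMatrix,
    design: SampleDesign,
    expressed: np.ndarray | None = None,
    f_cap: float = F_CAP_DEFAULT,
) -> GeneLevelStats:
    """One-way ANOVA F-statistic per gene across the design's groups.

    Parameters
    ----------
    em : ExpressionMatrix
        Transformed expression; columns must include every design sample.
    design : SampleDesign
        Sample → group assignment (k >= 2 groups, n > k samples).
    expressed : bool array, optional
        Per-gene expressed flag; unexpressed genes get f = 0.  Defaults to
        all genes expressed (see :func:`expressed_mask` for the count-based
        rule).
    f_cap : float
        Finite cap replacing an infinite F.
    """
    pos = {s: i for i, s in enumerate(em.sample_ids)}
    missing = [s for s in design.sample_ids if s not in pos]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing[:5]}")
    if design.n <= design.k:
        raise ValueError(
            f"need n > k samples for a within-group variance "
            f"(n={design.n}, k={design.k})"
        )
    cols = [pos[s] for s in design.sample_ids]
    values = em.values[:, cols]
    labels = design.labels()
    f = _f_from_values(values, labels, design.k, f_cap)
    if expressed is None:
        expressed = np.ones(em.n_genes, dtype=bool)
    expressed = np.asarray(expressed, dtype=bool)
    f = np.where(expressed, f, 0.0)
    return GeneLevelStats(list(em.gene_ids), f, expressed)


def raw_set_score(
    stats: GeneLevelStats, members: set[str] | list[str]
) -> tuple[float, int]:
    """Mean F over the set's members present in the gene universe.

    Returns ``(nan, 0)`` when no member is present; callers skip such sets
    with a warning rather than failing the run.
    """
    member_set = set(members)
    idx = [i for i, g in enumerate(stats.gene_ids) if g in member_set]
    if not idx:
        return float("nan"), 0
    return float(stats.f[idx].mean()), len(idx)


def _member_indices(stats: GeneLevelStats, members: set[str]) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(stats.gene_ids)}
    return np.array(sorted(lookup[g] for g in members if g in lookup), dtype=np.intp)


def _sample_index_sets(
    rng: np.random.Generator, n_universe: int, size: int, n_sets: int
) -> np.ndarray:
    """``n_sets`` uniform without-replacement index samples of ``size``.

    Small sets use rejection of rows containing duplicates (exact, fast
    when size << universe); sets comparable to the universe fall back to
    partial shuffles.
    """
    if size > n_universe:
        raise ValueError(f"set size {size} exceeds universe size {n_universe}")
    if size * size > n_universe:  # collision-heavy: partial-shuffle route
        keys = rng.random((n_sets, n_universe))
        return np.argpartition(keys, size - 1, axis=1)[:, :size].astype(np.intp)
    idx = rng.integers(0, n_universe, size=(n_sets, size))
    while True:
        srt = np.sort(idx, axis=1)
        bad = (np.diff(srt, axis=1) == 0).any(axis=1)
        if not bad.any():
            return idx.astype(np.intp)
        idx[bad] = rng.integers(0, n_universe, size=(int(bad.sum()), size))


def _standardize(raw: float, null_means: np.ndarray) -> float:
    mu = float(null_means.mean())
    sd = float(null_means.std(ddof=1)) if null_means.size > 1 else 0.0
    if sd == 0.0:
        return 0.0
    return (raw - mu) / sd


def _enumerated_set_means(f: np.ndarray, size: int) -> np.ndarray:
    return np.array(
        [f[list(c)].mean() for c in itertools.combinations(range(f.size), size)]
    )


def _null_set_means(
    f: np.ndarray,
    size: int,
    n_random: int,
    rng: np.random.Generator,
    method: str = "sample",
) -> np.ndarray:
    """Mean-F scores of the null (random same-size) gene sets.

    In ``"sample"`` mode, when every distinct subset can be covered by the
    ``n_random`` budget the enumeration replaces sampling — exact on toy
    universes, unreachable on realistic ones.
    """
    n_universe = f.size
    if size > n_universe:
        raise ValueError(f"set size {size} exceeds universe size {n_universe}")
    n_subsets = math.comb(n_universe, size)
    if method == "exhaustive":
        if n_subsets > 2_000_000:
            raise ValueError("universe too large for exhaustive enumeration")
        return _enumerated_set_means(f, size)
    if method != "sample":
        raise ValueError(f"unknown method {method!r}")
    if n_subsets <= n_random:
        return _enumerated_set_means(f, size)
    idx = _sample_index_sets(rng, n_universe, size, n_random)
    return f[idx].mean(axis=1)


def standardize_score(
    raw: float,
    size: int,
    stats: GeneLevelStats,
    n_random: int = 1000,
    rng: np.random.Generator | int | None = None,
    method: str = "sample",
) -> float:
    """Center and scale a raw set score by same-size random-set scores.

    ``method="sample"`` draws ``n_random`` gene sets of exactly ``size``
    genes uniformly without replacement from the full gene universe
    (unexpressed genes included, carrying f = 0) and standardizes with the
    sample mean and standard deviation (ddof=1) of their mean-F scores;
    when the universe admits no more than ``n_random`` distinct subsets
    they are enumerated exactly instead.  ``method="exhaustive"`` forces
    the enumeration, which is deterministic on small universes.  A zero
    standard deviation yields 0.
    """
    if size < 1:
        raise ValueError("set size must be >= 1")
    null_means = _null_set_means(
        stats.f, size, n_random, np.random.default_rng(rng), method
    )
    return _standardize(raw, null_means)


def _score_sets_for_stats(
    f: np.ndarray,
    member_idx: list[np.ndarray],
    n_random: int,
    rng: np.random.Generator,
    reuse_idx: list[np.ndarray] | None,
) -> np.ndarray:
    """Standardized score of every set under the gene stats ``f``."""
    out = np.empty(len(member_idx))
    for s, midx in enumerate(member_idx):
        raw = float(f[midx].mean())
        if reuse_idx is not None:
            null_means = f[reuse_idx[s]].mean(axis=1)
        else:
            null_means = _null_set_means(f, midx.size, n_random, rng)
        out[s] = _standardize(raw, null_means)
    return out


def permutation_null(
    em: ExpressionMatrix,
    design: SampleDesign,
    sets: GeneSetCollection,
    params: GsanovaParams,
    expressed: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Standardized null scores per set under label permutations.

    For each of B permutations the full group-label vector is shuffled
    uniformly (group sizes preserved, no stratification), gene F-statistics
    are recomputed, and every set's score is re-standardized — with freshly
    drawn random sets per permutation by default, or with the same index
    draws reused across permutations when ``params.reuse_random_sets`` is
    set (faster, slightly dependent nulls).  Fully reproducible from
    ``params.rng_seed``; the per-permutation streams are derived
    independently, so results do not depend on ``params.threads``.
    """
    stats = gene_f_statistics(em, design, expressed, params.f_cap)
    member_idx = [_member_indices(stats, sets[name]) for name in sets]
    if any(m.size == 0 for m in member_idx):
        raise ValueError("permutation_null requires every set to intersect the universe")
    labels = design.labels()
    pos = {s: i for i, s in enumerate(em.sample_ids)}
    values = em.values[:, [pos[s] for s in design.sample_ids]]
    expressed_arr = stats.expressed

    root = np.random.SeedSequence(params.rng_seed)
    perm_seeds = root.spawn(params.n_permutations)
    reuse_idx = None
    if params.reuse_random_sets:
        reuse_rng = np.random.default_rng(root.spawn(1)[0])
        reuse_idx = [
            _sample_index_sets(reuse_rng, stats.n_genes, m.size, params.n_random_sets)
            for m in member_idx
        ]

    def one_perm(seed: np.random.SeedSequence) -> np.ndarray:
        rng = np.random.default_rng(seed)
        perm_labels = rng.permutation(labels)
        f = _f_from_values(values, perm_labels, design.k, params.f_cap)
        f = np.where(expressed_arr, f, 0.0)
        return _score_sets_for_stats(
            f, member_idx, params.n_random_sets, rng, reuse_idx
        )

    if params.threads > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=params.threads)(
            delayed(one_perm)(s) for s in perm_seeds
        )
    else:
        rows = [one_perm(s) for s in perm_seeds]
    null = np.vstack(rows)  # B x n_sets
    return {name: null[:, s] for s, name in enumerate(sets)}


def exhaustive_permutation_null(
    em: ExpressionMatrix,
    design: SampleDesign,
    sets: GeneSetCollection,
    params: GsanovaParams,
    expressed: np.ndarray | None = None,
    standardize_method: str = "exhaustive",
) -> dict[str, np.ndarray]:
    """Null scores under every distinct group-label assignment.

    Only feasible on toy designs (the number of distinct assignments is a
    multinomial coefficient).  With ``standardize_method="exhaustive"`` the
    whole null is deterministic.
    """
    stats = gene_f_statistics(em, design, expressed, params.f_cap)
    member_idx = [_member_indices(stats, sets[name]) for name in sets]
    labels = design.labels()
    if len(labels) > 10:
        raise ValueError("exhaustive permutation is only feasible for <= 10 samples")
    pos = {s: i for i, s in enumerate(em.sample_ids)}
    values = em.values[:, [pos[s] for s in design.sample_ids]]
    assignments = sorted(set(itertools.permutations(labels.tolist())))
    rng = np.random.default_rng(params.rng_seed)
    rows = []
    for assign in assignments:
        f = _f_from_values(values, np.array(assign), design.k, params.f_cap)
        f = np.where(stats.expressed, f, 0.0)
        row = np.empty(len(member_idx))
        for s, midx in enumerate(member_idx):
            raw = float(f[midx].mean())
            fake = GeneLevelStats(stats.gene_ids, f, stats.expressed)
            row[s] = standardize_score(
                raw, midx.size, fake, params.n_random_sets, rng, standardize_method
            )
        rows.append(row)
    null = np.vstack(rows)
    return {name: null[:, s] for s, name in enumerate(sets)}


def nominal_p(observed: float, null_scores: np.ndarray) -> float:
    """Upper-tail permutation p with add-one correction: in (0, 1]."""
    null_scores = np.asarray(null_scores)
    if null_scores.size == 0:
        raise ValueError("empty null distribution")
    b = int((null_scores >= observed).sum())
    return (1 + b) / (null_scores.size + 1)


def pooled_p(observed: float, pooled_null: np.ndarray) -> float:
    """Upper-tail p against the global null pooled across all sets."""
    return nominal_p(observed, pooled_null)


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi0 via the cubic-smoother-on-a-lambda-grid procedure.

    pi0(λ) = #{p > λ} / (m (1 − λ)) on a grid of λ, smoothed with a cubic
    spline and read off at the largest λ; clipped to (0, 1].
    """
    from scipy.interpolate import UnivariateSpline

    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    if m < 8:  # too few points for the smoother to be meaningful
        return 1.0
    pi0_lam = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    spline = UnivariateSpline(lambdas, pi0_lam, k=3)
    pi0 = float(spline(lambdas[-1]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(p: np.ndarray, pi0_method: str = "fixed_one") -> np.ndarray:
    """q-values from p-values: pi0 × Benjamini–Hochberg adjusted p.

    With ``pi0_method="fixed_one"`` this is exactly the BH step-up
    adjustment.  ``"storey_smoother"`` scales by the estimated fraction of
    true nulls (:func:`estimate_pi0`), giving the classical q-value.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if pi0_method == "fixed_one":
        pi0 = 1.0
    elif pi0_method == "storey_smoother":
        pi0 = estimate_pi0(p)
    else:
        raise ValueError(f"unknown pi0_method {pi0_method!r}")
    bh = multipletests(p, method="fdr_bh")[1]
    return np.clip(pi0 * bh, 0.0, 1.0)


def run_gsanova(
    cm: CountMatrix,
    design: SampleDesign,
    sets: GeneSetCollection,
    params: GsanovaParams | None = None,
) -> GsanovaResults:
    """Full GSANOVA pipeline on a count matrix.

    Steps: log-transform normalized counts → per-gene F-statistics
    (unexpressed genes scored 0) → per-set raw and standardized scores →
    permutation null → nominal p per set → pooled p against the global
    null → q-values from the pooled p-values → enrichment call at
    q < ``params.q_cutoff``.  Results are sorted by q-value then pooled p;
    the returned list carries a ``log`` dict recording the seed,
    parameters and any skipped sets.
    """
    params = params or GsanovaParams()
    em = vst_log(cm, params.pseudocount)
    expressed = expressed_mask(cm, params.expressed_min_total)
    stats = gene_f_statistics(em, design, expressed, params.f_cap)

    surviving = GeneSetCollection()
    skipped: dict[str, str] = {}
    raw_scores: dict[str, tuple[float, int]] = {}
    for name in sets:
        raw, size = raw_set_score(stats, sets[name])
        if size == 0:
            skipped[name] = "no member in gene universe"
            logger.warning("skipping set %r: no member in gene universe", name)
            continue
        if params.min_set_size is not None and size < params.min_set_size:
            skipped[name] = f"size {size} < min_set_size {params.min_set_size}"
            continue
        if params.max_set_size is not None and size > params.max_set_size:
            skipped[name] = f"size {size} > max_set_size {params.max_set_size}"
            continue
        surviving.add(name, sets[name], sets.descriptions.get(name, ""))
        raw_scores[name] = (raw, size)
    if len(surviving) == 0:
        raise ValueError("no gene set survives filtering; nothing to test")

    root = np.random.SeedSequence(params.rng_seed)
    obs_rng = np.random.default_rng(root.spawn(3)[2])  # distinct from perm streams
    standardized = {
        name: standardize_score(
            raw_scores[name][0], raw_scores[name][1], stats,
            params.n_random_sets, obs_rng,
        )
        for name in surviving
    }
    null = permutation_null(em, design, surviving, params, expressed)
    pooled_null = np.concatenate([null[name] for name in surviving])
    p_nom = {name: nominal_p(standardized[name], null[name]) for name in surviving}
    p_pool = {name: pooled_p(standardized[name], pooled_null) for name in surviving}
    names = list(surviving)
    q = qvalues(np.array([p_pool[n] for n in names]), params.pi0_method)
    results = [
        EnrichmentResult(
            set_name=name,
            set_size_in_universe=raw_scores[name][1],
            raw_score=raw_scores[name][0],
            standardized_score=standardized[name],
            p_nominal=p_nom[name],
            p_pooled=p_pool[name],
            q_value=float(q[i]),
            significant=bool(q[i] < params.q_cutoff),
        )
        for i, name in enumerate(names)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_pooled, r.set_name))
    log = {
        "seed": params.rng_seed,
        "n_permutations": params.n_permutations,
        "n_random_sets": params.n_random_sets,
        "q_cutoff": params.q_cutoff,
        "pi0_method": params.pi0_method,
        "transform": em.transform_tag,
        "n_genes": cm.n_genes,
        "n_expressed": int(expressed.sum()),
        "n_sets_tested": len(surviving),
        "skipped_sets": skipped,
    }
    return GsanovaResults(results, log)
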