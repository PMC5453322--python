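"""Randomization-based term enrichment.

For every sufficiently frequent term, the observed coverage score of a
test exon set is compared with the distribution of scores of random
exon sets of approximately the same total coding size drawn from a
control pool (all coding exons, internal constitutive exons, ...).
Because coverage scores are approximately log-normal across random
sets, the comparison happens on the log scale:

    z = (log s_obs - mu) / sigma

where mu and sigma are the mean and standard deviation of the log
scores of ``n_sets`` random sets (1000 by default).  A two-sided normal
p-value is attached to each z (an empirical permutation p-value is
available as an alternative), and Benjamini-Hochberg adjustment across
the tested terms yields q-values.  Only terms annotated on at least a
configurable fraction of the control universe (4% by default) are
tested; rarer terms make the log-score null degenerate.

Zero scores are floored at the score of a single covered nucleotide
over the set's total coding size before taking logs — an
order-preserving choice that keeps the transform finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationStore, term_frequency
from .genome_model import ExonSet
from .ontology import OntologyTree
from .scoring import SCALE

log = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class NullDistribution:
    """Log-scale null for one term at one target set size."""

    term_id: str
    n_sets: int
    log_scores: np.ndarray
    mu: float
    sigma: float
    target_size_nt: int
    realized_sizes: np.ndarray


@dataclass
class EnrichmentResult:
    term_id: str
    observed_score: float
    covered_nt: int
    total_nt: int
    null_mu_log: float
    null_sigma_log: float
    z: float
    p: float
    q: float
    direction: str  # enriched / depleted / none / untestable


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sample_control_set(
    pool: ExonSet, target_size_nt: int, rng: np.random.Generator
) -> ExonSet:
    """Draw exons uniformly without replacement until the cumulative
    coding size first reaches *target_size_nt*."""
    lengths = np.array([e.coding_length for e in pool.exons])
    if lengths.sum() < target_size_nt:
        raise EnrichmentError(
            f"pool holds {lengths.sum()} coding nt < target {target_size_nt}"
        )
    order = rng.permutation(len(pool))
    cum = np.cumsum(lengths[order])
    k = int(np.searchsorted(cum, target_size_nt, side="left"))
    return ExonSet([pool.exons[i] for i in order[: k + 1]])


def _null_score_matrix(
    covered: np.ndarray,
    lengths: np.ndarray,
    target_size_nt: int,
    n_sets: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Scores (n_sets x n_terms) of random size-matched sets, plus sizes."""
    if lengths.sum() < target_size_nt:
        raise EnrichmentError("control pool smaller than target size")
    scores = np.empty((n_sets, covered.shape[1]))
    sizes = np.empty(n_sets, dtype=np.int64)
    for i in range(n_sets):
        order = rng.permutation(len(lengths))
        cum = np.cumsum(lengths[order])
        k = int(np.searchsorted(cum, target_size_nt, side="left"))
        sel = order[: k + 1]
        total = int(cum[k])
        sizes[i] = total
        scores[i] = SCALE * covered[sel].sum(axis=0) / total
        # floor zero scores at one covered nucleotide over this set's size
        scores[i][scores[i] == 0.0] = SCALE / total
    return scores, sizes


def build_null(
    store: AnnotationStore,
    pool: ExonSet,
    target_size_nt: int,
    terms: list[str],
    n_sets: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict[str, NullDistribution]:
    """One log-scale null distribution per term.

    A single pass over each sampled set scores all terms at once.
    Terms whose null has zero spread are flagged untestable downstream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    covered = store.coverage_matrix(pool.exon_ids, terms)
    lengths = np.array([e.coding_length for e in pool.exons])
    scores, sizes = _null_score_matrix(covered, lengths, target_size_nt, n_sets, rng)
    logs = np.log(scores)
    mus = logs.mean(axis=0)
    sigmas = logs.std(axis=0, ddof=1)
    return {
        t: NullDistribution(t, n_sets, logs[:, j], float(mus[j]), float(sigmas[j]),
                            target_size_nt, sizes)
        for j, t in enumerate(terms)
    }


def enrich(
    test: ExonSet,
    pool: ExonSet,
    store: AnnotationStore,
    tree: OntologyTree | None = None,
    n_sets: int = 1000,
    seed: int = 0,
    min_freq: float = 0.04,
    mode: str = "parametric",
    exclude_test: bool = False,
) -> "EnrichmentTable":
    """Test every sufficiently frequent term for enrichment/depletion.

    Parameters
    ----------
    test : ExonSet
        Exons of interest.
    pool : ExonSet
        Control universe the null sets are drawn from.  Test exons stay
        in the pool unless ``exclude_test`` is set (the usual designs —
        e.g. alternative vs constitutive exons — are disjoint already).
    n_sets : int
        Random sets per null distribution.
    min_freq : float
        Minimum fraction of pool exons a term must annotate to be
        tested.
    mode : {"parametric", "empirical"}
        Two-sided normal p from z, or a permutation p computed as
        ``(1 + #{null >= obs or <= obs}) / (n_sets + 1)``, doubled and
        capped at 1.
    """
    if len(test) == 0:
        raise EnrichmentError("empty test set")
    if mode not in ("parametric", "empirical"):
        raise EnrichmentError(f"unknown mode {mode!r}")
    if exclude_test:
        drop = set(test.exon_ids)
        pool = ExonSet([e for e in pool.exons if e.exon_id not in drop])
    freqs = term_frequency(store, pool)
    terms = sorted(t for t, f in freqs.items() if f >= min_freq)
    if not terms:
        log.warning("no term passes the %.0f%% frequency filter", 100 * min_freq)
        return EnrichmentTable([], n_sets=n_sets, seed=seed, mode=mode)

    target = test.total_coding_nt
    nulls = build_null(store, pool, target, terms, n_sets=n_sets, seed=seed)

    obs_cov = store.coverage_matrix(test.exon_ids, terms).sum(axis=0)
    obs_score = SCALE * obs_cov / target
    obs_floored = np.where(obs_score == 0.0, SCALE / target, obs_score)
    log_obs = np.log(obs_floored)

    results: list[EnrichmentResult] = []
    testable_idx, pvals = [], []
    for j, t in enumerate(terms):
        nd = nulls[t]
        # sigma of a constant null is ~1 ulp, not exactly 0
        if nd.sigma <= 1e-12 * max(1.0, abs(nd.mu)):
            log.warning("term %s has a degenerate null; flagged untestable", t)
            results.append(
                EnrichmentResult(t, float(obs_score[j]), int(obs_cov[j]), target,
                                 nd.mu, nd.sigma, np.nan, np.nan, np.nan, "untestable")
            )
            continue
        z = (log_obs[j] - nd.mu) / nd.sigma
        if mode == "parametric":
            p = 2.0 * stats.norm.sf(abs(z))
        else:
            ge = int(np.sum(nd.log_scores >= log_obs[j]))
            le = int(np.sum(nd.log_scores <= log_obs[j]))
            p = min(1.0, 2.0 * (1 + min(ge, le)) / (nd.n_sets + 1))
        direction = "enriched" if z > 0 else ("depleted" if z < 0 else "none")
        results.append(
            EnrichmentResult(t, float(obs_score[j]), int(obs_cov[j]), target,
                             nd.mu, nd.sigma, float(z), float(p), np.nan, direction)
        )
        testable_idx.append(len(results) - 1)
        pvals.append(p)
    if pvals:
        for i, q in zip(testable_idx, bh_fdr(pvals)):
            results[i].q = float(q)
    results.sort(
        key=lambda r: (
            np.isnan(r.q),
            r.q if not np.isnan(r.q) else 0.0,
            -abs(r.z) if not np.isnan(r.z) else 0.0,
            r.term_id,
        )
    )
    return EnrichmentTable(results, n_sets=n_sets, seed=seed, mode=mode)


class EnrichmentTable:
    """Ordered enrichment results with tabular export."""

    def __init__(self, results: list[EnrichmentResult], n_sets: int, seed: int, mode: str):
        self.results = results
        self.n_sets = n_sets
        self.seed = seed
        self.mode = mode

    def __len__(self):
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, i):
        return self.results[i]

    def to_frame(self, tree: OntologyTree | None = None) -> pd.DataFrame:
        rows = []
        for r in self.results:
            name = root = ""
            if tree is not None and r.term_id in tree:
                name = tree.nodes[r.term_id].name
                root = tree.root_class_of(r.term_id) or ""
            rows.append(
                (r.term_id, name, root, r.covered_nt, r.total_nt,
                 r.observed_score, r.null_mu_log, r.null_sigma_log,
                 r.z, r.p, r.q, r.direction)
            )
        return pd.DataFrame(
            rows,
            columns=["term_id", "name", "root_class", "covered_nt", "total_nt",
                     "score", "null_mu_log", "null_sigma_log", "z", "p", "q",
                     "direction"],
        )

    def summary(self, tree: OntologyTree | None = None) -> str:
        df = self.to_frame(tree)
        lines = [
            f"Term enrichment over {len(df)} tested terms "
            f"(n_null={self.n_sets}, mode={self.mode}, seed={self.seed})",
            df.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
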