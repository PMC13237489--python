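"""Label-permutation stress tests and pairwise similarity/label analysis.

Two independent checks of whether weak (LLM-derived) activity labels carry
real sequence-associated signal:

* a permutation null model — a classifier on pooled embeddings is scored by
  stratified CV on the true labels and on B label permutations drawn under
  increasingly strict covariate controls (global, length-binned, and
  dual length x composition-PC strata), with the add-one empirical p-value
  (b + 1) / (B + 1);
* a pair analysis — are same-label pairs more sequence-similar than
  different-label pairs?  Quantified by the Mann-Whitney AUC of global
  identity for predicting same-label status, the median identity
  difference, and the rank-biserial effect size (= 2 AUC - 1), with
  percentile bootstrap CIs and a label-permutation test on the fixed pair
  table (identities computed once and cached).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn import metrics as skm
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .model import ActivityLabel
from .splits import AlignmentScoring, global_identity
from .training import MetricReport, compute_metrics

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationScheme",
    "NullDistribution",
    "PairStats",
    "equal_frequency_bins",
    "composition_first_pc",
    "permute_labels",
    "permutation_stress_test",
    "pair_agreement_analysis",
    "pair_label_permutation",
]


@dataclass(frozen=True)
class PermutationScheme:
    """kind: 'global', 'length_binned' (10 bins) or 'dual_restricted'
    (5 length x 5 composition bins = 25 strata)."""

    kind: str = "global"
    length_bins: int = 10
    dual_length_bins: int = 5
    composition_bins: int = 5

    def __post_init__(self):
        if self.kind not in ("global", "length_binned", "dual_restricted"):
            raise ValueError(f"unknown permutation scheme {self.kind!r}")


def equal_frequency_bins(values, n_bins: int) -> np.ndarray:
    """Quantile bins via midrank ties; a value on a bin edge goes to the
    lower bin."""
    v = np.asarray(values, dtype=float)
    ranks = rankdata(v, method="average")      # in (0, n]
    bins = np.ceil(ranks * n_bins / len(v)).astype(int) - 1
    return np.clip(bins, 0, n_bins - 1)


def composition_first_pc(sequences) -> np.ndarray:
    """Projection of 20-dim relative amino-acid composition onto the leading
    principal component (mean-centered, sample covariance)."""
    from .seqio import CANONICAL_AA
    comp = np.zeros((len(sequences), 20))
    for i, s in enumerate(sequences):
        if not s:
            raise ValueError("empty sequence")
        for j, aa in enumerate(CANONICAL_AA):
            comp[i, j] = s.count(aa)
        comp[i] /= len(s)
    centered = comp - comp.mean(axis=0)
    cov = np.cov(centered, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    lead = evecs[:, -1]
    nz = lead[np.abs(lead) > 1e-12]
    if nz.size and nz[0] < 0:   # deterministic sign
        lead = -lead
    return centered @ lead


def _strata(scheme: PermutationScheme, n: int, lengths=None,
            composition_pc=None) -> np.ndarray:
    if scheme.kind == "global":
        return np.zeros(n, dtype=int)
    if lengths is None:
        raise ValueError("length covariate required for this scheme")
    if scheme.kind == "length_binned":
        return equal_frequency_bins(lengths, scheme.length_bins)
    if composition_pc is None:
        raise ValueError("composition covariate required for the dual scheme")
    lb = equal_frequency_bins(lengths, scheme.dual_length_bins)
    cb = equal_frequency_bins(composition_pc, scheme.composition_bins)
    return lb * scheme.composition_bins + cb


def permute_labels(labels, scheme: PermutationScheme,
                   rng: np.random.Generator, lengths=None,
                   composition_pc=None) -> np.ndarray:
    """Shuffle labels uniformly within each stratum; the global (and
    per-stratum) label multiset is preserved."""
    y = np.asarray(labels)
    strata = _strata(scheme, len(y), lengths, composition_pc)
    out = y.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(idx) == 1:
            logger.debug("stratum %d has a single member (fixed point)", s)
            continue
        out[idx] = y[idx[rng.permutation(len(idx))]]
    return out


@dataclass
class NullDistribution:
    observed: MetricReport
    null_scores: np.ndarray
    b: int
    p: float
    scheme: PermutationScheme | None = None


def _cv_macro_f1(estimator, features, y, k, seed) -> MetricReport:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    for tr, va in skf.split(features, y):
        est = clone(estimator)
        est.fit(features[tr], y[tr])
        preds[va] = est.predict(features[va])
    return compute_metrics(preds, y)


def permutation_stress_test(features, labels, estimator,
                            scheme: PermutationScheme, B: int = 500,
                            cv_folds: int = 5,
                            rng: np.random.Generator | None = None,
                            lengths=None, composition_pc=None,
                            cv_seed: int = 42) -> NullDistribution:
    """Observed CV Macro-F1 vs B stratified label permutations.

    ``estimator`` is any fit/predict learner on fixed-length feature
    vectors (cloned per fold).  One-sided p = (b + 1)/(B + 1) where b
    counts permutations whose Macro-F1 meets or exceeds the observed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    X = np.asarray(features)
    y = np.asarray([int(v) for v in labels])
    observed = _cv_macro_f1(estimator, X, y, cv_folds, cv_seed)
    null_scores = np.empty(B)
    for i in range(B):
        yp = permute_labels(y, scheme, rng, lengths, composition_pc)
        null_scores[i] = _cv_macro_f1(estimator, X, yp, cv_folds,
                                      cv_seed).macro_f1
    b = int(np.sum(null_scores >= observed.macro_f1))
    return NullDistribution(observed=observed, null_scores=null_scores, b=b,
                            p=(b + 1) / (B + 1), scheme=scheme)


@dataclass
class PairTable:
    """Fixed pair sample with cached identities (never recomputed)."""

    idx_a: np.ndarray
    idx_b: np.ndarray
    identity: np.ndarray
    record_labels: np.ndarray   # per-record labels used for the observed stats


@dataclass
class PairStats:
    n_pairs: int
    auc: float
    median_diff: float
    rank_biserial: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    pair_types: dict[str, int] = field(default_factory=dict)
    table: PairTable | None = None


def _pair_statistics(identity, same) -> tuple[float, float, float]:
    n1, n0 = int(same.sum()), int((~same).sum())
    if n1 == 0 or n0 == 0:
        return float("nan"), float("nan"), float("nan")
    ranks = rankdata(identity)
    auc = (ranks[same].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    median_diff = float(np.median(identity[same]) - np.median(identity[~same]))
    return float(auc), median_diff, float(2 * auc - 1)


def pair_agreement_analysis(records, labels, n_pairs: int = 20000,
                            rng: np.random.Generator | None = None,
                            scoring: AlignmentScoring = AlignmentScoring(),
                            n_boot: int = 1000) -> PairStats:
    """Sample unique unordered pairs, align them once, and quantify how well
    global identity predicts same-label status (same-label = positive)."""
    records = list(records)
    y = np.asarray([int(v) for v in labels])
    if len(records) < 2:
        raise ValueError("need at least two records")
    if not set(y) <= {int(ActivityLabel.HIGH), int(ActivityLabel.LOW)}:
        raise ValueError("pair analysis is restricted to HIGH/LOW labels")
    rng = np.random.default_rng() if rng is None else rng
    n = len(records)
    total = n * (n - 1) // 2
    if n_pairs > total:
        logger.warning("n_pairs capped at C(n,2) = %d", total)
        n_pairs = total
    flat = rng.choice(total, size=n_pairs, replace=False)
    # map linear index m to the unordered pair (i, j), i < j
    i_idx = (n - 2 - np.floor(
        np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(int)
    j_idx = (flat + i_idx + 1 - i_idx * (2 * n - i_idx - 1) // 2).astype(int)
    identity = np.array([
        global_identity(records[i].sequence, records[j].sequence, scoring)
        for i, j in zip(i_idx, j_idx)])
    table = PairTable(i_idx, j_idx, identity, y)

    same = y[i_idx] == y[j_idx]
    auc, median_diff, rb = _pair_statistics(identity, same)
    types = {"high-high": 0, "low-low": 0, "high-low": 0}
    for a, b in zip(y[i_idx], y[j_idx]):
        if a == b:
            types["high-high" if a == ActivityLabel.HIGH else "low-low"] += 1
        else:
            types["high-low"] += 1

    boots = {"auc": [], "median_diff": [], "rank_biserial": []}
    for _ in range(n_boot):
        take = rng.integers(0, n_pairs, size=n_pairs)
        a_, m_, r_ = _pair_statistics(identity[take], same[take])
        boots["auc"].append(a_)
        boots["median_diff"].append(m_)
        boots["rank_biserial"].append(r_)
    ci = {k: (float(np.nanpercentile(v, 2.5)), float(np.nanpercentile(v, 97.5)))
          for k, v in boots.items()}
    return PairStats(n_pairs=n_pairs, auc=auc, median_diff=median_diff,
                     rank_biserial=rb, ci=ci, pair_types=types, table=table)


def pair_label_permutation(table: PairTable, R: int = 1000,
                           rng: np.random.Generator | None = None
                           ) -> dict[str, float]:
    """Two-sided permutation p per statistic on the fixed pair table.

    Labels are permuted across sequence ids; the cached identities are
    reused.  p = (1 + #{|T_r - T_null| >= |T_obs - T_null|}) / (R + 1) with
    null centers AUC = 0.5, median difference = 0, rank-biserial = 0.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    y = table.record_labels
    same_obs = y[table.idx_a] == y[table.idx_b]
    obs = dict(zip(("auc", "median_diff", "rank_biserial"),
                   _pair_statistics(table.identity, same_obs)))
    centers = {"auc": 0.5, "median_diff": 0.0, "rank_biserial": 0.0}
    exceed = {k: 0 for k in obs}
    for _ in range(R):
        yp = y[rng.permutation(len(y))]
        same = yp[table.idx_a] == yp[table.idx_b]
        stat = dict(zip(("auc", "median_diff", "rank_biserial"),
                        _pair_statistics(table.identity, same)))
        for k in obs:
            if np.isnan(stat[k]):
                continue
            if abs(stat[k] - centers[k]) >= abs(obs[k] - centers[k]) - 1e-12:
                exceed[k] += 1
    return {k: (exceed[k] + 1) / (R + 1) for k in obs}
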