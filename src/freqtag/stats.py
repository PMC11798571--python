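"""Inferential statistics for frequency-tagged EEG responses.

Implements the full inferential battery: right-tailed one-sample peak tests
with Benjamini-Hochberg FDR over frequency bins, paired contrasts with the
paired effect size d_z (= t / sqrt(n)), additive-model classification of
multisensory integration (super-additive / additive / sub-additive from the
AV vs A+V contrast), per-electrode congruency effects, a sign-flip
cluster-based permutation test over electrodes for the congruency x
orientation interaction, Pearson correlation with single-pass 3-SD outlier
removal, and a median-split group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .montage import Montage


# --------------------------------------------------------------------------
# result types
# --------------------------------------------------------------------------

@dataclass
class PeakTestResult:
    freqs: np.ndarray
    t: np.ndarray
    p: np.ndarray           # one-tailed (right) raw probabilities
    q_significant: np.ndarray
    tested: np.ndarray      # bins entering the FDR family
    df: int
    alpha: float

    @property
    def significant_freqs(self) -> np.ndarray:
        return self.freqs[self.q_significant]


@dataclass
class ContrastResult:
    t: float
    p: float                # two-tailed
    d: float                # paired effect size d_z = mean(diff) / sd(diff)
    df: int
    mean_diff: float


@dataclass
class IntegrationMode:
    label: str              # super-additive | additive | sub-additive
    contrast: ContrastResult
    alpha: float


@dataclass
class Cluster:
    electrodes: tuple[str, ...]
    stat: float             # summed t over member electrodes
    p: float
    polarity: str           # "positive" | "negative"


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    cluster_alpha: float
    min_neighbors: int
    t_obs: np.ndarray
    labels: list[str]
    low_n_perm: bool = False
    null_max: np.ndarray = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n_used: int
    n_removed_outliers: int


@dataclass
class MedianSplitResult:
    t: float
    p: float
    mean_low: float
    mean_high: float
    n_low: int
    n_high: int


# --------------------------------------------------------------------------
# peak detection with FDR
# --------------------------------------------------------------------------

def peak_ttest_fdr(
    values: np.ndarray,
    freqs: np.ndarray,
    valid: np.ndarray | None = None,
    f_max: float = 5.33,
    alpha: float = 0.05,
) -> PeakTestResult:
    """Right-tailed one-sample t against zero per bin, BH-FDR below ``f_max``.

    ``values`` is subjects x bins (normalized amplitudes, typically averaged
    over electrodes).  Only valid bins with frequency below ``f_max`` enter
    the FDR family; other bins report t and p but can never be flagged.
    """
    values = np.asarray(values, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if values.ndim != 2 or values.shape[1] != freqs.size:
        raise DataError("values must be subjects x bins aligned with freqs")
    n = values.shape[0]
    if n < 3:
        raise DataError("need at least 3 subjects")
    valid = np.ones(freqs.size, bool) if valid is None else np.asarray(valid, bool)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.sign(mean) * np.inf)
    df = n - 1
    p = sps.t.sf(t, df)
    tested = valid & (freqs < f_max)
    q_significant = np.zeros(freqs.size, dtype=bool)
    if tested.any():
        reject, *_ = multipletests(p[tested], alpha=alpha, method="fdr_bh")
        q_significant[tested] = reject
    return PeakTestResult(freqs=freqs, t=t, p=p, q_significant=q_significant,
                          tested=tested, df=df, alpha=alpha)


# --------------------------------------------------------------------------
# paired contrasts and the additive model
# --------------------------------------------------------------------------

def paired_contrast(a: Sequence[float], b: Sequence[float]) -> ContrastResult:
    """Two-tailed paired t-test with the d_z effect size.

    d_z = mean(a - b) / sd(a - b), which equals t / sqrt(n); the published
    (t, d) pairs of this design obey that identity exactly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise DataError("a and b must be equal-length per-subject vectors (n >= 3)")
    diff = a - b
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DataError("zero variance of paired differences; t undefined")
    mean = diff.mean()
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return ContrastResult(t=float(t), p=float(p), d=float(mean / sd), df=n - 1,
                          mean_diff=float(mean))


def additive_classification(
    av: Sequence[float], a: Sequence[float], v: Sequence[float], alpha: float = 0.05
) -> IntegrationMode:
    """Classify multisensory integration from the AV vs (A + V) paired contrast."""
    av = np.asarray(av, dtype=float)
    s = np.asarray(a, dtype=float) + np.asarray(v, dtype=float)
    contrast = paired_contrast(av, s)
    if contrast.p < alpha:
        label = "super-additive" if contrast.t > 0 else "sub-additive"
    else:
        label = "additive"
    return IntegrationMode(label=label, contrast=contrast, alpha=alpha)


def congruency_effect(
    congruent: np.ndarray, incongruent_runs: Sequence[np.ndarray]
) -> np.ndarray:
    """Congruent minus the unweighted mean of the incongruent runs.

    All inputs are subjects x electrodes at a named frequency bin; the
    incongruent baseline averages the fast and slow runs.
    """
    congruent = np.asarray(congruent, dtype=float)
    if not incongruent_runs:
        raise DataError("need at least one incongruent run")
    runs = [np.asarray(r, dtype=float) for r in incongruent_runs]
    for r in runs:
        if r.shape != congruent.shape:
            raise DataError("electrode/subject mismatch between conditions")
    return congruent - np.mean(runs, axis=0)


# --------------------------------------------------------------------------
# cluster-based permutation test
# --------------------------------------------------------------------------

def _paired_t_matrix(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Per-electrode paired t for many sign-flip assignments at once.

    ``d`` is subjects x electrodes; ``signs`` is n_perm x subjects of +-1.
    Uses E[d^2] invariance under sign flips to avoid materializing flipped data.
    """
    n = d.shape[0]
    meansq = (d ** 2).mean(axis=0)
    m = signs @ d / n
    var = (meansq[None, :] - m ** 2) * (n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, m / np.sqrt(var / n), 0.0)
    return t


def _clusters_from_mask(
    mask: np.ndarray, tvals: np.ndarray, neighbors: list[np.ndarray]
) -> list[tuple[list[int], float]]:
    """Connected components of supra-threshold electrodes with summed t."""
    out = []
    visited = np.zeros(mask.size, dtype=bool)
    for start in np.flatnonzero(mask):
        if visited[start]:
            continue
        stack, members = [start], []
        visited[start] = True
        while stack:
            node = stack.pop()
            members.append(node)
            for nb in neighbors[node]:
                if mask[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        out.append((members, float(tvals[members].sum())))
    return out


def _retained_masks(
    t: np.ndarray, t_crit: float, adj: np.ndarray, min_neighbors: int
) -> tuple[np.ndarray, np.ndarray]:
    """Supra-threshold masks per sign after the minimum-neighbor retention rule.

    An electrode stays supra-threshold only if at least ``min_neighbors``
    adjacent electrodes are supra-threshold with the same sign (the cluster
    "at least two significant neighbors" requirement).  ``t`` may be 1-D or
    n_perm x electrodes.
    """
    pos = t > t_crit
    neg = t < -t_crit
    pos_keep = pos & ((pos.astype(float) @ adj) >= min_neighbors)
    neg_keep = neg & ((neg.astype(float) @ adj) >= min_neighbors)
    return pos_keep, neg_keep


def cluster_permutation_interaction(
    effect_upright: np.ndarray,
    effect_inverted: np.ndarray,
    montage: Montage,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    min_neighbors: int = 2,
    seed: int | None = None,
    exhaustive: bool = False,
) -> ClusterResult:
    """Sign-flip cluster permutation test for the upright vs inverted difference.

    Per electrode, a paired t on ``d = upright - inverted`` is thresholded at
    the two-sided ``cluster_alpha`` critical value; electrodes survive only
    with >= ``min_neighbors`` same-sign supra-threshold neighbors; surviving
    electrodes form connected clusters whose statistic is the summed t.  The
    null distribution is the maximum absolute cluster statistic over random
    per-subject sign flips of ``d`` (``exhaustive=True`` enumerates all 2^n
    assignments instead); cluster p = (1 + #{null >= observed}) / (1 + m).
    """
    up = np.asarray(effect_upright, dtype=float)
    inv = np.asarray(effect_inverted, dtype=float)
    if up.shape != inv.shape or up.ndim != 2:
        raise DataError("effect matrices must be equal-shape subjects x electrodes")
    n_sub, n_e = up.shape
    if n_e != montage.n_channels:
        raise DataError("electrode count does not match the montage")
    if n_sub < 3:
        raise DataError("need at least 3 subjects")
    # reachability check: the montage must be a single connected component
    comp = _clusters_from_mask(np.ones(n_e, bool), np.zeros(n_e),
                               [np.flatnonzero(montage.adjacency[i]) for i in range(n_e)])
    if len(comp) > 1:
        raise ConfigurationError("montage adjacency is disconnected")

    d = up - inv
    adj = montage.adjacency.astype(float)
    neighbors = [np.flatnonzero(montage.adjacency[i]) for i in range(n_e)]
    t_crit = sps.t.ppf(1.0 - cluster_alpha / 2.0, n_sub - 1)

    t_obs = _paired_t_matrix(d, np.ones((1, n_sub)))[0]
    pos_keep, neg_keep = _retained_masks(t_obs, t_crit, adj, min_neighbors)
    observed = (
        [(m, s, "positive") for m, s in _clusters_from_mask(pos_keep, t_obs, neighbors)]
        + [(m, s, "negative") for m, s in _clusters_from_mask(neg_keep, t_obs, neighbors)]
    )

    if exhaustive:
        if n_sub > 16:
            raise ConfigurationError("exhaustive enumeration limited to n <= 16 subjects")
        m_perm = 2 ** n_sub
        bits = ((np.arange(m_perm)[:, None] >> np.arange(n_sub)[None, :]) & 1)
        signs = bits * 2.0 - 1.0
    else:
        rng = np.random.default_rng(seed)
        m_perm = int(n_perm)
        signs = rng.integers(0, 2, size=(m_perm, n_sub)) * 2.0 - 1.0

    t_perm = _paired_t_matrix(d, signs)
    pos_p, neg_p = _retained_masks(t_perm, t_crit, adj, min_neighbors)
    null_max = np.zeros(m_perm)
    any_keep = np.flatnonzero(pos_p.any(axis=1) | neg_p.any(axis=1))
    for i in any_keep:
        best = 0.0
        for mask in (pos_p[i], neg_p[i]):
            if mask.any():
                for _, s in _clusters_from_mask(mask, t_perm[i], neighbors):
                    best = max(best, abs(s))
        null_max[i] = best

    clusters = []
    for members, stat, polarity in observed:
        p = (1.0 + np.count_nonzero(null_max >= abs(stat))) / (1.0 + m_perm)
        clusters.append(Cluster(
            electrodes=tuple(montage.labels[i] for i in sorted(members)),
            stat=stat, p=float(p), polarity=polarity))
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(clusters=clusters, n_permutations=m_perm,
                         cluster_alpha=cluster_alpha, min_neighbors=min_neighbors,
                         t_obs=t_obs, labels=list(montage.labels),
                         low_n_perm=m_perm < 100, null_max=null_max)


# --------------------------------------------------------------------------
# trait correlation
# --------------------------------------------------------------------------

def pearson_outlier_removed(
    x: Sequence[float], y: Sequence[float], sd_thresh: float = 3.0
) -> CorrelationResult:
    """Pearson correlation after single-pass outlier removal on ``y``.

    Subjects whose ``y`` (neural response) deviates more than ``sd_thresh``
    sample SDs from the group mean are removed once (no re-iteration); the
    correlation and two-tailed p are computed on the remainder.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length vectors")
    sd = y.std(ddof=1)
    keep = np.abs(y - y.mean()) <= sd_thresh * sd if sd > 0 else np.ones(y.size, bool)
    n_used = int(keep.sum())
    if n_used < 4:
        raise DataError("fewer than 4 subjects remain after outlier removal")
    r, p = sps.pearsonr(x[keep], y[keep])
    return CorrelationResult(r=float(r), p=float(p), n_used=n_used,
                             n_removed_outliers=int(y.size - n_used))


def median_split_compare(aq: Sequence[float], effect: Sequence[float]) -> MedianSplitResult:
    """Welch two-sample t between low-AQ and high-AQ halves of the cohort.

    Groups are AQ <= median (low, ties included) vs AQ > median (high).
    """
    aq = np.asarray(aq, dtype=float)
    effect = np.asarray(effect, dtype=float)
    if aq.shape != effect.shape or aq.ndim != 1:
        raise DataError("aq and effect must be equal-length vectors")
    med = np.median(aq)
    low = aq <= med
    high = ~low
    if low.sum() < 3 or high.sum() < 3:
        raise DataError("degenerate median split: need >= 3 subjects per group")
    t, p = sps.ttest_ind(effect[low], effect[high], equal_var=False)
    return MedianSplitResult(t=float(t), p=float(p),
                             mean_low=float(effect[low].mean()),
                             mean_high=float(effect[high].mean()),
                             n_low=int(low.sum()), n_high=int(high.sum()))
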