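"""Differential expression by the overdispersed negative-binomial exact test.

Two-group tag-count comparison in the classic small-sample framework:

* counts for gene g in lane j are NB with mean ``N_j * p_gj`` and a single
  common dispersion phi shared by all genes, so Var = mu + phi * mu^2;
* library sizes are equalized by a quantile-to-quantile transform onto the
  geometric-mean library size ("pseudo-counts"), making lanes exchangeable
  within a group;
* phi is estimated by conditional maximum likelihood: the likelihood of the
  within-group counts conditional on their group total depends only on phi,
  and the per-gene conditional log-likelihoods are summed and maximized over
  delta = phi / (1 + phi) in [0, 1);
* each gene is then tested with an exact conditional test: given the total
  pseudo-count t of the gene, the probability of every split (a, t - a) of
  the two group sums is computed under the null of equal proportions, and
  the two-sided p-value is the total probability of splits no more likely
  than the observed one.

Effect size is M = log2(propE) - log2(propF), the log ratio of corrected
tag proportions (pseudo-count lane averages over the equalized library
size, with a small prior so genes absent in one species get a large but
finite |M|). A gene is called DE when |M| > 0.58 (1.5-fold) and the
Benjamini-Hochberg adjusted p is below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

M_THRESHOLD_DEFAULT = float(np.round(np.log2(1.5), 2))  # 0.58
ALPHA_DEFAULT = 0.05
PRIOR_COUNT = 0.5
_MIN_DELTA = 1e-9


@dataclass
class CountMatrix:
    """Integer gene x lane counts with a two-group lane assignment."""

    counts: pd.DataFrame  # genes x lanes
    groups: pd.Series  # lane -> group label, exactly two labels

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups).reindex(self.counts.columns)
        if self.groups.isna().any():
            raise ValueError("every lane needs a group label")
        labels = list(pd.unique(self.groups))
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.labels = labels

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def lanes_of(self, label) -> list:
        return list(self.groups.index[self.groups == label])


@dataclass
class DispersionEstimate:
    phi: float
    pseudo_counts: pd.DataFrame
    pseudo_library_size: float
    n_iter: int


def equalize_library_sizes(cm: CountMatrix, phi: float) -> tuple[pd.DataFrame, float]:
    """Pseudo-counts at the geometric-mean library size, given dispersion."""
    lib = cm.library_sizes
    if (lib <= 0).any():
        raise ValueError("every lane needs a positive library size")
    return _pseudo_with_lib(cm.counts, lib, phi)


def _group_cll(y: np.ndarray, delta: float) -> float:
    """Summed conditional log-likelihood for one group (genes x lanes).

    Conditional on each gene's group total s, the within-group counts are
    free of the mean parameter; with r = 1/phi = (1-delta)/delta and n
    lanes the per-gene term is
        sum_i lgamma(y_i + r) + lgamma(n r) - lgamma(s + n r) - n lgamma(r).
    """
    n = y.shape[1]
    if n < 2:
        return 0.0
    delta = min(max(delta, _MIN_DELTA), 1 - 1e-9)
    r = (1 - delta) / delta
    s = y.sum(axis=1)
    ll = (
        special.gammaln(y + r).sum(axis=1)
        + special.gammaln(n * r)
        - special.gammaln(s + n * r)
        - n * special.gammaln(r)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    cm: CountMatrix, tol: float = 1e-4, max_iter: int = 20
) -> DispersionEstimate:
    """Common dispersion by conditional ML on quantile-adjusted pseudo-counts.

    Alternates (a) equalizing library sizes at the current phi and
    (b) maximizing the summed conditional log-likelihood over
    delta = phi/(1+phi), until phi moves less than ``tol``.
    """
    nonzero = cm.counts.sum(axis=1) > 0
    counts = cm.counts.loc[nonzero]
    sub = CountMatrix(counts, cm.groups)
    # library sizes must stay those of the full matrix (column totals)
    lib_full = cm.library_sizes

    group_cols = [sub.lanes_of(lbl) for lbl in sub.labels]
    if all(len(c) < 2 for c in group_cols):
        raise ValueError(
            "common dispersion is not identifiable without replicate lanes "
            "in at least one group"
        )

    phi = 0.0
    n_iter = 0
    pseudo, common = _pseudo_with_lib(sub.counts, lib_full, phi)
    for n_iter in range(1, max_iter + 1):
        ys = [pseudo[cols].to_numpy(dtype=float) for cols in group_cols]

        def neg_cll(delta: float) -> float:
            return -sum(_group_cll(y, delta) for y in ys)

        res = optimize.minimize_scalar(
            neg_cll, bounds=(_MIN_DELTA, 0.95), method="bounded",
            options={"xatol": 1e-7},
        )
        delta = float(res.x)
        new_phi = delta / (1 - delta)
        if new_phi < 1e-6:
            new_phi = 0.0
        done = abs(new_phi - phi) < tol
        phi = new_phi
        pseudo, common = _pseudo_with_lib(sub.counts, lib_full, phi)
        if done:
            break
    full_pseudo = pseudo.reindex(cm.counts.index).fillna(0.0)
    return DispersionEstimate(phi, full_pseudo, common, n_iter)


def _pseudo_with_lib(
    counts: pd.DataFrame, lib: pd.Series, phi: float
) -> tuple[pd.DataFrame, float]:
    """Moment-matched gamma quantile transform of counts onto the
    geometric-mean library size: each count is placed on the CDF of a gamma
    with its own lane's NB mean/variance and read off at the same quantile
    of the gamma matching the common size. Exactly the identity when sizes
    already agree, and zero counts always map to zero."""
    libv = lib.to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(libv))))
    y = counts.to_numpy(dtype=float)
    p_g = y.sum(axis=1) / libv.sum()
    mu_in = np.maximum(np.outer(p_g, libv), 1e-8)
    var_in = mu_in + phi * mu_in**2
    mu_out = np.maximum(p_g[:, None] * common, 1e-8)
    var_out = mu_out + phi * mu_out**2
    pcdf = stats.gamma.cdf(y, a=mu_in**2 / var_in, scale=var_in / mu_in)
    pcdf = np.clip(pcdf, 0.0, 1 - 1e-12)
    pseudo = stats.gamma.ppf(pcdf, a=mu_out**2 / var_out, scale=var_out / mu_out)
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns), common


def exact_test(s_a: float, n_a: int, s_b: float, n_b: int, phi: float) -> float:
    """Exact conditional test of equal proportions for two NB group sums.

    ``s_a`` and ``s_b`` are the (pseudo-count) sums over the ``n_a`` and
    ``n_b`` lanes of each group. Under the null both groups share one mean
    per lane, so group sums are NB with means proportional to lane numbers
    and sizes ``n_i / phi``. Conditioning on t = s_a + s_b, the two-sided
    p-value adds the probabilities of all splits (a, t - a) whose
    conditional probability does not exceed that of the observed split.
    At phi = 0 this reduces to the exact conditional binomial test.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    a_obs = int(round(s_a))
    b_obs = int(round(s_b))
    t = a_obs + b_obs
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    mu = t / (n_a + n_b)  # common per-lane mean under the null
    if phi < 1e-12:
        la = stats.poisson.logpmf(a, n_a * mu)
        lb = stats.poisson.logpmf(t - a, n_b * mu)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        la = stats.nbinom.logpmf(a, r_a, r_a / (r_a + n_a * mu))
        lb = stats.nbinom.logpmf(t - a, r_b, r_b / (r_b + n_b * mu))
    logp = la + lb
    logp -= special.logsumexp(logp)
    p_obs = logp[a_obs]
    keep = logp <= p_obs + 1e-10  # ties count as extreme
    return float(min(1.0, np.exp(special.logsumexp(logp[keep]))))


def exact_test_all(
    pseudo: pd.DataFrame, groups: pd.Series, labels: list, phi: float
) -> pd.Series:
    cols_a = list(groups.index[groups == labels[0]])
    cols_b = list(groups.index[groups == labels[1]])
    sa = pseudo[cols_a].sum(axis=1)
    sb = pseudo[cols_b].sum(axis=1)
    p = np.ones(len(pseudo))
    for i, g in enumerate(pseudo.index):
        p[i] = exact_test(sa.iloc[i], len(cols_a), sb.iloc[i], len(cols_b), phi)
    return pd.Series(p, index=pseudo.index, name="p_value")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def compute_m_and_call(
    pseudo: pd.DataFrame,
    groups: pd.Series,
    labels: list,
    pseudo_lib: float,
    p_values: pd.Series,
    m_threshold: float = M_THRESHOLD_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    prior: float = PRIOR_COUNT,
) -> pd.DataFrame:
    """Per-gene M values, BH-adjusted p-values and DE calls.

    ``labels[0]`` is treated as species E and ``labels[1]`` as species F:
    M > 0 means higher relative abundance in E. propE/propF are pseudo-count
    lane averages over the equalized library size, with ``prior`` added to
    both numerators so that zero-count groups give large finite |M|.
    """
    if m_threshold <= 0 or not (0 < alpha < 1):
        raise ValueError("thresholds must be positive (alpha in (0,1))")
    cols_e = list(groups.index[groups == labels[0]])
    cols_f = list(groups.index[groups == labels[1]])
    prop_e = (pseudo[cols_e].mean(axis=1) + prior) / pseudo_lib
    prop_f = (pseudo[cols_f].mean(axis=1) + prior) / pseudo_lib
    m = np.log2(prop_e) - np.log2(prop_f)
    adj = bh_adjust(p_values.to_numpy())
    call = np.where(
        (m > m_threshold) & (adj < alpha),
        "up_E",
        np.where((m < -m_threshold) & (adj < alpha), "up_F", "not_DE"),
    )
    return pd.DataFrame(
        {
            "propE": prop_e,
            "propF": prop_f,
            "M": m,
            "p_value": p_values,
            "adj_p": adj,
            "call": call,
        },
        index=pseudo.index,
    )


def de_analysis(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    labels: list | None = None,
    m_threshold: float = M_THRESHOLD_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> tuple[pd.DataFrame, DispersionEstimate]:
    """Full two-group DE analysis on a locus count matrix.

    Genes with zero counts in every lane are excluded before testing and
    returned with call ``not_tested``. Returns (result table, dispersion).
    """
    cm = CountMatrix(counts, pd.Series(groups))
    if labels is None:
        labels = cm.labels
    disp = estimate_common_dispersion(cm)
    nonzero = counts.sum(axis=1) > 0
    pseudo = disp.pseudo_counts.loc[nonzero]
    p = exact_test_all(pseudo, cm.groups, labels, disp.phi)
    res = compute_m_and_call(
        pseudo, cm.groups, labels, disp.pseudo_library_size, p,
        m_threshold=m_threshold, alpha=alpha,
    )
    skipped = counts.index[~nonzero]
    if len(skipped):
        pad = pd.DataFrame(
            {
                "propE": np.nan, "propF": np.nan, "M": np.nan,
                "p_value": np.nan, "adj_p": np.nan, "call": "not_tested",
            },
            index=skipped,
        )
        res = pd.concat([res, pad]).reindex(counts.index)
    return res, disp
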