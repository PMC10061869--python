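"""Bimodality screening of count data via a two-component log-normal mixture.

Genes whose expression occupies two discrete states (e.g. on/off between
donors, or strong differential expression between phenotypes) violate the
unimodality assumption behind the MAD-based EV statistic and are removed
before EV computation.  Per dose, with all donor groups pooled, each gene
is fitted with a two-component normal mixture on ``log(count / s)``
restricted to counts at or above a small threshold ``eps``, and the
bimodality index

    BI = sqrt(pi * (1 - pi)) * |mu1 - mu2| / sigma_pooled,
    sigma_pooled = sqrt(pi * sigma1^2 + (1 - pi) * sigma2^2)

is computed from the fit.  Genes with BI at or above the threshold
(1.1 for the full design; 1.3 recommended for reduced sample sizes) are
excluded.  Genes whose fraction of counts below ``eps`` exceeds
``zero_percent_thr`` cannot be assessed and are retained, flagged
ineligible.

The EM runs vectorized over all genes at once (masked for per-gene
usable observations); converged genes are frozen so the batch result is
identical to fitting genes one at a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import derive_rng

__all__ = ["BimodalityConfig", "MixtureFit", "bimodality_index", "fit_lognormal_mixture", "filter_bimodal"]

_SIGMA_FLOOR = 1e-4
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class BimodalityConfig:
    bi_threshold: float = 1.1
    zero_percent_thr: float = 0.2
    eps: float = 10.0
    max_em_iter: int = 500
    tol: float = 1e-8
    n_starts: int = 5
    seed: int = 0

    def validate(self) -> "BimodalityConfig":
        if self.bi_threshold <= 0:
            raise ValueError("bi_threshold must be positive")
        if not 0.0 <= self.zero_percent_thr <= 1.0:
            raise ValueError("zero_percent_thr must be in [0, 1]")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        return self


@dataclass
class MixtureFit:
    """Two-component mixture fit of one gene's log expression."""

    pi: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float
    bi: float
    converged: bool
    n_iter: int
    n_used: int
    eligible: bool = True
    monotone: bool = True


def bimodality_index(pi: float, mu1: float, mu2: float, sigma1: float, sigma2: float) -> float:
    """BI with the pooled-SD generalization to unequal component SDs.

    Reduces to the classical sqrt(p(1-p)) * |dmu| / sigma under equal
    SDs, and is invariant to swapping the component labels.
    """
    pooled = np.sqrt(pi * sigma1**2 + (1.0 - pi) * sigma2**2)
    if pooled <= 0:
        return 0.0
    return float(np.sqrt(pi * (1.0 - pi)) * abs(mu1 - mu2) / pooled)


def _two_means_init(y: np.ndarray, mask: np.ndarray):
    """Per-gene best 1-D 2-means split (exact scan, vectorized over splits).

    ``y`` is (genes x samples) with invalid entries arbitrary; ``mask``
    flags usable observations.  Returns per-gene (pi, mu1, mu2, s1, s2).
    """
    g, n = y.shape
    ys = np.where(mask, y, np.inf)
    ys = np.sort(ys, axis=1)  # usable values first, inf padding last
    counts = mask.sum(axis=1)
    ys_safe = np.where(np.isfinite(ys), ys, 0.0)
    cum = np.cumsum(ys_safe, axis=1)
    cum2 = np.cumsum(ys_safe**2, axis=1)
    idx = np.arange(1, n + 1)[None, :]

    tot = cum[np.arange(g), counts - 1]
    tot2 = cum2[np.arange(g), counts - 1]
    k = idx
    n2 = counts[:, None] - k
    with np.errstate(invalid="ignore", divide="ignore"):
        ss1 = cum2 - cum**2 / k
        ss2 = (tot2[:, None] - cum2) - (tot[:, None] - cum) ** 2 / np.where(n2 > 0, n2, 1)
        ss = ss1 + ss2
    ss = np.where((k >= 1) & (n2 >= 1), ss, np.inf)
    best_k = np.argmin(ss, axis=1) + 1  # split size of the lower component

    pi = best_k / counts
    mu1 = cum[np.arange(g), best_k - 1] / best_k
    hi_n = counts - best_k
    mu2 = (tot - cum[np.arange(g), best_k - 1]) / hi_n
    var1 = cum2[np.arange(g), best_k - 1] / best_k - mu1**2
    var2 = (tot2 - cum2[np.arange(g), best_k - 1]) / hi_n - mu2**2
    var_all = tot2 / counts - (tot / counts) ** 2
    sd_all = np.sqrt(np.clip(var_all, _SIGMA_FLOOR**2, None))
    s1 = np.maximum(np.sqrt(np.clip(var1, 0.0, None)), 0.25 * sd_all)
    s2 = np.maximum(np.sqrt(np.clip(var2, 0.0, None)), 0.25 * sd_all)
    return pi, mu1, mu2, s1, s2, sd_all


def _em_batch(y, mask, pi, mu1, mu2, s1, s2, max_iter: int, tol: float):
    """Masked EM over a batch of genes.

    Converged genes are removed from the working arrays (the updates of
    one gene never involve another, so compaction leaves results
    identical to per-gene fitting).  Returns final params, loglik,
    converged flag, iteration count and a per-gene monotonicity flag of
    the observed-data log-likelihood.
    """
    g = y.shape[0]
    out_pi = pi.astype(float).copy()
    out_mu1, out_mu2 = mu1.astype(float).copy(), mu2.astype(float).copy()
    out_s1 = np.maximum(s1.astype(float), _SIGMA_FLOOR).copy()
    out_s2 = np.maximum(s2.astype(float), _SIGMA_FLOOR).copy()
    out_ll = np.full(g, -np.inf)
    out_conv = np.zeros(g, dtype=bool)
    n_iter = np.zeros(g, dtype=int)
    monotone = np.ones(g, dtype=bool)

    idx = np.arange(g)  # positions of still-active genes
    ay, amask = y, mask
    api, amu1, amu2, as1, as2 = out_pi.copy(), out_mu1.copy(), out_mu2.copy(), out_s1.copy(), out_s2.copy()
    prev_ll = np.full(g, np.nan)
    acounts = amask.sum(axis=1).astype(float)

    for _ in range(max_iter):
        if idx.size == 0:
            break
        lp1 = np.log(api + 1e-300)[:, None] - 0.5 * (
            _LOG2PI + 2 * np.log(as1)[:, None] + ((ay - amu1[:, None]) / as1[:, None]) ** 2
        )
        lp2 = np.log(1.0 - api + 1e-300)[:, None] - 0.5 * (
            _LOG2PI + 2 * np.log(as2)[:, None] + ((ay - amu2[:, None]) / as2[:, None]) ** 2
        )
        m = np.maximum(lp1, lp2)
        e1 = np.exp(lp1 - m)
        e2 = np.exp(lp2 - m)
        ll_new = np.sum(np.where(amask, m + np.log(e1 + e2), 0.0), axis=1)

        seen = np.isfinite(prev_ll[idx])
        dec = ll_new < prev_ll[idx] - 1e-7 * (np.abs(prev_ll[idx]) + 1.0)
        monotone[idx[seen & dec]] = False
        out_ll[idx] = ll_new
        n_iter[idx] += 1

        r1 = np.where(amask, e1 / (e1 + e2), 0.0)
        w1 = r1.sum(axis=1)
        w2 = acounts - w1
        ok = (w1 > 1e-10) & (w2 > 1e-10)
        w1s = np.where(ok, w1, 1.0)
        w2s = np.where(ok, w2, 1.0)
        ym = np.where(amask, ay, 0.0)
        mu1_n = np.sum(r1 * ym, axis=1) / w1s
        mu2_n = np.sum((amask - r1) * ym, axis=1) / w2s
        s1_n = np.sqrt(np.sum(r1 * (ay - mu1_n[:, None]) ** 2 * amask, axis=1) / w1s)
        s2_n = np.sqrt(np.sum((amask - r1) * (ay - mu2_n[:, None]) ** 2 * amask, axis=1) / w2s)
        api = np.where(ok, w1 / acounts, api)
        amu1 = np.where(ok, mu1_n, amu1)
        amu2 = np.where(ok, mu2_n, amu2)
        as1 = np.where(ok, np.maximum(s1_n, _SIGMA_FLOOR), as1)
        as2 = np.where(ok, np.maximum(s2_n, _SIGMA_FLOOR), as2)
        out_pi[idx], out_mu1[idx], out_mu2[idx] = api, amu1, amu2
        out_s1[idx], out_s2[idx] = as1, as2

        conv = seen & (np.abs(ll_new - prev_ll[idx]) <= tol * (np.abs(prev_ll[idx]) + 1e-12))
        done = conv | ~ok
        out_conv[idx[done]] = True
        prev_ll[idx] = ll_new
        if done.any():
            keep = ~done
            idx = idx[keep]
            ay, amask, acounts = ay[keep], amask[keep], acounts[keep]
            api, amu1, amu2, as1, as2 = api[keep], amu1[keep], amu2[keep], as1[keep], as2[keep]

    return out_pi, out_mu1, out_mu2, out_s1, out_s2, out_ll, out_conv, n_iter, monotone


def _fit_batch(y: np.ndarray, mask: np.ndarray, cfg: BimodalityConfig):
    """Best-of-restarts mixture fit for a batch of genes.

    The first start is the exact 2-means split of each gene's usable log
    values; the remaining ``n_starts - 1`` starts perturb a symmetric
    split with shared random draws (one stream per configuration seed,
    so results do not depend on batch composition).  Ties between
    restarts break toward balanced mixing proportions.
    """
    g = y.shape[0]
    pi0, mu10, mu20, s10, s20, sd_all = _two_means_init(y, mask)
    counts = mask.sum(axis=1).astype(float)
    mu_all = np.sum(np.where(mask, y, 0.0), axis=1) / counts

    rng = derive_rng(cfg.seed, "bimodality", "restarts")
    starts = [(pi0, mu10, mu20, s10, s20)]
    for _ in range(cfg.n_starts - 1):
        p = rng.uniform(0.2, 0.8)
        d = rng.uniform(0.5, 2.0)
        starts.append(
            (np.full(g, p), mu_all - d * sd_all / 2, mu_all + d * sd_all / 2, sd_all, sd_all)
        )

    best = None
    for start in starts:
        res = _em_batch(y, mask, *start, max_iter=cfg.max_em_iter, tol=cfg.tol)
        pi, mu1, mu2, s1, s2, ll, conv, it, mono = res
        if best is None:
            best = [x.copy() if hasattr(x, "copy") else x for x in res]
            continue
        better = (ll > best[5]) | (
            np.isclose(ll, best[5], rtol=0, atol=1e-9)
            & (np.abs(pi - 0.5) < np.abs(best[0] - 0.5))
        )
        for i, new in enumerate(res):
            best[i] = np.where(better, new, best[i])
    return best


def fit_lognormal_mixture(gene_counts, size_factors, cfg: BimodalityConfig) -> MixtureFit:
    """Fit the mixture on ``log(count / s)`` over counts >= eps for one gene.

    Counts below ``eps`` are treated as left-censored and dropped; if
    their fraction exceeds ``zero_percent_thr`` the gene is ineligible
    (returned with ``bi = nan``).  The best of ``n_starts`` restarts by
    final log-likelihood is returned.
    """
    cfg.validate()
    c = np.asarray(gene_counts, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    if c.shape != s.shape:
        raise ValueError("gene_counts and size_factors must have equal length")
    mask = c >= cfg.eps
    if (1.0 - mask.mean()) > cfg.zero_percent_thr or mask.sum() < 6:
        return MixtureFit(
            pi=np.nan, mu1=np.nan, mu2=np.nan, sigma1=np.nan, sigma2=np.nan,
            loglik=np.nan, bi=np.nan, converged=False, n_iter=0,
            n_used=int(mask.sum()), eligible=False,
        )
    y = np.where(mask, np.log(np.where(mask, c, 1.0) / s), 0.0)[None, :]
    pi, mu1, mu2, s1, s2, ll, conv, it, mono = _fit_batch(y, mask[None, :], cfg)
    return MixtureFit(
        pi=float(pi[0]), mu1=float(mu1[0]), mu2=float(mu2[0]),
        sigma1=float(s1[0]), sigma2=float(s2[0]), loglik=float(ll[0]),
        bi=bimodality_index(float(pi[0]), float(mu1[0]), float(mu2[0]), float(s1[0]), float(s2[0])),
        converged=bool(conv[0]), n_iter=int(it[0]), n_used=int(mask.sum()),
        monotone=bool(mono[0]),
    )


def filter_bimodal(
    counts: pd.DataFrame, size_factors: pd.Series, cfg: BimodalityConfig
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Screen every gene of a single-dose (groups-pooled) matrix.

    Returns ``(retained, excluded, report)``: eligible genes with
    BI >= threshold are excluded; ineligible genes (too many low counts
    to assess) are retained; both lists preserve the input gene order.
    """
    cfg.validate()
    if counts.shape[0] == 0:
        raise ValueError("empty count matrix")
    s = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    c = counts.to_numpy(dtype=float)
    mask = c >= cfg.eps
    frac_below = 1.0 - mask.mean(axis=1)
    eligible = (frac_below <= cfg.zero_percent_thr) & (mask.sum(axis=1) >= 6)

    g = c.shape[0]
    pi = np.full(g, np.nan)
    mu1 = np.full(g, np.nan)
    mu2 = np.full(g, np.nan)
    s1 = np.full(g, np.nan)
    s2 = np.full(g, np.nan)
    ll = np.full(g, np.nan)
    bi = np.full(g, np.nan)
    conv = np.zeros(g, dtype=bool)
    mono = np.ones(g, dtype=bool)

    if eligible.any():
        sub = np.where(mask, np.log(np.where(mask, c, 1.0) / s[None, :]), 0.0)[eligible]
        submask = mask[eligible]
        rpi, rmu1, rmu2, rs1, rs2, rll, rconv, rit, rmono = _fit_batch(sub, submask, cfg)
        pooled = np.sqrt(rpi * rs1**2 + (1 - rpi) * rs2**2)
        rbi = np.where(pooled > 0, np.sqrt(rpi * (1 - rpi)) * np.abs(rmu1 - rmu2) / pooled, 0.0)
        for arr, vals in ((pi, rpi), (mu1, rmu1), (mu2, rmu2), (s1, rs1), (s2, rs2), (ll, rll), (bi, rbi)):
            arr[eligible] = vals
        conv[eligible] = rconv
        mono[eligible] = rmono

    is_excluded = eligible & (bi >= cfg.bi_threshold)
    gene_ids = list(counts.index)
    retained = [gid for gid, ex in zip(gene_ids, is_excluded) if not ex]
    excluded = [gid for gid, ex in zip(gene_ids, is_excluded) if ex]
    report = pd.DataFrame(
        {
            "gene_id": gene_ids, "pi": pi, "mu1": mu1, "mu2": mu2,
            "sigma1": s1, "sigma2": s2, "bi": bi, "eligible": eligible,
            "excluded": is_excluded, "converged": conv, "monotone": mono,
        }
    )
    return retained, excluded, report
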