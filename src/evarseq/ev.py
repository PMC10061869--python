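"""Expression variability (EV) computation.

EV separates a gene's variability from its expression magnitude.  Per
donor group x dose stratum:

* ``mad_obs``  — the median over B bootstrap resamples of the (scaled)
  median absolute deviation of the gene's normalized counts;
* ``mad_pred`` — the value of a local polynomial regression (loess) of
  ``mad_obs`` on ``log1p(median expression)``, fitted across the genes of
  the stratum, at this gene's median expression;
* ``ev``       — ``mad_obs - mad_pred``.

Because the loess absorbs the mean-variability trend of count data, EV is
approximately uncorrelated with expression magnitude, unlike CV or the
standardized MAD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import derive_seedseq

__all__ = ["EVConfig", "mad", "bootstrap_mad", "loess_fit", "fit_expected_mad", "compute_ev"]

MAD_NORMAL_CONSTANT = 1.4826


@dataclass
class EVConfig:
    """Tunables of the EV stage.

    B:             bootstrap iterations for the observed MAD.
    mad_constant:  normal-consistency scale constant (1.4826 makes the MAD
                   estimate the SD under normality).
    loess_span:    fraction of genes in each local window.
    loess_degree:  local polynomial degree (1 or 2).
    seed:          root seed; per-gene bootstrap streams are derived from
                   (seed, group, dose, gene id).
    """

    B: int = 1000
    mad_constant: float = MAD_NORMAL_CONSTANT
    loess_span: float = 0.75
    loess_degree: int = 2
    seed: int = 0

    def validate(self) -> "EVConfig":
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError("loess_span must be in (0, 1]")
        if self.loess_degree not in (1, 2):
            raise ValueError("loess_degree must be 1 or 2")
        return self


def mad(values, constant: float = MAD_NORMAL_CONSTANT) -> float:
    """``constant * median(|x - median(x)|)``."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad of empty input is undefined")
    return float(constant * np.median(np.abs(x - np.median(x))))


def bootstrap_mad(
    values,
    B: int = 1000,
    constant: float = MAD_NORMAL_CONSTANT,
    seed: int | np.random.Generator = 0,
) -> float:
    """Median over ``B`` with-replacement resamples of the scaled MAD.

    The input is sorted before resampling, so the estimate is invariant
    to permutations of the sample vector at a fixed seed.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("bootstrap_mad needs at least 2 observations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    res = x[idx]
    med = np.median(res, axis=1, keepdims=True)
    mads = constant * np.median(np.abs(res - med), axis=1)
    return float(np.median(mads))


def _bootstrap_mad_matrix(
    values: np.ndarray,
    B: int,
    constant: float,
    seedseqs,
    chunk: int = 128,
) -> np.ndarray:
    """Vectorized per-gene bootstrap MAD for a (genes x samples) block.

    Each gene uses its own seed sequence (one per row) so results do not
    depend on which other genes are present.  Rows are sorted first for
    permutation invariance.
    """
    x = np.sort(np.asarray(values, dtype=float), axis=1)
    g, n = x.shape
    out = np.empty(g)
    for start in range(0, g, chunk):
        stop = min(start + chunk, g)
        c = stop - start
        idx = np.empty((c, B, n), dtype=np.intp)
        for i in range(c):
            rng = np.random.default_rng(seedseqs[start + i])
            idx[i] = rng.integers(0, n, size=(B, n))
        res = np.take_along_axis(x[start:stop, None, :], idx, axis=2)
        med = np.median(res, axis=2, keepdims=True)
        mads = constant * np.median(np.abs(res - med), axis=2)
        out[start:stop] = np.median(mads, axis=1)
    return out


def loess_fit(
    x,
    y,
    span: float = 0.75,
    degree: int = 2,
    x_eval=None,
    max_exact: int = 500,
    n_grid: int = 200,
) -> np.ndarray:
    """Tricube-weighted local polynomial regression.

    Fits at each evaluation point using the nearest ``ceil(span * n)``
    neighbours.  For large inputs the fit is computed on a quantile grid
    and interpolated linearly, with linear extrapolation beyond the
    fitted range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("loess inputs must be finite")
    x_eval = x if x_eval is None else np.asarray(x_eval, dtype=float)

    order = np.argsort(x)
    xs, ys = x[order], y[order]
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)

    def fit_at(x0: float) -> float:
        d = np.abs(xs - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            # all k nearest points coincide with x0
            return float(np.mean(ys[d == 0]))
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        mask = w > 0
        xw, yw, ww = xs[mask] - x0, ys[mask], w[mask]
        if xw.size <= degree or np.ptp(xw) == 0:
            return float(np.average(yw, weights=ww))
        X = np.vander(xw, degree + 1, increasing=True)
        sw = np.sqrt(ww)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yw * sw, rcond=None)
        return float(beta[0])

    if n <= max_exact:
        return np.array([fit_at(v) for v in x_eval])

    # grid fit + interpolation: quantile-spaced knots over the data range
    qs = np.linspace(0.0, 1.0, n_grid)
    grid = np.unique(np.quantile(xs, qs))
    gy = np.array([fit_at(v) for v in grid])
    pred = np.interp(x_eval, grid, gy)
    # linear extrapolation outside the grid from the boundary segments
    if grid.size >= 2:
        lo = x_eval < grid[0]
        hi = x_eval > grid[-1]
        if lo.any():
            slope = (gy[1] - gy[0]) / (grid[1] - grid[0])
            pred[lo] = gy[0] + slope * (x_eval[lo] - grid[0])
        if hi.any():
            slope = (gy[-1] - gy[-2]) / (grid[-1] - grid[-2])
            pred[hi] = gy[-1] + slope * (x_eval[hi] - grid[-1])
    return pred


def fit_expected_mad(median_expr, mad_obs, cfg: EVConfig) -> np.ndarray:
    """Loess prediction of the observed MAD at each gene's median expression.

    The predictor is ``log1p(median_expr)``, which stabilizes the leverage
    of highly expressed genes.
    """
    cfg.validate()
    med = np.asarray(median_expr, dtype=float)
    obs = np.asarray(mad_obs, dtype=float)
    if med.size < 10:
        raise ValueError("need at least 10 genes to fit the expected-MAD trend")
    return loess_fit(np.log1p(med), obs, span=cfg.loess_span, degree=cfg.loess_degree)


def compute_ev(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    size_factors: pd.Series,
    retained_genes,
    cfg: EVConfig,
    groups=None,
    doses=None,
) -> pd.DataFrame:
    """EV table per gene x donor group x dose for the retained genes.

    ``retained_genes`` is either a sequence of gene ids (same universe at
    every dose) or a mapping ``dose -> sequence`` (per-dose universes, as
    produced by the bimodality filter).  Strata are processed
    independently: median expression and bootstrap MAD come from the
    stratum's samples, and the loess trend is fitted within the stratum.
    """
    cfg.validate()
    groups = list(groups) if groups is not None else sorted(metadata["donor_group"].unique())
    doses = list(doses) if doses is not None else sorted(metadata["dose"].unique())
    per_dose = isinstance(retained_genes, dict)

    norm = counts / size_factors.reindex(counts.columns)
    records = []
    for dose in doses:
        genes = list(retained_genes[dose]) if per_dose else list(retained_genes)
        for grp in groups:
            sel = metadata.index[(metadata["donor_group"] == grp) & (metadata["dose"] == dose)]
            sel = [s for s in sel if s in norm.columns]
            if len(sel) < 4:
                raise ValueError(f"stratum group={grp!r} dose={dose!r} has fewer than 4 samples")
            block = norm.loc[genes, sel].to_numpy()
            med = np.median(block, axis=1)
            seqs = [derive_seedseq(cfg.seed, "ev", grp, dose, gid) for gid in genes]
            mad_obs = _bootstrap_mad_matrix(block, cfg.B, cfg.mad_constant, seqs)
            mad_pred = fit_expected_mad(med, mad_obs, cfg)
            records.append(
                pd.DataFrame(
                    {
                        "gene_id": genes,
                        "group": grp,
                        "dose": dose,
                        "median_expr": med,
                        "mad_obs": mad_obs,
                        "mad_pred": mad_pred,
                        "ev": mad_obs - mad_pred,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)
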