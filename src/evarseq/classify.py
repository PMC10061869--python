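"""Hypo-/non-/hyper-variable gene classification with cross-validation.

Classification is anchored in the reference donor group: the interval

    [median_EV_ref - k * MAD_EV_ref,  median_EV_ref + k * MAD_EV_ref]

is estimated per dose from the reference group's EV values (MAD_EV as
the median of B bootstrap iterations, k = 3 by default) and applied to
every donor group at that dose.  EV below the interval -> hypo, above ->
hyper, inside or on a boundary -> non (closed interval, conservative).

Cross-validation repeats the complete classification pipeline R times on
random half-splits of every donor group: a repeat counts as a success
for a gene iff both halves reproduce the whole-data label.  Per gene a
one-sided binomial test against chance concordance (success probability
0.5) is computed, Benjamini-Hochberg adjusted per group x dose, and
labels that are not confirmed at the FDR threshold revert to
non-variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import derive_rng, derive_seedseq
from .ev import EVConfig, bootstrap_mad, compute_ev

__all__ = [
    "ClassificationThresholds",
    "reference_interval",
    "classify_ev",
    "classify_whole",
    "binomial_concordance_p",
    "bh_adjust",
    "crossvalidate",
]

LABELS = ("hypo", "non", "hyper")
LABEL_CODES = {"hypo": 1, "non": 2, "hyper": 3}


@dataclass
class ClassificationThresholds:
    dose: str
    ref_median_ev: float
    ref_mad_ev: float
    k: float = 3.0

    @property
    def interval(self) -> tuple[float, float]:
        return (
            self.ref_median_ev - self.k * self.ref_mad_ev,
            self.ref_median_ev + self.k * self.ref_mad_ev,
        )


def reference_interval(
    ev_ref,
    B: int = 1000,
    constant: float = 1.4826,
    k: float = 3.0,
    seed: int | np.random.Generator = 0,
    dose: str = "",
) -> ClassificationThresholds:
    """Interval median(EV_ref) +/- k * bootstrap-MAD(EV_ref)."""
    x = np.asarray(ev_ref, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 reference EV values")
    return ClassificationThresholds(
        dose=dose,
        ref_median_ev=float(np.median(x)),
        ref_mad_ev=bootstrap_mad(x, B=B, constant=constant, seed=seed),
        k=k,
    )


def classify_ev(ev, thresholds: ClassificationThresholds):
    """Vectorized label assignment; boundary values map to 'non'."""
    lo, hi = thresholds.interval
    arr = np.asarray(ev, dtype=float)
    out = np.where(arr < lo, "hypo", np.where(arr > hi, "hyper", "non"))
    return out if arr.ndim else str(out)


def classify_whole(
    ev_table: pd.DataFrame,
    reference_group: str,
    B: int = 1000,
    constant: float = 1.4826,
    k: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, ClassificationThresholds]]:
    """Label every gene x group x dose of an EV table by the reference interval.

    Returns the table with a ``label`` column added, and the per-dose
    thresholds.
    """
    out = ev_table.copy()
    out["label"] = "non"
    thresholds = {}
    for dose, sub in ev_table.groupby("dose", sort=False):
        ref = sub.loc[sub["group"] == reference_group, "ev"]
        thr = reference_interval(
            ref, B=B, constant=constant, k=k,
            seed=np.random.default_rng(derive_seedseq(seed, "interval", dose)),
            dose=str(dose),
        )
        thresholds[str(dose)] = thr
        out.loc[sub.index, "label"] = classify_ev(sub["ev"].to_numpy(), thr)
    return out, thresholds


def binomial_concordance_p(successes: int, R: int) -> float:
    """One-sided tail P(X >= successes) for X ~ Binomial(R, 0.5)."""
    if not 0 <= successes <= R:
        raise ValueError("successes must be in [0, R]")
    return float(stats.binom.sf(successes - 1, R, 0.5))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _split_halves(samples: pd.DataFrame, rng: np.random.Generator, by_triplet: bool):
    """One random half-split of a dose stratum's sample table.

    With ``by_triplet`` the matched triplets are shuffled and divided, so
    a triplet's three donors land in the same half in every group;
    otherwise samples are split independently within each donor group.
    """
    if by_triplet and samples["triplet_id"].notna().all():
        trip = np.asarray(sorted(samples["triplet_id"].unique()))
        perm = rng.permutation(len(trip))
        half = len(trip) // 2
        first = set(trip[perm[:half]])
        m1 = samples["triplet_id"].isin(first)
        return samples.index[m1], samples.index[~m1]
    idx1, idx2 = [], []
    for _, sub in samples.groupby("donor_group", sort=False):
        ids = np.asarray(sub.index)
        perm = rng.permutation(len(ids))
        half = len(ids) // 2
        idx1.extend(ids[perm[:half]])
        idx2.extend(ids[perm[half:]])
    return pd.Index(idx1), pd.Index(idx2)


def crossvalidate(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    size_factors: pd.Series,
    retained_genes,
    cfg: EVConfig,
    reference_group: str = "N0",
    R: int = 10,
    k: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
    by_triplet: bool = True,
    pool_bh: bool = False,
    whole: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Split-half cross-validation of the hypo/non/hyper classification.

    Returns one row per gene x group x dose with the whole-data label,
    the concordance success count out of ``R``, the binomial and
    BH-adjusted p-values, and the confirmed label (unconfirmed labels
    revert to 'non').  ``whole`` may carry a precomputed whole-data
    labelled EV table (as from :func:`classify_whole`).
    """
    cfg.validate()
    groups = sorted(metadata["donor_group"].unique())
    doses = sorted(metadata["dose"].unique())
    per_dose = isinstance(retained_genes, dict)

    if whole is None:
        ev_whole = compute_ev(counts, metadata, size_factors, retained_genes, cfg,
                              groups=groups, doses=doses)
        whole, _ = classify_whole(ev_whole, reference_group, B=cfg.B,
                                  constant=cfg.mad_constant, k=k, seed=cfg.seed)
    whole_idx = whole.set_index(["gene_id", "group", "dose"])["label"]

    success_acc = pd.Series(0, index=whole_idx.index, dtype=int)

    for r in range(R):
        for dose in doses:
            genes = list(retained_genes[dose]) if per_dose else list(retained_genes)
            stratum = metadata[metadata["dose"] == dose]
            min_group = stratum.groupby("donor_group").size().min()
            if min_group < 8:
                raise ValueError(f"dose {dose!r}: groups too small to split in half")
            rng = derive_rng(seed, "cv-split", r, dose)
            idx1, idx2 = _split_halves(stratum, rng, by_triplet)
            labels_half = []
            for h, idx in enumerate((idx1, idx2)):
                half_meta = metadata.loc[idx]
                half_cfg = EVConfig(
                    B=cfg.B, mad_constant=cfg.mad_constant,
                    loess_span=cfg.loess_span, loess_degree=cfg.loess_degree,
                    seed=int(derive_seedseq(seed, "cv-ev", r, dose, h).generate_state(1)[0] & 0x7FFFFFFF),
                )
                ev_h = compute_ev(counts, half_meta, size_factors, genes, half_cfg,
                                  groups=groups, doses=[dose])
                labelled, _ = classify_whole(ev_h, reference_group, B=cfg.B,
                                             constant=cfg.mad_constant, k=k,
                                             seed=half_cfg.seed)
                labels_half.append(labelled.set_index(["gene_id", "group", "dose"])["label"])
            l1, l2 = labels_half
            ref = whole_idx.reindex(l1.index)
            ok = (l1.to_numpy() == l2.reindex(l1.index).to_numpy()) & (
                l1.to_numpy() == ref.to_numpy()
            )
            success_acc = success_acc.add(
                pd.Series(ok.astype(int), index=l1.index), fill_value=0
            ).astype(int)

    result = whole_idx.rename("label_whole").reset_index()
    result["successes"] = success_acc.reindex(whole_idx.index).to_numpy()
    result["p_binomial"] = stats.binom.sf(result["successes"].to_numpy() - 1, R, 0.5)
    if pool_bh:
        result["p_adjusted"] = bh_adjust(result["p_binomial"].to_numpy())
    else:
        result["p_adjusted"] = np.nan
        for _, idx in result.groupby(["group", "dose"], sort=False).groups.items():
            result.loc[idx, "p_adjusted"] = bh_adjust(result.loc[idx, "p_binomial"].to_numpy())
    confirmed = result["p_adjusted"] < alpha
    result["confirmed"] = confirmed
    result["label_confirmed"] = np.where(confirmed, result["label_whole"], "non")
    return result
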