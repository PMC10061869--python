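"""Synthetic RNA-seq count generator with known variability ground truth.

Emulates the statistical structure the EV analysis assumes: a matched
case-control design with three donor groups (a reference group of
cancer-free controls and two survivor groups), three radiation doses
applied to each donor's fibroblasts, negative-binomial counts with a
mean-dispersion trend ``phi(mu) = a/mu + b``, per-sample size factors,
and planted minorities of genes that are hyper-variable (inflated
dispersion in exactly one non-reference group), hypo-variable (deflated
dispersion), bimodally expressed (two-component log-mean mixture in all
groups), or differentially expressed (mean shift in one non-reference
group).

Counts for gene g in sample j are drawn as

    X_gj ~ NB(mean = s_j * mu_gj,  var = mean + phi_gj * mean^2)

so the gene-level variance identity ``var = mu + phi * mu^2`` holds at
``s_j = 1``.  Identical configuration and seed give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._rng import derive_rng

__all__ = ["SimConfig", "SimTruth", "simulate_counts", "subsample_columns"]


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the matched-triplet study design."""

    n_genes: int = 2000
    samples_per_group: int = 52
    groups: tuple[str, ...] = ("N0", "N1", "N2+")
    doses: tuple[str, ...] = ("0", "0.05", "2")
    mean_log_mu_range: tuple[float, float] = (np.log(20.0), np.log(2000.0))
    dispersion_trend: tuple[float, float] = (3.0, 0.05)
    frac_hyper: float = 0.05
    frac_hypo: float = 0.05
    effect_hyper: float = 8.0
    effect_hypo: float = 8.0
    frac_bimodal: float = 0.02
    bimodal_shift: float = 1.5
    frac_de: float = 0.05
    de_log_shift: float = 0.7
    effect_expr_quantile: float = 0.5
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.samples_per_group <= 0:
            raise ValueError("samples_per_group must be positive")
        if len(self.groups) < 1:
            raise ValueError("groups must be non-empty")
        for name in ("frac_hyper", "frac_hypo", "frac_bimodal", "frac_de"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.frac_hyper + self.frac_hypo + self.frac_bimodal + self.frac_de
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"frac_hyper + frac_hypo + frac_bimodal + frac_de must be <= 1, got {total}"
            )
        if self.effect_hyper <= 1.0:
            raise ValueError(f"effect_hyper must be > 1, got {self.effect_hyper}")
        if self.effect_hypo <= 1.0:
            raise ValueError(f"effect_hypo must be > 1, got {self.effect_hypo}")
        lo, hi = self.size_factor_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError(f"size_factor_range must be positive and ordered, got {self.size_factor_range}")
        lo, hi = self.mean_log_mu_range
        if hi < lo:
            raise ValueError(f"mean_log_mu_range must be ordered, got {self.mean_log_mu_range}")
        a, b = self.dispersion_trend
        if a < 0 or b < 0:
            raise ValueError(f"dispersion_trend coefficients must be non-negative, got {self.dispersion_trend}")
        if not 0.0 <= self.effect_expr_quantile < 1.0:
            raise ValueError(f"effect_expr_quantile must be in [0, 1), got {self.effect_expr_quantile}")
        return self


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``labels`` has one row per gene x group x dose with columns
    ``gene_id, group, dose, true_class, true_bimodal, true_de, true_phi``;
    ``genes`` has one row per gene with the baseline parameters, the kind
    of planted effect (if any), the affected group, and — for bimodal
    genes — an approximate true bimodality index on the log scale.
    """

    labels: pd.DataFrame
    genes: pd.DataFrame
    size_factors: pd.Series

    def write(self, labels_path, genes_path) -> None:
        self.labels.to_csv(labels_path, sep="\t", index=False)
        self.genes.to_csv(genes_path, sep="\t", index=False)


def _assign_effects(cfg: SimConfig, rng: np.random.Generator, log_mu: np.ndarray) -> pd.DataFrame:
    """Per-gene effect kind and affected group; counts are round(frac * n).

    Dispersion effects (hyper/hypo) are planted only in genes whose
    baseline log-mean lies above ``effect_expr_quantile`` of the
    configured range: an 8-fold dispersion change in a near-noise-floor
    gene is not identifiable at this design's sample size, so the
    planted truth is kept within the regime the method can resolve.
    Bimodal and DE effects are drawn from the remaining genes.
    """
    g = cfg.n_genes
    n_hyper = round(cfg.frac_hyper * g)
    n_hypo = round(cfg.frac_hypo * g)
    n_bimodal = round(cfg.frac_bimodal * g)
    n_de = round(cfg.frac_de * g)
    kinds = np.array(["none"] * g, dtype=object)

    lo, hi = cfg.mean_log_mu_range
    cut = lo + cfg.effect_expr_quantile * (hi - lo)
    expressed = np.flatnonzero(log_mu >= cut)
    if n_hyper + n_hypo > expressed.size:
        raise ValueError(
            "frac_hyper + frac_hypo exceeds the fraction of genes above "
            "effect_expr_quantile; lower the fractions or the quantile"
        )
    pick = rng.permutation(expressed)
    kinds[pick[:n_hyper]] = "hyper"
    kinds[pick[n_hyper : n_hyper + n_hypo]] = "hypo"

    rest = np.flatnonzero(kinds == "none")
    pick = rng.permutation(rest)
    kinds[pick[:n_bimodal]] = "bimodal"
    kinds[pick[n_bimodal : n_bimodal + n_de]] = "de"
    non_ref = [grp for grp in cfg.groups if grp != cfg.groups[0]] or list(cfg.groups)
    affected = np.array(
        [rng.choice(non_ref) if k in ("hyper", "hypo", "de") else "" for k in kinds],
        dtype=object,
    )
    de_sign = np.where(rng.random(g) < 0.5, -1.0, 1.0)
    return pd.DataFrame({"kind": kinds, "affected_group": affected, "de_sign": de_sign})


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw a counts matrix, its sample metadata, and the ground truth.

    Returns ``(counts, metadata, truth)``; columns are ordered by dose,
    then group, then matched triplet.
    """
    cfg = config
    cfg.validate()
    seed = cfg.seed
    g = cfg.n_genes
    npg = cfg.samples_per_group

    rng_genes = derive_rng(seed, "simulate", "genes")
    log_mu = rng_genes.uniform(*cfg.mean_log_mu_range, size=g)
    mu = np.exp(log_mu)
    a, b = cfg.dispersion_trend
    phi_base = a / mu + b

    effects = _assign_effects(cfg, derive_rng(seed, "simulate", "effects"), log_mu)
    gene_ids = np.array([f"g{i:05d}" for i in range(g)])

    rng_sf = derive_rng(seed, "simulate", "size_factors")
    rng_cov = derive_rng(seed, "simulate", "covariates")

    # donors: one per (triplet, group); covariates constant across doses
    triplets = [f"t{t:03d}" for t in range(npg)]
    sexes = {t: ("F" if i % 2 == 0 else "M") for i, t in enumerate(triplets)}
    donor_cov = {}
    for t in triplets:
        for grp in cfg.groups:
            donor_cov[(t, grp)] = (
                int(rng_cov.integers(0, 31)),  # smoking pack years
                int(rng_cov.integers(0, 5)),  # alcoholic beverages per day
            )

    sample_ids, meta_rows, size_factors = [], [], []
    for dose in cfg.doses:
        for grp in cfg.groups:
            for t in triplets:
                sid = f"{grp}_{dose}Gy_{t}"
                sample_ids.append(sid)
                pack, alc = donor_cov[(t, grp)]
                meta_rows.append((sid, grp, dose, t, sexes[t], pack, alc))
                size_factors.append(rng_sf.uniform(*cfg.size_factor_range))
    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "donor_group", "dose", "triplet_id", "sex", "smoking_pack_years", "alcohol_per_day"],
    ).set_index("sample_id")
    s = pd.Series(size_factors, index=sample_ids, name="size_factor")

    kinds = effects["kind"].to_numpy()
    affected = effects["affected_group"].to_numpy()
    de_sign = effects["de_sign"].to_numpy()
    is_bimodal = kinds == "bimodal"

    rng_counts = derive_rng(seed, "simulate", "counts")
    blocks = []
    labels_rows = []
    for dose in cfg.doses:
        for grp in cfg.groups:
            mean = np.tile(mu[:, None], (1, npg))
            phi = np.tile(phi_base[:, None], (1, npg))
            hyper_here = (kinds == "hyper") & (affected == grp)
            hypo_here = (kinds == "hypo") & (affected == grp)
            de_here = (kinds == "de") & (affected == grp)
            phi[hyper_here, :] *= cfg.effect_hyper
            phi[hypo_here, :] /= cfg.effect_hypo
            mean[de_here, :] *= np.exp(cfg.de_log_shift * de_sign[de_here])[:, None]
            if is_bimodal.any():
                comp = rng_counts.random((int(is_bimodal.sum()), npg)) < 0.5
                shift = np.where(comp, cfg.bimodal_shift / 2.0, -cfg.bimodal_shift / 2.0)
                mean[is_bimodal, :] *= np.exp(shift)
            cols = [f"{grp}_{dose}Gy_{t}" for t in triplets]
            sf = s[cols].to_numpy()[None, :]
            m = mean * sf
            r = 1.0 / phi
            p = r / (r + m)
            block = rng_counts.negative_binomial(r, p)
            blocks.append(pd.DataFrame(block, index=gene_ids, columns=cols))

            cls = np.where(hyper_here, "hyper", np.where(hypo_here, "hypo", "non"))
            labels_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_ids,
                        "group": grp,
                        "dose": dose,
                        "true_class": cls,
                        "true_bimodal": is_bimodal,
                        "true_de": de_here,
                        "true_phi": phi[:, 0],
                    }
                )
            )

    counts = pd.concat(blocks, axis=1).astype(np.int64)
    labels = pd.concat(labels_rows, ignore_index=True)

    # approximate log-scale bimodality index of planted bimodal genes:
    # component log-SD via the delta method, var(log X) ~ 1/m + phi
    sigma2 = 0.5 * (
        (1.0 / (mu * np.exp(cfg.bimodal_shift / 2)) + phi_base)
        + (1.0 / (mu * np.exp(-cfg.bimodal_shift / 2)) + phi_base)
    )
    true_bi = np.where(is_bimodal, 0.5 * cfg.bimodal_shift / np.sqrt(sigma2), np.nan)
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log_mu": log_mu,
            "phi_base": phi_base,
            "kind": kinds,
            "affected_group": affected,
            "de_sign": de_sign,
            "true_bi": true_bi,
        }
    )
    truth = SimTruth(labels=labels, genes=genes, size_factors=s)
    return counts, metadata, truth


def subsample_columns(
    counts: pd.DataFrame, metadata: pd.DataFrame, n: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform sample of ``n`` columns without replacement, metadata kept in step."""
    total = counts.shape[1]
    if n > total:
        raise ValueError(f"cannot subsample {n} columns from {total}")
    rng = derive_rng(seed, "subsample")
    keep = np.sort(rng.choice(total, size=n, replace=False))
    cols = counts.columns[keep]
    return counts[cols], metadata.loc[cols]


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
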