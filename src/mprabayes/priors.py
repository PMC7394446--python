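"""Empirical gamma priors for the per-variant count model.

The five parameter families of the model (barcode DNA concentrations,
ref and alt transcription multipliers, DNA dispersion, RNA dispersion)
each receive a Gamma(shape, rate) prior whose hyperparameters are fit
by maximum likelihood to the population of per-variant MLEs across the
assay.  Three estimation modes are available:

* marginal  — every variant in the assay weighted equally;
* grouped   — an independent prior per categorical annotation group;
* conditional — per-variant weights from a t-distribution kernel in
  (standardized) continuous annotation space, widened until the n-th
  most highly weighted variant reaches 1% of the top weight, so the
  prior is informed by a neighborhood rather than a single neighbor.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import AnnotationTable, CountTable
from .nb import MLEFit, fit_variant_mle
from .util import stable_seed

logger = logging.getLogger(__name__)

__all__ = [
    "GammaPrior",
    "PriorSet",
    "KernelConfig",
    "GammaFitError",
    "fit_gamma_mle",
    "collect_mles",
    "MLECollection",
    "estimate_marginal_priors",
    "estimate_grouped_priors",
    "conditional_weights",
    "estimate_conditional_prior",
    "estimate_conditional_priors",
]

PARAM_FAMILIES = ("mu_dna", "mu_rna_ref", "mu_rna_alt", "phi_dna", "phi_rna")


class GammaFitError(ValueError):
    """Gamma MLE is unavailable (too few values or degenerate data)."""


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior; mean = shape / rate."""

    shape: float
    rate: float

    def __post_init__(self):
        if not (np.isfinite(self.shape) and np.isfinite(self.rate)
                and self.shape > 0 and self.rate > 0):
            raise ValueError("gamma shape and rate must be positive and finite")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def logpdf(self, value):
        return stats.gamma.logpdf(value, self.shape, scale=1.0 / self.rate)

    def rvs(self, size=None, rng=None):
        rng = rng or np.random.default_rng()
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)


@dataclass(frozen=True)
class PriorSet:
    """One GammaPrior per parameter family, with provenance."""

    mu_dna: GammaPrior
    mu_rna_ref: GammaPrior
    mu_rna_alt: GammaPrior
    phi_dna: GammaPrior
    phi_rna: GammaPrior
    provenance: str = "marginal"

    def family(self, name: str) -> GammaPrior:
        return getattr(self, name)

    def shape_rate_vectors(self, n_barcodes: int):
        """(shapes, rates) aligned with the log-parameter vector layout."""
        b = n_barcodes
        shapes = np.empty(b + 5)
        rates = np.empty(b + 5)
        shapes[:b], rates[:b] = self.mu_dna.shape, self.mu_dna.rate
        for i, fam in enumerate([self.mu_rna_ref, self.mu_rna_alt, self.phi_dna,
                                 self.phi_rna, self.phi_rna]):
            shapes[b + i], rates[b + i] = fam.shape, fam.rate
        return shapes, rates

    def log_prior_and_grad(self, x: np.ndarray, n_barcodes: int):
        """Log prior density (with log-scale Jacobian) and gradient.

        ``x`` are log-parameters, possibly batched (..., B + 5).  For
        theta = exp(x) ~ Gamma(a, b) the log density on the x scale is
        a*x - b*exp(x) + a*log(b) - lgamma(a).
        """
        x = np.asarray(x, dtype=float)
        shapes, rates = self.shape_rate_vectors(n_barcodes)
        ex = np.exp(x)
        const = float(np.sum(shapes * np.log(rates) - special.gammaln(shapes)))
        lp = np.sum(shapes * x - rates * ex, axis=-1) + const
        grad = shapes - rates * ex
        return lp, grad

    def to_dict(self) -> dict:
        d = {fam: {"shape": self.family(fam).shape, "rate": self.family(fam).rate}
             for fam in PARAM_FAMILIES}
        d["provenance"] = self.provenance
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSet":
        kwargs = {fam: GammaPrior(**d[fam]) for fam in PARAM_FAMILIES}
        return cls(provenance=d.get("provenance", "marginal"), **kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PriorSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class KernelConfig:
    """Adaptive t-kernel settings for the conditional prior."""

    n_top: int = 100
    weight_floor_ratio: float = 0.01
    df: float = 3.0
    grid_factor: float = 1.1

    def __post_init__(self):
        if self.n_top < 2:
            raise ValueError("n_top must be >= 2")
        if not 0 < self.weight_floor_ratio < 1:
            raise ValueError("weight_floor_ratio must lie in (0, 1)")
        if self.df <= 0 or self.grid_factor <= 1:
            raise ValueError("df must be > 0 and grid_factor > 1")


# ---------------------------------------------------------------------------
# Weighted gamma maximum likelihood
# ---------------------------------------------------------------------------

def fit_gamma_mle(values, weights=None, min_values: int = 10) -> GammaPrior:
    """Weighted gamma MLE via Newton iteration on the shape.

    Profiling out the rate (b = a / weighted mean) reduces the problem
    to solving log(a) - digamma(a) = log(wmean) - wmeanlog; the Minka
    approximation provides the starting point.
    """
    v = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != v.shape or np.any(w < 0):
            raise ValueError("weights must be non-negative and match values")
    keep = w > 0
    if np.any(v[keep] <= 0) or not np.all(np.isfinite(v[keep])):
        raise ValueError("values with positive weight must be positive and finite")
    if len(v) < min_values or not np.any(keep):
        raise GammaFitError(
            f"need >= {min_values} values with positive total weight "
            f"(got {len(v)}); fall back to the marginal prior"
        )
    v, w = v[keep], w[keep]
    wsum = w.sum()
    m = float(np.dot(w, v) / wsum)
    mlog = float(np.dot(w, np.log(v)) / wsum)
    s = np.log(m) - mlog
    if s <= 1e-10:
        raise GammaFitError("degenerate data: values are (near-)constant, shape diverges")

    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(100):
        f = np.log(a) - special.digamma(a) - s
        fp = 1.0 / a - special.polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-12 * max(1.0, a):
            a = a_new
            break
        a = a_new
    return GammaPrior(shape=float(a), rate=float(a / m))


# ---------------------------------------------------------------------------
# The per-variant MLE population that priors are fit to
# ---------------------------------------------------------------------------

@dataclass
class MLECollection:
    """Per-variant MLE fits plus tabular views used by prior estimation."""

    fits: dict                      # variant_id -> MLEFit

    def __post_init__(self):
        rows = []
        for vid, f in self.fits.items():
            rows.append({
                "variant_id": vid,
                "mu_ref": f.params.mu_allele[0],
                "mu_alt": f.params.mu_allele[1],
                "phi_dna": f.params.phi_dna,
                "phi_rna_ref": f.params.phi_allele[0],
                "phi_rna_alt": f.params.phi_allele[1],
                "ts": f.ts,
                "converged": f.converged,
                "boundary": f.boundary,
                "usable": f.usable,
            })
        self.variants = pd.DataFrame(rows).set_index("variant_id").sort_index()

    @property
    def usable_ids(self) -> list[str]:
        return list(self.variants.index[self.variants["usable"]])

    def family_values(self, ids=None):
        """Values per parameter family over the given (usable) variants."""
        ids = list(ids) if ids is not None else self.usable_ids
        sub = self.variants.loc[ids]
        mu_dna = np.concatenate([self.fits[v].params.mu_dna for v in ids]) if ids else np.array([])
        return {
            "mu_dna": mu_dna,
            "mu_rna_ref": sub["mu_ref"].to_numpy(),
            "mu_rna_alt": sub["mu_alt"].to_numpy(),
            "phi_dna": sub["phi_dna"].to_numpy(),
            "phi_rna": np.concatenate([sub["phi_rna_ref"].to_numpy(),
                                       sub["phi_rna_alt"].to_numpy()]),
        }

    def barcode_counts(self, ids) -> np.ndarray:
        return np.array([self.fits[v].n_barcodes for v in ids], dtype=int)


def collect_mles(table, depths: pd.Series | None = None, n_starts: int = 3,
                 seed: int = 0) -> MLECollection:
    """Fit the likelihood component for every variant in the assay.

    ``table`` is a CountTable (with ``depths``) or an iterable of
    already-extracted per-variant data.
    """
    fits = {}
    data_iter = table.iter_variant_data(depths) if isinstance(table, CountTable) else table
    for data in data_iter:
        try:
            fits[data.variant_id] = fit_variant_mle(
                data, n_starts=n_starts, seed=stable_seed(seed, data.variant_id)
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("MLE failed for %s: %s", data.variant_id, exc)
    if not fits:
        raise GammaFitError("no variant MLEs available")
    return MLECollection(fits)


# ---------------------------------------------------------------------------
# Marginal and grouped priors
# ---------------------------------------------------------------------------

def _fit_priorset(values: dict, weights: dict | None = None, provenance: str = "marginal") -> PriorSet:
    kwargs = {}
    for fam in PARAM_FAMILIES:
        w = None if weights is None else weights[fam]
        kwargs[fam] = fit_gamma_mle(values[fam], w)
    return PriorSet(provenance=provenance, **kwargs)


def estimate_marginal_priors(mles: MLECollection) -> PriorSet:
    """One PriorSet shared by every variant: all usable MLEs weighted equally."""
    return _fit_priorset(mles.family_values(), provenance="marginal")


def estimate_grouped_priors(
    mles: MLECollection,
    groups: pd.Series,
    min_group: int = 10,
    marginal: PriorSet | None = None,
) -> dict:
    """Independent PriorSet per categorical group; undersized groups fall back."""
    if marginal is None:
        marginal = estimate_marginal_priors(mles)
    usable = set(mles.usable_ids)
    out = {}
    for label, ids in groups.groupby(groups).groups.items():
        ids = sorted(set(ids) & usable)
        if len(ids) < min_group:
            warnings.warn(
                f"group {label!r} has {len(ids)} usable variants (< {min_group}); "
                "using the marginal prior",
                stacklevel=2,
            )
            out[label] = PriorSet(provenance=f"grouped:{label} (marginal fallback)",
                                  **{f: marginal.family(f) for f in PARAM_FAMILIES})
            continue
        out[label] = _fit_priorset(mles.family_values(ids), provenance=f"grouped:{label}")
    return out


# ---------------------------------------------------------------------------
# Conditional (annotation-kernel) priors
# ---------------------------------------------------------------------------

@dataclass
class KernelWeights:
    weights: np.ndarray      # normalized so the maximum weight is 1
    sigma: float             # the selected kernel scale
    grid_factor: float


def _kernel_weights_at(distances: np.ndarray, sigma: float, df: float) -> np.ndarray:
    return stats.t.pdf(distances / sigma, df) / stats.t.pdf(0.0, df)


def kernel_rule_holds(distances: np.ndarray, sigma: float, cfg: KernelConfig) -> bool:
    """True if the n_top-th largest weight is >= floor_ratio * the largest."""
    w = _kernel_weights_at(distances, sigma, cfg.df)
    w_sorted = np.sort(w)[::-1]
    return w_sorted[cfg.n_top - 1] >= cfg.weight_floor_ratio * w_sorted[0]


def conditional_weights(
    target_annotation: np.ndarray,
    annotations: np.ndarray,
    cfg: KernelConfig = KernelConfig(),
) -> KernelWeights:
    """Adaptive t-kernel weights over variants for one target variant.

    The kernel scale starts from the median annotation distance and is
    moved along a geometric grid (factor ``cfg.grid_factor``) to the
    smallest grid scale at which the n_top-th largest weight is at
    least ``weight_floor_ratio`` times the largest.  Variants with
    non-finite annotations receive weight 0.
    """
    ann = np.atleast_2d(np.asarray(annotations, dtype=float))
    if ann.shape[0] == 1 and ann.shape[1] > 1 and np.ndim(annotations) == 1:
        ann = ann.T
    target = np.atleast_1d(np.asarray(target_annotation, dtype=float))
    finite = np.isfinite(ann).all(axis=1)
    if not finite.all():
        warnings.warn(
            f"{int((~finite).sum())} variants with non-finite annotations "
            "excluded from kernel weighting",
            stacklevel=2,
        )
    n_finite = int(finite.sum())
    if n_finite < cfg.n_top + 1:
        raise ValueError(f"need at least n_top+1={cfg.n_top + 1} annotated variants, got {n_finite}")

    d = np.full(ann.shape[0], np.nan)
    d[finite] = np.sqrt(((ann[finite] - target) ** 2).sum(axis=1))
    d_fin = d[finite]
    positive = d_fin[d_fin > 0]
    if positive.size == 0:
        warnings.warn("all annotations identical; using uniform weights", stacklevel=2)
        w = np.where(finite, 1.0, 0.0)
        return KernelWeights(weights=w, sigma=np.inf, grid_factor=cfg.grid_factor)

    sigma0 = float(np.median(positive))
    f = cfg.grid_factor
    sigma_floor = 1e-9 * sigma0
    sigma = sigma0
    if kernel_rule_holds(d_fin, sigma, cfg):
        # walk down the grid to the smallest scale still satisfying the rule
        while sigma / f > sigma_floor and kernel_rule_holds(d_fin, sigma / f, cfg):
            sigma /= f
    else:
        for _ in range(2000):
            sigma *= f
            if kernel_rule_holds(d_fin, sigma, cfg):
                break
        else:  # pragma: no cover - unreachable for t kernels
            raise RuntimeError("kernel widening did not terminate")

    w = np.zeros(ann.shape[0])
    w[finite] = _kernel_weights_at(d_fin, sigma, cfg.df)
    w /= w.max()
    return KernelWeights(weights=w, sigma=float(sigma), grid_factor=f)


def standardize_annotations(ann: np.ndarray) -> np.ndarray:
    """Z-score each annotation dimension over its finite values."""
    ann = np.atleast_2d(np.asarray(ann, dtype=float))
    if ann.shape[0] == 1 and np.ndim(np.asarray(ann)) == 1:
        ann = ann.T
    out = ann.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        fin = np.isfinite(col)
        mu = col[fin].mean()
        sd = col[fin].std()
        out[fin, j] = (col[fin] - mu) / (sd if sd > 0 else 1.0)
    return out


def estimate_conditional_prior(
    variant_id: str,
    mles: MLECollection,
    annotations: AnnotationTable,
    cfg: KernelConfig = KernelConfig(),
    _prepared=None,
) -> PriorSet:
    """Kernel-weighted PriorSet for one variant (its own weight included)."""
    ids, ann_std, values = _prepared if _prepared is not None else _prepare_conditional(
        mles, annotations
    )
    try:
        idx = ids.index(variant_id)
    except ValueError:
        raise KeyError(f"{variant_id!r} has no usable MLE / annotation") from None
    if not np.isfinite(ann_std[idx]).all():
        warnings.warn(
            f"target {variant_id!r} has non-finite annotations; using marginal prior",
            stacklevel=2,
        )
        ps = estimate_marginal_priors(mles)
        return PriorSet(provenance=f"conditional:{variant_id} (marginal fallback)",
                        **{f: ps.family(f) for f in PARAM_FAMILIES})
    kw = conditional_weights(ann_std[idx], ann_std, cfg)
    w = kw.weights
    bc_counts = mles.barcode_counts(ids)
    weights = {
        "mu_dna": np.repeat(w, bc_counts),
        "mu_rna_ref": w,
        "mu_rna_alt": w,
        "phi_dna": w,
        "phi_rna": np.concatenate([w, w]),
    }
    return _fit_priorset(values, weights, provenance=f"conditional:{variant_id}")


def _prepare_conditional(mles: MLECollection, annotations: AnnotationTable):
    if annotations.kind != "continuous":
        raise ValueError("conditional priors require continuous annotations")
    ids = mles.usable_ids
    raw = annotations.frame.reindex(ids).to_numpy(dtype=float)
    ann_std = standardize_annotations(raw)
    values = mles.family_values(ids)
    return ids, ann_std, values


def estimate_conditional_priors(
    mles: MLECollection,
    annotations: AnnotationTable,
    cfg: KernelConfig = KernelConfig(),
) -> dict:
    """Conditional PriorSet for every usable variant (shared preprocessing)."""
    prepared = _prepare_conditional(mles, annotations)
    out = {}
    for vid in prepared[0]:
        out[vid] = estimate_conditional_prior(vid, mles, annotations, cfg, _prepared=prepared)
    return out
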