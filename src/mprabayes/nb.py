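"""Negative-binomial probability machinery for barcode-level MPRA counts.

The count model for one variant with B barcodes is

    DNA counts:  Counts[s, bc] ~ NB(mean = d_s * mu_dna[bc],             dispersion = phi_dna)
    RNA counts:  Counts[s, bc] ~ NB(mean = d_s * mu_dna[bc] * mu_allele, dispersion = phi_allele)

with the mean-dispersion parameterization Var = mu + mu^2 / phi (larger
phi means closer to Poisson).  ``mu_dna[bc]`` is the unknown input
concentration of barcode ``bc`` in the plasmid library, ``mu_allele`` is
the transcription-rate multiplier of the barcode's allele, and ``d_s``
is the depth factor of sample ``s``.

All likelihood computations are carried out on log-transformed
parameters and support batched evaluation (leading axes on the
parameter vector), which the HMC sampler exploits to advance all chains
in lock-step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

try:  # compiled inner loops; the numpy reference path below stays authoritative
    from . import _kernels

    HAVE_KERNELS = True
except ImportError:  # pragma: no cover
    _kernels = None
    HAVE_KERNELS = False

__all__ = [
    "VariantData",
    "VariantParameters",
    "MLEFit",
    "nb_log_pmf",
    "variant_log_likelihood",
    "loglik_and_grad",
    "fit_variant_mle",
]

# Box bounds for log-parameters during optimization; exp(13.8) ~ 1e6.
LOG_BOUND = 13.815510557964274


@dataclass(frozen=True)
class VariantData:
    """Counts, allele labels, and depth factors for a single variant.

    ``dna`` and ``rna`` are (B, S) float arrays of counts (one row per
    barcode); ``alt`` marks the barcodes carrying the alternate allele;
    ``d_dna``/``d_rna`` are the per-sample depth factors.
    """

    variant_id: str
    dna: np.ndarray
    rna: np.ndarray
    alt: np.ndarray
    d_dna: np.ndarray
    d_rna: np.ndarray

    def __post_init__(self) -> None:
        if self.dna.shape[0] != self.rna.shape[0] or self.dna.shape[0] != self.alt.shape[0]:
            raise ValueError("barcode dimension mismatch between dna, rna and alt")
        if self.dna.shape[1] != self.d_dna.shape[0]:
            raise ValueError("DNA sample dimension mismatch with depth factors")
        if self.rna.shape[1] != self.d_rna.shape[0]:
            raise ValueError("RNA sample dimension mismatch with depth factors")
        if not (self.alt.any() and (~self.alt).any()):
            raise ValueError(f"variant {self.variant_id!r} lacks barcodes for one allele")
        # contiguous copies + data constants for the compiled kernels
        object.__setattr__(self, "dna", np.ascontiguousarray(self.dna, dtype=float))
        object.__setattr__(self, "rna", np.ascontiguousarray(self.rna, dtype=float))
        object.__setattr__(self, "alt", np.ascontiguousarray(self.alt, dtype=bool))
        object.__setattr__(self, "d_dna", np.ascontiguousarray(self.d_dna, dtype=float))
        object.__setattr__(self, "d_rna", np.ascontiguousarray(self.d_rna, dtype=float))
        object.__setattr__(self, "_alt_u8", self.alt.astype(np.uint8))
        lgk1 = float(special.gammaln(self.dna + 1).sum() + special.gammaln(self.rna + 1).sum())
        object.__setattr__(self, "_lgk1", lgk1)

    @property
    def n_barcodes(self) -> int:
        return self.dna.shape[0]

    @property
    def n_params(self) -> int:
        # B barcode concentrations + mu_ref, mu_alt, phi_dna, phi_rna_ref, phi_rna_alt
        return self.n_barcodes + 5


@dataclass
class VariantParameters:
    """Natural-scale parameters of the per-variant count model."""

    mu_dna: np.ndarray          # (B,) expected DNA count per barcode in a depth-1 sample
    mu_allele: np.ndarray       # (2,) RNA/DNA multiplier for (ref, alt)
    phi_dna: float
    phi_allele: np.ndarray      # (2,) RNA dispersion for (ref, alt)

    def __post_init__(self) -> None:
        self.mu_dna = np.asarray(self.mu_dna, dtype=float)
        self.mu_allele = np.asarray(self.mu_allele, dtype=float)
        self.phi_allele = np.asarray(self.phi_allele, dtype=float)
        if not (
            np.all(self.mu_dna > 0)
            and np.all(self.mu_allele > 0)
            and self.phi_dna > 0
            and np.all(self.phi_allele > 0)
        ):
            raise ValueError("all variant parameters must be strictly positive")

    def to_vector(self) -> np.ndarray:
        """Pack into the log-parameter vector used by optimizers/samplers."""
        return np.concatenate(
            [
                np.log(self.mu_dna),
                np.log(self.mu_allele),
                [np.log(self.phi_dna)],
                np.log(self.phi_allele),
            ]
        )

    @classmethod
    def from_vector(cls, x: np.ndarray, n_barcodes: int) -> "VariantParameters":
        x = np.asarray(x, dtype=float)
        b = n_barcodes
        return cls(
            mu_dna=np.exp(x[:b]),
            mu_allele=np.exp(x[b : b + 2]),
            phi_dna=float(np.exp(x[b + 2])),
            phi_allele=np.exp(x[b + 3 : b + 5]),
        )

    @property
    def ts(self) -> float:
        """Transcription shift log(mu_alt) - log(mu_ref)."""
        return float(np.log(self.mu_allele[1]) - np.log(self.mu_allele[0]))


def nb_log_pmf(count, mean, dispersion):
    """Log pmf of the negative binomial with E = mean, Var = mean + mean^2/dispersion.

    Vectorized over all arguments.  Equivalent to
    ``scipy.stats.nbinom.logpmf(count, dispersion, dispersion/(dispersion+mean))``.
    """
    k = np.asarray(count, dtype=float)
    m = np.asarray(mean, dtype=float)
    phi = np.asarray(dispersion, dtype=float)
    if np.any(m <= 0) or np.any(phi <= 0):
        raise ValueError("mean and dispersion must be strictly positive")
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ValueError("counts must be non-negative integers")
    return (
        special.gammaln(k + phi)
        - special.gammaln(phi)
        - special.gammaln(k + 1)
        + phi * np.log(phi)
        + special.xlogy(k, m)
        - (k + phi) * np.log(phi + m)
    )


def _unpack(x: np.ndarray, data: VariantData):
    """Split a (possibly batched) log-parameter array into natural-scale pieces."""
    b = data.n_barcodes
    mu = np.exp(x[..., :b])                               # (..., B)
    mu_ref = np.exp(x[..., b])
    mu_alt = np.exp(x[..., b + 1])
    phi_d = np.exp(x[..., b + 2])
    phi_ref = np.exp(x[..., b + 3])
    phi_alt = np.exp(x[..., b + 4])
    alt = data.alt
    mu_al = np.where(alt, mu_alt[..., None], mu_ref[..., None])      # (..., B)
    phi_r = np.where(alt, phi_alt[..., None], phi_ref[..., None])    # (..., B)
    return mu, mu_ref, mu_alt, phi_d, phi_ref, phi_alt, mu_al, phi_r


def loglik_and_grad(x: np.ndarray, data: VariantData):
    """Log-likelihood and its gradient w.r.t. the log-parameter vector.

    ``x`` may have leading batch axes: shape (..., B + 5).  Returns
    (loglik with shape (...,), grad with shape x.shape).  Dispatches to
    the compiled kernel when available; ``loglik_and_grad_reference``
    is the plain-numpy implementation the kernel is checked against.
    """
    x = np.asarray(x, dtype=float)
    if HAVE_KERNELS:
        batch_shape = x.shape[:-1]
        x2 = np.ascontiguousarray(x.reshape(-1, x.shape[-1]))
        ll = np.empty(x2.shape[0])
        grad = np.empty_like(x2)
        _kernels.loglik_grad(
            x2, data.dna, data.rna, data.d_dna, data.d_rna,
            data._alt_u8, data._lgk1, ll, grad,
        )
        return ll.reshape(batch_shape), grad.reshape(x.shape)
    return loglik_and_grad_reference(x, data)


def loglik_and_grad_reference(x: np.ndarray, data: VariantData):
    """Plain-numpy log-likelihood and gradient (batched)."""
    x = np.asarray(x, dtype=float)
    # Overflow/divide warnings are expected for the extreme points an
    # unconstrained sampler may propose; such points get ll = -inf below.
    with np.errstate(all="ignore"):
        return _loglik_and_grad_impl(x, data)


def _loglik_and_grad_impl(x: np.ndarray, data: VariantData):
    b = data.n_barcodes
    mu, _, _, phi_d, _, _, mu_al, phi_r = _unpack(x, data)

    grad = np.zeros_like(x)
    ll = np.zeros(x.shape[:-1])

    # ---- DNA terms: mean m = mu[bc] * d_s, dispersion phi_dna --------
    if data.dna.shape[1]:
        m = mu[..., :, None] * data.d_dna                 # (..., B, Sd)
        k = data.dna
        phi = phi_d[..., None, None]
        kp = k + phi
        pm = phi + m
        ll += np.sum(
            special.gammaln(kp)
            - special.gammaln(phi)
            - special.gammaln(k + 1)
            + phi * np.log(phi)
            + special.xlogy(k, m)
            - kp * np.log(pm),
            axis=(-1, -2),
        )
        a_score = k - m * kp / pm                          # d ll / d log(mean)
        grad[..., :b] += a_score.sum(axis=-1)
        dphi = (
            special.digamma(kp)
            - special.digamma(phi)
            + np.log(phi)
            + 1.0
            - np.log(pm)
            - kp / pm
        )
        grad[..., b + 2] = phi_d * dphi.sum(axis=(-1, -2))

    # ---- RNA terms: mean m = mu[bc] * mu_allele * d_s, dispersion phi_allele
    if data.rna.shape[1]:
        m = (mu * mu_al)[..., :, None] * data.d_rna        # (..., B, Sr)
        k = data.rna
        phi = phi_r[..., :, None]
        kp = k + phi
        pm = phi + m
        ll += np.sum(
            special.gammaln(kp)
            - special.gammaln(phi)
            - special.gammaln(k + 1)
            + phi * np.log(phi)
            + special.xlogy(k, m)
            - kp * np.log(pm),
            axis=(-1, -2),
        )
        a_score = (k - m * kp / pm).sum(axis=-1)           # (..., B)
        grad[..., :b] += a_score
        grad[..., b] = np.sum(a_score, axis=-1, where=~data.alt)
        grad[..., b + 1] = np.sum(a_score, axis=-1, where=data.alt)
        dphi = (
            special.digamma(kp)
            - special.digamma(phi)
            + np.log(phi)
            + 1.0
            - np.log(pm)
            - kp / pm
        ) * phi
        dphi_bc = dphi.sum(axis=-1)                        # (..., B)
        grad[..., b + 3] = np.sum(dphi_bc, axis=-1, where=~data.alt)
        grad[..., b + 4] = np.sum(dphi_bc, axis=-1, where=data.alt)

    ll = np.where(np.isfinite(ll), ll, -np.inf)
    return ll, grad


def variant_log_likelihood(params: VariantParameters, data: VariantData) -> float:
    """Joint log-likelihood of one variant's DNA and RNA counts."""
    if params.mu_dna.shape[0] != data.n_barcodes:
        raise ValueError("mu_dna length must equal the variant's barcode count")
    ll, _ = loglik_and_grad(params.to_vector(), data)
    return float(ll)


def moment_start(data: VariantData) -> np.ndarray:
    """Method-of-moments starting point on the log scale."""
    b = data.n_barcodes
    x0 = np.empty(b + 5)
    if data.dna.shape[1]:
        adj_d = data.dna / data.d_dna
        mu0 = np.clip(adj_d.mean(axis=1), 0.5, None)
    else:
        mu0 = np.full(b, 1.0)
    x0[:b] = np.log(mu0)

    for j, mask in enumerate([~data.alt, data.alt]):
        if data.rna.shape[1]:
            adj_r = (data.rna / data.d_rna)[mask]
            ratio = adj_r.mean() / mu0[mask].mean()
            x0[b + j] = np.log(np.clip(ratio, 1e-3, 1e3))
        else:
            x0[b + j] = 0.0

    def _phi_mom(adj, mean_bc):
        if adj.shape[1] < 2:
            return 10.0
        v = adj.var(axis=1, ddof=1).mean()
        m = mean_bc.mean()
        return m * m / (v - m) if v > m else 10.0

    x0[b + 2] = np.log(
        np.clip(_phi_mom(data.dna / data.d_dna, mu0) if data.dna.shape[1] else 10.0, 0.1, 1e4)
    )
    for j, mask in enumerate([~data.alt, data.alt]):
        if data.rna.shape[1]:
            adj_r = (data.rna / data.d_rna)[mask]
            phi = _phi_mom(adj_r, mu0[mask] * np.exp(x0[b + j]))
        else:
            phi = 10.0
        x0[b + 3 + j] = np.log(np.clip(phi, 0.1, 1e4))
    return x0


@dataclass
class MLEFit:
    """Result of maximizing the per-variant likelihood."""

    variant_id: str
    params: VariantParameters
    x: np.ndarray                      # log-parameter vector at the optimum
    loglik: float
    converged: bool
    boundary: bool = False
    n_barcodes: int = 0

    @property
    def ts(self) -> float:
        return self.params.ts

    @property
    def usable(self) -> bool:
        """Whether this fit may enter the empirical-prior population."""
        return self.converged and not self.boundary


def fit_variant_mle(
    data: VariantData,
    n_starts: int = 3,
    seed: int | None = None,
    jitter_sd: float = 0.5,
) -> MLEFit:
    """Maximize the variant log-likelihood over log-parameters.

    Multi-start L-BFGS-B with analytic gradients; the first start is the
    method-of-moments point, further starts are jittered copies of it.
    Fits that end on the parameter box are flagged ``boundary`` and are
    excluded from empirical-prior estimation by the caller.
    """
    if data.dna.shape[1] < 1 or data.rna.shape[1] < 2:
        raise ValueError("MLE requires at least 1 DNA and 2 RNA samples")
    rng = np.random.default_rng(seed)
    x0 = moment_start(data)
    bounds = [(-LOG_BOUND, LOG_BOUND)] * data.n_params

    def objective(x):
        ll, g = loglik_and_grad(x, data)
        return -ll, -g

    best = None
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, jitter_sd, size=x0.shape)
        xs = np.clip(xs, -LOG_BOUND, LOG_BOUND)
        res = optimize.minimize(objective, xs, jac=True, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res

    xhat = np.asarray(best.x)
    boundary = bool(np.any(np.abs(xhat) > LOG_BOUND - 1e-3))
    return MLEFit(
        variant_id=data.variant_id,
        params=VariantParameters.from_vector(xhat, data.n_barcodes),
        x=xhat,
        loglik=float(-best.fun),
        converged=bool(best.success),
        boundary=boundary,
        n_barcodes=data.n_barcodes,
    )
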