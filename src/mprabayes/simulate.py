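"""Synthetic MPRA assays with known ground truth.

Counts are drawn from the same generative model the inference assumes:
per-barcode DNA concentrations and per-variant dispersions come from
gamma hyperpriors, a fraction of variants receives a nonzero
transcription shift, sample depths vary log-normally, and a small
fraction of barcodes drops out during library preparation (those rows
never appear in the table).  Defaults mirror a typical assay: 3000
variants, 5% functional, 10 barcodes per allele, 3 DNA and 5 RNA
samples.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountTable, validate_count_table

__all__ = ["SimConfig", "SimTruth", "simulate_assay", "simulation_grid"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth generative settings for one simulated assay."""

    n_variants: int = 3000
    frac_functional: float = 0.05
    barcodes_per_allele: int = 10
    n_dna_samples: int = 3
    n_rna_samples: int = 5
    # hyperpriors of the generative model
    mu_dna_shape: float = 5.0
    mu_dna_rate: float = 0.1          # mean DNA concentration ~ 50 counts at depth 1
    mu_allele_shape: float = 4.0
    mu_allele_rate: float = 4.0       # baseline transcription multiplier ~ 1
    phi_dna_shape: float = 10.0
    phi_dna_rate: float = 1.0         # dispersions ~ 10 (moderately overdispersed)
    phi_rna_shape: float = 10.0
    phi_rna_rate: float = 1.0
    # functional-effect distribution: |N(0, ts_sd^2)| truncated below at ts_min, random sign
    ts_sd: float = 0.5
    ts_min: float = 0.1
    # nuisance processes
    depth_log_sd: float = 0.3         # per-sample log-normal depth variation
    dropout: float = 0.05             # per-barcode library-prep failure probability
    barcode_length: int = 14
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.frac_functional <= 1 or not 0 <= self.dropout <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_variants < 1 or self.barcodes_per_allele < 1:
            raise ValueError("n_variants and barcodes_per_allele must be >= 1")
        for name in ("mu_dna_shape", "mu_dna_rate", "mu_allele_shape", "mu_allele_rate",
                     "phi_dna_shape", "phi_dna_rate", "phi_rna_shape", "phi_rna_rate",
                     "ts_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth_log_sd < 0:
            raise ValueError("depth_log_sd must be non-negative")


@dataclass
class SimTruth:
    """Everything the generator knows: the answer key for evaluation."""

    variants: pd.DataFrame       # variant_id, true_ts, functional, mu_ref, mu_alt, phis
    barcodes: pd.DataFrame       # variant_id, allele, barcode, mu_dna, dropped
    depths: pd.Series            # realized per-sample depth factors
    config: SimConfig


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list:
    seen: set = set()
    out = []
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out), length))
        for row in batch:
            bc = "".join(_BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def _draw_effects(n_functional: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """|N(0, ts_sd^2)| truncated below at ts_min, with Rademacher sign."""
    out = np.empty(n_functional)
    filled = 0
    while filled < n_functional:
        cand = np.abs(rng.normal(0.0, cfg.ts_sd, size=2 * (n_functional - filled) + 8))
        cand = cand[cand >= cfg.ts_min][: n_functional - filled]
        out[filled : filled + cand.size] = cand
        filled += cand.size
    signs = rng.choice([-1.0, 1.0], size=n_functional)
    return out * signs


def simulate_assay(cfg: SimConfig, seed: int | None = None) -> tuple[CountTable, SimTruth]:
    """Draw one assay from the generative model; returns counts plus the answer key."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    nv, bpa = cfg.n_variants, cfg.barcodes_per_allele
    vids = [f"var{i:05d}" for i in range(nv)]

    n_functional = int(round(cfg.frac_functional * nv))
    ts = np.zeros(nv)
    if n_functional:
        which = rng.choice(nv, size=n_functional, replace=False)
        ts[which] = _draw_effects(n_functional, cfg, rng)

    mu_ref = rng.gamma(cfg.mu_allele_shape, 1.0 / cfg.mu_allele_rate, size=nv)
    mu_alt = mu_ref * np.exp(ts)
    phi_dna = rng.gamma(cfg.phi_dna_shape, 1.0 / cfg.phi_dna_rate, size=nv)
    phi_rna = rng.gamma(cfg.phi_rna_shape, 1.0 / cfg.phi_rna_rate, size=(nv, 2))

    n_rows = nv * 2 * bpa
    mu_dna = rng.gamma(cfg.mu_dna_shape, 1.0 / cfg.mu_dna_rate, size=n_rows)
    dropped = rng.random(n_rows) < cfg.dropout

    d_dna = np.exp(rng.normal(0.0, cfg.depth_log_sd, size=cfg.n_dna_samples))
    d_rna = np.exp(rng.normal(0.0, cfg.depth_log_sd, size=cfg.n_rna_samples))
    depths = pd.Series(
        np.concatenate([d_dna, d_rna]),
        index=[f"dna{j}" for j in range(cfg.n_dna_samples)]
        + [f"rna{j}" for j in range(cfg.n_rna_samples)],
    )

    variant_col = np.repeat(vids, 2 * bpa)
    allele_col = np.tile(np.repeat(["ref", "alt"], bpa), nv)
    vidx = np.repeat(np.arange(nv), 2 * bpa)
    is_alt = allele_col == "alt"
    mu_allele_row = np.where(is_alt, mu_alt[vidx], mu_ref[vidx])
    phi_rna_row = np.where(is_alt, phi_rna[vidx, 1], phi_rna[vidx, 0])
    phi_dna_row = phi_dna[vidx]

    mean_dna = mu_dna[:, None] * d_dna[None, :]
    if np.nanmin(mean_dna) < 0.1:
        warnings.warn("expected DNA counts below 0.1; assay will be mostly zeros",
                      stacklevel=2)
    counts_dna = rng.negative_binomial(
        phi_dna_row[:, None], phi_dna_row[:, None] / (phi_dna_row[:, None] + mean_dna)
    )
    mean_rna = (mu_dna * mu_allele_row)[:, None] * d_rna[None, :]
    counts_rna = rng.negative_binomial(
        phi_rna_row[:, None], phi_rna_row[:, None] / (phi_rna_row[:, None] + mean_rna)
    )

    barcodes = _random_barcodes(n_rows, cfg.barcode_length, rng)
    frame = pd.DataFrame({"variant_id": variant_col, "allele": allele_col,
                          "barcode": barcodes})
    for j, sid in enumerate(depths.index[: cfg.n_dna_samples]):
        frame[sid] = counts_dna[:, j]
    for j, sid in enumerate(depths.index[cfg.n_dna_samples :]):
        frame[sid] = counts_rna[:, j]

    truth_variants = pd.DataFrame({
        "variant_id": vids,
        "true_ts": ts,
        "functional": ts != 0.0,
        "mu_ref": mu_ref,
        "mu_alt": mu_alt,
        "phi_dna": phi_dna,
        "phi_rna_ref": phi_rna[:, 0],
        "phi_rna_alt": phi_rna[:, 1],
    })
    truth_barcodes = pd.DataFrame({
        "variant_id": variant_col,
        "allele": allele_col,
        "barcode": barcodes,
        "mu_dna": mu_dna,
        "dropped": dropped,
    })

    kept = frame[~dropped].reset_index(drop=True)
    if kept.empty:
        raise ValueError("all barcodes dropped out; empty assay")
    sample_types = pd.Series(
        ["DNA"] * cfg.n_dna_samples + ["RNA"] * cfg.n_rna_samples, index=depths.index
    )
    table, _ = validate_count_table(kept, sample_types)
    truth = SimTruth(variants=truth_variants, barcodes=truth_barcodes,
                     depths=depths, config=cfg)
    return table, truth


def simulation_grid(grid: dict, base: SimConfig = SimConfig(), seed: int = 0,
                    replicates: int = 1):
    """Cartesian product of parameter lists, with deterministic seeds.

    ``grid`` maps SimConfig field names to lists of values; yields
    (SimConfig, seed) pairs, ``replicates`` per grid cell.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must map parameter names to non-empty lists")
    keys = sorted(grid)
    root = np.random.SeedSequence(seed)
    cells = list(itertools.product(*(grid[k] for k in keys)))
    children = root.spawn(len(cells) * replicates)
    i = 0
    for cell in cells:
        cfg = replace(base, **dict(zip(keys, cell)))
        for _ in range(replicates):
            yield cfg, int(children[i].generate_state(1)[0] % (2**31))
            i += 1
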