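"""Synthetic cohorts with the statistical structure the analysis assumes.

Counts are negative-binomial with variance ``mu + dispersion * mu**2``,
a per-sample log-normal library-size factor, and group-specific log2
fold-changes concentrated (by default) on ST8SIA1 and B4GALNT1. A pool of
uninformative background genes stands in for the lipid-metabolism null
pool, and a small generator produces replicated stained/unstained
flow-cytometry MFI records with a prescribed target RFI.

Everything is a pure function of its configuration, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .phenotyping import FlowRecord
from .signature import GANGLIOSIDE_PANEL

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_counts",
    "simulate_flow_records",
    "DEFAULT_PANEL_MEANS",
    "DEFAULT_LOG2_EFFECTS",
]

PANEL_GENES = GANGLIOSIDE_PANEL.genes

#: Baseline (negative-group) mean counts for the six panel genes. Free
#: choices, reported in output metadata; not estimates of any real cohort.
DEFAULT_PANEL_MEANS: dict[str, float] = {
    "ST3GAL5": 800.0,
    "ST8SIA1": 60.0,
    "ST8SIA5": 40.0,
    "B3GALT4": 250.0,
    "B4GALNT1": 50.0,
    "B4GALT6": 300.0,
}

#: Default group effect: signal only on the two GD2-proximal synthase genes.
DEFAULT_LOG2_EFFECTS: dict[str, float] = {"ST8SIA1": 2.0, "B4GALNT1": 2.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_pos: int = 50
    n_neg: int = 50
    panel_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_MEANS)
    )
    log2_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG2_EFFECTS)
    )
    dispersion: float | dict[str, float] = 0.1
    n_background: int = 520
    background_mean_range: tuple[float, float] = (20.0, 2000.0)
    libsize_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise InputError("n_pos and n_neg must both be >= 1")
        if self.n_background < 0:
            raise InputError("n_background must be >= 0")
        missing = [g for g in PANEL_GENES if g not in self.panel_means]
        if missing:
            raise InputError(f"panel_means missing panel gene(s): {missing}")
        if any(m <= 0 for m in self.panel_means.values()):
            raise InputError("panel means must be positive")
        if isinstance(self.dispersion, dict):
            if any(d < 0 for d in self.dispersion.values()):
                raise InputError("dispersions must be >= 0")
        elif self.dispersion < 0:
            raise InputError("dispersion must be >= 0")
        lo, hi = self.background_mean_range
        if not 0 < lo <= hi:
            raise InputError("background_mean_range must satisfy 0 < lo <= hi")
        if self.libsize_log_sd < 0:
            raise InputError("libsize_log_sd must be >= 0")

    def gene_dispersion(self, gene: str) -> float:
        if isinstance(self.dispersion, dict):
            return float(self.dispersion.get(gene, 0.0))
        return float(self.dispersion)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulatedDataset:
    """Counts, binary labels, the generating config, and the null-pool genes."""

    counts: pd.DataFrame
    labels: pd.Series  # sample id -> bool (True = GD2 positive)
    true_params: SimulationConfig
    pool_genes: tuple[str, ...]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw with variance mean + dispersion*mean^2 (Poisson at dispersion 0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(config: SimulationConfig) -> SimulatedDataset:
    """Draw a (panel + background) x (positive + negative) count matrix.

    Gene g in sample j is negative-binomial with mean
    ``L_j * mu_g * 2**(beta_g * I[j positive])`` where ``L_j`` is the
    sample's log-normal library-size factor. Identical config (seed
    included) reproduces the matrix bit-exactly.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_pos + config.n_neg
    sample_ids = [f"POS{i + 1:04d}" for i in range(config.n_pos)] + [
        f"NEG{i + 1:04d}" for i in range(config.n_neg)
    ]
    is_pos = np.array([True] * config.n_pos + [False] * config.n_neg)

    panel_genes = [g for g in PANEL_GENES] + [
        g for g in config.panel_means if g not in PANEL_GENES
    ]
    background_genes = [f"LMG{i + 1:04d}" for i in range(config.n_background)]
    clash = set(panel_genes) & set(background_genes)
    if clash:
        raise InputError(f"gene symbols shared by panel and background: {sorted(clash)}")
    genes = panel_genes + background_genes

    lo, hi = config.background_mean_range
    background_means = rng.uniform(lo, hi, size=config.n_background)
    base_means = np.concatenate(
        [np.array([config.panel_means[g] for g in panel_genes]), background_means]
    )
    log2_beta = np.array([config.log2_effects.get(g, 0.0) for g in genes])
    lib = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n_samples))

    mu = base_means[:, None] * lib[None, :] * np.power(
        2.0, log2_beta[:, None] * is_pos[None, :]
    )
    values = np.empty((len(genes), n_samples), dtype=np.int64)
    for i, gene in enumerate(genes):
        values[i] = _nb_draw(rng, mu[i], config.gene_dispersion(gene))

    counts = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)
    labels = pd.Series(is_pos, index=sample_ids, name="status")
    return SimulatedDataset(
        counts=counts,
        labels=labels,
        true_params=config,
        pool_genes=tuple(background_genes),
    )


def simulate_flow_records(
    cell_line_rfis: Mapping[str, float],
    n_replicates: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
    *,
    base_mfi: float = 100.0,
) -> list[FlowRecord]:
    """Replicated stained/unstained MFI readouts per cell line.

    Each replicate's stained/unstained ratio is the target RFI times a
    mean-one log-normal factor with coefficient of variation ``noise_cv``
    (exactly the target when ``noise_cv`` is 0); the unstained MFI gets an
    independent factor of the same kind.
    """
    if any(r <= 0 for r in cell_line_rfis.values()):
        raise InputError("target RFIs must be positive")
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    if noise_cv < 0:
        raise InputError("noise_cv must be >= 0")

    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    mu_log = -(sigma**2) / 2.0  # mean-one log-normal

    def factor() -> float:
        if noise_cv == 0:
            return 1.0
        return float(rng.lognormal(mu_log, sigma))

    records: list[FlowRecord] = []
    for cell_line, rfi in cell_line_rfis.items():
        for rep in range(1, n_replicates + 1):
            unstained = base_mfi * factor()
            stained = unstained * rfi * factor()
            records.append(
                FlowRecord(
                    cell_line=cell_line,
                    replicate=rep,
                    mfi_stained=stained,
                    mfi_unstained=unstained,
                )
            )
    return records
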